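"""Ground-truth atom labels for spectral peaks from excited-state records.

An X-ray transition promotes an electron from a core (1s-like) molecular
orbital into a virtual orbital. Each transition record carries the
excitation energy, oscillator strength, the contributing core/virtual
orbital pairs, and per-atom population decompositions of those orbitals.
For a chosen spectral peak, the atoms' contributions are the
oscillator-strength- and population-weighted sums over the peak's member
transitions, evaluated separately for the core and the virtual channel,
then max-normalized and binarized into 0/1 labels. These labels are the
reference against which CAM attributions are scored.

Transition records travel as JSON lines (one transition per object); see
:func:`read_transitions` for the schema. A converter from a quantum-
chemistry program's native output to this format is deliberately out of
scope — any backend that can emit energies, oscillator strengths and
orbital populations can produce these lines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .spectra import PeakRegion, StickSpectrum, assign_sticks_to_peak

DEFAULT_THETA = 0.1
_POP_TOL = 1e-6


class MissingPopulationError(KeyError):
    """A transition references an orbital with no population decomposition."""


class EmptyPeakError(ValueError):
    """A peak window contains no transitions."""


@dataclass
class TransitionRecord:
    """One excited state.

    ``pairs`` lists (core_mo_id, virtual_mo_id, weight) orbital-pair
    contributions; weights are normalized to sum to 1. ``mo_populations``
    maps orbital ids to per-atom population shares summing to 1.
    """

    state_id: str
    energy: float
    osc_strength: float
    pairs: list[tuple[str, str, float]]
    mo_populations: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.osc_strength < 0:
            raise ValueError(f"negative oscillator strength in {self.state_id}")
        total = sum(w for _, _, w in self.pairs)
        if total > 0 and abs(total - 1.0) > _POP_TOL:
            self.pairs = [(c, v, w / total) for c, v, w in self.pairs]
        for mo, pops in self.mo_populations.items():
            s = sum(pops.values())
            if abs(s - 1.0) > _POP_TOL:
                if s <= 0:
                    raise ValueError(f"orbital {mo} has non-positive population")
                warnings.warn(f"orbital {mo} populations sum to {s:.6g}; "
                              f"renormalizing", stacklevel=2)
                self.mo_populations[mo] = {a: p / s for a, p in pops.items()}

    def to_dict(self) -> dict:
        return {
            "state_id": self.state_id,
            "energy": self.energy,
            "osc_strength": self.osc_strength,
            "pairs": [{"core": c, "virtual": v, "weight": w}
                      for c, v, w in self.pairs],
            "mo_populations": {mo: {str(a): p for a, p in pops.items()}
                               for mo, pops in self.mo_populations.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionRecord":
        return cls(
            state_id=str(d["state_id"]),
            energy=float(d["energy"]),
            osc_strength=float(d["osc_strength"]),
            pairs=[(p["core"], p["virtual"], float(p["weight"]))
                   for p in d["pairs"]],
            mo_populations={mo: {int(a): float(p) for a, p in pops.items()}
                            for mo, pops in d["mo_populations"].items()},
        )


@dataclass
class GroundTruthLabels:
    """Continuous weights and binary labels per atom for one peak,
    separately for the core and the virtual orbital channel."""

    molecule_id: str
    peak: PeakRegion
    core_weights: np.ndarray
    virtual_weights: np.ndarray
    core_labels: np.ndarray
    virtual_labels: np.ndarray

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if name == "core":
            return self.core_weights, self.core_labels
        if name == "virtual":
            return self.virtual_weights, self.virtual_labels
        raise ValueError(f"unknown channel {name!r}")


def atom_weights(transitions: Sequence[TransitionRecord], channel: str,
                 n_atoms: int) -> np.ndarray:
    """Per-atom contribution weights for one orbital channel.

    ``w(a) = sum_s f_s * sum_pairs pair_weight * pop_a(MO)``, max-normalized
    to 1 when any weight is positive.
    """
    if channel not in ("core", "virtual"):
        raise ValueError(f"channel must be 'core' or 'virtual', got {channel!r}")
    if not transitions:
        raise ValueError("empty transition list")
    w = np.zeros(n_atoms)
    sel = 0 if channel == "core" else 1
    for t in transitions:
        for pair in t.pairs:
            mo = pair[sel]
            if mo not in t.mo_populations:
                raise MissingPopulationError(
                    f"no population decomposition for orbital {mo!r} "
                    f"referenced by state {t.state_id}")
            for a, p in t.mo_populations[mo].items():
                w[a] += t.osc_strength * pair[2] * p
    top = w.max()
    if top > 0:
        w = w / top
    return w


def binarize(weights: np.ndarray, theta: float = DEFAULT_THETA) -> np.ndarray:
    """Label an atom 1 iff its weight >= theta * max(weights) (inclusive);
    an all-zero weight vector yields all-zero labels."""
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    weights = np.asarray(weights, dtype=float)
    top = weights.max(initial=0.0)
    if top <= 0:
        return np.zeros(len(weights), dtype=int)
    return (weights >= theta * top).astype(int)


def labels_for_peak(sticks: StickSpectrum,
                    transitions: Sequence[TransitionRecord],
                    peak: PeakRegion, n_atoms: int,
                    theta: float = DEFAULT_THETA) -> GroundTruthLabels:
    """Compose stick assignment, channel weighting and binarization for one
    peak. Sticks map to transitions by position: ``sticks.sticks[i]``
    corresponds to ``transitions[i]``."""
    if len(sticks) != len(transitions):
        raise ValueError("sticks and transitions must be parallel lists")
    member = assign_sticks_to_peak(sticks, peak)
    if not member:
        raise EmptyPeakError(
            f"peak at {peak.center_energy:.2f} eV contains no transitions")
    selected = [transitions[i] for i in member]
    cw = atom_weights(selected, "core", n_atoms)
    vw = atom_weights(selected, "virtual", n_atoms)
    return GroundTruthLabels(
        molecule_id=sticks.molecule_id,
        peak=PeakRegion(peak.center_energy, peak.center_index, peak.fwhm,
                        peak.window, member),
        core_weights=cw,
        virtual_weights=vw,
        core_labels=binarize(cw, theta),
        virtual_labels=binarize(vw, theta),
    )


# ---------------------------------------------------------------------------
# JSON-lines interchange

def write_transitions(transitions: Iterable[TransitionRecord], path) -> None:
    """One JSON object per line: keys state_id, energy (eV), osc_strength,
    pairs ([{core, virtual, weight}]), mo_populations ({mo: {atom: share}})."""
    with open(path, "w") as fh:
        for t in transitions:
            fh.write(json.dumps(t.to_dict()) + "\n")


def read_transitions(path) -> list[TransitionRecord]:
    with open(path) as fh:
        return [TransitionRecord.from_dict(json.loads(line))
                for line in fh if line.strip()]
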