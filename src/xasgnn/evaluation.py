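"""Scoring explanations: per-peak AUC-ROC, report aggregation, robustness.

For each peak of the reference (quantum-chemistry) spectrum, the aggregated
CAM scores of all atoms are compared against the binary ground-truth atom
labels with the area under the ROC curve — the probability that a randomly
chosen contributing atom outranks a randomly chosen non-contributing one,
with half credit for ties. 0.5 is the random baseline, 1.0 perfect
discrimination. Peaks whose labels are single-class have no defined AUC and
are excluded from averages (but counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .attribution import aggregate_peak, cam
from .ground_truth import (DEFAULT_THETA, EmptyPeakError, GroundTruthLabels,
                           TransitionRecord, labels_for_peak)
from .molgraph import MolecularGraph
from .spectra import (EnergyGrid, GridSpectrum, PeakRegion, StickSpectrum,
                      broaden, find_peaks, rse)

CHANNELS = ("core", "virtual")


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> Optional[float]:
    """AUC-ROC of per-atom scores against binary labels.

    Equals the Mann-Whitney statistic P(score_pos > score_neg) + 0.5 P(tie).
    Returns None when the labels are single-class (undefined).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.min(initial=1) == labels.max(initial=0):
        return None
    if len(set(labels.tolist())) < 2:
        return None
    return float(roc_auc_score(labels, scores))


@dataclass
class PeakExplanation:
    """CAM-vs-ground-truth comparison for one spectral peak."""

    molecule_id: str
    peak: PeakRegion
    cam_peak_scores: np.ndarray
    labels: GroundTruthLabels
    auc_core: Optional[float]
    auc_virtual: Optional[float]

    def auc(self, channel: str) -> Optional[float]:
        return self.auc_core if channel == "core" else self.auc_virtual


@dataclass
class ExplainReport:
    """Aggregated explanation quality over a set of molecules."""

    per_molecule: list[dict] = field(default_factory=list)
    n_peaks: int = 0
    n_undefined_core: int = 0
    n_undefined_virtual: int = 0

    def add_molecule(self, molecule_id: str,
                     explanations: Sequence[PeakExplanation],
                     mol_rse: Optional[float] = None) -> None:
        core = [e.auc_core for e in explanations if e.auc_core is not None]
        virt = [e.auc_virtual for e in explanations if e.auc_virtual is not None]
        self.n_peaks += len(explanations)
        self.n_undefined_core += sum(e.auc_core is None for e in explanations)
        self.n_undefined_virtual += sum(e.auc_virtual is None
                                        for e in explanations)
        self.per_molecule.append({
            "molecule_id": molecule_id,
            "n_peaks": len(explanations),
            "mean_auc_core": float(np.mean(core)) if core else None,
            "mean_auc_virtual": float(np.mean(virt)) if virt else None,
            "rse": mol_rse,
        })

    def _defined(self, channel: str) -> list[float]:
        key = f"mean_auc_{channel}"
        return [m[key] for m in self.per_molecule if m[key] is not None]

    def mean_auc(self, channel: str) -> float:
        vals = self._defined(channel)
        if not vals:
            raise ValueError(f"no defined AUC values for channel {channel!r}")
        return float(np.mean(vals))

    def summary(self) -> dict:
        out = {"n_molecules": len(self.per_molecule), "n_peaks": self.n_peaks,
               "n_undefined_core": self.n_undefined_core,
               "n_undefined_virtual": self.n_undefined_virtual}
        for ch in CHANNELS:
            vals = self._defined(ch)
            if vals:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                out[f"mean_auc_{ch}"] = float(np.mean(vals))
                out[f"median_auc_{ch}"] = float(med)
                out[f"q1_auc_{ch}"] = float(q1)
                out[f"q3_auc_{ch}"] = float(q3)
        rses = [m["rse"] for m in self.per_molecule if m["rse"] is not None]
        if rses:
            out["mean_rse"] = float(np.mean(rses))
        return out


def explain_molecule(model, graph: MolecularGraph, sticks: StickSpectrum,
                     transitions: Sequence[TransitionRecord],
                     grid: EnergyGrid, theta: float = DEFAULT_THETA,
                     width: float = 0.8,
                     prominence_fraction: float = 0.05,
                     ) -> list[PeakExplanation]:
    """Explain every peak of a molecule's reference spectrum.

    Peaks are detected on the broadened reference (target) spectrum; per
    peak, ground-truth labels come from the member transitions and the CAM
    scores are summed over the peak's FWHM window.
    """
    target = broaden(sticks, grid, width)
    attr = cam(model, graph)
    if attr.scores.shape != (graph.n_atoms, grid.n_grid):
        raise ValueError("CAM matrix does not match graph/grid dimensions")
    explanations = []
    for peak in find_peaks(target, prominence_fraction):
        try:
            labels = labels_for_peak(sticks, transitions, peak,
                                     graph.n_atoms, theta)
        except EmptyPeakError:
            continue
        peak_scores = aggregate_peak(attr, peak)
        explanations.append(PeakExplanation(
            molecule_id=graph.molecule_id,
            peak=labels.peak,
            cam_peak_scores=peak_scores,
            labels=labels,
            auc_core=auc_roc(peak_scores, labels.core_labels),
            auc_virtual=auc_roc(peak_scores, labels.virtual_labels),
        ))
    return explanations


def evaluate_model(model, records, grid: EnergyGrid,
                   theta: float = DEFAULT_THETA, width: float = 0.8,
                   ) -> ExplainReport:
    """Run the full explanation scoring over dataset records.

    ``records`` iterates over objects with attributes ``graph``, ``sticks``,
    ``transitions`` and ``spectrum`` (the broadened reference).
    """
    report = ExplainReport()
    for rec in records:
        pred = model.predict(rec.graph)
        mol_rse = rse(rec.spectrum, GridSpectrum(grid, pred))
        expl = explain_molecule(model, rec.graph, rec.sticks,
                                rec.transitions, grid, theta, width)
        report.add_molecule(rec.graph.molecule_id, expl, mol_rse)
    return report


def rse_decile_profile(per_molecule: Sequence[tuple[float, float]]
                       ) -> list[tuple[float, float]]:
    """Sort molecules by RSE, split into 10 equal groups (remainder spread
    over the first groups), and average (RSE, AUC) per group."""
    if len(per_molecule) < 10:
        raise ValueError(f"need >= 10 molecules, got {len(per_molecule)}")
    pairs = sorted(per_molecule, key=lambda p: p[0])
    n = len(pairs)
    base, rem = divmod(n, 10)
    bins, start = [], 0
    for b in range(10):
        size = base + (1 if b < rem else 0)
        chunk = pairs[start:start + size]
        start += size
        bins.append((float(np.mean([p[0] for p in chunk])),
                     float(np.mean([p[1] for p in chunk]))))
    return bins


def delta_auc(before: ExplainReport, after: ExplainReport) -> dict[str, float]:
    """Percentage change in mean AUC per channel between paired reports:
    100 * (after - before) / before."""
    out = {}
    for ch in CHANNELS:
        b = before.mean_auc(ch)
        if b == 0:
            raise ValueError(f"zero baseline mean AUC for channel {ch!r}")
        out[ch] = 100.0 * (after.mean_auc(ch) - b) / b
    return out
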