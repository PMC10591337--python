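"""Class activation maps (CAM) for spectrum-predicting graph networks.

Every grid point of the predicted spectrum is treated as an independent
class ``c``. With ``F_k(i)`` the activation of unit ``k`` of the last
message-passing layer at atom ``i`` and ``omega_k^c`` the output layer's
weight of unit ``k`` for class ``c``, the CAM score of atom ``i`` for class
``c`` is ``sum_k omega_k^c F_k(i)``. Under sum readout and a bias-free
output layer, the scores of all atoms sum exactly to the model's prediction
at every grid point (completeness).

Negative scores are kept: the downstream AUC comparison uses rank order
only, so clamping would discard information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import MolecularGraph
from .spectra import PeakRegion


class UnsupportedArchitectureError(TypeError):
    """Raised when a model lacks the pooling-then-affine head CAM requires."""


@dataclass
class AtomAttribution:
    """Per-atom, per-grid-point CAM score matrix for one molecule."""

    molecule_id: str
    scores: np.ndarray  # (n_atoms, n_grid)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D (atoms x grid) matrix")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite CAM scores")


def cam(model, graph: MolecularGraph) -> AtomAttribution:
    """Compute CAM atom attributions for every spectrum grid point.

    ``scores[i, c] = sum_k omega_k^c F_k(i)``; with mean readout the scores
    are divided by the atom count so completeness still holds.
    """
    output_layer = getattr(model, "output_layer", None)
    config = getattr(model, "config", None)
    if output_layer is None or config is None or not hasattr(model, "forward"):
        raise UnsupportedArchitectureError(
            "model must expose node activations, a global readout and a "
            "single affine output layer")
    _, acts = model.forward(graph)           # (n_atoms, K)
    weights = output_layer.weight.data       # (K, n_out)
    scores = acts @ weights
    if config.readout == "mean":
        scores = scores / graph.n_atoms
    return AtomAttribution(molecule_id=graph.molecule_id, scores=scores)


def aggregate_peak(attr: AtomAttribution, peak: PeakRegion) -> np.ndarray:
    """Sum CAM scores over the peak's FWHM grid window, per atom."""
    lo, hi = peak.window
    n_grid = attr.scores.shape[1]
    if not (0 <= lo < hi <= n_grid):
        raise ValueError(f"peak window {peak.window} outside grid of {n_grid}")
    return attr.scores[:, lo:hi].sum(axis=1)
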