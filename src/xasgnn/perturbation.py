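"""Robustness perturbations: methyl addition and coordinate distortion.

Two stress tests for trained models and their explanations: (a) grow the
molecule by one methyl group at a random hydrogen-bearing heavy atom, which
pushes it just outside the training distribution; (b) jitter the Cartesian
coordinates with isotropic Gaussian noise of standard deviation sigma per
axis, emulating small conformational distortions.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem


class NoMethylSiteError(ValueError):
    """No heavy atom carries a hydrogen that a methyl group could replace."""


def methyl_sites(smiles: str) -> list[int]:
    """Heavy-atom indices (canonical order) with at least one hydrogen."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def add_methyl(smiles: str, seed: int) -> str:
    """Replace one hydrogen on a uniformly random eligible heavy atom with a
    methyl group; returns the canonical SMILES of the grown molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]
    if not sites:
        raise NoMethylSiteError(
            f"no hydrogen-bearing heavy atom in {smiles!r}")
    rng = np.random.default_rng(seed)
    site = int(rng.choice(sites))
    rw = Chem.RWMol(mol)
    c_new = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(site, c_new, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def distort_coords(coords: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add independent zero-mean Gaussian noise of standard deviation
    ``sigma`` (Angstrom) to every Cartesian coordinate."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    coords = np.asarray(coords, dtype=float)
    if sigma == 0:
        return coords.copy()
    rng = np.random.default_rng(seed)
    return coords + rng.normal(0.0, sigma, size=coords.shape)
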