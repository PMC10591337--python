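"""SMILES/XYZ to attributed molecular graphs.

Molecules are represented as heavy-atom graphs (hydrogens folded into a
per-atom count feature): nodes are C/N/O/F atoms with one-hot encoded
element, hybridization and aromaticity plus the integer hydrogen count;
edges are chemical bonds with one-hot bond order and, when 3-D coordinates
are available, the bond length in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

# Frozen encoding vocabularies — the bit layout of every feature vector.
ELEMENTS = ("C", "N", "O", "F")
HYBRIDIZATIONS = ("sp", "sp2", "sp3", "other")
NODE_FEATURE_DIM = len(ELEMENTS) + len(HYBRIDIZATIONS) + 2 + 1  # = 11
#: bond-order one-hot {single, double, triple, aromatic} + length + length-present flag
BOND_ORDERS = ("single", "double", "triple", "aromatic")
EDGE_FEATURE_DIM = len(BOND_ORDERS) + 2

_RDKIT_HYB = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}
_RDKIT_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class UnsupportedElementError(ValueError):
    """Raised for atoms outside the C/N/O/F heavy-atom vocabulary."""


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with encoded node and edge features."""

    molecule_id: str
    elements: list[str]
    node_features: np.ndarray          # (n_atoms, NODE_FEATURE_DIM)
    edges: list[tuple[int, int]]       # undirected, v < w
    edge_features: np.ndarray          # (n_edges, EDGE_FEATURE_DIM)
    hydrogen_counts: list[int]
    coords: Optional[np.ndarray] = None  # (n_atoms, 3) Angstrom
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        n = self.n_atoms
        if self.node_features.shape != (n, NODE_FEATURE_DIM):
            raise ValueError(f"node_features shape {self.node_features.shape} "
                             f"!= ({n}, {NODE_FEATURE_DIM})")
        for v, w in self.edges:
            if v == w:
                raise ValueError(f"self-loop edge ({v},{w})")
            if not (0 <= v < n and 0 <= w < n):
                raise ValueError(f"edge ({v},{w}) out of range for {n} atoms")
        if self.coords is not None and self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_dict(self) -> dict:
        d = {
            "molecule_id": self.molecule_id,
            "elements": self.elements,
            "node_features": self.node_features.tolist(),
            "edges": [list(e) for e in self.edges],
            "edge_features": self.edge_features.tolist(),
            "hydrogen_counts": self.hydrogen_counts,
            "smiles": self.smiles,
        }
        if self.coords is not None:
            d["coords"] = self.coords.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MolecularGraph":
        return cls(
            molecule_id=d["molecule_id"],
            elements=list(d["elements"]),
            node_features=np.asarray(d["node_features"], dtype=float),
            edges=[tuple(e) for e in d["edges"]],
            edge_features=np.asarray(d["edge_features"], dtype=float).reshape(
                len(d["edges"]), EDGE_FEATURE_DIM),
            hydrogen_counts=list(d["hydrogen_counts"]),
            coords=(np.asarray(d["coords"], dtype=float) if "coords" in d else None),
            smiles=d.get("smiles"),
        )


def featurize_atom(element: str, hybridization: str, aromatic: bool,
                   n_hydrogens: int) -> np.ndarray:
    """Encode one heavy atom: one-hot element (4) | one-hot hybridization (4)
    | one-hot aromatic flag (2) | integer H count. Length 11."""
    if element not in ELEMENTS:
        raise UnsupportedElementError(
            f"element {element!r} outside supported heavy-atom set {ELEMENTS}")
    if hybridization not in HYBRIDIZATIONS:
        hybridization = "other"
    vec = np.zeros(NODE_FEATURE_DIM)
    vec[ELEMENTS.index(element)] = 1.0
    vec[len(ELEMENTS) + HYBRIDIZATIONS.index(hybridization)] = 1.0
    vec[len(ELEMENTS) + len(HYBRIDIZATIONS) + (1 if aromatic else 0)] = 1.0
    vec[-1] = float(n_hydrogens)
    return vec


def _featurize_bond(bond: Chem.Bond, coords: Optional[np.ndarray],
                    v: int, w: int) -> np.ndarray:
    order = _RDKIT_BOND.get(bond.GetBondType())
    if order is None:
        raise ValueError(f"unsupported bond type {bond.GetBondType()}")
    vec = np.zeros(EDGE_FEATURE_DIM)
    vec[BOND_ORDERS.index(order)] = 1.0
    if coords is not None:
        vec[len(BOND_ORDERS)] = float(np.linalg.norm(coords[v] - coords[w]))
        vec[len(BOND_ORDERS) + 1] = 1.0
    return vec


def build_graph(smiles: str, coords: Optional[np.ndarray] = None,
                molecule_id: Optional[str] = None) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolecularGraph`.

    Atom order is RDKit's canonical order for the canonicalized SMILES, so
    the same molecule always yields the same graph. Optional coordinates
    must follow that heavy-atom order.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    # re-parse from the canonical SMILES so atom order is reproducible
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    n = mol.GetNumAtoms()
    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError(
                f"coordinate block has shape {coords.shape}, expected ({n}, 3) "
                f"matching the heavy-atom count of {canonical!r}")
    elements, h_counts = [], []
    feats = np.zeros((n, NODE_FEATURE_DIM))
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        hyb = _RDKIT_HYB.get(atom.GetHybridization(), "other")
        nh = atom.GetTotalNumHs()
        feats[atom.GetIdx()] = featurize_atom(sym, hyb, atom.GetIsAromatic(), nh)
        elements.append(sym)
        h_counts.append(nh)
    edges, efeats = [], []
    for bond in mol.GetBonds():
        v, w = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if v > w:
            v, w = w, v
        edges.append((v, w))
        efeats.append(_featurize_bond(bond, coords, v, w))
    edge_features = (np.stack(efeats) if efeats
                     else np.zeros((0, EDGE_FEATURE_DIM)))
    return MolecularGraph(
        molecule_id=molecule_id or canonical,
        elements=elements,
        node_features=feats,
        edges=edges,
        edge_features=edge_features,
        hydrogen_counts=h_counts,
        coords=coords,
        smiles=canonical,
    )


def carbon_indices(graph: MolecularGraph) -> list[int]:
    """Indices of all carbon atoms, in graph order (the K-edge absorbers)."""
    return [i for i, el in enumerate(graph.elements) if el == "C"]


def read_xyz(text: str) -> tuple[list[str], np.ndarray]:
    """Parse a standard XYZ block: count line, comment line, element x y z rows."""
    lines = [ln for ln in text.strip().splitlines()]
    n = int(lines[0].split()[0])
    rows = lines[2:2 + n]
    if len(rows) < n:
        raise ValueError(f"XYZ block declares {n} atoms but has {len(rows)} rows")
    elements, xyz = [], []
    for row in rows:
        parts = row.split()
        elements.append(parts[0])
        xyz.append([float(x) for x in parts[1:4]])
    return elements, np.array(xyz)


def write_xyz(elements: Sequence[str], coords: np.ndarray, comment: str = "") -> str:
    lines = [str(len(elements)), comment]
    for el, (x, y, z) in zip(elements, coords):
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"
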