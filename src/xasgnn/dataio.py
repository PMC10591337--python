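"""Plain-text serialization of datasets, spectra and reports.

A dataset lives in one directory of diffable text files:

* ``grid.json`` — energy-grid metadata (stored once per dataset)
* ``graphs.jsonl`` — one molecular graph per line
* ``spectra.csv`` — molecule_id followed by the n_grid intensities
* ``sticks.csv`` — columns molecule_id, energy_ev, osc_strength
* ``transitions.jsonl`` — transition records tagged with molecule_id
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .ground_truth import TransitionRecord
from .molgraph import MolecularGraph
from .spectra import EnergyGrid, GridSpectrum, StickSpectrum
from .synthetic_data import MoleculeRecord


def write_smiles(smiles: Sequence[str], path, ids: Sequence[str] = None) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(smiles):
            tag = ids[i] if ids else f"mol{i:05d}"
            fh.write(f"{s}\t{tag}\n")


def read_smiles(path) -> list[tuple[str, str]]:
    """Returns (smiles, id) pairs; ids autogenerated when absent."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            out.append((parts[0], parts[1] if len(parts) > 1 else f"mol{i:05d}"))
    return out


def write_sticks_csv(spectra: Sequence[StickSpectrum], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "energy_ev", "osc_strength"])
        for s in spectra:
            for e, f in s.sticks:
                w.writerow([s.molecule_id, repr(float(e)), repr(float(f))])


def read_sticks_csv(path) -> list[StickSpectrum]:
    by_mol: dict[str, list[tuple[float, float]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            mid = row["molecule_id"]
            if mid not in by_mol:
                by_mol[mid] = []
                order.append(mid)
            by_mol[mid].append((float(row["energy_ev"]),
                                float(row["osc_strength"])))
    return [StickSpectrum(mid, by_mol[mid]) for mid in order]


def save_dataset(records: Sequence[MoleculeRecord], directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    grid = records[0].spectrum.grid
    (d / "grid.json").write_text(json.dumps(grid.to_dict()) + "\n")
    with open(d / "graphs.jsonl", "w") as fh:
        for r in records:
            fh.write(json.dumps(r.graph.to_dict()) + "\n")
    with open(d / "spectra.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id"] + [f"i{k}" for k in range(grid.n_grid)])
        for r in records:
            w.writerow([r.molecule_id]
                       + [repr(float(v)) for v in r.spectrum.intensities])
    write_sticks_csv([r.sticks for r in records], d / "sticks.csv")
    with open(d / "transitions.jsonl", "w") as fh:
        for r in records:
            for t in r.transitions:
                obj = t.to_dict()
                obj["molecule_id"] = r.molecule_id
                fh.write(json.dumps(obj) + "\n")


def load_dataset(directory) -> list[MoleculeRecord]:
    d = Path(directory)
    grid = EnergyGrid.from_dict(json.loads((d / "grid.json").read_text()))
    graphs = {}
    order = []
    with open(d / "graphs.jsonl") as fh:
        for line in fh:
            g = MolecularGraph.from_dict(json.loads(line))
            graphs[g.molecule_id] = g
            order.append(g.molecule_id)
    spectra = {}
    with open(d / "spectra.csv", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            spectra[row[0]] = GridSpectrum(
                grid, np.array([float(x) for x in row[1:]]))
    sticks = {s.molecule_id: s for s in read_sticks_csv(d / "sticks.csv")}
    transitions: dict[str, list[TransitionRecord]] = {m: [] for m in order}
    with open(d / "transitions.jsonl") as fh:
        for line in fh:
            obj = json.loads(line)
            mid = obj.pop("molecule_id")
            transitions[mid].append(TransitionRecord.from_dict(obj))
    records = []
    for mid in order:
        records.append(MoleculeRecord(
            molecule_id=mid, smiles=graphs[mid].smiles, graph=graphs[mid],
            sticks=sticks.get(mid, StickSpectrum(mid, [])),
            transitions=transitions.get(mid, []),
            spectrum=spectra[mid], planted=[]))
    return records


def save_model(model, path) -> None:
    """Serialize config + weights as JSON."""
    from .gnn_models import ModelConfig
    cfg = model.config
    payload = {
        "config": {"architecture": cfg.architecture,
                   "hidden_sizes": list(cfg.hidden_sizes),
                   "n_out": cfg.n_out, "n_heads": cfg.n_heads,
                   "readout": cfg.readout, "output_bias": cfg.output_bias,
                   "leaky_slope": cfg.leaky_slope, "seed": cfg.seed},
        "weights": [p.data.tolist() for p in model.parameters()],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    from .gnn_models import ModelConfig, build_model
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    model = build_model(ModelConfig(
        architecture=cfg["architecture"],
        hidden_sizes=tuple(cfg["hidden_sizes"]),
        n_out=cfg["n_out"], n_heads=cfg["n_heads"], readout=cfg["readout"],
        output_bias=cfg["output_bias"], leaky_slope=cfg["leaky_slope"],
        seed=cfg["seed"]))
    for p, w in zip(model.parameters(), payload["weights"]):
        p.data = np.asarray(w, dtype=float)
    return model


def write_attribution_csv(attr, grid: EnergyGrid, path) -> None:
    """CAM matrix as CSV: one row per atom, one column per grid energy."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["atom_index"] + [f"{e:.3f}" for e in grid.energies])
        for i, row in enumerate(attr.scores):
            w.writerow([i] + [repr(float(v)) for v in row])


def write_metrics_csv(history: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_rmse", "lr"])
        for e, r, lr in zip(history["epoch"], history["train_rmse"],
                            history["lr"]):
            w.writerow([e, repr(float(r)), repr(float(lr))])
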