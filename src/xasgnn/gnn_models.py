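"""Three graph-network regressors mapping molecular graphs to spectra.

All three share the head contract that makes class-activation mapping exact:
message-passing layers produce per-atom activations ``F_k(i)`` (the last
layer's node states), a permutation-invariant readout pools them into one
graph vector, and a single affine output layer produces the ``n_out``
spectrum values. There are no hidden layers after the readout, so the output
layer's weight matrix is exactly the CAM weight ``omega_k^c``.

Architectures:

* ``gcn`` — degree-normalized neighbor averaging over node states only.
* ``graphnet`` — full block updates of edge, node and global states; the
  global state routes information between distant parts of the molecule.
* ``gatv2`` — multihead attention over neighborhoods, with the attention
  logits computed after the shared nonlinearity (the GATv2 form, which keeps
  the attention genuinely dynamic in both endpoints).

Training follows the reference protocol: AdamW on an RMSE loss, learning
rate decayed by a fixed factor on a fixed epoch schedule, 80:20
train/validation split, model selection by best validation RMSE with ties
broken by validation RSE.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, concat, segment_mean, segment_softmax, segment_sum
from .molgraph import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, MolecularGraph
from .nn import AdamW, Linear, get_state, set_state
from .spectra import GridSpectrum

ARCHITECTURES = ("gcn", "graphnet", "gatv2")

#: full-scale profile (GPU-sized training runs)
FULL_HIDDEN_SIZES = (128, 256, 512)
#: desk-scale profile used throughout the tests and examples
SMALL_HIDDEN_SIZES = (32, 64)


@dataclass
class ModelConfig:
    architecture: str = "gatv2"
    hidden_sizes: tuple[int, ...] = FULL_HIDDEN_SIZES
    n_out: int = 100
    n_heads: int = 4
    readout: str = "sum"          # {sum, mean}
    output_bias: bool = True
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if self.n_out < 1 or self.n_heads < 1:
            raise ValueError("n_out and n_heads must be >= 1")
        if self.readout not in ("sum", "mean"):
            raise ValueError(f"unknown readout {self.readout!r}")
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)


@dataclass
class TrainConfig:
    epochs: int = 1000
    lr: float = 1e-3
    lr_decay: float = 0.8
    decay_every: int = 100
    batch_size: int = 100
    val_fraction: float = 0.2
    val_check_every: int = 50
    weight_decay: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.lr <= 0 or not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr must be positive and lr_decay in (0, 1]")


class GraphBatch:
    """A list of molecular graphs flattened into one disjoint graph."""

    def __init__(self, graphs: Sequence[MolecularGraph]):
        if not graphs:
            raise ValueError("empty graph batch")
        self.graphs = list(graphs)
        xs, gids, srcs, dsts, eattrs = [], [], [], [], []
        e_src, e_dst = [], []
        offset = 0
        for gi, g in enumerate(graphs):
            xs.append(g.node_features)
            gids.append(np.full(g.n_atoms, gi))
            for (v, w) in g.edges:
                # directed both ways for message passing
                srcs += [offset + v, offset + w]
                dsts += [offset + w, offset + v]
            for (v, w) in g.edges:
                e_src.append(offset + v)
                e_dst.append(offset + w)
            eattrs.append(g.edge_features)
            offset += g.n_atoms
        self.n_nodes = offset
        self.n_graphs = len(graphs)
        self.x = np.concatenate(xs, axis=0)
        self.graph_id = np.concatenate(gids).astype(int)
        self.src = np.array(srcs, dtype=int)          # directed, both ways
        self.dst = np.array(dsts, dtype=int)
        self.edge_v = np.array(e_src, dtype=int)      # one entry per bond
        self.edge_w = np.array(e_dst, dtype=int)
        self.edge_attr = np.concatenate(eattrs, axis=0)
        self.n_bonds = len(self.edge_v)
        # neighbors-plus-self index lists for mean aggregation
        self.loop = np.arange(self.n_nodes)


class _GNNBase:
    """Shared head: message passing -> node activations -> readout -> affine."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._layers_params: list[Tensor] = []
        self.output_layer: Optional[Linear] = None

    # subclasses implement
    def _node_activations(self, batch: GraphBatch) -> Tensor:
        raise NotImplementedError

    def forward_batch(self, batch: GraphBatch) -> tuple[Tensor, Tensor]:
        """Returns (per-graph outputs (n_graphs, n_out), node activations)."""
        acts = self._node_activations(batch)
        if self.config.readout == "sum":
            pooled = segment_sum(acts, batch.graph_id, batch.n_graphs)
        else:
            pooled = segment_mean(acts, batch.graph_id, batch.n_graphs)
        return self.output_layer(pooled), acts

    def forward(self, graph: MolecularGraph) -> tuple[np.ndarray, np.ndarray]:
        """Predict one molecule; returns (spectrum (n_out,), activations)."""
        if graph.node_features.shape[1] != NODE_FEATURE_DIM:
            raise ValueError(
                f"node feature dimension {graph.node_features.shape[1]} does "
                f"not match the model input dimension {NODE_FEATURE_DIM}")
        out, acts = self.forward_batch(GraphBatch([graph]))
        return out.data[0], acts.data

    def predict(self, graph: MolecularGraph, grid=None,
                clamp_negative: bool = False) -> np.ndarray:
        y, _ = self.forward(graph)
        if clamp_negative:
            y = np.maximum(y, 0.0)
        return y

    def parameters(self) -> list[Tensor]:
        return self._layers_params + self.output_layer.parameters()

    @property
    def activation_dim(self) -> int:
        return self.config.hidden_sizes[-1]

    def _act(self, t: Tensor) -> Tensor:
        return t.leaky_relu(self.config.leaky_slope)


class GCNModel(_GNNBase):
    """Graph convolution: mean over self + neighbors, then a learned
    linear transform and nonlinearity. Edge features are unused."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        dims = [NODE_FEATURE_DIM, *config.hidden_sizes]
        self.layers = [Linear(dims[i], dims[i + 1], self.rng)
                       for i in range(len(config.hidden_sizes))]
        for lay in self.layers:
            self._layers_params += lay.parameters()
        self.output_layer = Linear(config.hidden_sizes[-1], config.n_out,
                                   self.rng, bias=config.output_bias)

    def _node_activations(self, batch: GraphBatch) -> Tensor:
        srcs = np.concatenate([batch.src, batch.loop])
        dsts = np.concatenate([batch.dst, batch.loop])
        h = Tensor(batch.x)
        for lay in self.layers:
            agg = segment_mean(h.gather_rows(srcs), dsts, batch.n_nodes)
            h = self._act(lay(agg))
        return h


class GraphNetModel(_GNNBase):
    """Full graph-network block: edge, node and global state updates.

    Per block of width k: the edge state is updated from (edge, the sum of
    its two endpoint states, global) — the endpoint sum keeps the update
    symmetric under the arbitrary storage orientation of an undirected
    bond; the node state from (node, sum of incident updated edges,
    global); the global state from (global, mean node, mean edge). The
    initial global state is the mean of the raw node features.
    """

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        nd, ed, ud = NODE_FEATURE_DIM, EDGE_FEATURE_DIM, NODE_FEATURE_DIM
        self.edge_layers, self.node_layers, self.global_layers = [], [], []
        for k in config.hidden_sizes:
            self.edge_layers.append(Linear(ed + nd + ud, k, self.rng))
            self.node_layers.append(Linear(nd + k + ud, k, self.rng))
            self.global_layers.append(Linear(ud + 2 * k, k, self.rng))
            nd = ed = ud = k
        for lay in (*self.edge_layers, *self.node_layers, *self.global_layers):
            self._layers_params += lay.parameters()
        self.output_layer = Linear(config.hidden_sizes[-1], config.n_out,
                                   self.rng, bias=config.output_bias)

    def _node_activations(self, batch: GraphBatch) -> Tensor:
        h = Tensor(batch.x)
        e = Tensor(batch.edge_attr)
        u = segment_mean(h, batch.graph_id, batch.n_graphs)
        edge_gid = batch.graph_id[batch.edge_v]
        for le, ln, lu in zip(self.edge_layers, self.node_layers,
                              self.global_layers):
            u_edge = u.gather_rows(edge_gid)
            e = self._act(le(concat(
                [e, h.gather_rows(batch.edge_v) + h.gather_rows(batch.edge_w),
                 u_edge], axis=1)))
            # incident-edge sum: each undirected edge contributes to both ends
            incident = segment_sum(
                concat([e, e], axis=0),
                np.concatenate([batch.edge_v, batch.edge_w]),
                batch.n_nodes)
            h = self._act(ln(concat(
                [h, incident, u.gather_rows(batch.graph_id)], axis=1)))
            node_mean = segment_mean(h, batch.graph_id, batch.n_graphs)
            edge_mean = segment_mean(e, edge_gid, batch.n_graphs)
            u = self._act(lu(concat([u, node_mean, edge_mean], axis=1)))
        return h


class GATv2Model(_GNNBase):
    """Multihead GATv2: attention logits ``a^T lrelu(W_l h_i + W_r h_j)``
    softmax-normalized over each node's neighborhood (self-loop included).
    Heads are concatenated on intermediate layers and averaged on the last
    message-passing layer, whose width is the activation dimension."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        H = config.n_heads
        self.head_dims: list[int] = []
        self.w_left: list[Linear] = []
        self.w_right: list[Linear] = []
        self.att: list[Tensor] = []
        d = NODE_FEATURE_DIM
        for li, k in enumerate(config.hidden_sizes):
            final = li == len(config.hidden_sizes) - 1
            dh = k if final else k // H
            if not final and k % H != 0:
                raise ValueError(
                    f"hidden size {k} not divisible by n_heads={H}")
            self.head_dims.append(dh)
            self.w_left.append(Linear(d, H * dh, self.rng))
            self.w_right.append(Linear(d, H * dh, self.rng))
            a = Tensor(self.rng.uniform(-0.1, 0.1, size=(1, H, dh)),
                       requires_grad=True)
            self.att.append(a)
            d = dh if final else k
        for lay in (*self.w_left, *self.w_right):
            self._layers_params += lay.parameters()
        self._layers_params += self.att
        self.output_layer = Linear(config.hidden_sizes[-1], config.n_out,
                                   self.rng, bias=config.output_bias)

    def _node_activations(self, batch: GraphBatch) -> Tensor:
        H = self.config.n_heads
        src = np.concatenate([batch.src, batch.loop])
        dst = np.concatenate([batch.dst, batch.loop])
        n_e = len(src)
        h = Tensor(batch.x)
        n_layers = len(self.w_left)
        for li in range(n_layers):
            dh = self.head_dims[li]
            final = li == n_layers - 1
            left = self.w_left[li](h)    # target-node term
            right = self.w_right[li](h)  # source-node term
            pair = (left.gather_rows(dst) + right.gather_rows(src)) \
                .reshape(n_e, H, dh)
            logits = (self._act(pair) * self.att[li]).sum(axis=2)  # (n_e, H)
            alpha = segment_softmax(logits, dst, batch.n_nodes)
            msgs = right.gather_rows(src).reshape(n_e, H, dh)
            weighted = msgs * alpha.reshape(n_e, H, 1)
            agg = segment_sum(weighted, dst, batch.n_nodes)  # (N, H, dh)
            if final:
                h = self._act(agg.mean(axis=1))
            else:
                h = self._act(agg.reshape(batch.n_nodes, H * dh))
        return h


def build_model(config: ModelConfig) -> _GNNBase:
    return {"gcn": GCNModel, "graphnet": GraphNetModel,
            "gatv2": GATv2Model}[config.architecture](config)


def _rmse_batch(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - target) ** 2)))


def _evaluate(model: _GNNBase, graphs: list[MolecularGraph],
              targets: np.ndarray, grid) -> tuple[float, float]:
    """(RMSE, mean RSE) of the model on a held-out set."""
    from .spectra import rse
    out, _ = model.forward_batch(GraphBatch(graphs))
    pred = out.data
    rmse = _rmse_batch(pred, targets)
    rses = []
    for i in range(len(graphs)):
        tot = targets[i].sum() * grid.delta_e
        if tot > 0:
            rses.append(rse(GridSpectrum(grid, targets[i]),
                            GridSpectrum(grid, pred[i])))
    return rmse, float(np.mean(rses)) if rses else float("nan")


def train(model: _GNNBase,
          dataset: Sequence[tuple[MolecularGraph, GridSpectrum]],
          cfg: TrainConfig) -> tuple[_GNNBase, dict]:
    """Train a model with AdamW on an RMSE loss.

    The dataset is split 1 - val_fraction : val_fraction (seeded shuffle);
    validation RMSE and RSE are computed every ``val_check_every`` epochs and
    the checkpoint with the best validation RMSE (ties broken by RSE) is
    restored before returning. The learning rate is multiplied by
    ``lr_decay`` every ``decay_every`` epochs.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    grid = dataset[0][1].grid
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(cfg.val_fraction * len(dataset))))
    if n_val >= len(dataset):
        raise ValueError("dataset too small for the requested validation split")
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_graphs = [dataset[i][0] for i in train_idx]
    train_y = np.stack([dataset[i][1].intensities for i in train_idx])
    val_graphs = [dataset[i][0] for i in val_idx]
    val_y = np.stack([dataset[i][1].intensities for i in val_idx])

    params = model.parameters()
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = {"epoch": [], "train_rmse": [], "lr": [],
               "val_epoch": [], "val_rmse": [], "val_rse": []}
    best = (float("inf"), float("inf"))
    best_state = get_state(params)

    n_train = len(train_graphs)
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.lr * cfg.lr_decay ** ((epoch - 1) // cfg.decay_every)
        perm = rng.permutation(n_train)
        epoch_sq, epoch_n = 0.0, 0
        for start in range(0, n_train, cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            batch = GraphBatch([train_graphs[i] for i in sel])
            y = Tensor(train_y[sel])
            out, _ = model.forward_batch(batch)
            loss = (out - y).square().mean().sqrt()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch} "
                                   f"(non-finite loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_sq += float(loss.data) ** 2 * len(sel)
            epoch_n += len(sel)
        history["epoch"].append(epoch)
        history["train_rmse"].append(float(np.sqrt(epoch_sq / epoch_n)))
        history["lr"].append(opt.lr)
        if epoch % cfg.val_check_every == 0 or epoch == cfg.epochs:
            val_rmse, val_rse = _evaluate(model, val_graphs, val_y, grid)
            history["val_epoch"].append(epoch)
            history["val_rmse"].append(val_rmse)
            history["val_rse"].append(val_rse)
            if (val_rmse, val_rse) < best:
                best = (val_rmse, val_rse)
                best_state = get_state(params)
    set_state(params, best_state)
    history["best_val_rmse"], history["best_val_rse"] = best
    history["val_indices"] = [int(i) for i in val_idx]
    return model, history
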