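"""Graph encoders for molecules.

Two encoders share the molecular graph vocabulary from
:mod:`cpifusion.chem`:

* :class:`PNAEncoder` — principal neighborhood aggregation over the 2D
  bond graph. Each layer aggregates neighbor messages with several
  aggregators (mean, max, min, std), rescales them with degree-dependent
  scalers (identity, amplification, attenuation), and updates node
  states; the graph readout concatenates several node-set reductions.
* :class:`Encoder3D` — a message-passing network over one 3D conformer
  that consumes only interatomic distances (radial-basis expanded), and
  is therefore invariant to rigid rotations and translations by
  construction.

The contrastive pretraining stage aligns the two encoders' outputs; the
fine-tuning stage reuses the PNA encoder's node features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .chem import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, ConformerCoords, MolecularGraph
from .nn import Linear, Module

__all__ = ["PNAConfig", "GraphData", "prepare_graph", "PNAEncoder", "Encoder3D"]

_AGGREGATORS = ("mean", "max", "min", "std")
_SCALERS = ("identity", "amplification", "attenuation")
_READOUTS = ("min", "max", "mean", "sum")


@dataclass
class PNAConfig:
    hidden_dim: int = 32
    n_layers: int = 3
    aggregators: tuple[str, ...] = _AGGREGATORS
    scalers: tuple[str, ...] = _SCALERS
    readouts: tuple[str, ...] = _READOUTS
    avg_degree: float = 2.0   # training-set mean node degree, used by the scalers
    out_dim: int = 32

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        unknown = (set(self.aggregators) - set(_AGGREGATORS)) | \
                  (set(self.scalers) - set(_SCALERS)) | \
                  (set(self.readouts) - set(_READOUTS))
        if unknown:
            raise ValueError(f"unknown aggregator/scaler/readout names: {unknown}")


@dataclass
class GraphData:
    """A molecular graph unpacked into arrays for message passing."""
    node_feat: np.ndarray        # (n, ATOM_FEATURE_DIM)
    src: np.ndarray              # (E,) directed edge sources
    dst: np.ndarray              # (E,) directed edge targets
    edge_feat: np.ndarray        # (E, BOND_FEATURE_DIM)
    incidence: np.ndarray        # (n, E), 1 where dst == node
    deg: np.ndarray              # (n,)

    @property
    def n_nodes(self) -> int:
        return self.node_feat.shape[0]


def prepare_graph(graph: MolecularGraph) -> GraphData:
    """Expand an undirected featurized graph into directed-edge arrays."""
    n = graph.n_nodes
    src, dst, feats = [], [], []
    for i, j, f in graph.edges:
        src += [i, j]
        dst += [j, i]
        feats += [f, f]
    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    edge_feat = np.asarray(feats).reshape(len(src), BOND_FEATURE_DIM)
    incidence = np.zeros((n, len(src)))
    incidence[dst, np.arange(len(src))] = 1.0
    deg = incidence.sum(axis=1)
    return GraphData(graph.node_features, src, dst, edge_feat, incidence, deg)


def mean_degree(graphs: list[GraphData]) -> float:
    """Average node degree over a molecule set (input to the PNA scalers)."""
    degs = np.concatenate([g.deg for g in graphs]) if graphs else np.array([1.0])
    return float(max(degs.mean(), 1e-6))


class PNALayer(Module):
    def __init__(self, cfg: PNAConfig, rng: np.random.Generator):
        d = cfg.hidden_dim
        self.cfg = cfg
        self.msg = Linear(d + BOND_FEATURE_DIM, d, rng)
        self.update = Linear(
            d + len(cfg.aggregators) * len(cfg.scalers) * d, d, rng)

    def _aggregate(self, m: Tensor, g: GraphData) -> Tensor:
        """Per-node multi-aggregator summary of incoming messages (n, n_agg*d)."""
        cfg = self.cfg
        d = cfg.hidden_dim
        n = g.n_nodes
        inc = g.incidence
        deg = np.maximum(g.deg, 1.0)[:, None]
        has_nb = (g.deg > 0).astype(float)[:, None]
        inc_t = Tensor(inc)
        msum = inc_t @ m
        pieces = []
        for name in cfg.aggregators:
            if name == "mean":
                pieces.append(msum * (1.0 / deg))
            elif name == "std":
                ex2 = (inc_t @ (m * m)) * (1.0 / deg)
                mean = msum * (1.0 / deg)
                pieces.append(((ex2 - mean * mean).relu() + 1e-10).sqrt() * has_nb)
            elif name in ("max", "min"):
                sign = 1.0 if name == "max" else -1.0
                mask3 = inc[:, :, None]                      # (n, E, 1)
                expanded = m.reshape(1, m.shape[0], d) * mask3 \
                    + Tensor((mask3 - 1.0) * 1e9 * sign)
                ext = expanded.max(axis=1) if name == "max" else expanded.min(axis=1)
                pieces.append(ext * has_nb)
        return concat(pieces, axis=1)

    def _scale(self, agg: Tensor, g: GraphData) -> Tensor:
        cfg = self.cfg
        log_avg = np.log(cfg.avg_degree + 1.0)
        log_deg = np.log(g.deg + 1.0)[:, None]
        scaled = []
        for name in cfg.scalers:
            if name == "identity":
                scaled.append(agg)
            elif name == "amplification":
                scaled.append(agg * (log_deg / log_avg))
            elif name == "attenuation":
                # deg 0 has no messages anyway; avoid 0-division
                inv = np.where(log_deg > 0, log_avg / np.maximum(log_deg, 1e-12), 0.0)
                scaled.append(agg * inv)
        return concat(scaled, axis=1)

    def __call__(self, h: Tensor, g: GraphData) -> Tensor:
        cfg = self.cfg
        width = len(cfg.aggregators) * len(cfg.scalers) * cfg.hidden_dim
        if g.src.size == 0:
            combined = Tensor(np.zeros((g.n_nodes, width)))
        else:
            m = self.msg(concat([h[g.src], Tensor(g.edge_feat)], axis=1)).relu()
            combined = self._scale(self._aggregate(m, g), g)
        return self.update(concat([h, combined], axis=1)).relu()


def _readout(h: Tensor, names: tuple[str, ...]) -> Tensor:
    parts = []
    for name in names:
        if name == "mean":
            parts.append(h.mean(axis=0))
        elif name == "sum":
            parts.append(h.sum(axis=0))
        elif name == "max":
            parts.append(h.max(axis=0))
        elif name == "min":
            parts.append(h.min(axis=0))
    return concat(parts, axis=0)


class PNAEncoder(Module):
    """2D molecular graph encoder ("what" branch of the compound view)."""

    def __init__(self, cfg: PNAConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.embed = Linear(ATOM_FEATURE_DIM, cfg.hidden_dim, rng)
        self.layers = [PNALayer(cfg, rng) for _ in range(cfg.n_layers)]
        self.readout = Linear(len(cfg.readouts) * cfg.hidden_dim, cfg.out_dim, rng)

    def node_features(self, g: GraphData) -> Tensor:
        h = self.embed(Tensor(g.node_feat)).relu()
        for layer in self.layers:
            h = layer(h, g)
        return h

    def __call__(self, g: GraphData) -> tuple[Tensor, Tensor]:
        """Return (graph embedding (out_dim,), node feature matrix (n, hidden))."""
        h = self.node_features(g)
        emb = self.readout(_readout(h, self.cfg.readouts).reshape(1, -1)).reshape(-1)
        return emb, h


def rbf_expand(dist: np.ndarray, n_centers: int = 16, d_max: float = 8.0) -> np.ndarray:
    """Gaussian radial basis expansion of distances over [0, d_max] Å."""
    centers = np.linspace(0.0, d_max, n_centers)
    width = d_max / (n_centers - 1)
    return np.exp(-((dist[:, None] - centers[None, :]) ** 2) / (2.0 * width ** 2))


class Encoder3D(Module):
    """Distance-based conformer encoder; rigid-motion invariant by construction."""

    N_RBF = 16
    D_MAX = 8.0
    N_ROUNDS = 3

    def __init__(self, hidden_dim: int, out_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.embed = Linear(ATOM_FEATURE_DIM, hidden_dim, rng)
        self.msg = [Linear(hidden_dim + self.N_RBF, hidden_dim, rng)
                    for _ in range(self.N_ROUNDS)]
        self.update = [Linear(2 * hidden_dim, hidden_dim, rng)
                       for _ in range(self.N_ROUNDS)]
        self.readout = Linear(2 * hidden_dim, out_dim, rng)

    def __call__(self, g: GraphData, conf: ConformerCoords) -> Tensor:
        coords = np.asarray(conf.coords, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("conformer coordinates contain NaN/Inf")
        n = g.n_nodes
        if coords.shape != (n, 3):
            raise ValueError(
                f"conformer has {coords.shape[0]} rows for a {n}-atom graph")
        h = self.embed(Tensor(g.node_feat)).relu()
        if n > 1:
            src, dst = np.nonzero(~np.eye(n, dtype=bool))
            dist = np.linalg.norm(coords[src] - coords[dst], axis=1)
            edge = Tensor(rbf_expand(dist, self.N_RBF, self.D_MAX))
            inc = np.zeros((n, len(src)))
            inc[dst, np.arange(len(src))] = 1.0
            inc_t = Tensor(inc / (n - 1))  # mean aggregation
            for msg_lin, upd_lin in zip(self.msg, self.update):
                m = msg_lin(concat([h[src], edge], axis=1)).relu()
                h = upd_lin(concat([h, inc_t @ m], axis=1)).relu()
        pooled = concat([h.mean(axis=0), h.sum(axis=0)], axis=0)
        return self.readout(pooled.reshape(1, -1)).reshape(-1)
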