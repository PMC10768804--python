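"""Contrastive 3D-aware pretraining of the molecular graph encoder.

A 2D graph encoder (PNA) and a distance-based 3D conformer encoder are
trained jointly so that the 2D embedding of molecule *i* is similar to
the 3D embeddings of its own conformers and dissimilar to conformers of
other molecules in the batch — a normalized temperature-scaled
cross-entropy (NT-Xent) objective over cosine similarities:

    L = −(1/N) Σ_i log [ Σ_j exp(sim(z2d_i, z3d_{i,j})/τ)
                       / Σ_{k≠i} Σ_j exp(sim(z2d_i, z3d_{k,j})/τ) ]

with N molecules and c conformers per molecule. Note the denominator as
written above runs over *other* molecules only (the positive pair is
excluded), which differs from the canonical NT-Xent convention of
including it; the canonical variant is available behind
``include_positives_in_denominator=True``. Under the default form the
loss equals ln(N−1) when all embeddings coincide and can be negative.

After pretraining, the first ⌊fraction · n_layers⌋ PNA message-passing
layers (counted from the input) can be frozen for fine-tuning; the
admissible freeze fraction range is [0, 0.95].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, stack
from .chem import MoleculeRecord
from .graphnet import Encoder3D, GraphData, PNAConfig, PNAEncoder, mean_degree, prepare_graph
from .nn import Adam, Module

__all__ = [
    "EmbeddingBatch", "FreezeMask", "PretrainResult", "ntxent_loss",
    "pretrain", "build_freeze_mask", "apply_freeze",
    "save_checkpoint", "load_checkpoint",
]

MAX_FREEZE_FRACTION = 0.95


@dataclass
class EmbeddingBatch:
    z2d: Tensor      # (N, d)
    z3d: Tensor      # (N, c, d)
    tau: float

    @property
    def n_molecules(self) -> int:
        return self.z2d.shape[0]

    @property
    def n_conformers(self) -> int:
        return self.z3d.shape[1]


def _l2_normalize(x: Tensor) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
    return x / norm


def ntxent_loss(batch: EmbeddingBatch,
                include_positives_in_denominator: bool = False) -> Tensor:
    """NT-Xent contrastive loss over cosine similarities (see module docstring)."""
    if batch.tau <= 0:
        raise ValueError("temperature tau must be positive")
    N = batch.n_molecules
    c = batch.n_conformers
    if N < 2:
        raise ValueError("NT-Xent needs at least two molecules in the batch")
    z2 = _l2_normalize(batch.z2d)                                  # (N, d)
    z3 = _l2_normalize(batch.z3d.reshape(N * c, -1))               # (N*c, d)
    sims = z2 @ z3.T                                               # (N, N*c)
    e = (sims * (1.0 / batch.tau)).exp()
    pos_mask = np.zeros((N, N * c))
    for i in range(N):
        pos_mask[i, i * c:(i + 1) * c] = 1.0
    pos = (e * Tensor(pos_mask)).sum(axis=1)
    neg = (e * Tensor(1.0 - pos_mask)).sum(axis=1)
    denom = neg + pos if include_positives_in_denominator else neg
    return -(pos.log() - denom.log()).mean()


@dataclass
class FreezeMask:
    fraction: float
    frozen_parameter_ids: set = field(default_factory=set)

    def __post_init__(self):
        if not (0.0 <= self.fraction <= MAX_FREEZE_FRACTION):
            raise ValueError(
                f"freeze fraction must lie in [0, {MAX_FREEZE_FRACTION}], "
                f"got {self.fraction}")


def build_freeze_mask(encoder: PNAEncoder, fraction: float) -> FreezeMask:
    """Mask covering the first ⌊fraction · n_layers⌋ PNA layers from the input."""
    mask = FreezeMask(fraction=fraction)
    n_frozen = int(np.floor(fraction * encoder.cfg.n_layers))
    for i in range(n_frozen):
        for name, _ in encoder.layers[i].named_parameters(prefix=f"layers.{i}."):
            mask.frozen_parameter_ids.add(name)
    return mask


def apply_freeze(encoder: PNAEncoder, mask: FreezeMask) -> PNAEncoder:
    """Flag masked parameters so optimizers leave them bitwise unchanged."""
    if not (0.0 <= mask.fraction <= MAX_FREEZE_FRACTION):
        raise ValueError("freeze fraction outside admissible range")
    for name, p in encoder.named_parameters():
        p.frozen = name in mask.frozen_parameter_ids
    return encoder


@dataclass
class PretrainResult:
    encoder2d: PNAEncoder
    encoder3d: Encoder3D
    config: PNAConfig
    losses: list[float]
    tau: float


def pretrain(molecules: list[MoleculeRecord], cfg: PNAConfig | None = None,
             epochs: int = 30, seed: int = 0, tau: float = 0.1,
             lr: float = 1e-3,
             include_positives_in_denominator: bool = False) -> PretrainResult:
    """Jointly train the 2D and 3D encoders with the contrastive objective.

    Runs full-batch over the molecule set; the number of conformers per
    molecule is truncated to the smallest count present so the batch is
    rectangular. Deterministic for a fixed seed.
    """
    if not molecules:
        raise ValueError("pretrain requires a nonempty molecule list")
    if len(molecules) < 2:
        raise ValueError("NT-Xent pretraining needs at least two molecules")
    for m in molecules:
        if not m.conformers:
            raise ValueError(f"molecule {m.id!r} has no conformers")
    c = min(len(m.conformers) for m in molecules)
    graphs = [prepare_graph(m.graph) for m in molecules]
    if cfg is None:
        cfg = PNAConfig()
    cfg.avg_degree = mean_degree(graphs)
    rng = np.random.default_rng(seed)
    enc2d = PNAEncoder(cfg, rng)
    enc3d = Encoder3D(cfg.hidden_dim, cfg.out_dim, rng)
    params = enc2d.parameters() + enc3d.parameters()
    opt = Adam(params, lr=lr)
    losses: list[float] = []
    for _ in range(epochs):
        z2 = stack([enc2d(g)[0] for g in graphs], axis=0)
        z3 = stack(
            [stack([enc3d(g, m.conformers[j]) for j in range(c)], axis=0)
             for g, m in zip(graphs, molecules)], axis=0)
        loss = ntxent_loss(EmbeddingBatch(z2, z3, tau),
                           include_positives_in_denominator)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return PretrainResult(enc2d, enc3d, cfg, losses, tau)


def save_checkpoint(path, module: Module, meta: dict) -> None:
    """Persist parameters plus a JSON metadata header to an .npz file."""
    payload = {f"param/{k}": v for k, v in module.state_dict().items()}
    payload["__meta__"] = np.frombuffer(
        json.dumps({"format": "cpifusion-ckpt-1", **meta}).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format") != "cpifusion-ckpt-1":
            raise ValueError(f"unsupported checkpoint format in {path}")
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    return state, meta
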