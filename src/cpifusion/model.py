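"""Compound–protein fusion network and its training loop.

The fine-tuning model combines four information streams:

* compound "what": per-atom features from the (optionally pretrained)
  PNA graph encoder — keys/values of the compound cross-attention;
* compound "where": one learnable embedding row per set fingerprint
  bit (a lookup table, suited to very sparse binary inputs) — queries;
* protein "what": a 1D convolutional tower over the atomic one-hot
  matrix ``A`` — keys/values of the protein cross-attention;
* protein "where": a 2D convolutional tower over the Fourier-mapped
  Cα distance map, flattened per residue block — queries.

Each cross-attention is ``softmax(Q Kᵀ / √(C/h))·V`` per head with a
residual and layer norm on the query path. The attended matrices are
mean-pooled into vectors ``x_comp`` and ``x_prot``, concatenated, and
passed through a two-layer MLP head:

    z = σ(w_zᵀ [x_comp; x_prot] + b_z),   ŷ = σ_out(w_oᵀ z + b_o)

with σ = ReLU and σ_out the identity for regression (MSE objective) or
the logistic function for classification (binary cross-entropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, stack
from .chem import FingerprintVector, MoleculeRecord
from .graphnet import GraphData, PNAConfig, PNAEncoder, prepare_graph
from .nn import Adam, Conv1d, Conv2d, CrossAttention, Embedding, Linear, Module, max_pool1d, max_pool2d
from .protein import ProteinStructure, build_atom_feature_matrix, build_distance_map, fourier_map

__all__ = [
    "FusionConfig", "InteractionRecord", "ProteinInput", "FusionModel",
    "featurize_protein", "cross_attention", "embed_fingerprint", "train",
    "TrainResult",
]


@dataclass
class FusionConfig:
    pna: PNAConfig = field(default_factory=PNAConfig)
    fp_bits: int = 2048
    fp_embed_dim: int = 32
    attn_dim: int = 32          # C of the cross-attention blocks
    n_heads: int = 4            # h; per-head dim C/h
    conv1d_channels: int = 16
    conv1d_kernel: int = 7
    conv1d_pool: int = 4
    conv2d_channels: int = 8
    conv2d_kernel: int = 3
    conv2d_pool: int = 2
    n_conv_layers: int = 3
    head_hidden: int = 32
    fourier_F: int = 4
    max_residues: int = 64      # proteins are truncated/padded (with masks) to this
    max_atoms: int = 256
    task: str = "regression"    # or "classification"

    def __post_init__(self):
        if self.attn_dim % self.n_heads != 0:
            raise ValueError("attn_dim must be divisible by n_heads")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class InteractionRecord:
    compound_id: str
    protein_id: str
    label: float
    task: str = "regression"


@dataclass
class ProteinInput:
    """Padded, masked protein views ready for the convolutional towers."""
    A: np.ndarray          # (M_pad, N) one-hot rows, zero rows where padded
    atom_mask: np.ndarray  # (M_pad,) 1 = real atom
    G: np.ndarray          # (L_pad, L_pad, 2F+1)
    res_mask: np.ndarray   # (L_pad,) 1 = real residue


def featurize_protein(s: ProteinStructure, cfg: FusionConfig) -> ProteinInput:
    """Build the padded A / γ(D) pair for one structure.

    Proteins longer than the configured maxima are truncated from the
    C-terminal end; shorter ones are zero-padded with explicit masks.
    """
    afm = build_atom_feature_matrix(s)
    A = afm.A[: cfg.max_atoms]
    m = A.shape[0]
    A_pad = np.zeros((cfg.max_atoms, A.shape[1]))
    A_pad[:m] = A
    atom_mask = np.zeros(cfg.max_atoms)
    atom_mask[:m] = 1.0

    G_full = fourier_map(build_distance_map(s), cfg.fourier_F).G
    L = min(G_full.shape[0], cfg.max_residues)
    G_pad = np.zeros((cfg.max_residues, cfg.max_residues, G_full.shape[2]))
    G_pad[:L, :L] = G_full[:L, :L]
    res_mask = np.zeros(cfg.max_residues)
    res_mask[:L] = 1.0
    return ProteinInput(A=A_pad, atom_mask=atom_mask, G=G_pad, res_mask=res_mask)


def embed_fingerprint(fp: FingerprintVector, table: Embedding) -> Tensor:
    """One embedding row per set bit, gathered from the lookup table."""
    on = fp.on_bits()
    if on.size == 0:
        raise ValueError("cannot embed an all-zero fingerprint")
    return table(on)


def cross_attention(q_src: Tensor, kv_src: Tensor, block: CrossAttention,
                    key_mask: np.ndarray | None = None) -> Tensor:
    """Raw multi-head cross-attention output (no residual/norm), one row per query."""
    out, _ = block.attend(q_src, kv_src, key_mask)
    return out


def _pool_mask_1d(mask: np.ndarray, size: int) -> np.ndarray:
    rem = (-len(mask)) % size
    if rem:
        mask = np.concatenate([mask, np.zeros(rem)])
    return mask.reshape(-1, size).max(axis=1)


class FusionModel(Module):
    def __init__(self, cfg: FusionConfig, rng: np.random.Generator,
                 atom_matrix_width: int):
        self.cfg = cfg
        self.pna = PNAEncoder(cfg.pna, rng)
        self.fp_embed = Embedding(cfg.fp_bits, cfg.fp_embed_dim, rng)
        self.comp_attn = CrossAttention(
            cfg.fp_embed_dim, cfg.pna.hidden_dim, cfg.attn_dim, cfg.n_heads, rng)
        c1, c2 = cfg.conv1d_channels, cfg.conv2d_channels
        self.tower1d = [Conv1d(atom_matrix_width if i == 0 else c1, c1,
                               cfg.conv1d_kernel, rng)
                        for i in range(cfg.n_conv_layers)]
        self.tower2d = [Conv2d((2 * cfg.fourier_F + 1) if i == 0 else c2, c2,
                               cfg.conv2d_kernel, rng)
                        for i in range(cfg.n_conv_layers)]
        l_out = cfg.max_residues
        for _ in range(cfg.n_conv_layers):
            l_out = -(-l_out // cfg.conv2d_pool)
        self._l_out = l_out
        self.prot_attn = CrossAttention(
            l_out * c2, c1, cfg.attn_dim, cfg.n_heads, rng)
        self.head_hidden = Linear(2 * cfg.attn_dim, cfg.head_hidden, rng)
        self.head_out = Linear(cfg.head_hidden, 1, rng)

    # -- compound branch ------------------------------------------------------
    def encode_compound(self, mol: MoleculeRecord,
                        graph: GraphData | None = None) -> Tensor:
        g = graph if graph is not None else prepare_graph(mol.graph)
        o_what = self.pna.node_features(g)                 # K, V  (n_atoms, d)
        o_where = embed_fingerprint(mol.fingerprint, self.fp_embed)  # Q
        fused = self.comp_attn(o_where, o_what)            # (n_set_bits, C)
        return fused.mean(axis=0)

    # -- protein branch -------------------------------------------------------
    def encode_protein(self, pin: ProteinInput) -> Tensor:
        cfg = self.cfg
        # 1D tower over atom rows; re-mask after every layer so padded atoms
        # never leak into valid positions through the convolution support
        x = Tensor(pin.A.T)                                # (N, M)
        amask = pin.atom_mask
        for conv in self.tower1d:
            x = conv(x).relu() * Tensor(amask[None, :])
            x = max_pool1d(x, cfg.conv1d_pool)
            amask = _pool_mask_1d(amask, cfg.conv1d_pool)
        t_what = x.transpose(1, 0)                         # (M', c1) keys/values
        key_mask = amask

        rmask2 = np.outer(pin.res_mask, pin.res_mask)
        y = Tensor(np.transpose(pin.G, (2, 0, 1)))         # (2F+1, L, L)
        rmask = pin.res_mask
        for conv in self.tower2d:
            y = conv(y).relu() * Tensor(rmask2[None, :, :])
            y = max_pool2d(y, cfg.conv2d_pool)
            rmask = _pool_mask_1d(rmask, cfg.conv2d_pool)
            rmask2 = np.outer(rmask, rmask)
        # flatten per residue block: row i of the pooled map becomes query i
        t_where = y.transpose(1, 0, 2).reshape(y.shape[1], -1)   # (L', c2*L')
        fused = self.prot_attn(t_where, t_what, key_mask=key_mask)  # (L', C)
        qweights = rmask / max(rmask.sum(), 1.0)
        return (fused * Tensor(qweights[:, None])).sum(axis=0)

    # -- head -----------------------------------------------------------------
    def predict(self, x_comp: Tensor, x_prot: Tensor) -> Tensor:
        z = self.head_hidden(concat([x_comp, x_prot], axis=0).reshape(1, -1)).relu()
        out = self.head_out(z).reshape(-1)[0]
        if self.cfg.task == "classification":
            out = out.sigmoid()
        return out

    def __call__(self, mol: MoleculeRecord, pin: ProteinInput,
                 graph: GraphData | None = None) -> Tensor:
        return self.predict(self.encode_compound(mol, graph),
                            self.encode_protein(pin))


@dataclass
class TrainResult:
    model: FusionModel
    history: list[dict]         # per-epoch {"epoch", "train_loss", "val_loss"}
    best_epoch: int


def _sample_loss(model: FusionModel, mol, pin, graph, label: float) -> Tensor:
    yhat = model(mol, pin, graph)
    if model.cfg.task == "classification":
        eps = 1e-9
        y = float(label)
        return -(yhat + eps).log() * y - (1.0 - yhat + eps).log() * (1.0 - y)
    diff = yhat - label
    return diff * diff


def train(dataset: list[InteractionRecord],
          compounds: dict[str, MoleculeRecord],
          proteins: dict[str, ProteinInput],
          model: FusionModel,
          epochs: int = 50, batch_size: int = 32, lr: float = 1e-4,
          seed: int = 0, val_fraction: float = 0.1, patience: int = 5) -> TrainResult:
    """Mini-batch training with early stopping on a held-out validation split.

    Frozen parameters (see the pretraining module's freeze utilities) are
    skipped by the optimizer and stay bitwise unchanged. Reproducible for
    a fixed seed.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    tasks = {r.task for r in dataset}
    if len(tasks) > 1:
        raise ValueError(f"mixed tasks in dataset: {tasks}")
    if tasks != {model.cfg.task}:
        raise ValueError(
            f"dataset task {tasks} does not match model task {model.cfg.task!r}")
    missing = ({r.compound_id for r in dataset} - set(compounds)) | \
              ({r.protein_id for r in dataset} - set(proteins))
    if missing:
        raise KeyError(f"unfeaturized entities referenced by dataset: {sorted(missing)}")

    graphs = {cid: prepare_graph(m.graph) for cid, m in compounds.items()}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(val_fraction * len(dataset)))) if len(dataset) > 4 else 0
    val_idx = order[:n_val]
    tr_idx = order[n_val:]
    opt = Adam(model.parameters(), lr=lr)

    def eval_loss(indices) -> float:
        if len(indices) == 0:
            return float("nan")
        total = 0.0
        for i in indices:
            r = dataset[i]
            total += _sample_loss(model, compounds[r.compound_id],
                                  proteins[r.protein_id],
                                  graphs[r.compound_id], r.label).item()
        return total / len(indices)

    history: list[dict] = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    bad = 0
    for epoch in range(epochs):
        perm = rng.permutation(tr_idx)
        running = 0.0
        for start in range(0, len(perm), batch_size):
            chunk = perm[start:start + batch_size]
            losses = []
            for i in chunk:
                r = dataset[i]
                losses.append(_sample_loss(model, compounds[r.compound_id],
                                           proteins[r.protein_id],
                                           graphs[r.compound_id], r.label))
            batch_loss = stack(losses, axis=0).mean()
            opt.zero_grad()
            batch_loss.backward()
            opt.step()
            running += batch_loss.item() * len(chunk)
        train_loss = running / max(len(perm), 1)
        val_loss = eval_loss(val_idx)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        monitored = val_loss if n_val else train_loss
        if monitored < best_val - 1e-9:
            best_val = monitored
            best_state = model.state_dict()
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


def predict_dataset(dataset: list[InteractionRecord],
                    compounds: dict[str, MoleculeRecord],
                    proteins: dict[str, ProteinInput],
                    model: FusionModel) -> np.ndarray:
    graphs = {cid: prepare_graph(m.graph) for cid, m in compounds.items()}
    return np.array([
        model(compounds[r.compound_id], proteins[r.protein_id],
              graphs[r.compound_id]).item()
        for r in dataset])
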