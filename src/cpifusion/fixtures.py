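"""Synthetic fixtures: toy molecules, ideal-helix proteins, planted-signal data.

Everything the pipeline consumes can be generated offline and
deterministically from a seed:

* **molecules** — drug-like SMILES assembled from a small library of ring
  scaffolds crossed with common substituents, each embedded with ETKDG
  conformers; the library spans several Butina clusters so the
  cluster-splitting machinery has real structure to work with;
* **proteins** — ideal α-helices (rise 1.5 Å, 100° twist, 2.3 Å radius)
  with four heavy backbone atoms per residue and a random sequence,
  serialized as valid PDB text;
* **interaction datasets** — labels are a linear function of a compound's
  Butina-cluster identity and a protein's amino-acid composition summary
  plus Gaussian noise, a planted signal that a correctly wired model can
  partially recover (and that vanishes under label permutation).

These fixtures exercise code paths and statistical contracts; they do not
imitate real binding physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import MoleculeRecord, generate_conformers, parse_molecule
from .model import InteractionRecord
from .protein import ProteinStructure, parse_structure
from .split import butina_cluster

__all__ = [
    "FixtureSpec", "make_toy_molecules", "make_toy_protein",
    "make_toy_dataset", "ToyDataset", "write_fixture_directory",
]

# ring scaffolds × substituents; appended groups keep the SMILES valid
_SCAFFOLDS = [
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "C1CCNCC1",        # piperidine
    "c1ccc2[nH]ccc2c1",  # indole
    "C1CCOC1",         # tetrahydrofuran
    "c1ccsc1",         # thiophene
]
_SUBSTITUENTS = [
    "C", "CC", "CCC", "O", "OC", "N", "NC", "Cl", "F",
    "C(=O)O", "C(=O)N", "C#N", "CO", "CN", "S(=O)(=O)N",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_HELIX_RISE = 1.5      # Å per residue
_HELIX_TWIST = 100.0   # degrees per residue
_HELIX_RADIUS = 2.3    # Å

# crude per-letter composition summary channels: hydrophobic, aromatic,
# charged, polar — the protein side of the planted signal
_AA_CLASSES = {
    "hydrophobic": set("AVLIMCFWY"),
    "aromatic": set("FWYH"),
    "charged": set("DEKR"),
    "polar": set("STNQH"),
}


@dataclass
class FixtureSpec:
    n_compounds: int = 50
    n_proteins: int = 10
    n_interactions: int = 200
    noise_sd: float = 0.1
    signal_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_compounds, self.n_proteins, self.n_interactions) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def smiles_library() -> list[str]:
    return [s + r for s in _SCAFFOLDS for r in _SUBSTITUENTS]


def make_toy_molecules(n: int, seed: int = 0, n_conf: int = 2,
                       fp_radius: int = 2, fp_bits: int = 2048) -> list[MoleculeRecord]:
    """Draw `n` featurized molecules (with conformers) from the fixed library."""
    if n < 1:
        raise ValueError("n must be >= 1")
    library = smiles_library()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(library), size=n, replace=n > len(library))
    records = []
    for k, idx in enumerate(chosen):
        rec = parse_molecule(library[int(idx)], f"cmpd{k:03d}",
                             fp_radius=fp_radius, fp_bits=fp_bits)
        records.append(generate_conformers(rec, n_conf=n_conf, seed=seed + k))
    return records


def make_toy_protein(length: int, seed: int = 0,
                     protein_id: str = "toy") -> tuple[ProteinStructure, str]:
    """Ideal α-helix with 4 heavy atoms per residue; returns (structure, PDB text).

    Backbone N, CA, C, O are placed at fixed local offsets from each Cα
    position on the helix; the sequence is drawn uniformly from the 20
    standard amino acids.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AA20), size=length))
    one_to_three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    lines = []
    serial = 1
    offsets = {  # local heavy-atom offsets from Cα, Å
        "N": np.array([-1.20, 0.60, -0.50]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.25, 0.55, 0.45]),
        "O": np.array([1.35, 1.75, 0.60]),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    for i in range(length):
        theta = np.deg2rad(_HELIX_TWIST * i)
        ca = np.array([_HELIX_RADIUS * np.cos(theta),
                       _HELIX_RADIUS * np.sin(theta),
                       _HELIX_RISE * i])
        res3 = one_to_three[seq[i]]
        for name in ("N", "CA", "C", "O"):
            xyz = ca + offsets[name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {elements[name]:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"
    # build the structure from exact coordinates (PDB text rounds to 3 decimals)
    residues = [(i, one_to_three[seq[i]]) for i in range(length)]
    atoms = []
    ca_list = []
    for i in range(length):
        theta = np.deg2rad(_HELIX_TWIST * i)
        ca = np.array([_HELIX_RADIUS * np.cos(theta),
                       _HELIX_RADIUS * np.sin(theta),
                       _HELIX_RISE * i])
        ca_list.append(ca)
        for name in ("N", "CA", "C", "O"):
            atoms.append((name, i, elements[name], ca + offsets[name]))
    structure = ProteinStructure(id=protein_id, residues=residues, atoms=atoms,
                                 ca_coords=np.array(ca_list))
    return structure, pdb_text


def _composition_summary(sequence: str) -> np.ndarray:
    counts = np.array([
        sum(ch in _AA_CLASSES[k] for ch in sequence)
        for k in ("hydrophobic", "aromatic", "charged", "polar")], dtype=float)
    return counts / max(len(sequence), 1)


@dataclass
class ToyDataset:
    spec: FixtureSpec
    compounds: list[MoleculeRecord]
    proteins: list[ProteinStructure]
    pdb_texts: dict[str, str]
    interactions: list[InteractionRecord]
    latent: np.ndarray                   # noise-free labels
    design: np.ndarray                   # generating feature matrix (rows per interaction)
    compound_cluster: dict[str, int] = field(default_factory=dict)


def make_toy_dataset(spec: FixtureSpec, task: str = "regression",
                     butina_cutoff: float = 0.6, fp_radius: int = 2,
                     fp_bits: int = 2048) -> ToyDataset:
    """Interaction dataset with a planted linear signal.

    label(c, p) = w · [one-hot Butina cluster of c ; composition summary
    of p] + N(0, noise_sd²). The binary variant thresholds the latent
    value at its median. Byte-identical regeneration for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    compounds = make_toy_molecules(spec.n_compounds, seed=spec.seed,
                                   fp_radius=fp_radius, fp_bits=fp_bits)
    labels = butina_cluster([m.fingerprint for m in compounds], cutoff=butina_cutoff)
    cluster_of = {m.id: int(l) for m, l in zip(compounds, labels)}
    n_clusters = int(labels.max()) + 1

    proteins, pdb_texts = [], {}
    for k in range(spec.n_proteins):
        length = int(rng.integers(20, 41))
        s, text = make_toy_protein(length, seed=spec.seed + 1000 + k,
                                   protein_id=f"prot{k:03d}")
        proteins.append(s)
        pdb_texts[s.id] = text

    n_feat = n_clusters + 4
    if spec.signal_weights is not None:
        w = np.asarray(spec.signal_weights, dtype=float)
        if w.size != n_feat:
            raise ValueError(
                f"signal_weights must have {n_feat} entries "
                f"({n_clusters} compound clusters + 4 composition channels)")
    else:
        w = np.concatenate([rng.normal(0.0, 0.7, size=n_clusters),
                            rng.normal(0.0, 8.0, size=4)])

    pairs = list({(int(rng.integers(spec.n_compounds)),
                   int(rng.integers(spec.n_proteins)))
                  for _ in range(spec.n_interactions * 3)})
    pairs.sort()
    rng.shuffle(pairs)
    pairs = pairs[: spec.n_interactions]
    while len(pairs) < spec.n_interactions:  # tiny grids: repeat pairs to fill
        pairs.append((int(rng.integers(spec.n_compounds)),
                      int(rng.integers(spec.n_proteins))))

    design, latent, interactions = [], [], []
    for ci, pi in pairs:
        c = compounds[ci]
        p = proteins[pi]
        x = np.zeros(n_feat)
        x[cluster_of[c.id]] = 1.0
        x[n_clusters:] = _composition_summary(p.sequence)
        design.append(x)
        latent.append(float(w @ x))
    latent = np.array(latent)
    noisy = latent + rng.normal(0.0, spec.noise_sd, size=latent.size)
    if task == "classification":
        thresh = np.median(latent)
        values = (noisy > thresh).astype(float)
    elif task == "regression":
        values = noisy
    else:
        raise ValueError(f"unknown task {task!r}")
    for (ci, pi), y in zip(pairs, values):
        interactions.append(InteractionRecord(
            compound_id=compounds[ci].id, protein_id=proteins[pi].id,
            label=float(y), task=task))
    return ToyDataset(spec=spec, compounds=compounds, proteins=proteins,
                      pdb_texts=pdb_texts, interactions=interactions,
                      latent=latent, design=np.array(design),
                      compound_cluster=cluster_of)


def write_fixture_directory(data: ToyDataset, out_dir) -> None:
    """Write SMILES CSV, PDB files, and the interaction CSV to a directory."""
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    with open(out / "compounds.csv", "w") as fh:
        fh.write("compound_id,smiles\n")
        for m in data.compounds:
            fh.write(f"{m.id},{m.smiles}\n")
    for pid, text in data.pdb_texts.items():
        (out / "structures" / f"{pid}.pdb").write_text(text)
    with open(out / "interactions.csv", "w") as fh:
        fh.write("compound_id,protein_id,structure_path,label,task\n")
        for r in data.interactions:
            fh.write(f"{r.compound_id},{r.protein_id},"
                     f"structures/{r.protein_id}.pdb,{r.label},{r.task}\n")
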