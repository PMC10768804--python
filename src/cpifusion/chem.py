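"""Compound featurization: molecular graphs, Morgan fingerprints, conformers.

A compound enters the model through three complementary views:

* a molecular graph whose nodes carry per-atom chemical descriptors and
  whose edges carry bond descriptors — the local "what" of the molecule;
* a binary Morgan (circular) fingerprint marking hashed substructure
  environments up to a radius — the high-level "where";
* zero or more 3D conformer coordinate sets used by the contrastive
  pretraining stage.

All chemistry (SMILES parsing, fingerprinting, ETKDG conformer embedding)
is delegated to RDKit; hydrogens are implicit throughout, so graphs and
coordinates cover heavy atoms only.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdFingerprintGenerator

__all__ = [
    "MoleculeRecord", "MolecularGraph", "FingerprintVector", "ConformerCoords",
    "parse_molecule", "compute_morgan_fingerprint", "tanimoto",
    "generate_conformers", "molecules_from_table", "write_record_cache",
    "read_record_cache",
]

# Pauling electronegativities, scaled to [0, 1] by 4.0 (max = F 3.98).
_ELECTRONEG = {
    "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58, "F": 3.98,
    "P": 2.19, "Cl": 3.16, "Br": 2.96, "I": 2.66,
}
_ELEMENTS = ["C", "N", "O", "S", "F", "P", "Cl", "Br", "I", "other"]
_HYBRID = {
    Chem.HybridizationType.SP: 0,
    Chem.HybridizationType.SP2: 1,
    Chem.HybridizationType.SP3: 2,
}
_N_DEGREE = 6        # degrees 0..5
_N_CHARGE = 5        # formal charge −2..+2
_N_HYBRID = 4        # sp, sp2, sp3, other
_BOND_ORDERS = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

ATOM_FEATURE_DIM = len(_ELEMENTS) + _N_DEGREE + _N_CHARGE + _N_HYBRID + 1 + 1
BOND_FEATURE_DIM = 4 + 1  # one-hot bond order + ring flag

# one-hot block boundaries (start, stop), used by invariant checks
ATOM_ONEHOT_BLOCKS = (
    (0, len(_ELEMENTS)),
    (len(_ELEMENTS), len(_ELEMENTS) + _N_DEGREE),
    (len(_ELEMENTS) + _N_DEGREE, len(_ELEMENTS) + _N_DEGREE + _N_CHARGE),
    (len(_ELEMENTS) + _N_DEGREE + _N_CHARGE,
     len(_ELEMENTS) + _N_DEGREE + _N_CHARGE + _N_HYBRID),
)


@dataclass
class MolecularGraph:
    """Undirected heavy-atom graph with per-node and per-edge feature vectors."""
    node_features: np.ndarray                  # (n_atoms, ATOM_FEATURE_DIM)
    edges: list[tuple[int, int, np.ndarray]]   # (i, j, bond feature), i < j

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class FingerprintVector:
    bits: np.ndarray           # uint8 {0,1}, length n_bits
    radius: int
    n_bits: int

    def on_bits(self) -> np.ndarray:
        return np.nonzero(self.bits)[0]

    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass
class ConformerCoords:
    coords: np.ndarray         # (n_atoms, 3), Angstrom


@dataclass
class MoleculeRecord:
    id: str
    smiles: str
    graph: MolecularGraph
    fingerprint: FingerprintVector
    conformers: list[ConformerCoords] = field(default_factory=list)


class MoleculeParseError(ValueError):
    pass


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    v = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    v[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS) - 1] = 1.0
    off = len(_ELEMENTS)
    v[off + min(atom.GetDegree(), _N_DEGREE - 1)] = 1.0
    off += _N_DEGREE
    v[off + int(np.clip(atom.GetFormalCharge(), -2, 2)) + 2] = 1.0
    off += _N_CHARGE
    v[off + _HYBRID.get(atom.GetHybridization(), 3)] = 1.0
    off += _N_HYBRID
    v[off] = float(atom.GetIsAromatic())
    v[off + 1] = _ELECTRONEG.get(sym, 2.2) / 4.0
    return v


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    v = np.zeros(BOND_FEATURE_DIM)
    v[_BOND_ORDERS.get(bond.GetBondType(), 0)] = 1.0
    v[4] = float(bond.IsInRing())
    return v


def _mol_from_smiles(smiles: str, mol_id: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"invalid SMILES for molecule {mol_id!r}: {smiles!r}")
    return mol


def parse_molecule(smiles: str, mol_id: str, fp_radius: int = 2,
                   fp_bits: int = 2048) -> MoleculeRecord:
    """Parse a SMILES string into a featurized :class:`MoleculeRecord`.

    The graph covers heavy atoms only; conformers are left empty (attach
    them with :func:`generate_conformers`).
    """
    mol = _mol_from_smiles(smiles, mol_id)
    nodes = np.array([_atom_features(a) for a in mol.GetAtoms()])
    edges = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j), _bond_features(b)))
    graph = MolecularGraph(nodes, edges)
    record = MoleculeRecord(id=mol_id, smiles=smiles, graph=graph,
                            fingerprint=None)  # type: ignore[arg-type]
    record.fingerprint = compute_morgan_fingerprint(record, fp_radius, fp_bits)
    return record


def compute_morgan_fingerprint(mol: MoleculeRecord, radius: int = 2,
                               n_bits: int = 2048) -> FingerprintVector:
    """Binary circular fingerprint of hashed atom environments up to `radius`."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    rdmol = _mol_from_smiles(mol.smiles, mol.id)
    if rdmol.GetNumAtoms() == 0:
        raise MoleculeParseError(f"empty molecule {mol.id!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(rdmol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return FingerprintVector(bits=bits, radius=radius, n_bits=n_bits)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| between two binary fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints have different lengths")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        warnings.warn("tanimoto of two all-zero fingerprints defined as 0.0")
        return 0.0
    return inter / union


def generate_conformers(mol: MoleculeRecord, n_conf: int, seed: int) -> MoleculeRecord:
    """Attach up to `n_conf` ETKDG-embedded 3D conformers (heavy atoms only).

    Embedding runs with explicit hydrogens for realistic geometry, then
    hydrogens are stripped so coordinate rows align with graph nodes.
    Deterministic for a fixed seed; embedding failures are logged and the
    record is returned with however many conformers succeeded.
    """
    if n_conf < 1:
        raise ValueError("n_conf must be >= 1")
    rdmol = Chem.AddHs(_mol_from_smiles(mol.smiles, mol.id))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    ids = AllChem.EmbedMultipleConfs(rdmol, numConfs=n_conf, params=params)
    if len(ids) < n_conf:
        warnings.warn(
            f"molecule {mol.id!r}: embedded {len(ids)}/{n_conf} conformers")
    rdmol = Chem.RemoveHs(rdmol)
    conformers = []
    for cid in ids:
        conf = rdmol.GetConformer(int(cid))
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(rdmol.GetNumAtoms())])
        conformers.append(ConformerCoords(coords=coords))
    mol.conformers = conformers
    return mol


def molecules_from_table(df, smiles_col: str = "smiles", id_col: str = "compound_id",
                         fp_radius: int = 2, fp_bits: int = 2048) -> list[MoleculeRecord]:
    """Featurize every row of a DataFrame with SMILES and id columns."""
    return [parse_molecule(row[smiles_col], str(row[id_col]), fp_radius, fp_bits)
            for _, row in df.iterrows()]


def molecules_from_sdf(path, fp_radius: int = 2, fp_bits: int = 2048) -> list[MoleculeRecord]:
    """Featurize molecules from an SDF file; 3D coordinates, when present,
    are attached as a single conformer."""
    records = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for k, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"skipping unparseable SDF entry {k} in {path}")
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") \
            else f"sdf{k:04d}"
        smiles = Chem.MolToSmiles(mol)
        rec = parse_molecule(smiles, mol_id, fp_radius, fp_bits)
        if mol.GetNumConformers() > 0:
            # SMILES output reorders atoms; realign coordinates to graph nodes
            order = [int(i) for i in
                     mol.GetProp("_smilesAtomOutputOrder").strip("[]").split(",") if i]
            conf = mol.GetConformer()
            coords = np.array([[conf.GetAtomPosition(i).x,
                                conf.GetAtomPosition(i).y,
                                conf.GetAtomPosition(i).z] for i in order])
            if coords.shape[0] == rec.graph.n_nodes:
                rec.conformers.append(ConformerCoords(coords=coords))
        records.append(rec)
    return records


_CACHE_VERSION = "cpifusion-molcache-1"


def write_record_cache(records: list[MoleculeRecord], path) -> None:
    """Persist featurized records to an .npz cache with a versioned header."""
    payload: dict[str, np.ndarray] = {}
    meta = {"version": _CACHE_VERSION, "ids": [], "smiles": []}
    for r in records:
        meta["ids"].append(r.id)
        meta["smiles"].append(r.smiles)
        payload[f"{r.id}/nodes"] = r.graph.node_features
        edge_arr = np.array([[i, j] for i, j, _ in r.graph.edges], dtype=np.int64
                            ).reshape(-1, 2)
        feat_arr = np.array([f for _, _, f in r.graph.edges]).reshape(-1, BOND_FEATURE_DIM)
        payload[f"{r.id}/edges"] = edge_arr
        payload[f"{r.id}/edge_feats"] = feat_arr
        payload[f"{r.id}/fp"] = r.fingerprint.bits
        payload[f"{r.id}/fp_meta"] = np.array([r.fingerprint.radius, r.fingerprint.n_bits])
        for k, c in enumerate(r.conformers):
            payload[f"{r.id}/conf{k}"] = c.coords
        payload[f"{r.id}/n_conf"] = np.array([len(r.conformers)])
    meta["digest"] = hashlib.sha256(
        json.dumps(meta["smiles"]).encode()).hexdigest()[:16]
    payload["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def read_record_cache(path) -> list[MoleculeRecord]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != _CACHE_VERSION:
            raise ValueError(f"unsupported cache version in {path}")
        records = []
        for mol_id, smiles in zip(meta["ids"], meta["smiles"]):
            edges = [(int(i), int(j), f) for (i, j), f in
                     zip(z[f"{mol_id}/edges"], z[f"{mol_id}/edge_feats"])]
            graph = MolecularGraph(z[f"{mol_id}/nodes"], edges)
            radius, n_bits = (int(v) for v in z[f"{mol_id}/fp_meta"])
            fp = FingerprintVector(z[f"{mol_id}/fp"].astype(np.uint8), radius, n_bits)
            confs = [ConformerCoords(z[f"{mol_id}/conf{k}"])
                     for k in range(int(z[f"{mol_id}/n_conf"][0]))]
            records.append(MoleculeRecord(mol_id, smiles, graph, fp, confs))
    return records
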