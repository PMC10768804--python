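"""Protein featurization from 3D structures.

Two views are extracted from a PDB-format structure (typically a
structure-prediction output, e.g. from a single-sequence folding model):

* an atomic one-hot matrix ``A`` (M atoms × concatenated one-hot blocks
  for atom name, amino acid, and element) — the atomic-level "what";
* the residue-level Cα–Cα Euclidean distance map ``D`` (L × L, Å),
  lifted to a higher-dimensional tensor by a Fourier feature mapping
  γ(d) = [d, sin(d)/2⁰, cos(d)/2⁰, …, sin(d)/2^{F−1}, cos(d)/2^{F−1}]
  — the spatial "where".

Parsing is delegated to gemmi; only heavy atoms of ATOM records are kept
(hydrogens and HETATM ligands/waters are ignored). Alternate locations
are resolved to the highest-occupancy copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "ProteinStructure", "AtomFeatureMatrix", "DistanceMap", "FourierFeatures",
    "parse_structure", "build_atom_feature_matrix", "build_distance_map",
    "fourier_map", "ATOM_NAME_VOCAB", "AA_VOCAB", "ELEMENT_VOCAB",
]

AA_VOCAB = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "other",
]

# Standard PDB heavy-atom names across the 20 amino acids.
ATOM_NAME_VOCAB = [
    "N", "CA", "C", "O", "CB", "CG", "CG1", "CG2", "CD", "CD1", "CD2",
    "CE", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2", "ND1", "ND2",
    "NE", "NE1", "NE2", "NH1", "NH2", "NZ", "OD1", "OD2", "OE1", "OE2",
    "OG", "OG1", "OH", "OXT", "SD", "SG", "other",
]

ELEMENT_VOCAB = ["C", "N", "O", "S", "other"]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ProteinStructure:
    id: str
    residues: list[tuple[int, str]]               # (0-based index, 3-letter code)
    atoms: list[tuple[str, int, str, np.ndarray]]  # (name, residue idx, element, xyz)
    ca_coords: np.ndarray                          # (L, 3) Å

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(code, "X") for _, code in self.residues)


@dataclass
class AtomFeatureMatrix:
    A: np.ndarray  # (M, N) binary
    blocks: tuple[tuple[int, int], ...]  # (start, stop) per one-hot block


@dataclass
class DistanceMap:
    D: np.ndarray  # (L, L) Å


@dataclass
class FourierFeatures:
    G: np.ndarray  # (L, L, 2F+1)
    F: int


class StructureParseError(ValueError):
    pass


def parse_structure(pdb_text: str, structure_id: str = "protein") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Keeps heavy atoms of ATOM records in file order; altloc duplicates are
    reduced to the highest-occupancy copy. Every residue must provide a
    Cα atom (structure-prediction outputs always do).
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureParseError(f"{structure_id}: no models in PDB input")
    model = st[0]
    residues: list[tuple[int, str]] = []
    atoms: list[tuple[str, int, str, np.ndarray]] = []
    ca: list[np.ndarray] = []
    ridx = 0
    for chain in model:
        for res in chain:
            if res.het_flag != "A":  # ATOM records only
                continue
            # resolve altlocs: keep highest occupancy per atom name, file order
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if atom.element.name == "H" or atom.element.name == "D":
                    continue
                if atom.name not in best:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > best[atom.name].occ:
                    best[atom.name] = atom
            if "CA" not in best:
                raise StructureParseError(
                    f"{structure_id}: residue {res.name} {res.seqid.num} has no CA atom")
            residues.append((ridx, res.name))
            for name in order:
                atom = best[name]
                el = atom.element.name
                xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                atoms.append((name, ridx, el, xyz))
                if name == "CA":
                    ca.append(xyz)
            ridx += 1
    if not residues:
        raise StructureParseError(f"{structure_id}: no ATOM records found")
    return ProteinStructure(id=structure_id, residues=residues, atoms=atoms,
                            ca_coords=np.array(ca))


def _onehot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[index] = 1.0
    return v


def build_atom_feature_matrix(s: ProteinStructure) -> AtomFeatureMatrix:
    """One-hot encode (atom name, amino acid, element) per atom and concatenate.

    Unknown categories fall into each block's "other" slot, so every block
    of every row sums to exactly one.
    """
    n_name, n_aa, n_el = len(ATOM_NAME_VOCAB), len(AA_VOCAB), len(ELEMENT_VOCAB)
    rows = []
    res_code = dict(s.residues)
    for name, ridx, el, _ in s.atoms:
        i_name = ATOM_NAME_VOCAB.index(name) if name in ATOM_NAME_VOCAB else n_name - 1
        aa = res_code[ridx]
        i_aa = AA_VOCAB.index(aa) if aa in AA_VOCAB else n_aa - 1
        i_el = ELEMENT_VOCAB.index(el) if el in ELEMENT_VOCAB else n_el - 1
        rows.append(np.concatenate([
            _onehot(i_name, n_name), _onehot(i_aa, n_aa), _onehot(i_el, n_el)]))
    blocks = ((0, n_name), (n_name, n_name + n_aa),
              (n_name + n_aa, n_name + n_aa + n_el))
    return AtomFeatureMatrix(A=np.array(rows), blocks=blocks)


def build_distance_map(s: ProteinStructure) -> DistanceMap:
    """Pairwise Euclidean Cα–Cα distances d_ij = sqrt(Σ_c (x_c − y_c)²)."""
    diff = s.ca_coords[:, None, :] - s.ca_coords[None, :, :]
    return DistanceMap(D=np.sqrt((diff ** 2).sum(axis=-1)))


def fourier_map(dmap: DistanceMap, F: int = 4, scale_argument: bool = False) -> FourierFeatures:
    """Lift the distance map to (L, L, 2F+1) Fourier features.

    Default form keeps the raw distance in channel 0 and appends
    sin/cos pairs with amplitudes divided by 2^k for k = 0..F−1.
    ``scale_argument=True`` instead scales the *argument* by 2^k
    (genuinely higher frequencies), an alternative reading of
    "sine and cosine functions with high frequencies"; off by default.
    """
    if F < 1:
        raise ValueError("F must be >= 1")
    D = dmap.D
    channels = [D]
    for k in range(F):
        if scale_argument:
            channels.append(np.sin(D * 2.0 ** k))
            channels.append(np.cos(D * 2.0 ** k))
        else:
            channels.append(np.sin(D) / 2.0 ** k)
            channels.append(np.cos(D) / 2.0 ** k)
    return FourierFeatures(G=np.stack(channels, axis=-1), F=F)
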