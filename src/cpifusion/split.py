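"""Leakage-controlled cluster cross-validation splits.

Rather than random K-fold assignment — under which near-duplicate
compounds or homologous proteins routinely straddle the train/test
boundary — interactions are split along *cluster* lines:

* compounds are grouped by greedy sphere-exclusion (Butina) clustering
  on Tanimoto distances between Morgan fingerprints;
* proteins are grouped by k-means on L2-normalized 3-mer composition
  vectors of their sequences.

Five split settings are supported. ``novel_compound`` / ``novel_protein``
keep every compound (resp. protein) cluster wholly on one side of each
fold boundary; ``novel_pair`` enforces both; ``novel_hard_pair``
additionally removes training interactions whose compound Tanimoto or
protein sequence similarity to any test item exceeds a threshold
(default 0.3); ``cross_domain`` trains on one dataset and tests on
another with the same removal rule. Every split carries a leakage audit
reporting the exhaustive maximum train-vs-test compound and protein
similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from Bio import Align
from sklearn.cluster import KMeans

from .chem import FingerprintVector, tanimoto

__all__ = [
    "SplitAssignment", "LeakageReport", "butina_cluster", "kmeans_cluster",
    "protein_descriptor", "protein_similarity", "make_split", "audit_split",
    "random_kfold",
]

SETTINGS = ("novel_pair", "novel_compound", "novel_protein",
            "novel_hard_pair", "cross_domain")

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA20)}
_N_SYMBOLS = len(_AA20) + 1  # + "other" (X) channel for nonstandard letters


@dataclass
class LeakageReport:
    max_compound_tanimoto_train_vs_test: float
    max_protein_similarity_train_vs_test: float
    n_removed: int


@dataclass
class SplitAssignment:
    setting: str
    n_folds: int
    fold_of_interaction: dict[int, int]          # interaction index -> test fold
    compound_cluster: dict[str, int]
    protein_cluster: dict[str, int]
    train_indices: dict[int, list[int]] = field(default_factory=dict)
    test_indices: dict[int, list[int]] = field(default_factory=dict)
    audit: LeakageReport | None = None


def butina_cluster(fps: list[FingerprintVector], cutoff: float = 0.6) -> np.ndarray:
    """Classic Butina sphere-exclusion clustering on Tanimoto distance.

    Neighbors are pairs at distance (1 − Tanimoto) strictly below `cutoff`.
    Candidates are sorted by descending neighbor count (ties broken by
    lower index); each unassigned candidate in turn becomes a centroid and
    claims its unassigned neighbors. Returns integer labels, deterministic
    for a given input order.
    """
    if not fps:
        raise ValueError("butina_cluster requires a nonempty fingerprint list")
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must lie in (0, 1]")
    n = len(fps)
    dist = np.ones((n, n))
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    neighbor = dist < cutoff
    np.fill_diagonal(neighbor, False)
    counts = neighbor.sum(axis=1)
    order = sorted(range(n), key=lambda i: (-counts[i], i))
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for i in order:
        if labels[i] >= 0:
            continue
        labels[i] = next_label
        for j in np.nonzero(neighbor[i])[0]:
            if labels[j] < 0:
                labels[j] = next_label
        next_label += 1
    return labels


def kmeans_cluster(vectors, K: int, seed: int = 0) -> np.ndarray:
    """Lloyd k-means with seeded k-means++ initialization (scikit-learn)."""
    X = np.asarray(vectors, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > X.shape[0]:
        raise ValueError("K cannot exceed the number of points")
    km = KMeans(n_clusters=K, n_init=10, random_state=int(seed) % (2 ** 31 - 1))
    return km.fit_predict(X)


def protein_descriptor(sequence: str) -> np.ndarray:
    """L2-normalized 3-mer composition vector of an amino-acid sequence.

    Nonstandard letters map to a dedicated "other" symbol, giving a
    21³-dimensional composition space. Sequences shorter than 3 residues
    are described by their (padded) single available window.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.upper()
    if len(seq) < 3:
        seq = seq + "X" * (3 - len(seq))
    v = np.zeros(_N_SYMBOLS ** 3)
    other = _N_SYMBOLS - 1
    for i in range(len(seq) - 2):
        a, b, c = (_AA_INDEX.get(ch, other) for ch in seq[i:i + 3])
        v[(a * _N_SYMBOLS + b) * _N_SYMBOLS + c] += 1.0
    return v / np.linalg.norm(v)


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        _aligner = Align.PairwiseAligner(
            mode="global", match_score=1.0, mismatch_score=0.0,
            open_gap_score=-1.0, extend_gap_score=-1.0)
    return _aligner


def protein_similarity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: alignment score / longer sequence length.

    Match +1, mismatch 0, linear gap −1; clipped to [0, 1]. Equal
    sequences score exactly 1.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty protein sequence")
    score = _get_aligner().score(seq_a, seq_b)
    return float(np.clip(score / max(len(seq_a), len(seq_b)), 0.0, 1.0))


def _balance_clusters_into_folds(labels: np.ndarray, weights: np.ndarray,
                                 n_folds: int) -> dict[int, int]:
    """Greedy size balancing: largest cluster first into the lightest fold."""
    sizes: dict[int, float] = {}
    for lab, w in zip(labels, weights):
        sizes[int(lab)] = sizes.get(int(lab), 0.0) + float(w)
    fold_load = [0.0] * n_folds
    assignment: dict[int, int] = {}
    for lab in sorted(sizes, key=lambda l: (-sizes[l], l)):
        fold = int(np.argmin(fold_load))  # argmin ties -> lowest fold index
        assignment[lab] = fold
        fold_load[fold] += sizes[lab]
    return assignment


def random_kfold(n_items: int, n_folds: int, seed: int = 0) -> np.ndarray:
    """Plain random K-fold assignment; the leakage-prone control."""
    rng = np.random.default_rng(seed)
    folds = np.arange(n_items) % n_folds
    rng.shuffle(folds)
    return folds


def make_split(interactions, fps: dict[str, FingerprintVector],
               sequences: dict[str, str], setting: str, n_folds: int = 5,
               sim_threshold: float = 0.3, seed: int = 0,
               butina_cutoff: float = 0.6,
               domain_of: dict[int, str] | None = None) -> SplitAssignment:
    """Build a cluster cross-validation split for a list of interactions.

    `interactions` is a sequence of objects with ``compound_id`` and
    ``protein_id`` attributes. For ``cross_domain``, `domain_of` maps each
    interaction index to a dataset tag; the lexicographically first tag is
    the training domain and the rest are tested (single fold).
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; expected one of {SETTINGS}")
    comp_ids = sorted({r.compound_id for r in interactions})
    prot_ids = sorted({r.protein_id for r in interactions})
    comp_labels = butina_cluster([fps[c] for c in comp_ids], cutoff=butina_cutoff)
    compound_cluster = dict(zip(comp_ids, (int(v) for v in comp_labels)))
    K = max(1, int(np.ceil(np.sqrt(len(prot_ids)))))
    prot_vecs = [protein_descriptor(sequences[p]) for p in prot_ids]
    prot_labels = kmeans_cluster(prot_vecs, K=K, seed=seed)
    protein_cluster = dict(zip(prot_ids, (int(v) for v in prot_labels)))

    n = len(interactions)
    comp_of = np.array([compound_cluster[r.compound_id] for r in interactions])
    prot_of = np.array([protein_cluster[r.protein_id] for r in interactions])
    ones = np.ones(n)

    if setting == "cross_domain":
        if domain_of is None:
            raise ValueError("cross_domain requires domain_of")
        domains = sorted({domain_of[i] for i in range(n)})
        if len(domains) < 2:
            raise ValueError("cross_domain requires at least two dataset tags")
        train_dom = domains[0]
        fold_of = {i: (0 if domain_of[i] != train_dom else -1) for i in range(n)}
        n_folds = 1
    elif setting in ("novel_pair", "novel_compound", "novel_hard_pair"):
        cl2fold = _balance_clusters_into_folds(comp_of, ones, n_folds)
        fold_of = {i: cl2fold[int(comp_of[i])] for i in range(n)}
    else:  # novel_protein
        cl2fold = _balance_clusters_into_folds(prot_of, ones, n_folds)
        fold_of = {i: cl2fold[int(prot_of[i])] for i in range(n)}

    # for pair settings the protein clusters are independently partitioned:
    # fold-f test pairs live in compound fold f AND protein fold f, and the
    # training complement avoids both, so neither entity type crosses over
    pfold_of = None
    if setting in ("novel_pair", "novel_hard_pair"):
        p2fold = _balance_clusters_into_folds(prot_of, ones, n_folds)
        pfold_of = np.array([p2fold[int(prot_of[i])] for i in range(n)])

    split = SplitAssignment(setting=setting, n_folds=n_folds,
                            fold_of_interaction=fold_of,
                            compound_cluster=compound_cluster,
                            protein_cluster=protein_cluster)
    n_removed = 0
    for f in range(n_folds):
        if pfold_of is not None:
            test = [i for i in range(n) if fold_of[i] == f and pfold_of[i] == f]
            train = [i for i in range(n) if fold_of[i] != f and pfold_of[i] != f]
        elif setting == "cross_domain":
            test = [i for i in range(n) if fold_of[i] == 0]
            train = [i for i in range(n) if fold_of[i] == -1]
        else:
            test = [i for i in range(n) if fold_of[i] == f]
            train = [i for i in range(n) if fold_of[i] != f]
        if setting in ("novel_hard_pair", "cross_domain"):
            train, removed = _similarity_filter(
                interactions, train, test, fps, sequences, sim_threshold)
            n_removed += removed
        if not train or not test:
            raise ValueError(
                f"fold {f} has an empty {'train' if not train else 'test'} set; "
                f"try fewer folds or more data")
        split.train_indices[f] = train
        split.test_indices[f] = test
    split.audit = audit_split(split, interactions, fps, sequences)
    split.audit.n_removed = n_removed
    return split


def _similarity_filter(interactions, train: list[int], test: list[int],
                       fps, sequences, threshold: float) -> tuple[list[int], int]:
    """Drop training interactions too similar to any test item (OR rule)."""
    test_comp = {interactions[i].compound_id for i in test}
    test_prot = {interactions[i].protein_id for i in test}
    train_comp = {interactions[i].compound_id for i in train}
    train_prot = {interactions[i].protein_id for i in train}
    bad_comp = {c for c in train_comp
                if any(tanimoto(fps[c], fps[t]) > threshold for t in test_comp)}
    bad_prot = {p for p in train_prot
                if any(protein_similarity(sequences[p], sequences[t]) > threshold
                       for t in test_prot)}
    kept = [i for i in train
            if interactions[i].compound_id not in bad_comp
            and interactions[i].protein_id not in bad_prot]
    return kept, len(train) - len(kept)


def audit_split(split: SplitAssignment, interactions, fps,
                sequences) -> LeakageReport:
    """Exhaustive max train-vs-test compound and protein similarity over folds."""
    max_tan = 0.0
    max_prot = 0.0
    for f in split.test_indices:
        tr = split.train_indices[f]
        te = split.test_indices[f]
        tr_c = {interactions[i].compound_id for i in tr}
        te_c = {interactions[i].compound_id for i in te}
        tr_p = {interactions[i].protein_id for i in tr}
        te_p = {interactions[i].protein_id for i in te}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-zero fingerprints score 0
            for a, b in product(tr_c, te_c):
                max_tan = max(max_tan, tanimoto(fps[a], fps[b]))
        for a, b in product(tr_p, te_p):
            max_prot = max(max_prot, protein_similarity(sequences[a], sequences[b]))
    return LeakageReport(max_compound_tanimoto_train_vs_test=max_tan,
                         max_protein_similarity_train_vs_test=max_prot,
                         n_removed=0)
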