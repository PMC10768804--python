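"""Cluster cross-validation: Butina, k-means, descriptors, split contracts."""

import numpy as np
import pytest

from cpifusion.chem import FingerprintVector, tanimoto
from cpifusion.model import InteractionRecord
from cpifusion.split import (audit_split, butina_cluster, kmeans_cluster,
                             make_split, protein_descriptor, protein_similarity,
                             random_kfold)


def _fp(bits_on, n_bits=64):
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bits_on)] = 1
    return FingerprintVector(bits=bits, radius=2, n_bits=n_bits)


# -- Butina clustering --------------------------------------------------------

def test_identical_fingerprints_form_one_cluster():
    fps = [_fp({1, 2, 3})] * 5
    assert len(set(butina_cluster(fps, cutoff=0.5))) == 1


def test_fully_dissimilar_fingerprints_are_singletons():
    fps = [_fp({i}) for i in range(6)]
    labels = butina_cluster(fps, cutoff=0.5)
    assert len(set(labels)) == 6


def test_butina_matches_hand_run_on_known_matrix():
    """4 items; similarities: (0,1)=3/5, (0,2)=3/5, (1,2)=1/3, others 0.

    Distances below cutoff 0.5: (0,1)=0.4, (0,2)=0.4. Neighbor counts
    [2,1,1,0]: item 0 seeds {0,1,2}; item 3 is a singleton.
    """
    fps = [_fp({1, 2, 3, 4}), _fp({1, 2, 3, 9}), _fp({2, 3, 4, 8}), _fp({20, 21})]
    labels = butina_cluster(fps, cutoff=0.5)
    assert labels[0] == labels[1] == labels[2]
    assert labels[3] != labels[0]


def test_butina_agrees_with_rdkit_reference():
    from rdkit.ML.Cluster import Butina as RDButina
    rng = np.random.default_rng(12)
    fps = [_fp(set(rng.choice(64, size=8, replace=False))) for _ in range(20)]
    cutoff = 0.7
    mine = butina_cluster(fps, cutoff=cutoff)
    dists = [1.0 - tanimoto(fps[j], fps[i])
             for i in range(1, 20) for j in range(i)]
    ref = RDButina.ClusterData(dists, 20, cutoff, isDistData=True)
    mine_partition = {frozenset(np.nonzero(mine == l)[0]) for l in set(mine)}
    ref_partition = {frozenset(c) for c in ref}
    assert mine_partition == ref_partition


def test_butina_input_validation():
    with pytest.raises(ValueError):
        butina_cluster([], cutoff=0.5)
    with pytest.raises(ValueError):
        butina_cluster([_fp({1})], cutoff=1.5)


# -- k-means ------------------------------------------------------------------

def test_kmeans_degenerate_cluster_counts():
    X = np.arange(12, dtype=float).reshape(6, 2)
    assert len(set(kmeans_cluster(X, K=1, seed=0))) == 1
    assert len(set(kmeans_cluster(X, K=6, seed=0))) == 6
    with pytest.raises(ValueError):
        kmeans_cluster(X, K=0, seed=0)
    with pytest.raises(ValueError):
        kmeans_cluster(X, K=7, seed=0)


def test_kmeans_recovers_well_separated_blobs():
    rng = np.random.default_rng(1)
    a = rng.normal(0.0, 0.1, size=(30, 3))
    b = rng.normal(100.0, 0.1, size=(30, 3))
    labels = kmeans_cluster(np.vstack([a, b]), K=2, seed=3)
    assert len(set(labels[:30])) == 1
    assert len(set(labels[30:])) == 1
    assert labels[0] != labels[30]


# -- protein descriptors & similarity ----------------------------------------

def test_descriptor_of_homopolymer_concentrates_on_one_kmer():
    v = protein_descriptor("AAAA")
    assert np.count_nonzero(v) == 1
    assert np.linalg.norm(v) == pytest.approx(1.0)


def test_descriptor_self_cosine_is_one_and_unrelated_sequences_diverge():
    rng = np.random.default_rng(5)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    s1 = "".join(rng.choice(aas, 200))
    s2 = "".join(rng.choice(aas, 200))
    v1, v2 = protein_descriptor(s1), protein_descriptor(s2)
    assert float(v1 @ v1) == pytest.approx(1.0)
    assert float(v1 @ v2) < 0.5
    with pytest.raises(ValueError):
        protein_descriptor("")


def test_protein_similarity_identity_and_range():
    assert protein_similarity("ACDEFG", "ACDEFG") == pytest.approx(1.0)
    s = protein_similarity("ACDEFGHIKL", "MNPQRSTVWY")
    assert 0.0 <= s < 0.5


# -- split generation ---------------------------------------------------------

def _fixture_world(planted_dataset):
    fps = {m.id: m.fingerprint for m in planted_dataset.compounds}
    seqs = {p.id: p.sequence for p in planted_dataset.proteins}
    return planted_dataset.interactions, fps, seqs


def test_novel_pair_split_shares_no_compounds_or_proteins(planted_dataset):
    interactions, fps, seqs = _fixture_world(planted_dataset)
    split = make_split(interactions, fps, seqs, setting="novel_pair",
                       n_folds=3, seed=0)
    # fold assignment partitions the dataset; pair-setting test sets are the
    # subset of each fold whose protein fold matches as well
    folds = np.array([split.fold_of_interaction[i] for i in range(len(interactions))])
    assert np.bincount(folds, minlength=3).sum() == len(interactions)
    for f in split.test_indices:
        assert set(split.test_indices[f]) <= {i for i, ff in enumerate(folds) if ff == f}
        tr = {interactions[i].compound_id for i in split.train_indices[f]}
        te = {interactions[i].compound_id for i in split.test_indices[f]}
        assert tr & te == set()
        trp = {interactions[i].protein_id for i in split.train_indices[f]}
        tep = {interactions[i].protein_id for i in split.test_indices[f]}
        assert trp & tep == set()


def test_novel_compound_keeps_clusters_on_one_side(planted_dataset):
    interactions, fps, seqs = _fixture_world(planted_dataset)
    split = make_split(interactions, fps, seqs, setting="novel_compound",
                       n_folds=3, seed=0)
    for f in split.test_indices:
        tr = {split.compound_cluster[interactions[i].compound_id]
              for i in split.train_indices[f]}
        te = {split.compound_cluster[interactions[i].compound_id]
              for i in split.test_indices[f]}
        assert tr & te == set()


def test_novel_hard_pair_respects_similarity_threshold(planted_dataset):
    interactions, fps, seqs = _fixture_world(planted_dataset)
    split = make_split(interactions, fps, seqs, setting="novel_hard_pair",
                       n_folds=3, sim_threshold=0.3, seed=0)
    assert split.audit.max_compound_tanimoto_train_vs_test <= 0.3
    assert split.audit.max_protein_similarity_train_vs_test <= 0.3
    assert split.audit.n_removed > 0


def test_threshold_one_removes_nothing(planted_dataset):
    interactions, fps, seqs = _fixture_world(planted_dataset)
    hi = make_split(interactions, fps, seqs, setting="novel_hard_pair",
                    n_folds=3, sim_threshold=1.0, seed=0)
    assert hi.audit.n_removed == 0  # no similarity can exceed 1.0


def test_random_kfold_control_violates_the_leakage_bound(planted_dataset):
    interactions, fps, seqs = _fixture_world(planted_dataset)
    folds = random_kfold(len(interactions), 3, seed=0)
    from cpifusion.split import SplitAssignment
    control = SplitAssignment(
        setting="novel_pair", n_folds=3,
        fold_of_interaction={i: int(f) for i, f in enumerate(folds)},
        compound_cluster={}, protein_cluster={})
    for f in range(3):
        control.test_indices[f] = [i for i, ff in enumerate(folds) if ff == f]
        control.train_indices[f] = [i for i, ff in enumerate(folds) if ff != f]
    audit = audit_split(control, interactions, fps, seqs)
    assert audit.max_compound_tanimoto_train_vs_test > 0.3


def test_split_is_deterministic(planted_dataset):
    interactions, fps, seqs = _fixture_world(planted_dataset)
    a = make_split(interactions, fps, seqs, setting="novel_pair", n_folds=3, seed=7)
    b = make_split(interactions, fps, seqs, setting="novel_pair", n_folds=3, seed=7)
    assert a.fold_of_interaction == b.fold_of_interaction
    assert a.train_indices == b.train_indices


def test_cross_domain_split_trains_on_one_dataset_and_filters_lookalikes():
    from cpifusion.fixtures import FixtureSpec, make_toy_dataset
    d_a = make_toy_dataset(FixtureSpec(n_compounds=25, n_proteins=5,
                                       n_interactions=80, seed=0), fp_bits=512)
    d_b = make_toy_dataset(FixtureSpec(n_compounds=25, n_proteins=5,
                                       n_interactions=80, seed=123), fp_bits=512)
    interactions, fps, seqs, domain_of = [], {}, {}, {}
    for tag, d in (("A", d_a), ("B", d_b)):
        for m in d.compounds:
            fps[f"{tag}:{m.id}"] = m.fingerprint
        for p in d.proteins:
            seqs[f"{tag}:{p.id}"] = p.sequence
        for r in d.interactions:
            domain_of[len(interactions)] = tag
            interactions.append(InteractionRecord(
                f"{tag}:{r.compound_id}", f"{tag}:{r.protein_id}", r.label))
    split = make_split(interactions, fps, seqs, setting="cross_domain",
                       sim_threshold=0.6, seed=0, domain_of=domain_of)
    assert split.n_folds == 1
    assert all(domain_of[i] == "B" for i in split.test_indices[0])
    assert all(domain_of[i] == "A" for i in split.train_indices[0])
    # both libraries draw from the same scaffold space: identical compounds
    # recur across datasets and must have been filtered out of training
    assert split.audit.n_removed > 0
    assert split.audit.max_compound_tanimoto_train_vs_test <= 0.6


def test_audit_matches_brute_force_double_loop(planted_dataset):
    interactions, fps, seqs = _fixture_world(planted_dataset)
    split = make_split(interactions, fps, seqs, setting="novel_pair",
                       n_folds=3, seed=0)
    expected = 0.0
    for f in split.test_indices:
        for i in split.train_indices[f]:
            for j in split.test_indices[f]:
                expected = max(expected, tanimoto(
                    fps[interactions[i].compound_id],
                    fps[interactions[j].compound_id]))
    assert split.audit.max_compound_tanimoto_train_vs_test == pytest.approx(expected)


def test_identical_compound_across_split_audits_to_one():
    fps = {"c1": _fp({1, 2}), "c2": _fp({1, 2})}
    seqs = {"p1": "ACDEFGHIKL", "p2": "MNPQRSTVWY"}
    inters = [InteractionRecord("c1", "p1", 0.0),
              InteractionRecord("c2", "p2", 1.0)]
    from cpifusion.split import SplitAssignment
    split = SplitAssignment(setting="novel_pair", n_folds=1,
                            fold_of_interaction={0: -1, 1: 0},
                            compound_cluster={}, protein_cluster={})
    split.train_indices[0] = [0]
    split.test_indices[0] = [1]
    audit = audit_split(split, inters, fps, seqs)
    assert audit.max_compound_tanimoto_train_vs_test == 1.0


def test_make_split_rejects_unknown_setting(planted_dataset):
    interactions, fps, seqs = _fixture_world(planted_dataset)
    with pytest.raises(ValueError):
        make_split(interactions, fps, seqs, setting="random", n_folds=3)
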