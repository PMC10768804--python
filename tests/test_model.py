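"""Fusion network: attention algebra, encoding invariances, head arithmetic,
training contracts on the planted-signal fixtures."""

import numpy as np
import pytest
from rdkit import Chem

from cpifusion.autodiff import Tensor
from cpifusion.chem import parse_molecule
from cpifusion.fixtures import make_toy_protein
from cpifusion.model import (FusionConfig, FusionModel, InteractionRecord,
                             cross_attention, embed_fingerprint, featurize_protein,
                             train)
from cpifusion.nn import CrossAttention, Embedding
from cpifusion.graphnet import PNAConfig


# -- fingerprint lookup -------------------------------------------------------

def test_fingerprint_embedding_gathers_table_rows():
    rng = np.random.default_rng(0)
    table = Embedding(64, 5, rng)
    rec = parse_molecule("CCO", "m", fp_bits=64)
    out = embed_fingerprint(rec.fingerprint, table)
    on = rec.fingerprint.on_bits()
    assert out.shape == (len(on), 5)
    np.testing.assert_array_equal(out.data, table.table.data[on])


def test_fingerprint_embedding_rejects_all_zero():
    from cpifusion.chem import FingerprintVector
    rng = np.random.default_rng(0)
    table = Embedding(64, 5, rng)
    zero = FingerprintVector(np.zeros(64, dtype=np.uint8), 2, 64)
    with pytest.raises(ValueError):
        embed_fingerprint(zero, table)


def test_same_bits_give_same_embedding_rows():
    rng = np.random.default_rng(0)
    table = Embedding(64, 5, rng)
    from cpifusion.chem import FingerprintVector
    bits = np.zeros(64, dtype=np.uint8)
    bits[[3, 10, 40]] = 1
    a = FingerprintVector(bits.copy(), 2, 64)
    b = FingerprintVector(bits.copy(), 2, 64)
    np.testing.assert_array_equal(embed_fingerprint(a, table).data,
                                  embed_fingerprint(b, table).data)


# -- cross-attention ----------------------------------------------------------

def test_single_key_returns_projected_value_regardless_of_query():
    rng = np.random.default_rng(1)
    block = CrossAttention(3, 3, 4, 2, rng)
    kv = Tensor(rng.normal(size=(1, 3)))
    v = block.f_v(kv).data
    for _ in range(3):
        q = Tensor(rng.normal(size=(2, 3)))
        out = cross_attention(q, kv, block)
        np.testing.assert_allclose(out.data, np.vstack([v, v]), atol=1e-12)


def test_equal_logits_average_projected_values():
    rng = np.random.default_rng(2)
    block = CrossAttention(2, 2, 2, 1, rng)
    kv = Tensor(np.zeros((2, 2)))        # identical keys -> equal logits
    block.f_v.bias.data = np.zeros(2)
    v_rows = block.f_v(kv).data
    out = cross_attention(Tensor(rng.normal(size=(1, 2))), kv, block)
    np.testing.assert_allclose(out.data[0], v_rows.mean(axis=0), atol=1e-12)


def test_hand_computed_softmax_weight():
    # h=1, C=1, identity projections: Q=[2], K=[1,-1], V=[1,0]
    rng = np.random.default_rng(3)
    block = CrossAttention(1, 1, 1, 1, rng, identity_init=True)
    for lin in (block.f_q, block.f_k):
        lin.weight.data = np.array([[1.0]])
        lin.bias.data = np.array([0.0])
    # value projection chosen to map the keys [1, -1] onto the values [1, 0]
    block.f_v.weight.data = np.array([[0.5]])
    block.f_v.bias.data = np.array([0.5])
    out = cross_attention(Tensor([[2.0]]), Tensor([[1.0], [-1.0]]), block)
    w = np.exp(2.0) / (np.exp(2.0) + np.exp(-2.0))
    assert out.data[0, 0] == pytest.approx(w)       # ~0.9820
    assert w == pytest.approx(0.9820, abs=1e-4)


def test_attention_weights_are_convex_per_query():
    rng = np.random.default_rng(4)
    block = CrossAttention(3, 3, 4, 2, rng)
    q = Tensor(rng.normal(size=(5, 3)))
    kv = Tensor(rng.normal(size=(7, 3)))
    _, weights = block.attend(q, kv)
    np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)
    assert np.all(weights >= 0)
    # each output row lies in the convex hull of projected values per head
    v = block.f_v(kv).data.reshape(7, 2, 2).transpose(1, 0, 2)  # (h, nk, dh)
    out = weights @ v
    for h in range(2):
        assert np.all(out[h].min(axis=0) >= v[h].min(axis=0) - 1e-9)
        assert np.all(out[h].max(axis=0) <= v[h].max(axis=0) + 1e-9)


def test_embed_dim_must_divide_heads():
    with pytest.raises(ValueError):
        CrossAttention(4, 4, 5, 2, np.random.default_rng(0))


# -- compound & protein encoders ---------------------------------------------

def test_compound_encoding_is_deterministic_and_discriminative(small_model, toy_molecules):
    model, _ = small_model
    x1 = model.encode_compound(toy_molecules[0]).data
    x2 = model.encode_compound(toy_molecules[0]).data
    np.testing.assert_array_equal(x1, x2)
    other = model.encode_compound(toy_molecules[3]).data
    assert np.abs(x1 - other).max() > 1e-8


def test_compound_encoding_invariant_to_atom_permutation(small_model):
    model, _ = small_model
    smiles = "CC(=O)Nc1ccncc1"
    mol = Chem.MolFromSmiles(smiles)
    perm = list(reversed(range(mol.GetNumAtoms())))
    shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
    a = model.encode_compound(parse_molecule(smiles, "a", fp_bits=512)).data
    b = model.encode_compound(parse_molecule(shuffled, "b", fp_bits=512)).data
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_protein_encoding_unchanged_by_extra_masked_padding(small_fusion_config,
                                                            toy_protein):
    import dataclasses
    model_rng = np.random.default_rng(8)
    pin = featurize_protein(toy_protein[0], small_fusion_config)
    model = FusionModel(small_fusion_config, model_rng,
                        atom_matrix_width=pin.A.shape[1])
    wider = dataclasses.replace(small_fusion_config, max_atoms=160)
    pin_wide = featurize_protein(toy_protein[0], wider)
    x1 = model.encode_protein(pin).data
    x2 = model.encode_protein(pin_wide).data
    np.testing.assert_allclose(x1, x2, atol=1e-9)


def test_different_folds_give_different_protein_encodings(small_model,
                                                          small_fusion_config):
    model, pin = small_model
    other, _ = make_toy_protein(28, seed=99, protein_id="other")
    pin2 = featurize_protein(other, small_fusion_config)
    assert np.abs(model.encode_protein(pin).data
                  - model.encode_protein(pin2).data).max() > 1e-8


# -- prediction head ----------------------------------------------------------

def _zeroed_head(model):
    model.head_hidden.weight.data[:] = 0
    model.head_hidden.bias.data[:] = 0
    model.head_out.weight.data[:] = 0
    model.head_out.bias.data[:] = 0


def test_zero_weights_predict_zero_or_half(small_fusion_config, toy_protein):
    import dataclasses
    pin = featurize_protein(toy_protein[0], small_fusion_config)
    reg = FusionModel(small_fusion_config, np.random.default_rng(0),
                      atom_matrix_width=pin.A.shape[1])
    _zeroed_head(reg)
    assert reg.predict(Tensor(np.ones(8)), Tensor(np.ones(8))).item() == 0.0
    clf_cfg = dataclasses.replace(small_fusion_config, task="classification")
    clf = FusionModel(clf_cfg, np.random.default_rng(0),
                      atom_matrix_width=pin.A.shape[1])
    _zeroed_head(clf)
    assert clf.predict(Tensor(np.ones(8)), Tensor(np.ones(8))).item() == 0.5


def test_hand_set_head_weights_reproduce_arithmetic(small_fusion_config, toy_protein):
    pin = featurize_protein(toy_protein[0], small_fusion_config)
    model = FusionModel(small_fusion_config, np.random.default_rng(0),
                        atom_matrix_width=pin.A.shape[1])
    C = small_fusion_config.attn_dim
    _zeroed_head(model)
    # hidden unit 0 = relu(sum of x_comp) ; output = 2 * hidden0 + 0.5
    model.head_hidden.weight.data[:C, 0] = 1.0
    model.head_out.weight.data[0, 0] = 2.0
    model.head_out.bias.data[0] = 0.5
    x_comp = Tensor(np.full(C, 0.25))
    x_prot = Tensor(np.zeros(C))
    expected = 2.0 * max(0.25 * C, 0.0) + 0.5
    assert model.predict(x_comp, x_prot).item() == pytest.approx(expected)


def test_forward_is_finite_across_many_seeds(small_fusion_config, toy_molecules,
                                             toy_protein):
    pin = featurize_protein(toy_protein[0], small_fusion_config)
    for seed in range(100):
        model = FusionModel(small_fusion_config, np.random.default_rng(seed),
                            atom_matrix_width=pin.A.shape[1])
        y = model(toy_molecules[seed % len(toy_molecules)], pin).item()
        assert np.isfinite(y)


def test_gradient_reaches_every_fine_tuning_parameter(small_model, toy_molecules):
    model, pin = small_model
    model.zero_grad()
    y = model(toy_molecules[0], pin)
    (y * y).backward()
    # the PNA graph-level readout head only participates in pretraining
    for name, p in model.named_parameters():
        if name.startswith("pna.readout"):
            continue
        assert p.grad is not None, name


# -- training contracts -------------------------------------------------------

def test_fine_tuning_respects_frozen_encoder_layers(small_fusion_config,
                                                    toy_molecules, toy_protein):
    from cpifusion.pretrain import apply_freeze, build_freeze_mask
    pin = featurize_protein(toy_protein[0], small_fusion_config)
    model = FusionModel(small_fusion_config, np.random.default_rng(5),
                        atom_matrix_width=pin.A.shape[1])
    mask = build_freeze_mask(model.pna, 0.95)
    apply_freeze(model.pna, mask)
    frozen_before = {name: p.data.copy() for name, p in model.pna.named_parameters()
                     if name in mask.frozen_parameter_ids}
    records = [InteractionRecord(m.id, "helix20", float(i % 3))
               for i, m in enumerate(toy_molecules)]
    comps = {m.id: m for m in toy_molecules}
    train(records, comps, {"helix20": pin}, model, epochs=2, batch_size=4,
          lr=1e-2, seed=0)
    state = dict(model.pna.named_parameters())
    assert frozen_before
    for name, before in frozen_before.items():
        np.testing.assert_array_equal(before, state[name].data)


def test_train_validates_inputs(small_model, toy_molecules):
    model, pin = small_model
    with pytest.raises(ValueError):
        train([], {}, {}, model)
    recs = [InteractionRecord("c", "p", 1.0, "regression"),
            InteractionRecord("c", "p", 1.0, "classification")]
    with pytest.raises(ValueError, match="mixed"):
        train(recs, {"c": toy_molecules[0]}, {"p": pin}, model)
    with pytest.raises(KeyError):
        train([InteractionRecord("missing", "p", 1.0)], {}, {"p": pin}, model)
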