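"""Shape contracts, masking, pooling, determinism, and the parameter audit."""

import numpy as np
import pytest

from plikit import autodiff as ad
from plikit.autodiff import Tensor
from plikit.finetune import batch_loss, prepare_records
from plikit.model import (
    ConfigError, JointTransformer, ModelConfig, N_TASKS, collate, encode,
)
from tests.conftest import random_joint


def test_preset_validation():
    with pytest.raises(ConfigError, match="divisible"):
        ModelConfig(embed_dim=30, n_heads=4, ligand_vocab_size=42)
    with pytest.raises(ConfigError, match="preset"):
        ModelConfig.preset("huge")
    ref = ModelConfig.preset("reference", ligand_vocab_size=42)
    assert ref.embed_dim == 480 and ref.embed_dim % ref.n_heads == 0


def test_encode_output_shape(tiny_model, vocabs):
    rng = np.random.default_rng(0)
    js = random_joint(rng, vocabs, protein_len=8)
    emb = encode(js, tiny_model)
    assert emb.shape == (len(js), tiny_model.cfg.embed_dim)
    assert np.all(np.isfinite(emb))


def test_zero_joint_layers_is_concat_of_encoders(tiny_cfg, vocabs):
    cfg = ModelConfig.from_dict({**tiny_cfg.to_dict(), "joint_layers": 0})
    model = JointTransformer(cfg)
    rng = np.random.default_rng(1)
    batch = collate([random_joint(rng, vocabs) for _ in range(3)])
    with ad.no_grad():
        joint = model.encode(batch)
        hp = model.protein_encoder(batch.prot_ids, batch.prot_valid)
        hl = model.ligand_encoder(batch.lig_ids, batch.lig_valid)
    expected = np.concatenate([hp.data, hl.data], axis=1)
    np.testing.assert_array_equal(joint.data, expected)


def test_pad_positions_cannot_influence_valid_outputs(tiny_model, vocabs):
    rng = np.random.default_rng(2)
    short = random_joint(rng, vocabs, protein_len=6)
    long = random_joint(rng, vocabs, protein_len=20)
    batch = collate([short, long])
    altered = collate([short, long])
    # scribble over every PAD slot of the short record
    altered.prot_ids[0, ~altered.prot_valid[0]] = 9
    altered.lig_ids[0, ~altered.lig_valid[0]] = 9
    with ad.no_grad():
        a = tiny_model.encode(batch).data
        b = tiny_model.encode(altered).data
    valid = batch.joint_valid
    np.testing.assert_array_equal(a[valid], b[valid])


def test_forward_determinism_and_construction_determinism(tiny_cfg, vocabs):
    m1 = JointTransformer(tiny_cfg)
    m2 = JointTransformer(tiny_cfg)
    s1, s2 = m1.state_dict(), m2.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)
    rng = np.random.default_rng(3)
    js = random_joint(rng, vocabs)
    np.testing.assert_array_equal(encode(js, m1), encode(js, m1))


def test_pooled_regression_excludes_pad_and_specials(tiny_model, vocabs):
    rng = np.random.default_rng(4)
    js = random_joint(rng, vocabs, protein_len=10)
    other = random_joint(rng, vocabs, protein_len=25)
    alone, _ = tiny_model.predict_record(js)
    with ad.no_grad():
        batch = collate([js, other])
        mu, sigma = tiny_model.regress(tiny_model.encode(batch), batch)
    # same record padded inside a batch: pooled prediction unchanged
    np.testing.assert_allclose(alone.mu, mu.data[0], atol=2e-4)
    assert np.all(sigma.data > 0)


def test_all_equal_embedding_rows_pool_to_that_row(tiny_model, vocabs):
    rng = np.random.default_rng(5)
    js = random_joint(rng, vocabs, protein_len=7)
    batch = collate([js])
    E = tiny_model.cfg.embed_dim
    row = rng.normal(size=E)
    emb = Tensor(np.tile(row, (1, len(js), 1)))
    with ad.no_grad():
        mu, _ = tiny_model.regress(emb, batch)
        direct = tiny_model.reg_head(Tensor(row[None, :]))
    np.testing.assert_allclose(mu.data[0], direct.data[0, :N_TASKS], atol=1e-5)


def test_sigma_positive_for_random_weights(tiny_cfg, vocabs):
    rng = np.random.default_rng(6)
    js = random_joint(rng, vocabs)
    batch = collate([js])
    for seed in range(20):
        model = JointTransformer(ModelConfig.from_dict({**tiny_cfg.to_dict(), "seed": seed}))
        with ad.no_grad():
            _, sigma = model.regress(model.encode(batch), batch)
        assert np.all(sigma.data > 0)


def test_mu_bias_shift_is_exact(tiny_model, vocabs):
    rng = np.random.default_rng(7)
    js = random_joint(rng, vocabs)
    before, _ = tiny_model.predict_record(js)
    tiny_model.reg_head.b.data[:N_TASKS] += 1.5
    after, _ = tiny_model.predict_record(js)
    np.testing.assert_allclose(after.mu - before.mu, 1.5, atol=1e-5)
    np.testing.assert_allclose(after.sigma, before.sigma, atol=1e-7)


def test_site_probabilities_cover_protein_residues_only(tiny_model, vocabs):
    rng = np.random.default_rng(8)
    js = random_joint(rng, vocabs, protein_len=50)
    _, sites = tiny_model.predict_record(js)
    assert sites.shape == (50,)
    assert np.all((sites >= 0) & (sites <= 1))


def test_zero_weight_site_head_gives_half(tiny_model, vocabs):
    tiny_model.site_head.W.data[:] = 0
    tiny_model.site_head.b.data[:] = 0
    rng = np.random.default_rng(9)
    _, sites = tiny_model.predict_record(random_joint(rng, vocabs))
    np.testing.assert_allclose(sites, 0.5, atol=1e-7)


def test_masked_prediction_distributions(tiny_model, vocabs):
    rng = np.random.default_rng(10)
    js = random_joint(rng, vocabs)
    batch = collate([js])
    with ad.no_grad():
        emb = tiny_model.encode(batch)
        logp_p, logp_l = tiny_model.predict_masked(emb, batch)
    assert logp_p.shape[-1] == tiny_model.cfg.protein_vocab_size
    assert logp_l.shape[-1] == tiny_model.cfg.ligand_vocab_size
    np.testing.assert_allclose(np.exp(logp_p.data).sum(axis=-1), 1.0, atol=1e-5)
    np.testing.assert_allclose(np.exp(logp_l.data).sum(axis=-1), 1.0, atol=1e-5)


def test_parameter_count_matches_closed_form(tiny_cfg):
    model = JointTransformer(tiny_cfg)
    E, F = tiny_cfg.embed_dim, tiny_cfg.ffn_dim
    Vp, Vl = tiny_cfg.protein_vocab_size, tiny_cfg.ligand_vocab_size
    block = 2 * (2 * E) + 4 * (E * E + E) + (E * F + F) + (F * E + E)

    def encoder(V, max_len, layers):
        return V * E + max_len * E + layers * block + 2 * E

    expected = (
        encoder(Vp, tiny_cfg.max_protein_len + 2, tiny_cfg.protein_layers)
        + encoder(Vl, tiny_cfg.max_ligand_len + 2, tiny_cfg.ligand_layers)
        + 3 * E + tiny_cfg.joint_layers * block + 2 * E          # joint stage
        + (E * 2 * N_TASKS + 2 * N_TASKS)                        # regression head
        + (E + 1)                                                # site head
        + (E * Vp + Vp) + (E * Vl + Vl)                          # masked-LM heads
    )
    assert model.n_parameters() == expected


def test_gradients_reach_joint_layer_from_every_head(tiny_model, vocabs, small_dataset):
    pv, lv = vocabs
    prep = prepare_records(small_dataset.subset("train")[:8], pv, lv)
    loss = batch_loss(tiny_model, prep)
    loss.backward()
    params = tiny_model.parameters()
    joint_w = params["joint.blocks.0.attn.wq.W"]
    assert joint_w.grad is not None and np.any(joint_w.grad != 0)
    assert params["heads.regression.W"].grad is not None
    assert params["heads.site.W"].grad is not None


def test_frozen_encoders_receive_zero_gradient(tiny_model, vocabs, small_dataset):
    pv, lv = vocabs
    prep = prepare_records(small_dataset.subset("train")[:8], pv, lv)
    params = tiny_model.parameters()
    for name, p in params.items():
        p.requires_grad = not name.startswith(("protein.", "ligand."))
    try:
        loss = batch_loss(tiny_model, prep)
        loss.backward()
        assert params["protein.blocks.0.attn.wq.W"].grad is None
        assert params["ligand.tok_emb"].grad is None
        assert params["joint.blocks.0.attn.wq.W"].grad is not None
    finally:
        for p in params.values():
            p.requires_grad = True


def test_over_length_input_rejected(tiny_cfg, vocabs):
    cfg = ModelConfig.from_dict({**tiny_cfg.to_dict(), "max_protein_len": 8})
    model = JointTransformer(cfg)
    rng = np.random.default_rng(11)
    batch = collate([random_joint(rng, vocabs, protein_len=20)])
    with pytest.raises(ConfigError, match="protein segment length"):
        model.encode(batch)
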