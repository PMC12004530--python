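"""LoRA contracts, bootstrap statistics, the stopping rule, and freeze/
determinism guarantees of the four finetuning regimes."""

import math

import numpy as np
import pytest

from plikit import autodiff as ad
from plikit.finetune import (
    StrategyConfig, StrategyError, TrainingHistory, bootstrap_resample,
    inject_lora, merge_lora, prepare_records, pretrain, steady_state_stop,
    train, trainable_parameter_report,
)
from plikit.model import JointTransformer, ModelConfig, collate, encode
from tests.conftest import random_joint


def make_model(tiny_cfg, seed=21):
    return JointTransformer(ModelConfig.from_dict({**tiny_cfg.to_dict(), "seed": seed}))


class TestStrategyConfig:
    def test_rank_required_iff_lora(self):
        with pytest.raises(StrategyError):
            StrategyConfig(strategy="lora")
        with pytest.raises(StrategyError):
            StrategyConfig(strategy="base", rank=4)
        StrategyConfig(strategy="lora", rank=2)

    def test_ensemble_needs_two_members(self):
        with pytest.raises(StrategyError):
            StrategyConfig(strategy="ensemble", members=1)


class TestLoRA:
    def test_injection_is_bit_exact_noop(self, tiny_cfg, vocabs):
        model = make_model(tiny_cfg)
        js = random_joint(np.random.default_rng(0), vocabs)
        before = encode(js, model)
        inject_lora(model, rank=2)
        after = encode(js, model)
        np.testing.assert_array_equal(before, after)

    def test_trainable_count_per_matrix(self, tiny_cfg):
        model = make_model(tiny_cfg)
        inject_lora(model, rank=2)
        for name, lin in model.block_linears().items():
            n = int(np.prod(lin.lora_A.shape) + np.prod(lin.lora_B.shape))
            assert n == 2 * (lin.d_in + lin.d_out), name

    def test_merge_equivalence_on_random_inputs(self, tiny_cfg, vocabs):
        with ad.dtype_context(np.float64):
            model = make_model(tiny_cfg)
            inject_lora(model, rank=4, seed=5)
            rng = np.random.default_rng(6)
            # give the adapters non-trivial content
            for lin in model.block_linears().values():
                lin.lora_B.data = rng.normal(0, 0.05, size=lin.lora_B.shape)
            joints = [random_joint(rng, vocabs) for _ in range(100)]
            with_adapters = [encode(js, model) for js in joints]
            merge_lora(model)
            merged = [encode(js, model) for js in joints]
            for a, b in zip(with_adapters, merged):
                np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-7)

    def test_delta_matrix_rank_bounded_by_r(self, tiny_cfg):
        rng = np.random.default_rng(7)
        for r in (2, 6):
            model = make_model(tiny_cfg)
            inject_lora(model, rank=r, seed=1)
            for lin in model.block_linears().values():
                lin.lora_A.data = rng.normal(size=lin.lora_A.shape)
                lin.lora_B.data = rng.normal(size=lin.lora_B.shape)
                delta = lin.lora_scale * (lin.lora_A.data @ lin.lora_B.data)
                sv = np.linalg.svd(delta, compute_uv=False)
                assert np.sum(sv > 1e-6 * sv[0]) <= r

    def test_rank_too_large_rejected(self, tiny_cfg):
        with pytest.raises(StrategyError, match="rank"):
            inject_lora(make_model(tiny_cfg), rank=32)

    def test_double_merge_rejected(self, tiny_cfg):
        model = make_model(tiny_cfg)
        inject_lora(model, rank=2)
        merge_lora(model)
        with pytest.raises(StrategyError, match="adapters"):
            merge_lora(model)

    def test_merge_of_zero_adapters_leaves_weights_unchanged(self, tiny_cfg):
        model = make_model(tiny_cfg)
        before = model.state_dict()
        inject_lora(model, rank=3)
        merge_lora(model)
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])


class TestParameterReport:
    def test_base_freezes_encoders(self, tiny_cfg):
        report = trainable_parameter_report(make_model(tiny_cfg), StrategyConfig())
        assert set(report["by_component"]) == {"joint", "heads"}

    def test_lora_counts_monotone_in_rank_and_below_full(self, tiny_cfg):
        model2 = make_model(tiny_cfg)
        inject_lora(model2, rank=2)
        r2 = trainable_parameter_report(model2, StrategyConfig(strategy="lora", rank=2))
        model6 = make_model(tiny_cfg)
        inject_lora(model6, rank=6)
        r6 = trainable_parameter_report(model6, StrategyConfig(strategy="lora", rank=6))
        full = trainable_parameter_report(make_model(tiny_cfg),
                                          StrategyConfig(strategy="full"))
        assert r2["trainable"] < r6["trainable"] < full["trainable"]

    def test_full_equals_total_parameter_audit(self, tiny_cfg):
        model = make_model(tiny_cfg)
        report = trainable_parameter_report(model, StrategyConfig(strategy="full"))
        assert report["trainable"] == model.n_parameters()


class TestBootstrap:
    def test_single_record_dataset(self):
        idx = bootstrap_resample(1, member_index=0, seed=0)
        assert idx.tolist() == [0]

    def test_unique_fraction_near_one_minus_inv_e(self):
        n = 10_000
        idx = bootstrap_resample(n, member_index=0, seed=1)
        unique_frac = len(np.unique(idx)) / n
        expected = 1 - (1 - 1 / n) ** n
        sd = math.sqrt(expected * (1 - expected) / n)
        assert abs(unique_frac - expected) < 3 * sd

    def test_deterministic_and_member_dependent(self):
        a = bootstrap_resample(100, 2, seed=3)
        b = bootstrap_resample(100, 2, seed=3)
        c = bootstrap_resample(100, 3, seed=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestStoppingRule:
    def test_steady_state_example(self):
        losses = [5, 4, 4.0001, 4.0002, 4.0001]
        assert steady_state_stop(losses, patience=3, tol=1e-3) == (5, "steady_state")

    def test_monotone_improvement_runs_to_cap(self):
        losses = [5, 4, 3, 2, 1]
        assert steady_state_stop(losses, patience=3, tol=1e-3) == (5, "epoch_cap")

    def test_constant_losses_stop_at_patience(self):
        losses = [2.0] * 10
        assert steady_state_stop(losses, patience=4, tol=1e-3) == (5, "steady_state")


@pytest.fixture(scope="module")
def train_val(small_dataset):
    return small_dataset.subset("train"), small_dataset.subset("val")


class TestTraining:
    def test_zero_learning_rate_stops_at_patience(self, tiny_cfg, vocabs, train_val):
        pv, lv = vocabs
        model = make_model(tiny_cfg)
        cfg = StrategyConfig(lr_phase1=0.0, epochs_phase1=20, patience=3)
        result = train(model, *train_val, cfg, pv, lv)
        h = result.histories[0]
        assert h.stop_reason == "steady_state"
        assert h.stop_epoch == 4  # first epoch sets best, then 3 flat epochs
        assert np.allclose(h.val_loss, h.val_loss[0])

    def test_base_training_reduces_loss_and_freezes_encoders(self, tiny_cfg, vocabs,
                                                             train_val):
        pv, lv = vocabs
        model = make_model(tiny_cfg)
        frozen_before = {k: v.data.copy() for k, v in model.parameters().items()
                         if k.startswith(("protein.", "ligand."))}
        cfg = StrategyConfig(epochs_phase1=6, patience=10, seed=1)
        result = train(model, *train_val, cfg, pv, lv)
        h = result.histories[0]
        assert h.val_loss[-1] < h.val_loss[0]
        params = model.parameters()
        for k, v in frozen_before.items():
            np.testing.assert_array_equal(params[k].data, v)

    def test_full_phase1_keeps_encoders_fixed_then_phase2_moves_them(
            self, tiny_cfg, vocabs, train_val):
        pv, lv = vocabs
        model = make_model(tiny_cfg)
        enc_before = model.parameters()["protein.blocks.0.ff1.W"].data.copy()
        cfg = StrategyConfig(strategy="full", epochs_phase1=2, epochs_phase2=0,
                             patience=10, seed=2)
        train(model, *train_val, cfg, pv, lv)
        np.testing.assert_array_equal(
            model.parameters()["protein.blocks.0.ff1.W"].data, enc_before)
        cfg2 = StrategyConfig(strategy="full", epochs_phase1=1, epochs_phase2=2,
                              patience=10, seed=2)
        train(model, *train_val, cfg2, pv, lv)
        assert not np.array_equal(
            model.parameters()["protein.blocks.0.ff1.W"].data, enc_before)

    def test_lora_phase2_trains_only_adapters_and_heads(self, tiny_cfg, vocabs,
                                                        train_val):
        pv, lv = vocabs
        model = make_model(tiny_cfg)
        cfg = StrategyConfig(strategy="lora", rank=2, epochs_phase1=1,
                             epochs_phase2=2, patience=10, seed=3)
        base_weights = {k: v.data.copy() for k, v in model.parameters().items()}
        train(model, *train_val, cfg, pv, lv)
        params = model.parameters()
        # encoder base matrices untouched through both phases
        for k in base_weights:
            if k.startswith(("protein.", "ligand.")) and ".lora_" not in k:
                np.testing.assert_array_equal(params[k].data, base_weights[k])
        # adapters moved away from their zero-product initialization
        moved = [k for k in params if k.endswith(".lora_B")
                 and np.any(params[k].data != 0)]
        assert moved

    def test_ensemble_members_differ_and_source_untouched(self, tiny_cfg, vocabs,
                                                          train_val):
        pv, lv = vocabs
        model = make_model(tiny_cfg)
        source_state = model.state_dict()
        cfg = StrategyConfig(strategy="ensemble", members=2, epochs_phase1=2,
                             patience=10, seed=4, bagging_seed=4)
        result = train(model, *train_val, cfg, pv, lv)
        assert len(result.models) == 2
        m0 = result.models[0].parameters()
        m1 = result.models[1].parameters()
        dist = sum(float(np.abs(m0[k].data - m1[k].data).sum())
                   for k in m0 if k.startswith("joint."))
        assert dist > 0
        # members share the source's frozen encoders
        for k in m0:
            if k.startswith(("protein.", "ligand.")):
                np.testing.assert_array_equal(m0[k].data, source_state[k])
        # the source model itself is untouched
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, source_state[k])

    def test_training_is_deterministic_given_seeds(self, tiny_cfg, vocabs, train_val):
        pv, lv = vocabs
        cfg = StrategyConfig(epochs_phase1=2, patience=10, seed=5)
        states = []
        for _ in range(2):
            model = make_model(tiny_cfg)
            train(model, *train_val, cfg, pv, lv)
            states.append(model.state_dict())
        for k in states[0]:
            np.testing.assert_array_equal(states[0][k], states[1][k])

    def test_empty_split_rejected(self, tiny_cfg, vocabs, train_val):
        pv, lv = vocabs
        with pytest.raises(StrategyError, match="empty"):
            train(make_model(tiny_cfg), [], train_val[1], StrategyConfig(), pv, lv)


class TestPretraining:
    def test_masked_lm_loss_decreases_and_beats_uniform(self, tiny_cfg, vocabs,
                                                        small_dataset):
        pv, lv = vocabs
        model = make_model(tiny_cfg, seed=8)
        records = small_dataset.subset("train")[:60]
        history = pretrain(model, records, pv, lv, epochs=3, lr=3e-3, seed=0)
        assert history.train_loss[-1] < history.train_loss[0]
        # mean reciprocal rank of the true token at masked positions must beat
        # the uniform-guess baseline sum(1/i)/V computed analytically
        from plikit.objectives import corrupt_for_mlm
        prep = prepare_records(records[:30], pv, lv)
        rng = np.random.default_rng(1)
        ranks = []
        Vp = len(pv)
        with ad.no_grad():
            for p in prep:
                res = corrupt_for_mlm(p.joint, 0.15, rng)
                if not res.positions:
                    continue
                batch = collate([res.corrupted])
                emb = model.encode(batch)
                logp_p, logp_l = model.predict_masked(emb, batch)
                prot_seg = p.joint.protein_span[1] + 1
                for pos, tok in zip(res.positions, res.targets):
                    if tok < Vp:
                        scores = logp_p.data[0, pos]
                        rank = 1 + int((scores > scores[tok]).sum())
                    else:
                        col = pos - prot_seg + batch.prot_len
                        scores = logp_l.data[0, col]
                        rank = 1 + int((scores > scores[tok - Vp]).sum())
                    ranks.append(1.0 / rank)
        mrr = float(np.mean(ranks))
        v = max(len(pv), len(lv))
        uniform_mrr = sum(1.0 / i for i in range(1, v + 1)) / v
        assert mrr > uniform_mrr
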