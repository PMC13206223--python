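"""Tokenizer, encoder, joint loss and training behavior of the selector."""

import dataclasses

import numpy as np
import pytest

from t2select import (
    CohortTable,
    FeatureSchema,
    FeatureSpec,
    GeneratorConfig,
    SelectorHyperparams,
    classification_logit,
    encode,
    generate,
    statistical_loss,
    tokenize,
    total_loss,
    train,
)
from t2select import _autodiff as ad
from t2select._autodiff import Tensor
from t2select.cohort import apply_preprocessor, fit_preprocessor
from t2select.selector import random_selector, TrainingDiverged
from t2select.hotelling import hotelling_t2


def _prep(cohort):
    return apply_preprocessor(fit_preprocessor(cohort), cohort)


@pytest.fixture
def prepped(tiny_cohort):
    return _prep(tiny_cohort)


@pytest.fixture
def rand_sel(prepped, tiny_hp):
    return random_selector(prepped.schema, tiny_hp)


class TestTokenize:
    def test_zero_input_yields_bias(self, prepped, rand_sel):
        table = dataclasses.replace(prepped, values=np.zeros_like(prepped.values))
        toks = tokenize(table, rand_sel).data
        for j, spec in enumerate(prepped.schema.specs):
            if spec.kind != "categorical":
                bias = rand_sel.params["tok_b"].data[j]
                np.testing.assert_allclose(
                    toks[:, j + 1, :], np.broadcast_to(bias, (table.n, bias.size))
                )

    def test_linearity_in_numeric_value(self, prepped, rand_sel):
        t1 = dataclasses.replace(prepped, values=np.ones_like(prepped.values))
        v2 = np.ones_like(prepped.values)
        v2[:, 0] = 2.0
        t2 = dataclasses.replace(prepped, values=v2)
        d = tokenize(t2, rand_sel).data[:, 1, :] - tokenize(t1, rand_sel).data[:, 1, :]
        np.testing.assert_allclose(
            d, np.broadcast_to(rand_sel.params["tok_w"].data[0], d.shape),
            rtol=1e-5, atol=1e-7,
        )

    def test_identical_rows_identical_tokens(self, prepped, rand_sel):
        v = prepped.values.copy()
        v[1] = v[0]
        table = dataclasses.replace(prepped, values=v)
        toks = tokenize(table, rand_sel).data
        np.testing.assert_array_equal(toks[0], toks[1])

    def test_cls_shared_across_samples(self, prepped, rand_sel):
        toks = tokenize(prepped, rand_sel).data
        assert (toks[:, 0, :] == toks[0, 0, :]).all()


class TestEncode:
    def test_permutation_equivariance(self, prepped, rand_sel):
        """Permuting feature tokens (not CLS) and un-permuting the output
        reproduces the unpermuted encoding: no positional information."""
        toks = tokenize(prepped, rand_sel)
        out = encode(toks, rand_sel).data
        rng = np.random.default_rng(0)
        perm = rng.permutation(prepped.p)
        full = np.r_[0, perm + 1]
        toks_p = Tensor(toks.data[:, full, :])
        out_p = encode(toks_p, rand_sel).data
        inv = np.argsort(full)
        np.testing.assert_allclose(out_p[:, inv, :], out, atol=1e-5)

    def test_residual_identity_with_zeroed_weights(self, prepped, tiny_hp):
        sel = random_selector(prepped.schema, tiny_hp)
        for k in ("l0_wo", "l0_wo_b", "l0_ffn2", "l0_ffn2_b"):
            sel.params[k].data = np.zeros_like(sel.params[k].data)
        toks = tokenize(prepped, sel)
        out = encode(toks, sel).data
        np.testing.assert_allclose(out, toks.data, atol=1e-12)

    def test_cls_depends_on_every_feature_token(self, prepped, rand_sel):
        """Finite difference: perturbing any one input feature token moves
        the CLS output."""
        toks = tokenize(prepped, rand_sel).data
        base = encode(Tensor(toks), rand_sel).data[:, 0, :]
        for j in [1, prepped.p]:  # first and last feature token
            bumped = toks.copy()
            bumped[:, j, 0] += 1e-3  # non-uniform bump (LN absorbs constants)
            out = encode(Tensor(bumped), rand_sel).data[:, 0, :]
            assert np.abs(out - base).max() > 1e-9


class TestLogitAndLosses:
    def test_zero_cls_zero_head_gives_half_probability(self, prepped, rand_sel):
        enc = Tensor(np.zeros((prepped.n, prepped.p + 1, rand_sel.hp.d_token)))
        rand_sel.params["head_b"].data = np.zeros(())
        logits = classification_logit(enc, rand_sel).data
        np.testing.assert_allclose(logits, 0.0)

    def test_logits_invariant_to_feature_permutation(self, prepped, rand_sel):
        toks = tokenize(prepped, rand_sel)
        base = classification_logit(encode(toks, rand_sel), rand_sel).data
        perm = np.r_[0, np.random.default_rng(1).permutation(prepped.p) + 1]
        toks_p = Tensor(toks.data[:, perm, :])
        out = classification_logit(encode(toks_p, rand_sel), rand_sel).data
        np.testing.assert_allclose(out, base, atol=1e-5)

    def test_statistical_loss_zero_for_identical_representations(self):
        enc = Tensor(np.tile(np.arange(24.0).reshape(1, 3, 8), (10, 1, 1)))
        y = np.r_[np.ones(5), np.zeros(5)]
        loss = statistical_loss(enc, y, ridge=0.5)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_statistical_loss_decreases_with_mean_shift(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 3, 4))
        y = np.r_[np.ones(10), np.zeros(10)]
        l0 = float(statistical_loss(Tensor(base.copy()), y, ridge=0.1).data)
        shifted = base.copy()
        shifted[y == 1, 1, :] += 2.0
        l1 = float(statistical_loss(Tensor(shifted), y, ridge=0.1).data)
        assert l1 < l0

    def test_statistical_loss_large_ridge_limit(self):
        """As ridge grows, T² -> (n0 n1/(n0+n1)) ||delta||² / ridge."""
        rng = np.random.default_rng(3)
        enc = rng.normal(size=(20, 3, 3))  # CLS slot + 2 features
        y = np.r_[np.ones(8), np.zeros(12)]
        ridge = 1e8
        loss = float(statistical_loss(Tensor(enc), y, ridge=ridge).data)
        feats = enc[:, 1:, :]
        deltas = feats[y == 1].mean(0) - feats[y == 0].mean(0)  # (p, d)
        expect = -np.mean(
            (8 * 12 / 20) * (deltas**2).sum(axis=1) / ridge
        )
        assert loss == pytest.approx(expect, rel=1e-4)

    def test_statistical_loss_matches_exact_hotelling(self, prepped, rand_sel):
        """Dual route: the differentiable per-feature T² at ridge equals the
        exact test-statistic implementation on the same representations."""
        enc = encode(tokenize(prepped, rand_sel), rand_sel)
        y = prepped.outcome
        ridge = 0.01
        loss = float(statistical_loss(enc, y, ridge=ridge).data)
        feats = enc.data[:, 1:, :]
        t2s = [
            hotelling_t2(feats[y == 0, j, :], feats[y == 1, j, :], ridge=ridge)
            for j in range(prepped.p)
        ]
        assert loss == pytest.approx(-np.mean(t2s), rel=1e-4)

    def test_total_loss_reduces_to_bce(self, prepped, rand_sel):
        hp = dataclasses.replace(rand_sel.hp, lambda1=0.0, lambda2=0.0)
        enc = encode(tokenize(prepped, rand_sel), rand_sel)
        logits = classification_logit(enc, rand_sel)
        total, l_cls, l_stat = total_loss(logits, prepped.outcome, enc, hp)
        assert float(total.data) == pytest.approx(l_cls)
        assert l_stat == 0.0

    def test_single_class_rejected(self, prepped, rand_sel):
        enc = encode(tokenize(prepped, rand_sel), rand_sel)
        with pytest.raises(ValueError):
            statistical_loss(enc, np.zeros(prepped.n), ridge=0.1)


class TestJointGradient:
    def test_total_loss_gradient_matches_finite_difference(self, prepped, tiny_hp):
        """Automatic gradient of the joint objective vs central differences
        on tokenizer weights, attention weights and the head."""
        sel = random_selector(prepped.schema, tiny_hp)
        y = prepped.outcome

        def loss_value():
            enc = encode(tokenize(prepped, sel), sel)
            logits = classification_logit(enc, sel)
            total, _, _ = total_loss(logits, y, enc, tiny_hp)
            return total

        loss = loss_value()
        for p in sel.params.values():
            p.grad = None
        loss.backward()
        eps = 1e-6
        rng = np.random.default_rng(0)
        for key in ("tok_w", "l0_wq", "head_w", "emb_cat_006"):
            param = sel.params[key]
            flat = param.data.ravel()
            idx = rng.integers(flat.size, size=3)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                hi = float(loss_value().data)
                flat[i] = orig - eps
                lo = float(loss_value().data)
                flat[i] = orig
                num = (hi - lo) / (2 * eps)
                auto = param.grad.ravel()[i]
                assert auto == pytest.approx(num, rel=1e-4, abs=1e-9), key


class TestTrain:
    def test_loss_decreases_on_separable_cohort(self):
        cfg = GeneratorConfig(
            n=200, event_rate=0.4, n_numeric=2, n_binary=0, n_categorical=0,
            informative=((0, 3.0),), block_size=1, seed=5,
        )
        cohort, _ = generate(cfg)
        hp = SelectorHyperparams(
            d_token=8, n_heads=2, epochs=60, lr=3e-3, seed=1
        )
        sel = train(cohort, hp)
        log = sel.training_log
        assert log.l_cls.iloc[-1] < log.l_cls.iloc[0]
        assert len(log) == hp.epochs

    def test_same_seed_identical_training_log(self, tiny_cohort):
        hp = SelectorHyperparams(d_token=8, n_heads=2, epochs=4, seed=9)
        log1 = train(tiny_cohort, hp).training_log
        log2 = train(tiny_cohort, hp).training_log
        assert log1.equals(log2)

    def test_divergence_aborts_naming_epoch(self, tiny_cohort):
        """A non-finite loss (here forced by a corrupt input value) aborts
        with a diagnostic carrying the epoch number."""
        bad = dataclasses.replace(
            tiny_cohort, values=np.where(
                np.arange(tiny_cohort.p) == 0, np.inf, tiny_cohort.values
            )
        )
        hp = SelectorHyperparams(d_token=8, n_heads=2, epochs=5, seed=0)
        with pytest.raises(TrainingDiverged, match="epoch"):
            train(bad, hp, preprocess=False)

    def test_schema_permutation_permutes_t2_preserves_logits(self):
        """End-to-end equivariance: training on a column-permuted cohort
        with identically permuted per-feature parameters yields permuted
        per-feature T² values and identical logits."""
        from t2select.hotelling import feature_significance

        cfg = GeneratorConfig(
            n=60, event_rate=0.35, n_numeric=5, n_binary=0, n_categorical=0,
            informative=((0, 1.5),), block_size=1, seed=21,
        )
        cohort, _ = generate(cfg)
        hp = SelectorHyperparams(d_token=8, n_heads=2, epochs=5, seed=4,
                                 dtype="float64")
        sel = train(cohort, hp)
        coh_p = apply_preprocessor(sel.preprocessor, cohort)
        rep = feature_significance(sel, coh_p)
        logits = sel.predict_logits(coh_p)

        # permute the cohort's columns and the per-feature parameters alike
        perm = np.array([3, 0, 4, 1, 2])
        specs = tuple(cohort.schema.specs[j] for j in perm)
        schema_p = FeatureSchema(specs=specs, outcome_name="nop_lbbb")
        cohort_p = CohortTable(
            values=cohort.values[:, perm], outcome=cohort.outcome,
            schema=schema_p,
        )
        sel_p = train(cohort_p, hp)
        sel_p.params["tok_w"].data = sel.params["tok_w"].data[perm]
        sel_p.params["tok_b"].data = sel.params["tok_b"].data[perm]
        for k in sel.params:
            if k not in ("tok_w", "tok_b"):
                sel_p.params[k].data = sel.params[k].data.copy()
        coh_pp = apply_preprocessor(sel_p.preprocessor, cohort_p)
        rep_p = feature_significance(sel_p, coh_pp)
        t2 = {r.feature: r.t2 for r in rep.results}
        t2_p = {r.feature: r.t2 for r in rep_p.results}
        for name in t2:
            assert t2_p[name] == pytest.approx(t2[name], rel=1e-6)
        np.testing.assert_allclose(sel_p.predict_logits(coh_pp), logits,
                                   atol=1e-8)

    def test_save_load_round_trip(self, tiny_cohort, tmp_path):
        hp = SelectorHyperparams(d_token=8, n_heads=2, epochs=2, seed=3)
        sel = train(tiny_cohort, hp)
        path = tmp_path / "sel.npz"
        sel.save(path)
        from t2select import TrainedSelector

        loaded = TrainedSelector.load(path)
        coh = apply_preprocessor(sel.preprocessor, tiny_cohort)
        np.testing.assert_allclose(
            loaded.predict_logits(coh), sel.predict_logits(coh), rtol=1e-6
        )
        assert loaded.hp == sel.hp
        assert len(loaded.training_log) == 2
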