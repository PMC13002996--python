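"""Enhancer sample construction and the self-attention classifier."""

import numpy as np
import pytest

from test_quant import table_from_counts
from sixbct.attention import AttentionClassifier, ModelConfig
from sixbct.enhancer import (
    EnhancerSample,
    evaluate,
    prepare_samples,
    simulate_enhancer_samples,
    split_by_chromosome,
    train,
)
from sixbct.errors import InvalidInputError, InvalidParameterError
from sixbct.reference import EnhancerSet


class TestPrepareSamples:
    def test_count_normalisation(self):
        # counts (X, M, H, U) = (0, 5, 0, 15) -> (0, 0.25, 0, 0.75)
        t = table_from_counts({("chr2", 50, "+"): (15, 5, 0, 0)})
        enh = EnhancerSet([("chr2", 0, 100, "active")])
        samples = prepare_samples([t], enh)
        assert len(samples) == 1
        np.testing.assert_allclose(samples[0].vectors[0],
                                   [0, 0.25, 0, 0.75])
        assert samples[0].label == 0

    def test_replicate_averaging(self):
        # (0,1,0,0) and (0,0,0,1) average to (0, 0.5, 0, 0.5)
        ta = table_from_counts({("chr2", 50, "+"): (0, 10, 0, 0)})
        tb = table_from_counts({("chr2", 50, "+"): (10, 0, 0, 0)})
        enh = EnhancerSet([("chr2", 0, 100, "poised")])
        samples = prepare_samples([ta, tb], enh)
        np.testing.assert_allclose(samples[0].vectors[0], [0, 0.5, 0, 0.5])
        assert samples[0].label == 1

    def test_sites_ordered_by_coordinate(self):
        t = table_from_counts({("chr2", 80, "+"): (0, 10, 0, 0),
                               ("chr2", 20, "+"): (10, 0, 0, 0)})
        enh = EnhancerSet([("chr2", 0, 100, "primed")])
        samples = prepare_samples([t], enh)
        np.testing.assert_allclose(samples[0].vectors[:, 3], [1.0, 0.0])

    def test_uncovered_enhancer_dropped(self):
        t = table_from_counts({("chr2", 50, "+"): (10, 0, 0, 0)})
        enh = EnhancerSet([("chr3", 0, 100, "active"),
                           ("chr2", 0, 100, "poised")])
        samples = prepare_samples([t], enh)
        assert [s.label for s in samples] == [1]


class TestSplit:
    def _samples(self, chroms):
        return [EnhancerSample(f"s{i}", c, np.full((3, 4), 0.25), i % 3)
                for i, c in enumerate(chroms)]

    def test_partition_is_exact(self):
        samples = self._samples(["chr1"] * 20 + ["chr2"] * 80)
        tr, te = split_by_chromosome(samples, "chr1")
        assert len(tr) == 80 and len(te) == 20
        assert len(tr) + len(te) == len(samples)
        assert all(s.chrom != "chr1" for s in tr)

    def test_missing_holdout_raises(self):
        with pytest.raises(InvalidInputError):
            split_by_chromosome(self._samples(["chr2"] * 5), "chr1")


SMALL = dict(d_model=16, num_head=2, ff_dim=32, mlp_h_dim=32)


class TestAttentionModel:
    def test_parameter_count_matches_closed_form(self):
        model = AttentionClassifier(ModelConfig(max_len=40))
        d, ff, mlp, ncls, nfeat = 32, 256, 256, 3, 4
        expected = (
            nfeat * d + d                 # input projection
            + 4 * (d * d + d)             # Wq, Wk, Wv, Wo
            + d * ff + ff + ff * d + d    # feed-forward block
            + d * mlp + mlp               # head layer 1
            + mlp * mlp + mlp             # head layer 2
            + mlp * ncls + ncls           # output
        )
        assert model.n_parameters == expected == 96067

    def test_gradients_match_finite_differences(self):
        cfg = ModelConfig(d_model=8, num_head=2, ff_dim=10, mlp_h_dim=12,
                          dropp=0.0, seed=0, max_len=5)
        model = AttentionClassifier(cfg)
        rng = np.random.default_rng(1)
        X = rng.random((3, 5, 4))
        mask = np.ones((3, 5))
        mask[1, 3:] = 0
        y = np.array([0, 1, 2])
        _, grads = model.loss_and_grads(X, mask, y, train=False)
        eps = 1e-6
        for name, g in grads.items():
            P = model.params[name]
            idx = tuple(rng.integers(0, s) for s in P.shape)
            P[idx] += eps
            lp, _ = model.loss_and_grads(X, mask, y, train=False)
            P[idx] -= 2 * eps
            lm, _ = model.loss_and_grads(X, mask, y, train=False)
            P[idx] += eps
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-7), name

    def test_logits_invariant_to_cpg_permutation(self):
        # no positional encoding + mean pooling: order cannot matter
        cfg = ModelConfig(dropp=0.0, seed=3, max_len=12, **SMALL)
        model = AttentionClassifier(cfg)
        rng = np.random.default_rng(0)
        v = rng.random((10, 4))
        p1 = model.predict_proba([v])
        model2 = AttentionClassifier(cfg)
        p2 = model2.predict_proba([v[rng.permutation(10)]])
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_training_deterministic_per_seed(self):
        sig = {"active": (0.05, 0.6), "poised": (0.6, 0.05),
               "primed": (0.3, 0.3)}
        samples = simulate_enhancer_samples(sig, n_per_class=20,
                                            cpgs_range=(5, 10), seed=4)
        losses = []
        for _ in range(2):
            cfg = ModelConfig(seed=11, max_epochs=3, **SMALL)
            model = train(samples, cfg)
            losses.append(model.history["train_loss"][-1])
        assert losses[0] == losses[1]

    def test_single_class_training_raises(self):
        samples = [EnhancerSample(f"s{i}", "chr2", np.full((3, 4), 0.25), 0)
                   for i in range(10)]
        with pytest.raises(InvalidParameterError):
            train(samples, ModelConfig(**SMALL))

    def test_separable_classes_reach_high_training_accuracy(self):
        sig = {"active": (0.02, 0.9), "poised": (0.9, 0.02),
               "primed": (0.4, 0.4)}
        samples = simulate_enhancer_samples(sig, n_per_class=60,
                                            cpgs_range=(8, 16), seed=5)
        cfg = ModelConfig(seed=0, max_epochs=50, **SMALL)
        model = train(samples, cfg)
        acc = float(np.mean(model.predict([s.vectors for s in samples])
                            == [s.label for s in samples]))
        assert acc >= 0.95

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            ModelConfig(d_model=30, num_head=4)
        with pytest.raises(InvalidParameterError):
            ModelConfig(dropp=1.0)


class TestEvaluate:
    def _samples(self):
        rng = np.random.default_rng(2)
        return [EnhancerSample(f"s{i}", "chr1", rng.random((4, 4)), i % 3)
                for i in range(30)]

    def test_perfect_scores_give_auc_one(self):
        samples = self._samples()

        class Oracle:
            def predict_proba(self, vectors):
                return np.eye(3)[[s.label for s in samples]]

        rep = evaluate(Oracle(), samples)
        assert rep.macro_roc_auc == pytest.approx(1.0)
        assert rep.accuracy == 1.0
        assert np.trace(rep.confusion) == 30

    def test_absent_class_curves_undefined(self):
        samples = [s for s in self._samples() if s.label != 2]

        class Oracle:
            def predict_proba(self, vectors):
                return np.full((len(samples), 3), 1 / 3)

        rep = evaluate(Oracle(), samples)
        assert rep.roc["primed"] is None
        assert rep.pr["primed"] is None

    def test_empty_test_set_raises(self):
        model = AttentionClassifier(ModelConfig(max_len=5, **SMALL))
        with pytest.raises(InvalidInputError):
            evaluate(model, [])
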