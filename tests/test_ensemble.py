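import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lglink.ensemble import (
    LocalGlobalEnsemble,
    compare_methods,
    compute_metrics,
    fuse_scores,
    leave_one_disease_out,
    make_splits,
    repeated_partition_eval,
)
from lglink.io import AssociationSet, Config, SupplementConfig
from lglink.synthetic import SyntheticSpec, generate


def _pairs(arr):
    return {tuple(r) for r in np.asarray(arr).reshape(-1, 2).tolist()}


class TestMakeSplits:
    def test_single_disease_five_positives_arithmetic(self):
        A = np.ones((5, 1), dtype=np.int8)
        aset = AssociationSet(a_ids=[f"p{i}" for i in range(5)], b_ids=["d0"], A=A)
        # not enough unknown pairs for negatives -> error
        with pytest.raises(ValueError, match="negatives"):
            make_splits(aset, seed=0)
        A = np.zeros((20, 1), dtype=np.int8)
        A[:5, 0] = 1
        aset = AssociationSet(a_ids=[f"p{i}" for i in range(20)], b_ids=["d0"], A=A)
        s = make_splits(aset, seed=0)
        assert len(s.independent_pos) == 1
        assert len(s.train_pos) + len(s.validation_pos) == 4

    def test_negative_sets_balanced(self, tiny_data):
        assoc, *_ = tiny_data
        for seed in range(5):
            s = make_splits(assoc, seed=seed)
            assert len(s.train_neg) == len(s.train_pos)
            assert len(s.validation_neg) == len(s.validation_pos)
            assert len(s.independent_neg) == len(s.independent_pos)

    def test_sets_pairwise_disjoint_and_labels_correct(self, tiny_data):
        assoc, *_ = tiny_data
        s = make_splits(assoc, seed=3)
        sets = s._sets()
        keys = list(sets)
        for i, k1 in enumerate(keys):
            for k2 in keys[i + 1 :]:
                assert not (_pairs(sets[k1]) & _pairs(sets[k2])), (k1, k2)
        for k in ("train_pos", "validation_pos", "independent_pos"):
            for p, d in sets[k]:
                assert assoc.A[p, d] == 1
        for k in ("train_neg", "validation_neg", "independent_neg"):
            for p, d in sets[k]:
                assert assoc.A[p, d] == 0

    def test_deterministic_per_seed_and_varies_across_seeds(self, tiny_data):
        assoc, *_ = tiny_data
        s1 = make_splits(assoc, seed=11)
        s2 = make_splits(assoc, seed=11)
        for k, v in s1._sets().items():
            np.testing.assert_array_equal(v, s2._sets()[k])
        s3 = make_splits(assoc, seed=12)
        assert _pairs(s1.train_neg) != _pairs(s3.train_neg)


class TestFusion:
    def test_boundaries_reproduce_each_branch(self):
        yg, yl = np.array([0.8, 0.2]), np.array([0.1, 0.9])
        np.testing.assert_array_equal(fuse_scores(yg, yl, 1.0), yg)
        np.testing.assert_array_equal(fuse_scores(yg, yl, 0.0), yl)

    def test_midpoint(self):
        assert fuse_scores(np.array([0.8]), np.array([0.6]), 0.5)[0] == pytest.approx(0.7)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        delta=st.floats(0, 1),
        vals=st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=1, max_size=20),
    )
    def test_fusion_exactness(self, delta, vals):
        yg = np.array([v[0] for v in vals])
        yl = np.array([v[1] for v in vals])
        fused = fuse_scores(yg, yl, delta)
        assert np.abs(fused - (delta * yg + (1 - delta) * yl)).max() == 0.0

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            fuse_scores(np.ones(3), np.ones(2), 0.5)
        with pytest.raises(ValueError):
            fuse_scores(np.ones(2), np.ones(2), 1.5)


def auc_oracle(scores, labels):
    """Exhaustive concordant-pair count (ties count half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s in pos:
        for t in neg:
            total += 1.0 if s > t else (0.5 if s == t else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_ranking(self):
        rep = compute_metrics(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert rep.auc == 1.0 and rep.aupr == 1.0

    def test_reversed_ranking(self):
        rep = compute_metrics(np.array([0.1, 0.2, 0.8, 0.9]), np.array([1, 1, 0, 0]))
        assert rep.auc == 0.0

    def test_auc_equals_concordance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = rng.choice(np.linspace(0, 1, 7), size=30)  # force ties
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            rep = compute_metrics(scores, labels)
            assert rep.auc == pytest.approx(auc_oracle(scores, labels))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        a1 = compute_metrics(scores, labels).auc
        a2 = compute_metrics(np.exp(3 * scores) + 7, labels).auc
        assert a1 == pytest.approx(a2)

    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = np.array([1] * 20 + [0] * 20)
        rep = compute_metrics(scores, labels)
        assert rep.acc == pytest.approx((rep.sen + rep.spe) / 2, abs=1e-12)

    def test_confusion_identities(self):
        scores = np.array([0.9, 0.7, 0.3, 0.2, 0.8, 0.1])
        labels = np.array([1, 0, 1, 0, 1, 0])
        rep = compute_metrics(scores, labels)
        if rep.pre + rep.sen > 0:
            assert rep.f1 == pytest.approx(2 * rep.pre * rep.sen / (rep.pre + rep.sen))

    def test_single_class_gives_nan_ranking_metrics(self):
        with pytest.warns(UserWarning, match="single-class"):
            rep = compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
        assert np.isnan(rep.auc) and np.isnan(rep.aupr)
        # thresholded metrics still computed: 0.8 rescales to 1 (predicted pos)
        assert rep.acc == 0.5 and rep.pre == 1.0

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0.5, 0.5]), np.array([0, 2]))


class TestEnsembleEstimator:
    def test_auto_delta_requires_validation(self, tiny_data, fast_config):
        assoc, S_p, S_d, _ = tiny_data
        s = make_splits(assoc, seed=0)
        X, y = s.train_xy()
        model = LocalGlobalEnsemble(S_p=S_p.S, S_d=S_d.S, config=fast_config, delta="auto")
        with pytest.raises(ValueError, match="validation"):
            model.fit(X, y)

    def test_fused_scores_combine_modules(self, tiny_data, fast_config):
        assoc, S_p, S_d, _ = tiny_data
        s = make_splits(assoc, seed=0)
        X, y = s.train_xy()
        model = LocalGlobalEnsemble(S_p=S_p.S, S_d=S_d.S, config=fast_config, delta=0.3)
        model.fit(X, y)
        X_ind, _ = s.independent_xy()
        yg = model.global_.decision_function(X_ind)
        yl = model.local_.decision_function(X_ind)
        np.testing.assert_allclose(
            model.decision_function(X_ind), 0.3 * yg + 0.7 * yl, atol=1e-12
        )

    def test_get_params_round_trip(self, fast_config):
        model = LocalGlobalEnsemble(config=fast_config, delta=0.4)
        params = model.get_params(deep=False)
        clone = LocalGlobalEnsemble(**params)
        assert clone.delta == 0.4


class TestProtocols:
    def test_single_repeat_reduces_to_one_split(self, tiny_data, fast_config):
        assoc, S_p, S_d, _ = tiny_data
        out = repeated_partition_eval(
            assoc, S_p.S, S_d.S, config=fast_config, n_repeats=1, base_seed=4
        )
        assert len(out["per_repeat"]) == 1
        rep = out["per_repeat"][0]
        for kind in ("global", "local", "fused"):
            assert out["means"][kind]["auc"] == rep[kind].auc

    def test_means_bounded_by_extremes_and_deterministic(self, tiny_data, fast_config):
        assoc, S_p, S_d, _ = tiny_data
        out1 = repeated_partition_eval(
            assoc, S_p.S, S_d.S, config=fast_config, n_repeats=2, base_seed=0
        )
        aucs = [r["fused"].auc for r in out1["per_repeat"]]
        assert min(aucs) <= out1["means"]["fused"]["auc"] <= max(aucs)
        out2 = repeated_partition_eval(
            assoc, S_p.S, S_d.S, config=fast_config, n_repeats=2, base_seed=0
        )
        assert out1["means"] == out2["means"]

    def test_lodo_never_sees_target_disease_edges(self):
        # two diseases with disjoint A-side entity sets
        A = np.zeros((8, 2), dtype=np.int8)
        A[:4, 0] = 1
        A[4:, 1] = 1
        aset = AssociationSet(
            a_ids=[f"p{i}" for i in range(8)], b_ids=["d0", "d1"], A=A
        )
        rng = np.random.default_rng(0)
        S_p = np.eye(8) * 0 + 0.1
        np.fill_diagonal(S_p, 1.0)
        S_d = np.eye(2)
        cfg = Config(
            epochs_global=5, embed_dim=4, dense_dims=(6, 5, 4), epochs_local=1,
            local_width=4, mlp_hidden=8, supplement=SupplementConfig(n_base=0),
        )
        import lglink.ensemble as ens

        captured = {}
        orig = ens.LocalGlobalEnsemble.fit

        def spy(self, X, y, **kw):
            captured.setdefault("X", []).append((np.asarray(X), np.asarray(y)))
            return orig(self, X, y, **kw)

        ens.LocalGlobalEnsemble.fit = spy
        try:
            leave_one_disease_out(aset, S_p, S_d, config=cfg, base_seed=0)
        finally:
            ens.LocalGlobalEnsemble.fit = orig
        # first call holds out disease 0: no training positive touches d0
        X0, y0 = captured["X"][0]
        assert not ((X0[y0 == 1][:, 1] == 0).any())
        X1, y1 = captured["X"][1]
        assert not ((X1[y1 == 1][:, 1] == 1).any())

    def test_lodo_test_sets_balanced(self, tiny_data, fast_config):
        assoc, S_p, S_d, _ = tiny_data
        cfg = Config(
            epochs_global=5, embed_dim=4, dense_dims=(6, 5, 4), epochs_local=1,
            local_width=4, mlp_hidden=8, supplement=SupplementConfig(n_base=0),
        )
        # balance is structural: equal sampled negatives per disease; spot-check 2 diseases
        small = AssociationSet(
            a_ids=assoc.a_ids, b_ids=assoc.b_ids[:3], A=assoc.A[:, :3]
        )
        reports = leave_one_disease_out(small, S_p.S, S_d.S[:3, :3], config=cfg)
        assert len(reports) >= 2

    def test_rank_sum_comparison_tiers(self):
        a = np.full(20, 0.9)
        b = np.full(20, 0.1)
        out = compare_methods(a, b)
        assert out["tier"] == "***"
        same = compare_methods(np.arange(10), np.arange(10))
        assert same["tier"] == "ns"
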