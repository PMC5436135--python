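import numpy as np
import pandas as pd
import pytest

from renalmatch.errors import InvalidArgumentError
from renalmatch.expression import (calls_to_frame, classify_margin,
                                   combat_adjust, select_threshold,
                                   train_nsc, _fit_centroids)
from renalmatch.harmonize import GeneMatrix
from renalmatch.synthetic import simulate_expression

GENES = [f"g{i}" for i in range(400)]


def two_class_matrix(seed=0, n_per_class=30, **kwargs):
    kwargs.setdefault("n_intermediate", 0)
    kwargs.setdefault("batch_shift", 0.0)
    m, truth = simulate_expression(GENES, n_per_class=n_per_class, seed=seed,
                                   **kwargs)
    labels = truth.expression_class[truth.expression_class != "intermediate"]
    return GeneMatrix(m.values[labels.index], "expression"), labels, truth


class TestCombat:
    def test_pure_shift_equalizes_batch_means(self):
        rng = np.random.default_rng(0)
        base = np.tile(rng.normal(7, 1, 60)[:, None], (1, 5))
        X = pd.DataFrame(np.hstack([base, base + 3.0]),
                         index=[f"g{i}" for i in range(60)],
                         columns=[f"s{i}" for i in range(10)])
        batch = pd.Series(["a"] * 5 + ["b"] * 5, index=X.columns)
        adj, _ = combat_adjust(GeneMatrix(X, "expression"), batch)
        means = adj.values.T.groupby(batch).mean()
        assert np.abs(means.iloc[0] - means.iloc[1]).max() < 1e-6

    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 6)),
                         index=[f"g{i}" for i in range(20)],
                         columns=[f"s{i}" for i in range(6)])
        batch = pd.Series("only", index=X.columns)
        with pytest.warns(UserWarning, match="single batch"):
            adj, model = combat_adjust(GeneMatrix(X, "expression"), batch)
        assert adj.values.equals(X)
        assert model is None

    def test_no_batch_effect_near_identity(self):
        m, truth = simulate_expression(GENES[:100], n_per_class=20,
                                       n_intermediate=0, n_marker_genes=30,
                                       batch_shift=0.0, batch_scale=1.0,
                                       noise_sd=0.4, seed=2)
        adj, _ = combat_adjust(m, truth.batch)
        # only EB noise-level rebalancing; values stay close to input
        assert np.abs(adj.values - m.values).to_numpy().max() < 0.5

    def test_parameter_recovery(self):
        """Location gamma~N(0.5,0.1) and scale delta=1.5 injected into one
        batch are recovered within 10%."""
        rng = np.random.default_rng(3)
        n, n_genes = 200, 400
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"s{i}" for i in range(n)]
        base = rng.normal(7, 1, (n_genes, 1)) + rng.normal(0, 1, (n_genes, n))
        gamma_true = rng.normal(0.5, 0.1, n_genes)
        X = base.copy()
        X[:, n // 2:] = (base[:, n // 2:] - base.mean(axis=1, keepdims=True)) \
            * np.sqrt(1.5) + base.mean(axis=1, keepdims=True) + gamma_true[:, None]
        batch = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2), index=samples)
        m = GeneMatrix(pd.DataFrame(X, index=genes, columns=samples), "expression")
        _, model = combat_adjust(m, batch)
        gamma_est = ((model.gamma_star.loc["b"] - model.gamma_star.loc["a"])
                     * np.sqrt(model.pooled_var[model.adjusted_genes])).mean()
        delta_est = (model.delta_star.loc["b"] / model.delta_star.loc["a"]).mean()
        assert gamma_est == pytest.approx(0.5, rel=0.10)
        assert delta_est == pytest.approx(1.5, rel=0.10)

    def test_scanpy_combat_agrees(self):
        """Independent empirical-Bayes batch-correction implementation gives
        the same adjusted matrix."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        m, truth = simulate_expression(GENES[:150], n_per_class=25,
                                       n_intermediate=0, n_marker_genes=40,
                                       batch_shift=1.0, batch_scale=1.3, seed=4)
        adj, _ = combat_adjust(m, truth.batch)
        A = ad.AnnData(m.values.T.to_numpy(),
                       obs=pd.DataFrame({"batch": truth.batch.astype("category")},
                                        index=m.values.columns))
        oracle = sc.pp.combat(A, key="batch", inplace=False)
        assert np.abs(oracle.T - adj.values.to_numpy()).max() < 5e-3

    def test_missing_batch_label_rejected(self):
        X = pd.DataFrame(np.zeros((3, 4)), index=list("abc"),
                         columns=[f"s{i}" for i in range(4)])
        with pytest.raises(InvalidArgumentError):
            combat_adjust(GeneMatrix(X, "expression"),
                          pd.Series({"s0": "a", "s1": "a"}))


class TestNscModel:
    def test_zero_shrinkage_equals_plain_nearest_centroid(self):
        matrix, labels, _ = two_class_matrix(seed=5, noise_sd=1.0,
                                             class_effect_size=1.0)
        model = _fit_centroids(matrix.values, labels, delta=0.0)
        pred = model.predict(matrix)
        # independent diagonal-covariance nearest-centroid computation
        values = matrix.values
        for sid in values.columns:
            x = values[sid]
            scores = {}
            for k in model.classes:
                mu = model.centroids[k]  # unshrunken at delta 0
                scores[k] = float((((x - mu) / (model.s + model.s0)) ** 2).sum())
            assert pred[sid] == min(scores, key=scores.get)

    def test_full_shrinkage_degenerates_to_priors(self):
        matrix, labels, _ = two_class_matrix(seed=6)
        model = _fit_centroids(matrix.values, labels, delta=1e9)
        assert model.surviving_genes == []
        pred = model.predict(matrix)  # reported, not crashed
        assert set(pred) <= set(model.classes)

    def test_surviving_count_nonincreasing_in_delta(self):
        matrix, labels, _ = two_class_matrix(seed=7)
        counts = [len(_fit_centroids(matrix.values, labels, d).surviving_genes)
                  for d in np.linspace(0, 20, 15)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_constant_gene_handled_via_fudge(self):
        matrix, labels, _ = two_class_matrix(seed=8)
        values = matrix.values.copy()
        values.iloc[0] = 5.0  # constant gene: s_j = 0
        model = _fit_centroids(values, labels, delta=0.0)
        assert np.isfinite(model.shrunken.to_numpy()).all()

    def test_json_round_trip(self, tmp_path):
        matrix, labels, _ = two_class_matrix(seed=9)
        model = _fit_centroids(matrix.values, labels, delta=2.0)
        path = tmp_path / "model.json"
        model.to_json(path)
        from renalmatch.expression import ShrunkenCentroidModel
        back = ShrunkenCentroidModel.from_json(path)
        assert back.surviving_genes == model.surviving_genes
        assert np.allclose(back.shrunken, model.shrunken)


class TestSelectThreshold:
    def test_single_row(self):
        table = pd.DataFrame({"delta": [1.5], "mean_cv_error": [0.1]})
        assert select_threshold(table) == 1.5

    def test_tie_broken_toward_larger_delta(self):
        table = pd.DataFrame({"delta": [0.0, 1.0, 2.0, 3.0],
                              "mean_cv_error": [0.10, 0.04, 0.04, 0.12]})
        assert select_threshold(table) == 2.0

    def test_chosen_delta_keeps_markers_drops_nulls(self):
        matrix, labels, truth = two_class_matrix(
            seed=10, n_per_class=50, class_effect_size=2.0,
            n_marker_genes=80, noise_sd=0.5)
        model, cv = train_nsc(matrix, labels, folds=5, seed=10)
        markers = set(truth.marker_genes)
        nulls = set(GENES) - markers
        surviving = set(model.surviving_genes)
        assert surviving <= markers          # no null genes retained
        assert len(nulls & surviving) == 0
        assert len(nulls - surviving) >= 0.9 * len(nulls)


class TestClassifyMargin:
    def centroid_fixture(self):
        matrix, labels, _ = two_class_matrix(seed=11, n_per_class=40,
                                             n_marker_genes=100)
        model, _ = train_nsc(matrix, labels, threshold_grid=[2.0], folds=5,
                             seed=11)
        return model

    @pytest.mark.parametrize("ca,cb,expected", [
        (0.30, 0.20, "ccA"),          # margin 0.10
        (0.30, 0.27, "unclassified"),  # margin 0.03
        (0.25, 0.20, "ccA"),          # boundary: exactly 0.05 inclusive
        (0.20, 0.30, "ccB"),
    ])
    def test_margin_rule(self, ca, cb, expected, monkeypatch):
        model = self.centroid_fixture()
        from renalmatch import expression as ex
        vals = iter([ca, cb])

        class FakeResult:
            def __init__(self, v):
                self.statistic = v

        monkeypatch.setattr(ex.stats, "spearmanr",
                            lambda *a, **k: FakeResult(next(vals)))
        sample = GeneMatrix(
            pd.DataFrame({"s": np.zeros(len(model.surviving_genes))},
                         index=model.surviving_genes), "expression")
        (call,) = classify_margin(model, sample)
        assert call.call == expected

    def test_excessive_missing_genes_rejected(self):
        model = self.centroid_fixture()
        few = model.surviving_genes[:max(1, len(model.surviving_genes) // 2)]
        sample = GeneMatrix(pd.DataFrame({"s": np.zeros(len(few))}, index=few),
                            "expression")
        with pytest.raises(InvalidArgumentError):
            classify_margin(model, sample)


class TestEndToEnd:
    def test_recovery_with_batch_effects(self):
        """Held-out two-class calling through batch correction, threshold
        selection and margin calling; intermediates mostly unclassified."""
        genes = [f"g{i}" for i in range(600)]
        m, truth = simulate_expression(genes, n_per_class=60, n_intermediate=15,
                                       class_effect_size=2.0, n_marker_genes=120,
                                       batch_shift=1.0, noise_sd=0.5, seed=12)
        adj, _ = combat_adjust(m, truth.batch)
        labels = truth.expression_class[truth.expression_class != "intermediate"]
        model, _ = train_nsc(GeneMatrix(adj.values[labels.index], "expression"),
                             labels, folds=5, seed=12)
        m2, truth2 = simulate_expression(genes, n_per_class=30, n_intermediate=15,
                                         class_effect_size=2.0, n_marker_genes=120,
                                         batch_shift=1.0, noise_sd=0.5, seed=120)
        adj2, _ = combat_adjust(m2, truth2.batch)
        calls = calls_to_frame(classify_margin(model, adj2)).set_index("sample_id")
        cls2 = truth2.expression_class
        ab = cls2[cls2 != "intermediate"]
        inter = cls2[cls2 == "intermediate"]
        assert (calls.loc[ab.index, "call"] == ab).mean() >= 0.95
        assert (calls.loc[inter.index, "call"] == "unclassified").mean() >= 0.70
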