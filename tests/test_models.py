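"""SDM engine contracts: replicate splits, the four families, prediction
paths and ensembles."""

import numpy as np
import pandas as pd
import pytest

from ecosdm import covsel, metrics, models, synthetic

from conftest import make_design

FAST_HP = {"rf_trees": 100}


def separable_design(n=60):
    x = np.concatenate([np.linspace(1, 2, n // 2), np.linspace(-2, -1, n // 2)])
    y = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
    X = pd.DataFrame({"bio1": x, "bio12": 0.5 * x})
    return covsel.DesignMatrix("sp", X, y, np.ones(n),
                               {"bio1": "climate", "bio12": "climate"})


class TestSplits:
    def test_stratified_counts(self):
        d = make_design(n=600, seed=0, n_vars=5)
        # relabel to exactly 100 presences for clean arithmetic
        y = np.zeros(600)
        y[:100] = 1
        d = covsel.DesignMatrix(d.species_id, d.X, y, d.weights, d.categories)
        splits = models.split_replicates(d, n_replicates=10, test_fraction=0.2, seed=1)
        assert len(splits) == 10
        for s in splits:
            assert (d.y[s.test_idx] == 1).sum() == 20
            assert len(np.intersect1d(s.train_idx, s.test_idx)) == 0
            assert len(s.train_idx) + len(s.test_idx) == 600

    def test_zero_test_fraction_rejected(self):
        d = make_design(n=100, seed=0, n_vars=5)
        with pytest.raises(ValueError, match="test_fraction"):
            models.split_replicates(d, 2, 0.0, seed=0)

    def test_same_seed_identical(self):
        d = make_design(n=200, seed=0, n_vars=5)
        a = models.split_replicates(d, 5, 0.2, seed=7)
        b = models.split_replicates(d, 5, 0.2, seed=7)
        for s, t in zip(a, b):
            assert np.array_equal(s.train_idx, t.train_idx)
            assert np.array_equal(s.test_idx, t.test_idx)


class TestFitPredict:
    @pytest.mark.parametrize("family", models.FAMILIES)
    def test_separable_design_reaches_perfect_auc(self, family):
        d = separable_design()
        m = models.fit_model(d, family, FAST_HP, seed=0)
        scores = m.predict_matrix(d.X)
        assert metrics.auc(d.y, scores) == pytest.approx(1.0)

    def test_null_design_auc_near_half(self):
        # response independent of predictors: mean held-out AUC ~ 0.5
        aucs = []
        for seed in range(20):
            d = make_design(n=400, seed=2000 + seed, effect=0.0,
                            signal_vars=(), n_vars=5)
            splits = models.split_replicates(d, 1, 0.25, seed=seed)
            for family in models.FAMILIES:
                m = models.fit_model(
                    covsel.DesignMatrix(d.species_id,
                                        d.X.iloc[splits[0].train_idx].reset_index(drop=True),
                                        d.y[splits[0].train_idx],
                                        d.weights[splits[0].train_idx], d.categories),
                    family, FAST_HP, seed=seed)
                scores = m.predict_matrix(d.X.iloc[splits[0].test_idx])
                aucs.append(metrics.auc(d.y[splits[0].test_idx], scores))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    @pytest.mark.parametrize("family", ["GAM", "MAXENT"])
    def test_gaussian_niche_response_is_unimodal_with_peak_near_optimum(self, family):
        # single-variable virtual species: the fitted response curve peaks
        # within one niche breadth of the true optimum
        ls = synthetic.generate_env_layers(1, 0, (64, 64), seed=21)
        sp = synthetic.VirtualSpecies("s", {"bio1": (0.5, 0.8)})
        suit = synthetic.suitability_surface(sp, ls)
        occ = synthetic.sample_occurrences(suit, ls, 250, seed=21)
        rng = np.random.default_rng(21)
        bx = rng.uniform(0, 64, 800)
        by = rng.uniform(0, 64, 800)
        bg = pd.DataFrame({"species": "s", "x": bx, "y": by})
        d = covsel.build_design(occ, bg, ls, ["bio1"])
        m = models.fit_model(d, family, seed=0)
        grid = np.linspace(d.X["bio1"].min(), d.X["bio1"].max(), 101)
        resp = m.predict_matrix(pd.DataFrame({"bio1": grid}))
        peak = grid[np.argmax(resp)]
        assert abs(peak - 0.5) < 0.8
        # unimodal up to small numerical ripple: rises then falls
        k = int(np.argmax(resp))
        assert np.all(np.diff(resp[:k + 1]) > -0.02)
        assert np.all(np.diff(resp[k:]) < 0.02)

    def test_constant_rows_give_constant_scores(self):
        d = separable_design()
        m = models.fit_model(d, "GLM", seed=0)
        X = pd.DataFrame({"bio1": [0.3] * 5, "bio12": [0.1] * 5})
        assert np.ptp(m.predict_matrix(X)) == 0.0

    def test_missing_variable_named_in_error(self):
        d = separable_design()
        m = models.fit_model(d, "GLM", seed=0)
        with pytest.raises(KeyError, match="bio12"):
            m.predict_matrix(pd.DataFrame({"bio1": [0.0]}))

    def test_landscape_prediction_equals_matrix_prediction(self, landscape32):
        sp = synthetic.VirtualSpecies("s", {"bio1": (0.0, 1.0)})
        suit = synthetic.suitability_surface(sp, landscape32)
        occ = synthetic.sample_occurrences(suit, landscape32, 100, seed=3)
        rng = np.random.default_rng(3)
        bg = pd.DataFrame({"species": "s", "x": rng.uniform(0, 32, 300),
                           "y": rng.uniform(0, 32, 300)})
        d = covsel.build_design(occ, bg, landscape32, ["bio1", "bio12"])
        m = models.fit_model(d, "GLM", seed=0)
        smap = m.predict_landscape(landscape32)
        rows, cols = np.indices(landscape32.shape)
        X = pd.DataFrame({v: landscape32.layers[v].ravel() for v in ["bio1", "bio12"]})
        assert np.allclose(smap.ravel(), m.predict_matrix(X), atol=1e-12)

    @pytest.mark.parametrize("family", ["GLM", "GAM", "MAXENT"])
    def test_affine_rescaling_invariance(self, family):
        d = make_design(n=300, seed=9, effect=2.0, signal_vars=(0,), n_vars=3)
        m1 = models.fit_model(d, family, seed=0)
        X2 = d.X.copy()
        X2["bio1"] = X2["bio1"] * 50.0 + 7.0
        d2 = covsel.DesignMatrix(d.species_id, X2, d.y, d.weights, d.categories)
        m2 = models.fit_model(d2, family, seed=0)
        p1 = m1.predict_matrix(d.X)
        p2 = m2.predict_matrix(X2)
        assert np.allclose(p1, p2, atol=5e-3)

    def test_rf_monotone_rescaling_invariance(self):
        d = make_design(n=300, seed=9, effect=2.0, signal_vars=(0,), n_vars=3)
        m1 = models.fit_model(d, "RF", FAST_HP, seed=0)
        X2 = d.X.copy()
        X2["bio1"] = np.exp(X2["bio1"])  # strictly monotone transform
        d2 = covsel.DesignMatrix(d.species_id, X2, d.y, d.weights, d.categories)
        m2 = models.fit_model(d2, "RF", FAST_HP, seed=0)
        diff = np.abs(m1.predict_matrix(d.X) - m2.predict_matrix(X2))
        # vote fractions are invariant up to rare split tie-breaks
        assert diff.max() <= 0.05 and diff.mean() <= 0.01


class TestEnsemble:
    def _bundle(self, preds):
        fms = {}
        for i, p in enumerate(preds):
            fms[("GLM", i + 1)] = models.FittedModel(
                "GLM", ["bio1"], (lambda q: (lambda A: np.full(len(A), q)))(p))
        return models.ModelBundle("sp", "climate_only", ["bio1"], fms, [])

    def test_identical_members_pass_through(self):
        b = self._bundle([0.4, 0.4, 0.4])
        X = pd.DataFrame({"bio1": [0.0, 1.0]})
        assert np.allclose(models.ensemble_predict(b, X), 0.4)

    def test_mean_rule_arithmetic(self):
        b = self._bundle([0.2, 0.8])
        X = pd.DataFrame({"bio1": [0.0]})
        assert models.ensemble_predict(b, X)[0] == pytest.approx(0.5)

    def test_tss_weighted_rule(self):
        b = self._bundle([1.0, 0.0])
        tss_w = {("GLM", 1): 0.9, ("GLM", 2): 0.1}
        X = pd.DataFrame({"bio1": [0.0]})
        out = models.ensemble_predict(b, X, rule="tss_weighted", member_tss=tss_w)
        assert out[0] == pytest.approx(0.9)

    def test_bracketing_by_member_min_max(self, landscape32):
        d = make_design(n=200, seed=4, n_vars=3)
        splits = models.split_replicates(d, 2, 0.2, seed=4)
        bundle = models.fit_bundle(d, splits, ("GLM", "RF"), hyperparams=FAST_HP, seed=4)
        X = d.X.iloc[:50]
        member_preds = np.stack([m.predict_matrix(X)
                                 for m in bundle.live_members().values()])
        ens = models.ensemble_predict(bundle, X)
        assert np.all(ens >= member_preds.min(axis=0) - 1e-12)
        assert np.all(ens <= member_preds.max(axis=0) + 1e-12)

    def test_all_members_excluded_reports_tss(self):
        b = self._bundle([0.5, 0.6])
        tss_w = {("GLM", 1): 0.1, ("GLM", 2): 0.2}
        with pytest.raises(ValueError, match="below TSS cutoff"):
            models.ensemble_predict(b, pd.DataFrame({"bio1": [0.0]}),
                                    member_tss=tss_w, inclusion_cutoff=0.5)
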