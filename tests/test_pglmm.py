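import numpy as np
import pandas as pd
import pytest

from bristlephylo import pglmm, synthdata
from bristlephylo.pglmm import (
    ModelSpec, PriorSpec, backward_eliminate, build_design,
    effective_sample_size, gelman_rubin, liability_scale, pmcmc, run_chain,
    run_model, summarize_model,
)
from bristlephylo.treeio import parse_tree


@pytest.fixture(scope="module")
def small_world():
    tree = synthdata.simulate_tree(60, seed=31)
    data, truth = synthdata.simulate_ecological_dataset(tree, seed=32)
    return tree, data, truth


FAST = dict(total=3000, burnin=600, thin=3)


class TestBuildDesign:
    def test_treatment_coding_against_reference(self, small_world):
        tree, data, _ = small_world
        spec = ModelSpec("gaussian", "length", factors=("habitat_type",))
        d = build_design(data, spec, tree)
        assert d.columns[0] == "(intercept)"
        assert "habitat_type:Open" not in d.columns  # reference level
        assert all(c.startswith("habitat_type:") for c in d.columns[1:])
        assert d.X[:, 0].min() == 1.0
        # rows with the reference level have all-zero dummies
        ref_rows = data["habitat_type"] == "Open"
        assert np.all(d.X[ref_rows.to_numpy(), 1:] == 0)

    def test_incidence_matrices(self, small_world):
        tree, data, _ = small_world
        spec = ModelSpec("gaussian", "length", factors=())
        d = build_design(data, spec, tree)
        assert d.Z.sum() == len(data) and set(d.Z.sum(axis=1)) == {1.0}
        assert d.W.shape[1] == data["individual"].nunique()
        assert np.allclose(np.diag(d.C), 1.0)

    def test_species_missing_from_tree_named(self, small_world):
        tree, data, _ = small_world
        bad = data.copy()
        bad.loc[bad.index[0], "species"] = "not_a_tip"
        spec = ModelSpec("gaussian", "length")
        with pytest.raises(ValueError, match="not_a_tip"):
            build_design(bad, spec, tree)

    def test_undeclared_level_rejected(self, small_world):
        tree, data, _ = small_world
        spec = ModelSpec("gaussian", "length", factors=("habitat_type",),
                         levels={"habitat_type": ["Open"]})
        with pytest.raises(ValueError, match="undeclared"):
            build_design(data, spec, tree)

    def test_threshold_requires_binary(self, small_world):
        tree, data, _ = small_world
        spec = ModelSpec("threshold", "length", factors=())
        with pytest.raises(ValueError, match="binary"):
            build_design(data, spec, tree)

    def test_bad_spec_arguments(self):
        with pytest.raises(ValueError):
            ModelSpec("poisson", "y")
        with pytest.raises(ValueError):
            ModelSpec("gaussian", "y", total=100, burnin=200)
        with pytest.raises(ValueError):
            PriorSpec(V=-1)


class TestPmcmc:
    def test_balanced_sample(self):
        assert pmcmc([-1, 1, -2, 2]) == 1.0

    def test_one_sided_floored(self):
        assert pmcmc(np.ones(100)) == pytest.approx(0.02)

    def test_three_to_one(self):
        assert pmcmc([1.0, 2.0, 3.0, -1.0]) == pytest.approx(0.5)

    def test_too_small(self):
        with pytest.raises(ValueError):
            pmcmc([1.0])


class TestGelmanRubin:
    def _chain(self, seed, n=2000):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"x": rng.normal(size=n)})

    def test_identical_chains_give_exact_value(self):
        c = self._chain(0)
        n = len(c)
        r = gelman_rubin([c, c, c])
        assert r["x"] == pytest.approx(np.sqrt((n - 1) / n), abs=1e-12)

    def test_iid_chains_near_one(self):
        r = gelman_rubin([self._chain(i) for i in range(4)])
        assert abs(r["x"] - 1.0) < 0.01

    def test_shifted_chain_flagged(self):
        shifted = self._chain(1) + 5.0
        r = gelman_rubin([self._chain(0), shifted])
        assert r["x"] > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([self._chain(0)])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([self._chain(0, 100), self._chain(1, 120)])


class TestEffectiveSampleSize:
    def test_iid_ess_near_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        assert abs(effective_sample_size(x) - 4000) < 800

    def test_autocorrelated_ess_much_smaller(self):
        rng = np.random.default_rng(1)
        x = np.empty(4000)
        x[0] = 0.0
        for i in range(1, 4000):
            x[i] = 0.95 * x[i - 1] + rng.normal()
        assert effective_sample_size(x) < 1000


class TestGaussianChain:
    def test_conjugate_fit_matches_ols_when_variance_structure_flat(self):
        # star tree + huge residual prior weight: posterior mean of beta
        # should sit close to the OLS estimate of the same regression
        tips = ",".join(f"s{i}:1" for i in range(40))
        tree = parse_tree(f"({tips});")
        rng = np.random.default_rng(5)
        x = rng.choice(["Open", "Closed"], size=40)
        y = 3.0 + 2.0 * (x == "Closed") + rng.normal(0, 0.3, size=40)
        data = pd.DataFrame({"species": [f"s{i}" for i in range(40)],
                             "individual": [f"i{i}" for i in range(40)],
                             "habitat_type": x, "length": y})
        spec = ModelSpec("gaussian", "length", factors=("habitat_type",),
                         **FAST)
        d = build_design(data, spec, tree)
        out = run_chain(d, PriorSpec(), plan=(spec.total, spec.burnin,
                                              spec.thin), seed=0)
        X = d.X
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        post = out["samples"][d.columns].mean().to_numpy()
        assert np.allclose(post, ols, atol=0.25)

    def test_bit_reproducible(self, small_world):
        tree, data, _ = small_world
        spec = ModelSpec("gaussian", "length", factors=("habitat_type",),
                         **FAST)
        d = build_design(data, spec, tree)
        a = run_chain(d, PriorSpec(), plan=(3000, 600, 3), seed=7)
        b = run_chain(d, PriorSpec(), plan=(3000, 600, 3), seed=7)
        pd.testing.assert_frame_equal(a["samples"], b["samples"])
        assert a["dic"] == b["dic"]

    def test_retained_count_and_schema(self, small_world):
        tree, data, _ = small_world
        spec = ModelSpec("gaussian", "length", factors=(), **FAST)
        d = build_design(data, spec, tree)
        out = run_chain(d, PriorSpec(), plan=(3000, 600, 3), seed=1)
        assert len(out["samples"]) == (3000 - 600) // 3
        for col in ("var_phylo", "var_individual", "var_residual"):
            assert (out["samples"][col] > 0).all()

    def test_recovers_generating_effect(self, small_world):
        tree, data, truth = small_world
        spec = ModelSpec("gaussian", "length",
                         factors=("activity_period", "habitat_type"),
                         total=6000, burnin=1200, thin=4, n_chains=2)
        fit = run_model(data, tree, spec, seed=2)
        summ = summarize_model(fit)
        t = summ.table
        b = truth.beta["activity_period:Obligate nocturnal"]
        row = t.loc["activity_period:Obligate nocturnal"]
        assert row["ci_lower"] < b < row["ci_upper"]
        assert row["significant"]


class TestThresholdChain:
    def test_liability_respects_signs(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(size=500)
        y = (rng.random(500) < 0.5).astype(float)
        liab = pglmm._truncated_liability(rng, eta, y)
        assert np.all((liab > 0) == (y > 0.5))

    def test_residual_variance_fixed_at_one(self, small_world):
        tree, data, _ = small_world
        spec = ModelSpec("threshold", "presence", factors=(), **FAST)
        d = build_design(data, spec, tree)
        out = run_chain(d, PriorSpec(), plan=(2000, 400, 2), seed=3)
        assert (out["samples"]["var_residual"] == 1.0).all()

    def test_liability_scale_normalization(self):
        s = pd.DataFrame({"(intercept)": [2.0, 2.0],
                          "var_phylo": [1.0, 3.0],
                          "var_individual": [1.0, 0.5],
                          "var_residual": [2.0, 0.5]})
        out = liability_scale(s)
        assert out["(intercept)"].tolist() == [1.0, 1.0]
        assert out["var_phylo"].tolist() == [1.0, 3.0]  # variances untouched


class TestSummaries:
    def test_constant_parameter_handled(self):
        c = {"samples": pd.DataFrame({"x": np.ones(100)}), "dic": 10.0}
        s = summarize_model([c])
        assert s.table.loc["x", "mean"] == 1.0
        assert s.table.loc["x", "ess"] == 100.0
        assert s.dic == 10.0

    def test_significance_flag_tracks_ci(self):
        rng = np.random.default_rng(2)
        c = {"samples": pd.DataFrame({
            "pos": rng.normal(5, 1, 500),
            "null": rng.normal(0, 1, 500)}), "dic": 0.0}
        t = summarize_model([c]).table
        assert t.loc["pos", "significant"] and not t.loc["null", "significant"]
        assert t.loc["pos", "pMCMC"] == pytest.approx(2 / 500)

    def test_convergence_flag(self):
        rng = np.random.default_rng(3)
        good = [{"samples": pd.DataFrame({"x": rng.normal(size=1000)}),
                 "dic": 0.0} for _ in range(2)]
        assert summarize_model(good).converged
        bad = [good[0],
               {"samples": good[1]["samples"] + 50.0, "dic": 0.0}]
        assert not summarize_model(bad).converged


class TestBackwardElimination:
    def test_drops_pure_noise_factor(self, small_world):
        tree, data, truth = small_world
        spec = ModelSpec("gaussian", "length",
                         factors=("activity_period", "diet"),
                         total=3000, burnin=600, thin=3, n_chains=2)
        reduced, fit, trail = backward_eliminate(data, tree, spec, seed=4)
        assert "activity_period" in reduced.factors  # true effect retained
        # every decision in the trail is consistent with the DIC rule
        for step in trail:
            assert step["kept"] == (step["dic_after"] < step["dic_before"])

    def test_intercept_never_dropped(self, small_world):
        tree, data, _ = small_world
        spec = ModelSpec("gaussian", "length", factors=(),
                         total=2000, burnin=400, thin=2, n_chains=2)
        reduced, fit, trail = backward_eliminate(data, tree, spec, seed=5)
        assert trail == []
        assert "(intercept)" in fit["design"].columns
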