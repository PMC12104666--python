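"""The statistics layer: median CIs, circular tests, correlations, LMMs."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from natdisp.lmm import fit_lmm
from natdisp.stats import (CoefficientTable, Scaling, density_trend,
                           fit_lmm_reduced, holm_adjust, kde_mode,
                           median_ci_sign, pearson_holm, rayleigh_test,
                           scaled_log, zero_crossing_density)


# ---------------------------------------------------------------------------
# Sign-test median CI
# ---------------------------------------------------------------------------

class TestMedianCI:
    def test_one_to_ten(self):
        res = median_ci_sign(range(1, 11))
        assert res.median == 5.5
        assert (res.lower, res.upper) == (2.0, 9.0)
        assert res.achieved_conf == pytest.approx(0.9785, abs=5e-4)

    def test_constant_vector(self):
        res = median_ci_sign([4.2] * 12)
        assert (res.lower, res.upper) == (4.2, 4.2)

    def test_small_sample_returns_whole_range_with_warning(self):
        with pytest.warns(UserWarning):
            res = median_ci_sign([1.0, 2.0, 3.0, 4.0])
        assert (res.lower, res.upper) == (1.0, 4.0)
        assert res.achieved_conf < 0.95

    def test_bounds_are_observed_values_and_widen_with_confidence(self, rng):
        x = rng.lognormal(3.5, 0.8, 43)
        lo = median_ci_sign(x, conf=0.90)
        hi = median_ci_sign(x, conf=0.99)
        assert {lo.lower, lo.upper, hi.lower, hi.upper} <= set(x)
        assert hi.upper - hi.lower >= lo.upper - lo.lower

    def test_coverage_at_least_nominal(self, rng):
        # lognormal samples at the study's female sample size
        true_median = np.exp(4.0)
        hits = 0
        reps = 2000
        for _ in range(reps):
            x = rng.lognormal(4.0, 0.8, 43)
            res = median_ci_sign(x)
            hits += res.lower <= true_median <= res.upper
        # nominal achieved confidence for n=43 is ~0.956; allow MC error
        assert hits / reps >= 0.95 - 2 * np.sqrt(0.05 * 0.95 / reps)


# ---------------------------------------------------------------------------
# Rayleigh test
# ---------------------------------------------------------------------------

class TestRayleigh:
    def test_concentrated_bearings(self):
        res = rayleigh_test([180.0] * 10)
        assert res.r == pytest.approx(1.0)
        assert res.mean_angle == pytest.approx(180.0)
        assert res.p < 1e-6

    def test_perfectly_symmetric_bearings(self):
        res = rayleigh_test([0.0, 90.0, 180.0, 270.0])
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_needs_three_bearings(self):
        with pytest.raises(ValueError):
            rayleigh_test([10.0, 20.0])

    def test_rotation_invariance(self, rng):
        ang = rng.uniform(0, 360, 25)
        base = rayleigh_test(ang)
        rot = rayleigh_test((ang + 137.0) % 360.0)
        assert rot.r == pytest.approx(base.r, abs=1e-12)
        assert rot.p == pytest.approx(base.p, abs=1e-12)
        assert rot.mean_angle == pytest.approx(
            (base.mean_angle + 137.0) % 360.0, abs=1e-9)

    def test_p_value_agrees_with_permutation_null(self, rng):
        # moderate-n fixture against an exhaustive uniform resampling null
        ang = np.degrees(rng.vonmises(1.0, 0.9, 20)) % 360
        res = rayleigh_test(ang)
        N = 100_000
        th = rng.uniform(0, 2 * np.pi, (N, 20))
        rnull = np.abs(np.exp(1j * th).sum(axis=1)) / 20
        pmc = float((rnull >= res.r).mean())
        se = np.sqrt(pmc * (1 - pmc) / N)
        assert abs(res.p - pmc) < 3 * se + 1e-3


# ---------------------------------------------------------------------------
# Pearson + Holm
# ---------------------------------------------------------------------------

class TestPearsonHolm:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        out = pearson_holm({"t": (x, x)})
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_holm_adjustment_matches_hand_computation(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        # step-down with monotonicity: sorted (0.01, 0.03, 0.04) ->
        # (3*0.01, 2*0.03, max(0.06, 1*0.04))
        np.testing.assert_allclose(holm_adjust([0.03, 0.01, 0.04]),
                                   [0.06, 0.03, 0.06])

    def test_family_of_one_is_unadjusted(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        out = pearson_holm({"only": (x, y)})
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_zero_variance_reported_as_undefined(self, rng):
        out = pearson_holm({"flat": (np.ones(10), rng.normal(size=10)),
                            "ok": (np.arange(10.0), np.arange(10.0))})
        assert np.isnan(out.set_index("label").loc["flat", "r"])
        assert np.isfinite(out.set_index("label").loc["ok", "p_adj"])


# ---------------------------------------------------------------------------
# KDE mode
# ---------------------------------------------------------------------------

class TestKdeMode:
    def test_symmetric_sample_mode_near_median(self, rng):
        x = rng.normal(10.0, 1.0, 2000)
        h = sps.gaussian_kde(x).factor * x.std(ddof=1)
        assert abs(kde_mode(x) - np.median(x)) < h

    def test_mixture_mode_finds_the_major_component(self, rng):
        x = np.concatenate([rng.normal(0.007, 0.001, 8000),
                            rng.normal(0.02, 0.001, 2000)])
        assert kde_mode(x) == pytest.approx(0.007, abs=0.002)

    def test_permutation_invariant_and_degenerate_input(self, rng):
        x = rng.lognormal(0, 1, 500)
        assert kde_mode(x) == kde_mode(np.sort(x))
        assert kde_mode(np.full(10, 3.3)) == 3.3


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

def simulate_lmm_data(rng, n=150, n_terr=40, n_year=7, sex_effect=0.55,
                      sd_terr=0.4, sd_year=0.3, sd_eps=0.6):
    terr = rng.integers(0, n_terr, n)
    year = rng.integers(0, n_year, n)
    female = rng.integers(0, 2, n)
    x = rng.normal(size=n)
    y = (3.5 + sex_effect * female - 0.1 * x
         + rng.normal(0, sd_terr, n_terr)[terr]
         + rng.normal(0, sd_year, n_year)[year]
         + rng.normal(0, sd_eps, n))
    return pd.DataFrame({
        "y": y, "x": x,
        "sex": np.where(female == 1, "female", "male"),
        "natal_territory": [f"T{t}" for t in terr],
        "natal_year": 2012 + year,
        "natal_period": np.where(year < 3, "stagnation", "growth"),
    })


class TestFitLMM:
    def test_matches_lmerTest_reference(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: cannot run the lmerTest oracle")
        df = simulate_lmm_data(rng)
        X = pd.DataFrame({"(Intercept)": 1.0,
                          "female": (df["sex"] == "female").astype(float),
                          "x": df["x"]})
        fit = fit_lmm(df["y"], X, {"terr": df["natal_territory"],
                                   "year": df["natal_year"]})
        csv = tmp_path / "d.csv"
        df.assign(female=(df["sex"] == "female").astype(int)).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            m <- lmer(y ~ female + x + (1|natal_territory) + (1|natal_year), data=d)
            co <- coef(summary(m))
            write.csv(co, "{tmp_path}/out.csv")
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        np.testing.assert_allclose(fit.params.to_numpy(),
                                   ref["Estimate"].to_numpy(), rtol=1e-4)
        np.testing.assert_allclose(fit.bse.to_numpy(),
                                   ref["Std. Error"].to_numpy(), rtol=1e-3)
        np.testing.assert_allclose(fit.df.to_numpy(),
                                   ref["df"].to_numpy(), rtol=5e-3)
        np.testing.assert_allclose(fit.pvalues.to_numpy(),
                                   ref["Pr(>|t|)"].to_numpy(), rtol=2e-2, atol=1e-6)

    def test_reduces_to_ols_when_group_variance_vanishes(self, rng):
        n = 80
        X = pd.DataFrame({"(Intercept)": np.ones(n), "x": rng.normal(size=n)})
        groups = np.arange(n) % 10  # balanced
        eps = rng.normal(0, 1.0, n)
        # remove all between-group variation so the REML variance estimate
        # sits exactly on the zero boundary
        for g in range(10):
            eps[groups == g] -= eps[groups == g].mean()
        y = (2.0 + 0.5 * X["x"] + eps).to_numpy()
        fit = fit_lmm(y, X, {"g": groups})
        assert fit.singular
        beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-6)
        resid = y - X.to_numpy() @ beta
        s2 = resid @ resid / (n - 2)
        se_ols = np.sqrt(np.diag(s2 * np.linalg.inv(X.T.to_numpy() @ X.to_numpy())))
        np.testing.assert_allclose(fit.bse.to_numpy(), se_ols, rtol=1e-5)

    def test_parameter_recovery_of_sex_effect(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            df = simulate_lmm_data(rng, n=200, sex_effect=0.55)
            X = pd.DataFrame({"(Intercept)": 1.0,
                              "female": (df["sex"] == "female").astype(float),
                              "x": df["x"]})
            fit = fit_lmm(df["y"], X, {"terr": df["natal_territory"],
                                       "year": df["natal_year"]})
            tcrit = sps.t.ppf(0.975, fit.df["female"])
            lo = fit.params["female"] - tcrit * fit.bse["female"]
            hi = fit.params["female"] + tcrit * fit.bse["female"]
            hits += lo <= 0.55 <= hi
        assert hits / reps >= 0.85  # ~95% coverage, small-replicate slack


class TestBackwardReduction:
    def test_spurious_terms_dropped_main_effects_kept(self, rng):
        df = simulate_lmm_data(rng, n=250, sex_effect=0.0)
        tab = fit_lmm_reduced(df, "y", ["sex", "x", "natal_period"],
                              quadratic=["x"],
                              references={"sex": "male",
                                          "natal_period": "stagnation"})
        terms = set(tab.table["term"])
        # main effects survive regardless of significance
        assert {"(Intercept)", "sex[female]", "x",
                "natal_period[growth]"} <= terms
        # every eliminated term was non-significant when dropped
        assert all(p >= 0.05 for _, p in tab.reduction_path)
        # interactions are considered strictly before quadratic terms
        kinds = [0 if ":" in t else 1 for t, _ in tab.reduction_path
                 if ":" in t or t.endswith("^2")]
        assert kinds == sorted(kinds)
        # whatever remains beyond the mains is significant at the threshold
        kept = tab.table.set_index("term")
        for t in terms - {"(Intercept)", "sex[female]", "x",
                          "natal_period[growth]"}:
            assert kept.loc[t, "p"] < 0.05

    def test_reduction_is_deterministic(self, rng):
        df = simulate_lmm_data(rng, n=180)
        a = fit_lmm_reduced(df, "y", ["sex", "x"], quadratic=["x"])
        b = fit_lmm_reduced(df, "y", ["sex", "x"], quadratic=["x"])
        assert a.reduction_path == b.reduction_path
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_genuine_interaction_survives(self, rng):
        n = 300
        female = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        y = 1.0 + 0.3 * female + 0.2 * x + 1.5 * female * x + rng.normal(0, 0.4, n)
        df = pd.DataFrame({"y": y, "x": x,
                           "sex": np.where(female == 1, "female", "male"),
                           "natal_territory": rng.integers(0, 30, n),
                           "natal_year": rng.integers(0, 6, n)})
        tab = fit_lmm_reduced(df, "y", ["sex", "x"], references={"sex": "male"})
        assert "sex[female]:x" in set(tab.table["term"])


class TestDensityTrend:
    @staticmethod
    def make_table(rng, slope=np.log(1.10), n_terr=50, years=range(2011, 2023),
                   noise=0.1):
        rows = []
        base = rng.normal(np.log(0.007), 0.3, n_terr)
        for i in range(n_terr):
            for t, year in enumerate(years):
                rows.append({"territory_id": f"T{i}", "year": year,
                             "density": np.exp(base[i] + slope * t
                                               + rng.normal(0, noise))})
        return pd.DataFrame(rows)

    def test_constant_densities_give_zero_slope(self):
        tab = pd.DataFrame([{"territory_id": f"T{i}", "year": y, "density": 0.01}
                            for i in range(10) for y in (2011, 2012, 2013)])
        res = density_trend(tab)
        assert res.slope == pytest.approx(0.0, abs=1e-8)

    def test_ten_percent_growth_recovered(self, rng):
        res = density_trend(self.make_table(rng))
        assert res.slope == pytest.approx(np.log(1.10), abs=3 * res.se)

    def test_single_territory_falls_back_to_regression(self, rng):
        tab = self.make_table(rng, n_terr=1)
        with pytest.warns(UserWarning, match="single territory"):
            res = density_trend(tab)
        assert np.isfinite(res.slope)

    def test_year_permutation_destroys_the_trend(self, rng):
        tab = self.make_table(rng, n_terr=25, noise=0.3)
        covered = 0
        reps = 30
        for _ in range(reps):
            perm = tab.copy()
            perm["year"] = rng.permutation(perm["year"].to_numpy())
            res = density_trend(perm)
            tcrit = sps.t.ppf(0.975, max(res.df, 1.0))
            covered += abs(res.slope) <= tcrit * res.se
        assert covered / reps >= 0.8


class TestZeroCrossing:
    @staticmethod
    def table(rows):
        return CoefficientTable(
            table=pd.DataFrame([{"term": t, "estimate": e, "SE": 0.1,
                                 "df": 90.0, "t": 1.0, "p": 0.5}
                                for t, e in rows]),
            response="density_difference", reduction_path=[], re_var={},
            sigma2=1.0, singular=False)

    def test_linear_crossing_algebra(self):
        # intercept -0.519, scaled-log-density slope -0.578
        model = self.table([("(Intercept)", -0.519),
                            ("log_natal_density", -0.578)])
        sc = Scaling(mean=np.log(0.0075), sd=0.55)
        out = zero_crossing_density(model, sc)
        # z* = -b0/b1 = -(-0.519)/(-0.578) ~ -0.898
        assert out.scaled_log_density == pytest.approx(-0.519 / 0.578, abs=1e-9)
        assert out.density == pytest.approx(
            np.exp(np.log(0.0075) + 0.55 * (-0.898)), rel=1e-3)

    def test_flat_model_has_no_crossing(self):
        model = self.table([("(Intercept)", 0.0)])
        with pytest.raises(ValueError, match="flat|crossing"):
            zero_crossing_density(model, Scaling(0.0, 1.0))

    def test_out_of_range_crossing_flagged(self):
        model = self.table([("(Intercept)", -5.0),
                            ("log_natal_density", -0.5)])
        out = zero_crossing_density(model, Scaling(-5.0, 0.5),
                                    observed_log_range=(-6.0, -4.0))
        assert not out.in_range

    def test_crossing_invariant_to_predictor_rescaling(self, rng):
        # the back-transformed crossing does not depend on whether the
        # log predictor was z-scored or left raw
        n = 200
        logd = rng.normal(np.log(0.008), 0.5, n)
        y = -0.3 - 0.6 * (logd - np.log(0.008)) / 0.5 + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"dd": y,
                           "natal_territory": rng.integers(0, 40, n),
                           "natal_year": rng.integers(0, 6, n)})
        z, sc = scaled_log(np.exp(logd))
        crossings = []
        for pred, scaling in ((z, sc), (logd, Scaling(0.0, 1.0))):
            d = df.assign(log_natal_density=pred)
            tab = fit_lmm_reduced(d, "dd", ["log_natal_density"],
                                  interactions=False)
            crossings.append(zero_crossing_density(tab, scaling).density)
        assert crossings[0] == pytest.approx(crossings[1], rel=1e-6)
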