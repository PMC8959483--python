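import numpy as np
import pandas as pd
import pytest

from coxradius.cox import (
    CoxError,
    concordance_index,
    filter_covariates,
    fit_cox,
    interaction_map,
    lr_test,
)
from coxradius.curves import SummaryCurve


def toy_survival(seed=0, n=120, beta=(0.5, -0.3), tie=False):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, len(beta)))
    t = rng.exponential(1.0 / (0.05 * np.exp(x @ np.asarray(beta))))
    c = rng.uniform(0, 40, n)
    time = np.minimum(t, c)
    if tie:
        time = np.ceil(time)
    df = pd.DataFrame(x, columns=[f"x{i}" for i in range(len(beta))])
    df["time"] = np.maximum(time, 1e-6)
    df["event"] = (t <= c).astype(int)
    return df


class TestFilterCovariates:
    def test_complete_table_unchanged(self):
        df = pd.DataFrame(
            {"time": [1, 2, 3], "event": [1, 0, 1], "a": [1.0, 2, 3]}
        )
        kept, out = filter_covariates(df, ["a"])
        assert kept == ["a"]
        assert len(out) == 3

    def test_half_missing_covariate_dropped_rows_kept(self):
        df = pd.DataFrame(
            {
                "time": np.arange(1, 11, dtype=float),
                "event": [1] * 10,
                "a": [np.nan] * 5 + [1.0] * 5,
                "b": np.arange(10, dtype=float),
            }
        )
        kept, out = filter_covariates(df, ["a", "b"])
        assert kept == ["b"]
        assert len(out) == 10

    def test_engineered_missingness_hand_tally(self):
        # hand tally at the strict over-90% rule:
        # a: 9/10 available = exactly 90% -> dropped (not *over* 90%)
        # b: 10/10 available -> kept; c: 5/10 -> dropped
        # complete-case on {b}: all 10 rows kept
        df = pd.DataFrame(
            {
                "time": np.arange(1, 11, dtype=float),
                "event": [1, 0] * 5,
                "a": [np.nan] + [1.0] * 9,
                "b": np.arange(10, dtype=float),
                "c": [np.nan] * 5 + [2.0] * 5,
            }
        )
        kept, out = filter_covariates(df, ["a", "b", "c"])
        assert kept == ["b"]
        assert len(out) == 10

    def test_all_rows_removed_errors(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0], "event": [1, 0], "a": [np.nan, np.nan]}
        )
        with pytest.raises(ValueError):
            filter_covariates(df, ["a"], availability_threshold=-1.0)


class TestFitCox:
    def test_null_model_c_half(self):
        df = toy_survival()
        fit = fit_cox(df, [])
        assert fit.c_index == 0.5
        assert fit.log_likelihood == fit.log_likelihood_null

    def test_six_subject_grid_search_oracle(self):
        # no ties: Efron == exact partial likelihood; 1-D grid search
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        def pl(b):
            ll = 0.0
            for i in range(6):
                if not event[i]:
                    continue
                risk = time >= time[i]
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return ll

        grid = np.arange(-5.0, 5.0, 1e-4)
        oracle = grid[np.argmax([pl(b) for b in grid])]
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = fit_cox(df, ["x"])
        assert fit.coefs[0] == pytest.approx(oracle, abs=1e-4)
        assert fit.log_likelihood == pytest.approx(pl(fit.coefs[0]), abs=1e-10)

    def test_duplication_near_invariance(self):
        # duplicating records leaves the Breslow MLE exactly unchanged;
        # Efron's tie correction (duplicates are ties) perturbs it only
        # slightly, and must agree with the reference implementation
        from lifelines import CoxPHFitter

        df = toy_survival(seed=1, n=60)
        doubled = pd.concat([df, df], ignore_index=True)
        fit1 = fit_cox(df, ["x0", "x1"])
        fit2 = fit_cox(doubled, ["x0", "x1"])
        np.testing.assert_allclose(fit1.coefs, fit2.coefs, atol=0.02)
        cph = CoxPHFitter().fit(doubled, "time", "event")
        np.testing.assert_allclose(fit2.coefs, cph.params_.values, atol=1e-5)

    @pytest.mark.parametrize("tie", [False, True])
    def test_matches_lifelines(self, tie):
        from lifelines import CoxPHFitter

        df = toy_survival(seed=2, n=150, beta=(0.4, -0.2), tie=tie)
        fit = fit_cox(df, ["x0", "x1"])
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(fit.coefs, cph.params_.values, atol=1e-5)
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov)), cph.standard_errors_.values, atol=1e-5
        )
        assert fit.c_index == pytest.approx(cph.concordance_index_, abs=1e-9)

    def test_no_events_errors(self):
        df = toy_survival(seed=3, n=20)
        df["event"] = 0
        with pytest.raises(CoxError, match="no events"):
            fit_cox(df, ["x0"])

    def test_singular_design_named(self):
        df = toy_survival(seed=4, n=40)
        df["x2"] = df["x0"] * 2.0
        with pytest.raises(CoxError, match="singular"):
            fit_cox(df, ["x0", "x1", "x2"])

    def test_constant_column_named(self):
        df = toy_survival(seed=5, n=40)
        df["flat"] = 1.0
        with pytest.raises(CoxError, match="flat"):
            fit_cox(df, ["x0", "flat"])


class TestConcordance:
    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index as lifelines_ci

        rng = np.random.default_rng(6)
        t = rng.exponential(10, 80)
        e = rng.uniform(size=80) < 0.5
        r = rng.normal(size=80)
        assert concordance_index(t, r, e) == pytest.approx(
            lifelines_ci(t, -r, e), abs=1e-12
        )

    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0])
        assert concordance_index(t, np.array([3.0, 2.0, 1.0]), np.ones(3)) == 1.0


class TestLrTest:
    def test_identical_models_p_one(self):
        df = toy_survival(seed=7)
        fit = fit_cox(df, ["x0"])
        # same ll, nominal extra df
        full = fit_cox(df, ["x0", "x1"])
        assert lr_test(fit, fit, df=1) == pytest.approx(1.0)
        assert 0 < lr_test(full, fit) <= 1

    def test_chi2_reference_value(self):
        from scipy.stats import chi2

        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_monotone_in_statistic(self):
        from scipy.stats import chi2

        stats = np.linspace(0, 10, 30)
        ps = chi2.sf(stats, 1)
        assert (np.diff(ps) < 0).all()

    def test_non_nested_errors(self):
        df = toy_survival(seed=8)
        full = fit_cox(df, ["x0", "x1"])
        red = fit_cox(df, ["x0"])
        with pytest.raises(CoxError):
            lr_test(red, full, df=1)


def curves_from_matrix(mat, window_lo=0.0):
    out = {}
    for i, row in enumerate(mat):
        out[f"P{i:04d}"] = SummaryCurve(
            statistic="mean",
            distances_cm=window_lo + 0.05 + np.arange(len(row)) * 0.1,
            values=row,
            valid=np.isfinite(row),
        )
    return out


class TestInteractionMap:
    @pytest.fixture
    def small_cohort(self):
        rng = np.random.default_rng(9)
        n = 80
        dens = rng.normal(0, 1, size=(n, 4)) + rng.normal(size=(n, 1))
        dose = rng.normal(0, 1, size=(n, 3)) + rng.normal(size=(n, 1))
        t = rng.exponential(20, n)
        c = rng.uniform(0, 30, n)
        clinical = pd.DataFrame(
            {
                "time": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "age": rng.normal(70, 5, n),
            },
            index=[f"P{i:04d}" for i in range(n)],
        )
        return curves_from_matrix(dens), curves_from_matrix(dose, 2.0), clinical

    def test_shape_and_windows(self, small_cohort):
        dens, dose, clinical = small_cohort
        m = interaction_map(
            dens, dose, clinical, ["age"], ("mean", "dose_sd"), min_events=5
        )
        assert m.shape == (4, 3)
        assert m.n_cells == 12
        assert m.density_window_cm == pytest.approx((0.0, 0.4))
        assert m.dose_window_cm == pytest.approx((2.0, 2.3))

    def test_cells_in_unit_interval(self, small_cohort):
        dens, dose, clinical = small_cohort
        m = interaction_map(
            dens, dose, clinical, ["age"], ("mean", "dose_sd"), min_events=5
        )
        finite = m.p_values[np.isfinite(m.p_values)]
        assert finite.size == 12
        assert ((finite > 0) & (finite <= 1)).all()

    def test_deterministic(self, small_cohort):
        dens, dose, clinical = small_cohort
        args = (dens, dose, clinical, ["age"], ("mean", "dose_sd"))
        m1 = interaction_map(*args, min_events=5)
        m2 = interaction_map(*args, min_events=5)
        np.testing.assert_array_equal(m1.p_values, m2.p_values)

    def test_min_events_masks_cells(self, small_cohort):
        dens, dose, clinical = small_cohort
        m = interaction_map(
            dens, dose, clinical, ["age"], ("mean", "dose_sd"),
            min_events=10**6,
        )
        assert np.isnan(m.p_values).all()

    def test_invalid_annulus_reduces_n(self, small_cohort):
        dens, dose, clinical = small_cohort
        key = "P0000"
        vals = dens[key].values.copy()
        vals[0] = np.nan
        dens[key] = SummaryCurve(
            statistic="mean",
            distances_cm=dens[key].distances_cm,
            values=vals,
            valid=np.isfinite(vals),
        )
        m = interaction_map(
            dens, dose, clinical, ["age"], ("mean", "dose_sd"), min_events=5
        )
        assert m.n_used[0, 0] == len(clinical) - 1
        assert m.n_used[1, 0] == len(clinical)

    def test_full_ll_at_least_reduced(self, small_cohort):
        # LR statistic never negative: p-values never above 1
        dens, dose, clinical = small_cohort
        m = interaction_map(
            dens, dose, clinical, ["age"], ("mean", "dose_sd"), min_events=5
        )
        assert np.nanmax(m.p_values) <= 1.0
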