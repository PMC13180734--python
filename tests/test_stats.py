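"""Association models, bootstrap, E-values and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neobag import stats as ST
from neobag import synthetic as S


def _table(rng, n=120, gap_slope=-0.22, noise=0.15):
    """Occasion table with a known apnoea-rate/gap slope."""
    n_inf = n // 2
    infants = np.repeat([f"i{k}" for k in range(n_inf)], 2)
    gap = rng.normal(0, 0.9, n)
    pma = rng.uniform(31, 37, n)
    length = rng.uniform(2, 12, n)
    infection = rng.choice(["no", "suspected", "treated"], n)
    y = 1.0 + gap_slope * gap + noise * rng.standard_normal(n)
    return pd.DataFrame({"infant_id": infants, "pma_weeks": pma,
                         "corrected_gap": gap, "apnoea_rate": y,
                         "resp_rate": 55 - 1.87 * (pma - 34)
                         + rng.normal(0, 1.5, n),
                         "ip_length_h": length, "infection": infection})


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.normal(size=(2, 80))
        rho, _ = ST.partial_correlation(x, y)
        assert rho == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_removes_shared_covariate(self, rng):
        z = rng.normal(size=200)
        x = z + 0.1 * rng.normal(size=200)
        y = z + 0.1 * rng.normal(size=200)
        covs = np.column_stack([np.ones(200), z])
        rho_raw, _ = ST.partial_correlation(x, y)
        rho_adj, _ = ST.partial_correlation(x, y, covs)
        assert rho_raw > 0.9
        assert abs(rho_adj) < 0.3


class TestFitAssociation:
    def test_near_deterministic_cohort_recovers_slope(self, rng):
        table = _table(rng, n=160, gap_slope=-0.22, noise=1e-7)
        fr = ST.fit_association(table, "apnoea_rate", "corrected_gap")
        assert fr.beta == pytest.approx(-0.22, abs=1e-6)

    def test_result_contract(self, rng):
        table = _table(rng)
        fr = ST.fit_association(table, "apnoea_rate", "corrected_gap")
        assert fr.ci_low <= fr.beta <= fr.ci_high
        assert 0.0 <= fr.p_value <= 1.0
        assert -1.0 <= fr.partial_rho <= 1.0
        assert fr.n == len(table)

    def test_constant_predictor_rejected(self, rng):
        table = _table(rng)
        table["corrected_gap"] = 0.0
        with pytest.raises(ValueError, match="singular"):
            ST.fit_association(table, "apnoea_rate", "corrected_gap")

    def test_unknown_columns_rejected(self, rng):
        with pytest.raises(ValueError):
            ST.fit_association(_table(rng), "apnoea_rate", "gap")


class TestBootstrap:
    def test_p_zero_when_gap_rho_below_all_resamples(self, rng):
        # strong negative gap association, no pma association
        table = _table(rng, n=150, gap_slope=-1.5, noise=0.05)
        res = ST.bootstrap_compare(table, n_reps=400, seed=0)
        assert res.rho_gap < res.samples.min()
        assert res.p_one_tailed == 0.0

    def test_gap_identical_to_pma_gives_half(self, rng):
        table = _table(rng, n=150, gap_slope=0.0, noise=0.3)
        table["corrected_gap"] = table["pma_weeks"]
        res = ST.bootstrap_compare(table, n_reps=2000, seed=1)
        assert res.p_one_tailed == pytest.approx(0.5, abs=0.08)

    def test_order_invariance_and_seed_reproducibility(self, rng):
        table = _table(rng, n=100)
        a = ST.bootstrap_compare(table, n_reps=500, seed=3)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = ST.bootstrap_compare(shuffled, n_reps=500, seed=3)
        assert a.rho_gap == pytest.approx(b.rho_gap, abs=1e-12)
        c = ST.bootstrap_compare(table, n_reps=500, seed=3)
        assert a.p_one_tailed == c.p_one_tailed

    def test_null_rejection_is_anticonservative(self):
        # comparing the full-sample gap coefficient against the bootstrap
        # distribution of the PMA coefficient is a point-vs-CI test; under
        # equal true associations with independent predictors its one-sided
        # rejection rate is Phi(-1.645/sqrt(2)) ~ 0.12, not the nominal 0.05
        rej = 0
        n_sims = 60
        for s in range(n_sims):
            r = np.random.default_rng(70_000 + s)
            n = 150
            x1, x2 = r.normal(0, 0.9, (2, n))
            y = 1.0 - 0.2 * x1 - 0.2 * x2 + 0.3 * r.standard_normal(n)
            tab = pd.DataFrame({
                "infant_id": np.repeat([f"i{k}" for k in range(n // 2)], 2),
                "pma_weeks": 34 + x1, "corrected_gap": x2, "apnoea_rate": y,
                "resp_rate": 55 + r.normal(0, 1, n),
                "ip_length_h": r.uniform(2, 12, n),
                "infection": r.choice(["no", "suspected", "treated"], n)})
            res = ST.bootstrap_compare(tab, n_reps=250, seed=s)
            rej += res.p_one_tailed < 0.05
        assert 0.06 <= rej / n_sims <= 0.25

    def test_cluster_bootstrap_runs(self, rng):
        table = _table(rng, n=80)
        res = ST.bootstrap_compare(table, n_reps=200, seed=4, cluster=True)
        assert 0.0 <= res.p_one_tailed <= 1.0


class TestEvalue:
    def test_null_gives_one(self):
        assert ST.evalue(1.0).e_point == 1.0

    def test_closed_form_at_two(self):
        assert ST.evalue(2.0).e_point == pytest.approx(2.0 + np.sqrt(2.0),
                                                       abs=1e-12)

    @given(st.floats(1.01, 50.0), st.floats(1.01, 50.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_reciprocal_symmetric(self, a, b):
        lo, hi = sorted([a, b])
        assert ST.evalue(hi).e_point >= ST.evalue(lo).e_point
        assert ST.evalue(1.0 / a).e_point == pytest.approx(
            ST.evalue(a).e_point, rel=1e-9)

    def test_ci_crossing_null_gives_one(self):
        assert ST.evalue(2.0, ci_limit_rr=1.0).e_ci == 1.0
        assert ST.evalue(2.0, ci_limit_rr=0.8).e_ci == 1.0
        assert ST.evalue(0.5, ci_limit_rr=1.2).e_ci == 1.0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            ST.evalue(0.0)
        with pytest.raises(ValueError):
            ST.evalue(-2.0)

    def test_rho_conversion_monotone(self):
        rrs = [ST.rho_to_rr(r) for r in (-0.5, -0.19, 0.0, 0.19, 0.5)]
        assert all(np.diff(rrs) > 0)
        assert ST.rho_to_rr(0.0) == pytest.approx(1.0)


class TestCaffeineStop:
    def _subset(self, rng, n=27, slope=-0.26, noise=1.0):
        gap = rng.normal(0, 0.9, n)
        stop = 34.0 + slope * gap + noise * rng.standard_normal(n)
        return pd.DataFrame({
            "caffeine_stop_pma_weeks": stop, "corrected_gap": gap,
            "infection": rng.choice(["no", "suspected", "treated"], n)})

    def test_recovery_coverage(self):
        covered = 0
        for s in range(40):
            rng = np.random.default_rng(500 + s)
            fr = ST.caffeine_stop_regression(self._subset(rng))
            covered += fr.ci_low <= -0.26 <= fr.ci_high
        assert covered / 40 >= 0.90

    def test_orthogonal_gap_gives_null_slope(self, rng):
        sub = self._subset(rng, n=400, slope=0.0, noise=0.5)
        fr = ST.caffeine_stop_regression(sub)
        assert abs(fr.beta) < 0.15

    def test_default_subset_size_runs(self, rng):
        fr = ST.caffeine_stop_regression(self._subset(rng, n=27))
        assert np.isfinite([fr.beta, fr.ci_low, fr.ci_high, fr.p_value]).all()
        assert fr.n == 27

    def test_too_small_subset_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            ST.caffeine_stop_regression(self._subset(rng, n=4))


class TestPostCaffeineGroups:
    def _vitals(self, rng, ratio=2.0, n=17):
        gap = np.concatenate([rng.uniform(0.1, 1.5, n // 2 + 1),
                              rng.uniform(-1.5, -0.1, n - n // 2 - 1)])
        apnoea = np.where(gap > 0, 0.5, 0.5 * ratio) \
            + 0.02 * rng.standard_normal(n)
        desat = np.where(gap > 0, 0.25, 0.25 * ratio) \
            + 0.02 * rng.standard_normal(n)
        apnoea[:3] = np.nan                # some infants had no IP monitoring
        return pd.DataFrame({"corrected_gap": gap, "apnoea_rate": apnoea,
                             "desat_rate": desat})

    def test_zero_rates_give_zero_means(self):
        df = pd.DataFrame({"corrected_gap": [-1.0, -0.5, 0.5, 1.0],
                           "apnoea_rate": [0.0] * 4, "desat_rate": [0.0] * 4})
        out = ST.post_caffeine_group_rates(df)
        assert out["apnoea_rate"].mature_mean == 0.0
        assert out["apnoea_rate"].immature_mean == 0.0

    def test_rate_ratio_recovered(self, rng):
        out = ST.post_caffeine_group_rates(self._vitals(rng, ratio=2.0))
        gc = out["apnoea_rate"]
        assert gc.immature_mean / gc.mature_mean == pytest.approx(2.0,
                                                                  rel=0.15)

    def test_group_sizes_reported_per_outcome(self, rng):
        df = self._vitals(rng)
        out = ST.post_caffeine_group_rates(df)
        n_apnoea = out["apnoea_rate"].n_mature + out["apnoea_rate"].n_immature
        n_desat = out["desat_rate"].n_mature + out["desat_rate"].n_immature
        assert n_desat == len(df)
        assert n_apnoea == len(df) - 3

    @pytest.mark.parametrize("mature, immature, expected", [
        (0.41, 1.02, 60),
        (0.26, 0.45, 42),
        (0.7, 0.7, 0),
    ])
    def test_percent_reduction(self, mature, immature, expected):
        assert ST.percent_reduction(mature, immature) == expected

    def test_percent_reduction_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ST.percent_reduction(0.4, 0.0)


class TestQQ:
    def test_quantile_table_shape(self, rng):
        df = ST.qq_diagnostics(rng.normal(size=50))
        assert list(df.columns) == ["theoretical", "sample"]
        assert (df["sample"].diff().dropna() >= 0).all()
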