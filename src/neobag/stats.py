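"""Association models, bootstrap comparison, E-values and group summaries.

Four linear mixed-effects models relate the respiratory outcomes
(apnoea rate, respiratory rate) to postmenstrual age (PMA) and to the
bias-corrected brain-age gap.  Each model includes infection status
("no"/"suspected"/"treated") as a fixed factor, IP data length as an
additional fixed factor for the apnoea-rate models, and a random
intercept per infant for the repeated test occasions.

Partial correlation coefficients are computed residual-on-residual: the
outcome and the predictor are each regressed (OLS, occasion level) on
the fixed covariates, and the Pearson correlation of the two residual
vectors is reported with a Fisher-z confidence interval.

To compare predictors, the partial correlation between apnoea rate and
PMA is bootstrapped (10,000 occasion resamples); the one-tailed p-value
is the proportion of bootstrap coefficients at or below the observed
partial correlation between apnoea rate and gap.

E-values quantify how strong an unmeasured confounder would have to be
(on the risk-ratio scale, with both exposure and outcome) to explain an
observed association away: E = RR + sqrt(RR (RR - 1)) after mapping
RR < 1 to its reciprocal; the confidence-interval E-value uses the CI
limit closest to the null and is 1 when the CI crosses the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as spstats

logger = logging.getLogger(__name__)

INFECTION_LEVELS = ("no", "suspected", "treated")
APNOEA_RATE, RESP_RATE = "apnoea_rate", "resp_rate"
PMA, GAP = "pma_weeks", "corrected_gap"


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Slope, CI, p and partial correlation of one association model."""

    response: str
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    partial_rho: float
    rho_ci_low: float
    rho_ci_high: float
    n: int
    model: str = "mixedlm"

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must contain the slope")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class BootstrapResult:
    n_reps: int
    rho_gap: float
    rho_pma: float
    p_one_tailed: float
    ci_low: float            # lower bound of the one-tailed 95% interval
    ci_high: float
    n_degenerate_redraws: int
    samples: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class EValueResult:
    rr: float                # input effect mapped to the >= 1 scale
    e_point: float
    e_ci: float

    def __post_init__(self):
        if self.e_point < 1 or self.e_ci < 1:
            raise ValueError("E-values are at least 1")


@dataclass(frozen=True)
class GroupComparison:
    """Post-caffeine apnoea/desaturation rates by maturity group."""

    outcome: str
    mature_mean: float
    mature_sd: float
    n_mature: int
    immature_mean: float
    immature_sd: float
    n_immature: int

    @property
    def available(self) -> bool:
        return self.n_mature > 0 and self.n_immature > 0


# ---------------------------------------------------------------------------
# partial correlation machinery
# ---------------------------------------------------------------------------

def _covariate_matrix(table: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(table))]
    for cov in covariates:
        if cov == "infection":
            for level in INFECTION_LEVELS[1:]:
                cols.append((table["infection"] == level).to_numpy(float))
        else:
            cols.append(table[cov].to_numpy(float))
    return np.column_stack(cols)


def _residualise(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(z, y, rcond=None)
    return y - z @ beta


def partial_correlation(x, y, covariates: np.ndarray | None = None
                        ) -> tuple[float, tuple[float, float]]:
    """Correlation of x and y after adjusting both for covariates.

    With no covariates this reduces to the plain Pearson correlation.
    The CI is Fisher-z based with n - k - 3 effective degrees of freedom
    (k adjusted covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = 0
    if covariates is not None:
        x = _residualise(x, covariates)
        y = _residualise(y, covariates)
        k = covariates.shape[1] - 1
    rho = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    se = 1.0 / np.sqrt(max(n - k - 3, 1))
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return rho, (float(lo), float(hi))


def _model_covariates(response: str) -> list[str]:
    # data length only enters the apnoea-rate models; infection enters all
    covs = ["infection"]
    if response == APNOEA_RATE:
        covs.append("ip_length_h")
    return covs


# ---------------------------------------------------------------------------
# mixed-effects association models
# ---------------------------------------------------------------------------

def fit_association(table: pd.DataFrame, response: str,
                    predictor: str) -> FitResult:
    """Linear mixed model of a respiratory outcome on PMA or gap.

    Random intercept per infant; fixed covariates per
    :func:`_model_covariates`.  Returns slope, Wald 95% CI, p-value and
    the covariate-adjusted partial correlation.
    """
    if response not in (APNOEA_RATE, RESP_RATE):
        raise ValueError(f"unknown response {response!r}")
    if predictor not in (PMA, GAP):
        raise ValueError(f"unknown predictor {predictor!r}")
    if np.ptp(table[response].to_numpy(float)) == 0:
        raise ValueError(f"singular design: response {response!r} is constant")
    if np.ptp(table[predictor].to_numpy(float)) == 0:
        raise ValueError(f"singular design: predictor {predictor!r} is constant")
    covs = _model_covariates(response)
    terms = [predictor] + ["C(infection)" if c == "infection" else c for c in covs]
    formula = f"{response} ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, table, groups=table["infant_id"])
        try:
            try:
                res = model.fit(reml=True)
            except np.linalg.LinAlgError:
                res = model.fit(reml=True, method="powell")
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular design for {formula!r}") from err
    beta = float(res.params[predictor])
    ci = res.conf_int().loc[predictor]
    p = float(res.pvalues[predictor])
    z = _covariate_matrix(table, covs)
    rho, rho_ci = partial_correlation(table[response], table[predictor], z)
    return FitResult(response=response, predictor=predictor, beta=beta,
                     ci_low=float(ci[0]), ci_high=float(ci[1]),
                     p_value=min(max(p, 0.0), 1.0), partial_rho=rho,
                     rho_ci_low=rho_ci[0], rho_ci_high=rho_ci[1],
                     n=len(table))


# ---------------------------------------------------------------------------
# bootstrap comparison of the two predictors
# ---------------------------------------------------------------------------

def bootstrap_compare(table: pd.DataFrame, n_reps: int = 10_000,
                      seed: int = 0, cluster: bool = False) -> BootstrapResult:
    """Is apnoea rate better associated with gap than with PMA?

    The partial correlation between apnoea rate and PMA is bootstrapped
    by resampling test occasions with replacement; the one-tailed
    p-value is the proportion of bootstrap coefficients less than or
    equal to the observed partial correlation between apnoea rate and
    gap.  ``cluster=True`` resamples infants (all their occasions)
    instead of individual occasions.  Degenerate resamples (constant
    predictor or outcome) are redrawn and counted.
    """
    covs = _model_covariates(APNOEA_RATE)
    z = _covariate_matrix(table, covs)
    y = table[APNOEA_RATE].to_numpy(float)
    x_pma = table[PMA].to_numpy(float)
    x_gap = table[GAP].to_numpy(float)
    for name, arr in ((APNOEA_RATE, y), (PMA, x_pma), (GAP, x_gap)):
        if np.ptp(arr) == 0:
            raise ValueError(f"degenerate column {name!r} (constant)")
    rho_gap, _ = partial_correlation(y, x_gap, z)
    rho_pma, _ = partial_correlation(y, x_pma, z)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xb007]))
    n = len(table)
    infants = table["infant_id"].to_numpy()
    unique_infants = np.unique(infants)
    samples = np.empty(n_reps)
    redraws = 0
    i = 0
    while i < n_reps:
        if cluster:
            chosen = rng.choice(unique_infants, size=len(unique_infants))
            idx = np.concatenate([np.flatnonzero(infants == c) for c in chosen])
        else:
            idx = rng.integers(0, n, size=n)
        yb, xb, zb = y[idx], x_pma[idx], z[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            redraws += 1
            continue
        ry = _residualise(yb, zb)
        rx = _residualise(xb, zb)
        denom = np.std(ry) * np.std(rx)
        if denom == 0:
            redraws += 1
            continue
        samples[i] = np.mean((ry - ry.mean()) * (rx - rx.mean())) / denom
        i += 1
    p = float(np.mean(samples <= rho_gap))
    ci_low = float(np.percentile(samples, 5.0))
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    return BootstrapResult(n_reps=n_reps, rho_gap=rho_gap, rho_pma=rho_pma,
                           p_one_tailed=p, ci_low=ci_low, ci_high=1.0,
                           n_degenerate_redraws=redraws, samples=samples)


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------

def evalue(effect_rr: float, ci_limit_rr: float | None = None) -> EValueResult:
    """E-value of an effect on the risk-ratio scale.

    Effects below 1 are mapped to their reciprocal first.  The CI
    E-value uses the limit closest to the null; a CI that crosses the
    null yields an E-value of exactly 1.
    """
    if effect_rr <= 0:
        raise ValueError("risk ratios must be positive")
    flip = effect_rr < 1.0
    rr = 1.0 / effect_rr if flip else effect_rr
    e_point = 1.0 if rr == 1.0 else rr + np.sqrt(rr * (rr - 1.0))
    if ci_limit_rr is None:
        e_ci = 1.0
    else:
        if ci_limit_rr <= 0:
            raise ValueError("risk ratios must be positive")
        ci = 1.0 / ci_limit_rr if flip else ci_limit_rr
        e_ci = 1.0 if ci <= 1.0 else ci + np.sqrt(ci * (ci - 1.0))
    return EValueResult(rr=float(rr), e_point=float(e_point), e_ci=float(e_ci))


def rho_to_rr(rho: float) -> float:
    """Approximate risk ratio for a partial correlation.

    Route: standardised mean difference d = 2 rho / sqrt(1 - rho^2),
    then RR ~= exp(0.91 d).  This is one of several published
    conversions; it is provided for sensitivity analysis, not as a
    reproduction of any specific calculator.
    """
    if not -1 < rho < 1:
        raise ValueError("correlation must lie strictly inside (-1, 1)")
    d = 2.0 * rho / np.sqrt(1.0 - rho ** 2)
    return float(np.exp(0.91 * d))


# ---------------------------------------------------------------------------
# caffeine analyses
# ---------------------------------------------------------------------------

def caffeine_stop_regression(subset: pd.DataFrame) -> FitResult:
    """OLS of caffeine-stop PMA on the gap measured shortly before stop.

    ``subset`` holds one row per infant whose brain-age gap was assessed
    within two weeks before caffeine discontinuation, with columns
    ``caffeine_stop_pma_weeks``, ``corrected_gap`` and ``infection``.
    Infection is the only fixed covariate (no data-length term: the EEG
    analysis window is fixed).
    """
    if len(subset) < 5:
        raise ValueError(
            f"caffeine-stop regression needs at least 5 infants, got {len(subset)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.ols("caffeine_stop_pma_weeks ~ corrected_gap + C(infection)",
                      subset).fit()
    beta = float(res.params["corrected_gap"])
    ci = res.conf_int().loc["corrected_gap"]
    z = _covariate_matrix(subset, ["infection"])
    rho, rho_ci = partial_correlation(subset["caffeine_stop_pma_weeks"],
                                      subset["corrected_gap"], z)
    return FitResult(response="caffeine_stop_pma_weeks",
                     predictor="corrected_gap", beta=beta,
                     ci_low=float(ci[0]), ci_high=float(ci[1]),
                     p_value=float(res.pvalues["corrected_gap"]),
                     partial_rho=rho, rho_ci_low=rho_ci[0],
                     rho_ci_high=rho_ci[1], n=len(subset), model="ols")


def post_caffeine_group_rates(vitals: pd.DataFrame) -> dict[str, GroupComparison]:
    """Mean +/- SD apnoea and desaturation rates by maturity group.

    ``vitals`` holds one row per infant with the gap measured before
    caffeine stop (column ``corrected_gap``) and the rates measured over
    the 7 days after discontinuation (``apnoea_rate``, ``desat_rate``;
    NaN where the corresponding signal was not monitored).  Group sizes
    are reported separately per outcome.  No hypothesis test is applied.
    """
    mature = vitals["corrected_gap"].to_numpy(float) > 0
    out = {}
    for outcome in (APNOEA_RATE, "desat_rate"):
        x = vitals[outcome].to_numpy(float)
        ok = np.isfinite(x)
        xm, xi = x[ok & mature], x[ok & ~mature]
        out[outcome] = GroupComparison(
            outcome=outcome,
            mature_mean=float(np.mean(xm)) if xm.size else float("nan"),
            mature_sd=float(np.std(xm, ddof=1)) if xm.size > 1 else float("nan"),
            n_mature=int(xm.size),
            immature_mean=float(np.mean(xi)) if xi.size else float("nan"),
            immature_sd=float(np.std(xi, ddof=1)) if xi.size > 1 else float("nan"),
            n_immature=int(xi.size))
    return out


def percent_reduction(mean_mature: float, mean_immature: float) -> int:
    """Percent fewer events in the mature group, to the nearest percent."""
    if mean_immature <= 0:
        raise ValueError("immature-group mean must be positive")
    return int(round(100.0 * (1.0 - mean_mature / mean_immature)))


def qq_diagnostics(residuals) -> pd.DataFrame:
    """Theoretical vs sample quantiles for a residual normality check."""
    r = np.sort(np.asarray(residuals, dtype=float))
    n = len(r)
    probs = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"theoretical": spstats.norm.ppf(probs), "sample": r})
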