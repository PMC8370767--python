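"""Extreme limiting-dilution analysis under the single-hit Poisson model.

A well receiving dose d cells is negative (no sphere) with probability
exp(-f*d), where f is the frequency of sphere-forming cells. Negative-well
counts at each dose are binomial, and the maximum-likelihood estimate of f
comes from a binomial GLM for the positive-well indicator with a
complementary log-log link and offset ln(d): the intercept is ln f. The
95% confidence interval is Wald on ln f, reported on the "1 in N" scale
(N = 1/f). Group differences are tested by a likelihood-ratio chi-square
between a pooled single-frequency fit and per-group fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats


@dataclass
class LDAFit:
    """Single-hit fit: frequency f (active cells per plated cell), so the
    conventional report '1 in N' has N = 1/f."""

    frequency: float
    n: float  # 1/f
    ci_low: float  # lower bound on N (from the upper bound on f)
    ci_high: float
    loglik: float
    boundary: bool = False
    group: str | None = None

    def as_dict(self) -> dict:
        return {
            "frequency": self.frequency,
            "one_in_n": self.n,
            "ci_low_n": self.ci_low,
            "ci_high_n": self.ci_high,
            "loglik": self.loglik,
            "boundary": self.boundary,
            "group": self.group,
        }


def _validate(data: pd.DataFrame) -> pd.DataFrame:
    d = data.copy()
    for col in ("dose", "tested", "positive"):
        if col not in d.columns:
            raise ValueError(f"LDA data lacks column {col!r}")
    if (d["dose"] <= 0).any():
        raise ValueError("doses must be positive")
    if ((d["positive"] < 0) | (d["positive"] > d["tested"])).any():
        raise ValueError("positive well counts must lie in [0, tested]")
    if (d["tested"] < 1).any():
        raise ValueError("tested well counts must be >= 1")
    return d


def _loglik(log_f: float, dose: np.ndarray, tested: np.ndarray, positive: np.ndarray) -> float:
    f = np.exp(log_f)
    p_neg = np.exp(-f * dose)
    neg = tested - positive
    with np.errstate(divide="ignore"):
        ll = neg * (-f * dose) + positive * np.log1p(-p_neg)
    return float(np.sum(np.where(positive > 0, ll, neg * (-f * dose))))


def fit_single_hit(data: pd.DataFrame, group: str | None = None) -> LDAFit:
    """Maximum-likelihood single-hit fit for one group's well counts.

    Uses a binomial GLM (cloglog link, offset ln dose); the single-dose
    closed form f = -ln(neg/tested)/d initializes the fit and is the exact
    solution when only one distinct dose is informative. All-negative data
    give the boundary result f = 0 (N = infinite, flagged); all-positive
    data leave f unbounded above and raise.
    """
    d = _validate(data)
    dose = d["dose"].to_numpy(dtype=float)
    tested = d["tested"].to_numpy(dtype=float)
    positive = d["positive"].to_numpy(dtype=float)
    if np.all(positive == tested):
        raise ValueError("all wells positive at every dose: frequency unbounded")
    if np.all(positive == 0):
        return LDAFit(0.0, float("inf"), float("nan"), float("nan"),
                      loglik=0.0, boundary=True, group=group)

    # closed-form initializer from the pooled fraction negative
    frac_neg = np.clip((tested - positive).sum() / tested.sum(), 1e-12, 1 - 1e-12)
    init = np.log(-np.log(frac_neg) / np.average(dose, weights=tested))

    endog = np.column_stack([positive, tested - positive])
    model = sm.GLM(endog, np.ones((len(d), 1)),
                   family=sm.families.Binomial(link=sm.families.links.CLogLog()),
                   offset=np.log(dose))
    try:
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(start_params=[init], maxiter=200, tol=1e-10)
        log_f = float(res.params[0])
        se = float(res.bse[0])
        converged = np.isfinite(log_f) and np.isfinite(se)
    except Exception:
        converged = False
    if not converged:
        # concave 1-d log-likelihood: bracket the score root by bisection
        def nll(lf: float) -> float:
            return -_loglik(lf, dose, tested, positive)

        r = optimize.minimize_scalar(nll, bounds=(init - 20, init + 20), method="bounded",
                                     options={"xatol": 1e-12})
        log_f = float(r.x)
        h = 1e-5
        d2 = (nll(log_f + h) - 2 * nll(log_f) + nll(log_f - h)) / h**2
        se = float(1.0 / np.sqrt(max(d2, 1e-300)))
    f = float(np.exp(log_f))
    z = stats.norm.ppf(0.975)
    ci_low_n = float(np.exp(-(log_f + z * se)))  # upper bound on f -> lower on N
    ci_high_n = float(np.exp(-(log_f - z * se)))
    return LDAFit(f, 1.0 / f, ci_low_n, ci_high_n,
                  loglik=_loglik(log_f, dose, tested, positive), group=group)


def single_dose_frequency(dose: float, tested: int, positive: int) -> float:
    """Closed-form single-dose MLE: f = -ln(negative fraction)/dose."""
    if positive == 0:
        return 0.0
    if positive == tested:
        raise ValueError("all wells positive: frequency unbounded")
    return float(-np.log((tested - positive) / tested) / dose)


def compare_groups(data: pd.DataFrame) -> dict:
    """Likelihood-ratio test of equal sphere-forming frequency across groups.

    chi_square = 2*(sum of per-group maximized log-likelihoods - pooled
    maximized log-likelihood), on (n_groups - 1) df. Returns per-group fits
    and the test. A group that cannot be fitted raises, naming it.
    """
    d = _validate(data)
    if "group" not in d.columns:
        raise ValueError("LDA data lacks a 'group' column")
    groups = sorted(map(str, d["group"].unique()))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    fits = {}
    ll_full = 0.0
    for g in groups:
        sub = d[d["group"].astype(str) == g]
        try:
            fit = fit_single_hit(sub, group=g)
        except ValueError as exc:
            raise ValueError(f"group {g!r} is not fittable: {exc}") from exc
        fits[g] = fit
        ll_full += fit.loglik
    pooled = fit_single_hit(d)
    chi2 = max(2.0 * (ll_full - pooled.loglik), 0.0)
    df = len(groups) - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return {"fits": fits, "chi_square": float(chi2), "df": df, "p": p,
            "pooled": pooled}
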