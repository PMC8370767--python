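"""Batch-aware moderated differential expression (MES vs non-MES).

Per gene, an ordinary least-squares fit of standardized expression on an
intercept, a two-level group indicator, and batch indicator columns gives
the group effect and residual variance. Residual variances are shrunk
toward a common prior by empirical Bayes: the prior (d0, s0^2) is a scaled
inverse-chi-square (equivalently the s2 marginally follow a scaled F), and
is estimated by method of moments on log s2 using digamma/trigamma
matching. The moderated t statistic uses the posterior variance and
d0 + df_resid degrees of freedom; p-values are BH-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DesignInfo:
    """Per-sample group (two levels) and batch assignment."""

    group: pd.Series  # sample -> {"MES", "nonMES"} (any two labels)
    batch: pd.Series  # sample -> batch id
    mes_label: str = "MES"

    def __post_init__(self) -> None:
        self.group = self.group.astype(str)
        self.batch = self.batch.astype(str)
        if not self.group.index.equals(self.batch.index):
            raise ValueError("group and batch must be indexed by the same samples")
        levels = sorted(self.group.unique())
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, got {levels}")
        if self.mes_label not in levels:
            raise ValueError(f"mes_label {self.mes_label!r} not among group levels {levels}")
        counts = self.group.value_counts()
        if counts.min() < 1:
            raise ValueError("both groups must be non-empty")

    def design_matrix(self) -> pd.DataFrame:
        """Intercept + group indicator (1 = MES) + batch dummies (first batch
        as reference). Raises on rank deficiency, naming aliased columns."""
        samples = self.group.index
        cols = {"intercept": np.ones(len(samples))}
        cols["group"] = (self.group == self.mes_label).to_numpy(dtype=float)
        batches = sorted(self.batch.unique())
        for b in batches[1:]:
            cols[f"batch_{b}"] = (self.batch == b).to_numpy(dtype=float)
        x = pd.DataFrame(cols, index=samples)
        rank = np.linalg.matrix_rank(x.to_numpy())
        if rank < x.shape[1]:
            aliased = _aliased_columns(x.to_numpy(), list(x.columns))
            raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
        return x


def _aliased_columns(x: np.ndarray, names: list[str]) -> list[str]:
    aliased, kept = [], []
    for j, name in enumerate(names):
        trial = x[:, kept + [j]]
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            aliased.append(name)
        else:
            kept.append(j)
    return aliased


def fit_gene_models(values: pd.DataFrame, design: DesignInfo) -> pd.DataFrame:
    """Per-gene OLS of expression on the design; vectorized across genes.

    Returns a DataFrame indexed by gene with columns effect (group
    coefficient), s2 (residual variance on df_resid), df_resid.
    """
    x = design.design_matrix().loc[values.columns]
    xm = x.to_numpy()
    n, p = xm.shape
    df_resid = n - p
    if df_resid < 2:
        raise ValueError(f"need >= 2 residual degrees of freedom, have {df_resid}")
    y = values.to_numpy()  # genes x samples
    pinv = np.linalg.pinv(xm)
    beta = y @ pinv.T  # genes x p
    resid = y - beta @ xm.T
    rss = np.einsum("ij,ij->i", resid, resid)
    gi = list(x.columns).index("group")
    return pd.DataFrame(
        {"effect": beta[:, gi], "s2": rss / df_resid, "df_resid": float(df_resid)},
        index=values.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton; monotone decreasing)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return float(x)


def eb_moderate(s2: np.ndarray, df_resid: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes variance moderation: estimate the scaled-inverse-
    chi-square prior (d0, s0^2) by moments of log s2, and return posterior
    variances (d0*s0^2 + df*s2) / (d0 + df).

    When the observed dispersion of log s2 does not exceed what sampling
    alone implies, d0 is infinite and the posterior collapses to the pooled
    (mean) variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("need >= 10 genes for prior estimation")
    if np.any(s2 <= 0):
        raise ValueError("all residual variances must be positive")
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, df_resid / 2.0))
    if excess <= 0:
        s0sq = float(np.mean(s2))
        return np.inf, s0sq, np.full_like(s2, s0sq)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
    return d0, s0sq, post


def moderated_test(
    fits: pd.DataFrame,
    design: DesignInfo,
    no_shrinkage: bool = False,
) -> pd.DataFrame:
    """Moderated t-test per gene with BH adjustment.

    ``no_shrinkage=True`` forces d0 = 0 (posterior variance = per-gene s2,
    ordinary t-test with df_resid). Returns columns effect, s2, df_resid,
    t_mod, p, q plus attrs d0, s0sq.
    """
    df_resid = float(fits["df_resid"].iloc[0])
    if no_shrinkage:
        d0, s0sq, post = 0.0, float("nan"), fits["s2"].to_numpy()
    else:
        d0, s0sq, post = eb_moderate(fits["s2"].to_numpy(), df_resid)
    x = design.design_matrix().to_numpy()
    xtx_inv = np.linalg.inv(x.T @ x)
    gi = list(design.design_matrix().columns).index("group")
    v_coef = xtx_inv[gi, gi]  # unscaled coefficient variance
    se = np.sqrt(post * v_coef)
    t_mod = fits["effect"].to_numpy() / se
    df_total = df_resid + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    q = multipletests(p, method="fdr_bh")[1]
    out = fits.copy()
    out["t_mod"] = t_mod
    out["p"] = p
    out["q"] = q
    out.attrs["d0"] = d0
    out.attrs["s0sq"] = s0sq
    out.attrs["df_total"] = df_total
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def make_signature(
    results: pd.DataFrame, q_threshold: float = 0.05, top_n: int = 100
) -> tuple[list[str], list[str], list[str]]:
    """Significant up/down gene lists plus a display list of the top_n genes.

    up: q < q_threshold and effect > 0; down: q < q_threshold and
    effect < 0; top_n genes ordered by q, ties by |t_mod| descending, then
    gene id.
    """
    if results.empty:
        raise ValueError("empty results table")
    sig = results["q"] < q_threshold
    up = sorted(results.index[sig & (results["effect"] > 0)])
    down = sorted(results.index[sig & (results["effect"] < 0)])
    if not up and not down:
        warnings.warn("no genes pass the q threshold; signature lists are empty")
    # stable sort + gene-id pre-sort => ties fall back to gene id
    order = (
        results.loc[results.index.sort_values()]
        .assign(_abs_t=lambda d: d["t_mod"].abs())
        .sort_values(by=["q", "_abs_t"], ascending=[True, False], kind="mergesort")
    )
    top = list(order.index[: min(top_n, len(order))])
    return up, down, top
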