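"""TF-target regulon inference by mutual information.

The default MI estimator is the Gaussian-copula (rank / normal-score)
closed form: each vector is mapped to normal scores, and for correlation r
between the scores the mutual information is -0.5*ln(1 - r^2). This is
deterministic, symmetric, invariant under strictly monotone transforms of
either input, and zero exactly at score-correlation zero. Edge
significance comes from a pooled permutation null: every TF's sample
order is permuted n_perm times, null MI values against all of that TF's
candidate targets are pooled across TFs into a single distribution, and
each observed edge gets an empirical upper-tail p-value, BH-adjusted over
all tested edges. Edges passing the FDR threshold are pruned by the data
processing inequality (DPI): in every fully connected triangle of two TFs
and a target the strictly weakest edge is removed, on the premise that an
indirect dependence is weaker than the direct ones it passes through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mesreg.diffexp import bh_adjust

_R2_CLIP = 1.0 - 1e-12


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Map a vector (or each row of a matrix) to standard normal quantiles
    of its average ranks: rank -> Phi^{-1}(rank / (n + 1))."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average", axis=-1)
    return stats.norm.ppf(ranks / (x.shape[-1] + 1))


def _unit_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(z, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant vector: ranks (and MI) undefined")
    return z / norms


def _mi_from_r(r: np.ndarray) -> np.ndarray:
    r2 = np.minimum(r * r, _R2_CLIP)
    return -0.5 * np.log1p(-r2)


def mutual_information(x: np.ndarray, y: np.ndarray, estimator: str = "normal_scores",
                       bins: int | None = None) -> float:
    """Mutual information between two sample vectors.

    ``normal_scores`` (default): -0.5*ln(1-r^2) for the correlation r of
    the normal scores, with r^2 clipped to 1 - 1e-12. ``histogram``: plug-in
    estimate on a fixed square grid (for comparison only; biased).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 8:
        raise ValueError("need >= 8 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: ranks (and MI) undefined")
    if estimator == "normal_scores":
        zx = _unit_rows(_normal_scores(x))
        zy = _unit_rows(_normal_scores(y))
        return float(_mi_from_r(np.dot(zx, zy)))
    if estimator == "histogram":
        nb = bins or max(2, int(np.sqrt(x.size / 5)))
        h, _, _ = np.histogram2d(x, y, bins=nb)
        pxy = h / h.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        nz = pxy > 0
        return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class RegulonNetwork:
    """Pruned network: per-TF regulons with MI weight and sign."""

    edges: pd.DataFrame  # columns regulator, target, mi, sign, p, q
    provenance: dict = field(default_factory=dict)

    @property
    def regulons(self) -> dict[str, pd.DataFrame]:
        return {tf: g.set_index("target") for tf, g in self.edges.groupby("regulator")}

    def regulon_targets(self, tf: str) -> set[str]:
        sub = self.edges[self.edges["regulator"] == tf]
        return set(sub["target"])

    def to_gmt_sets(self, signed: bool = False) -> dict[str, list[str]]:
        sets: dict[str, list[str]] = {}
        for tf, g in self.edges.groupby("regulator"):
            if signed:
                pos = sorted(g.loc[g["sign"] > 0, "target"])
                neg = sorted(g.loc[g["sign"] < 0, "target"])
                if pos:
                    sets[f"{tf}_pos"] = pos
                if neg:
                    sets[f"{tf}_neg"] = neg
            else:
                sets[str(tf)] = sorted(g["target"])
        return sets


def edge_pvalues(
    values: pd.DataFrame,
    tfs: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    chunk_tfs: int = 8,
) -> pd.DataFrame:
    """MI, sign and pooled-permutation p/q for every TF x non-self target.

    The null permutes each TF's sample order ``n_perm`` times and scores it
    against all of that TF's candidate targets; all null values are pooled
    into one distribution of size n_tfs * n_perm * (n_genes - 1). The
    empirical p of an edge is (1 + #{null >= observed}) / (pool + 1).
    Fully deterministic for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if values.shape[1] < 8:
        raise ValueError("need >= 8 samples for MI inference")
    genes = values.index.to_numpy(dtype=object)
    tfs = [str(t) for t in tfs]
    missing = set(tfs) - set(genes)
    if missing:
        raise ValueError(f"TFs absent from the matrix: {sorted(missing)[:5]}")
    if not tfs:
        raise ValueError("empty TF list")
    gene_pos = {g: i for i, g in enumerate(genes)}
    tf_idx = np.array([gene_pos[t] for t in tfs])
    n_genes, n = values.shape

    z = _unit_rows(_normal_scores(values.to_numpy()))  # genes x samples, unit rows

    # observed statistics (r, MI, sign) for all TF x target pairs
    r_obs = z[tf_idx] @ z.T  # n_tfs x n_genes
    self_mask = np.zeros_like(r_obs, dtype=bool)
    self_mask[np.arange(len(tfs)), tf_idx] = True
    r2_obs = np.minimum(r_obs * r_obs, _R2_CLIP)

    keep = ~self_mask
    reg_col = np.repeat(np.array(tfs, dtype=object), n_genes)[keep.ravel()]
    tgt_col = np.tile(genes, len(tfs))[keep.ravel()]
    r2_flat = r2_obs[keep]
    sign_flat = np.where(r_obs[keep] >= 0, 1, -1)

    # pooled null, streamed in chunks of TFs; MI is monotone in r^2, so all
    # counting happens on the r^2 scale. Each chunk is sorted once and the
    # observed values located by binary search (far cheaper than searching
    # each null value against the observed set).
    counts = np.zeros(r2_flat.size, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for start in range(0, len(tfs), chunk_tfs):
        idx = tf_idx[start : start + chunk_tfs]
        perms = np.empty((len(idx) * n_perm, n))
        for j, gi in enumerate(idx):
            tiled = np.tile(z[gi], (n_perm, 1))
            perms[j * n_perm : (j + 1) * n_perm] = rng.permuted(tiled, axis=1)
        null_r = perms @ z.T  # (c*n_perm) x n_genes
        null_r2 = np.minimum(null_r * null_r, _R2_CLIP)
        null_r2 = null_r2.reshape(len(idx), n_perm, n_genes)
        for j, gi in enumerate(idx):
            null_r2[j, :, gi] = -1.0  # self target: sorts below every obs >= 0
        flat = np.sort(null_r2.ravel())
        # #null >= obs = total - #null < obs; the -1 sentinels land in the
        # strictly-below part, so they never inflate the counts
        counts += flat.size - np.searchsorted(flat, r2_flat, side="left")
    pool = len(tfs) * n_perm * (n_genes - 1)
    p = (1.0 + counts) / (pool + 1.0)

    table = pd.DataFrame(
        {
            "regulator": reg_col,
            "target": tgt_col,
            "mi": -0.5 * np.log1p(-r2_flat),
            "sign": sign_flat,
            "p": p,
        }
    )
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def filter_edges(edge_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep edges with BH-adjusted p below alpha."""
    if "q" not in edge_table.columns:
        raise ValueError("edge table lacks adjusted p-values (column 'q')")
    return edge_table.loc[edge_table["q"] < alpha].reset_index(drop=True)


def dpi_prune(
    edge_table: pd.DataFrame,
    tolerance: float = 0.0,
    protect_tf_tf: bool = False,
    provenance: Mapping | None = None,
) -> RegulonNetwork:
    """Data-processing-inequality pruning of a filtered edge table.

    For every triangle {TF1-target, TF2-target, TF1-TF2} whose three edges
    are all present, the strictly weakest edge is marked for removal when
    its MI falls below (1 - tolerance) times the smaller of the other two;
    exact ties remove nothing. Marks are computed against the un-pruned
    table and applied simultaneously, so the result is order-independent
    and idempotent. By default any of the three edges may be removed;
    ``protect_tf_tf=True`` exempts TF-TF edges.
    """
    tfs = sorted(set(edge_table["regulator"]))
    tf_set = set(tfs)
    # undirected weights (TF-TF pairs appear in both directions with equal MI)
    w: dict[tuple[str, str], float] = {}
    neighbors: dict[str, set[str]] = {}
    for reg, tgt, mi in zip(edge_table["regulator"], edge_table["target"], edge_table["mi"]):
        key = (reg, tgt) if reg <= tgt else (tgt, reg)
        w[key] = mi
        neighbors.setdefault(reg, set()).add(tgt)
        neighbors.setdefault(tgt, set()).add(reg)

    marked: set[tuple[str, str]] = set()
    for i, t1 in enumerate(tfs):
        for t2 in tfs[i + 1 :]:
            pair = (t1, t2) if t1 <= t2 else (t2, t1)
            if pair not in w:
                continue
            common = (neighbors.get(t1, set()) & neighbors.get(t2, set())) - {t1, t2}
            for tgt in common:
                e12, e1t, e2t = (
                    pair,
                    (t1, tgt) if t1 <= tgt else (tgt, t1),
                    (t2, tgt) if t2 <= tgt else (tgt, t2),
                )
                tri = [(w[e12], e12), (w[e1t], e1t), (w[e2t], e2t)]
                tri.sort(key=lambda t: t[0])
                lo, mid = tri[0], tri[1]
                if lo[0] == mid[0]:
                    continue  # tie on the minimum: no removal
                if lo[0] < (1.0 - tolerance) * mid[0]:
                    if protect_tf_tf and lo[1][0] in tf_set and lo[1][1] in tf_set:
                        continue
                    marked.add(lo[1])

    def undirected(row_reg: str, row_tgt: str) -> tuple[str, str]:
        return (row_reg, row_tgt) if row_reg <= row_tgt else (row_tgt, row_reg)

    keys = [undirected(r, t) for r, t in zip(edge_table["regulator"], edge_table["target"])]
    keep_mask = np.array([k not in marked for k in keys])
    pruned = edge_table.loc[keep_mask].reset_index(drop=True)
    prov = dict(provenance or {})
    prov.update({"tolerance": tolerance, "protect_tf_tf": protect_tf_tf,
                 "n_edges_in": int(len(edge_table)), "n_edges_removed": int((~keep_mask).sum())})
    return RegulonNetwork(pruned, provenance=prov)


def infer_network(
    values: pd.DataFrame,
    tfs: Sequence[str],
    n_perm: int = 1000,
    alpha: float = 0.05,
    dpi_tolerance: float = 0.0,
    seed: int = 0,
) -> RegulonNetwork:
    """edge_pvalues -> filter_edges -> dpi_prune in one call."""
    table = edge_pvalues(values, tfs, n_perm=n_perm, seed=seed)
    kept = filter_edges(table, alpha=alpha)
    return dpi_prune(
        kept,
        tolerance=dpi_tolerance,
        provenance={"n_perm": n_perm, "alpha": alpha, "seed": seed},
    )
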