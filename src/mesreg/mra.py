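"""Master-regulator analysis: regulon vs phenotype-signature enrichment.

Two complementary statistics per TF. (1) Hypergeometric overlap between the
TF's regulon and the differential-expression signature genes, within the
universe of genes actually present in the harmonized matrix, BH-adjusted
across TFs — the primary ranking. (2) One-tail GSEA of the (unsigned)
regulon against the gene ranking by moderated t statistic, with a
size-matched resampling null giving a normalized enrichment score (NES =
ES / mean |null ES|) and an empirical p-value.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from mesreg._util import sample_index_sets
from mesreg.diffexp import bh_adjust


def hypergeom_pvalue(overlap: int, universe_size: int, signature_size: int,
                     regulon_size: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    return float(stats.hypergeom.sf(overlap - 1, universe_size, signature_size, regulon_size))


def hypergeom_mra(
    regulons: Mapping[str, set[str]],
    signature_genes: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Overlap statistics for every regulon against the signature.

    Regulons are intersected with the universe before testing; the
    signature must be a subset of the universe. Returns a DataFrame
    indexed by TF with regulon_size, overlap, universe_size, p_hyper,
    q_hyper.
    """
    if not universe:
        raise ValueError("empty universe")
    if not signature_genes:
        raise ValueError("empty signature")
    extra = set(signature_genes) - set(universe)
    if extra:
        raise ValueError(f"signature genes outside the universe: {sorted(extra)[:5]}")
    m = len(universe)
    k_sig = len(signature_genes)
    rows = []
    for tf in sorted(regulons):
        reg = set(regulons[tf]) & set(universe)
        ov = len(reg & set(signature_genes))
        p = hypergeom_pvalue(ov, m, k_sig, len(reg)) if reg else 1.0
        rows.append({"tf": tf, "regulon_size": len(reg), "overlap": ov,
                     "universe_size": m, "p_hyper": p})
    out = pd.DataFrame(rows).set_index("tf")
    out["q_hyper"] = bh_adjust(out["p_hyper"].to_numpy())
    return out


def _ordered_stats(ranked_stats: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    genes = ranked_stats.index.to_numpy(dtype=object)
    vals = ranked_stats.to_numpy(dtype=float)
    order = np.lexsort((genes, -vals))
    return genes[order], vals[order]


def gsea_es(ranked_stats: pd.Series, gene_set: set[str], weight: float = 1.0) -> float:
    """Classical weighted Kolmogorov-Smirnov enrichment score.

    Genes are ordered by decreasing statistic (ties by gene id); hits
    advance the running sum by |stat|^weight normalized over in-set genes,
    misses retreat by 1/(N - n_hits); ES is the signed maximum deviation
    from zero (the larger magnitude of the running maximum and minimum;
    an exact magnitude tie returns the positive deviation).
    """
    genes, vals = _ordered_stats(ranked_stats)
    inset = np.isin(genes, list(gene_set))
    n_in = int(inset.sum())
    if n_in == 0:
        raise ValueError("gene set shares no genes with the ranking")
    if n_in == genes.size:
        raise ValueError("gene set covers every ranked gene")
    w = np.where(inset, np.abs(vals) ** weight, 0.0)
    tot = w.sum()
    steps = (w / tot if tot > 0 else inset / n_in) - (~inset) / (genes.size - n_in)
    running = np.cumsum(steps)
    hi, lo = float(running.max()), float(running.min())
    return hi if hi >= -lo else lo


def _null_es(
    vals_sorted: np.ndarray, k: int, n_perm: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """ES of n_perm random size-k gene sets against a fixed ranking.

    The running sum rises only at hit positions and falls linearly between
    them, so its extrema are attained immediately after a hit (maximum
    candidates) or immediately before one (minimum candidates).
    """
    n = vals_sorted.size
    wa = np.abs(vals_sorted) ** weight
    pos = np.sort(sample_index_sets(rng, n, k, n_perm), axis=1)  # (B, k) ascending
    w_hit = wa[pos]
    wsum = w_hit.sum(axis=1, keepdims=True)
    uniform = np.full_like(w_hit, 1.0 / k)
    wnorm = np.where(wsum > 0, w_hit / np.where(wsum > 0, wsum, 1.0), uniform)
    cum = np.cumsum(wnorm, axis=1)  # running sum just after each hit, hit part
    j = np.arange(k)
    n_miss = n - k
    after_hit = cum - (pos + 1 - (j + 1)) / n_miss  # misses so far = pos+1-(j+1)
    before_hit = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - (pos - j) / n_miss
    hi = after_hit.max(axis=1)
    lo = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def regulon_gsea_1t(
    regulon: set[str],
    ranked_stats: pd.Series,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float, float] | None:
    """One-tail GSEA of an unsigned regulon against the DE ranking.

    Returns (es, nes, p_gsea) with NES = ES / mean(|null ES|) and
    p = (1 + #{|null ES| >= |ES|}) / (n_perm + 1), the null being
    size-matched random gene sets. Regulons with fewer than 3 genes in the
    ranking are skipped (returns None) with a warning.
    """
    present = set(regulon) & set(ranked_stats.index)
    if len(present) < 3:
        warnings.warn(f"regulon has {len(present)} genes in the ranking; skipped")
        return None
    es = gsea_es(ranked_stats, present, weight=weight)
    rng = np.random.default_rng(seed)
    _, vals_sorted = _ordered_stats(ranked_stats)
    null = _null_es(vals_sorted, len(present), n_perm, weight, rng)
    denom = float(np.mean(np.abs(null)))
    nes = es / denom if denom > 0 else float("nan")
    p = float((1 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1))
    return es, nes, p


def rank_mrs(mr_table: pd.DataFrame, alpha: float = 1e-4) -> tuple[list[str], list[str]]:
    """Order TFs by adjusted hypergeometric p and slice the significant top.

    Sort key: q_hyper ascending, then p_hyper, then |nes| descending (0
    when absent), then TF id. Returns (ordered TFs, those with q < alpha).
    """
    if "q_hyper" not in mr_table.columns:
        raise ValueError("mr_table lacks q_hyper")
    t = mr_table.copy()
    t["_absnes"] = t["nes"].abs().fillna(0.0) if "nes" in t.columns else 0.0
    t["_tf"] = t.index.astype(str)
    t = t.sort_values(by=["q_hyper", "p_hyper", "_absnes", "_tf"],
                      ascending=[True, True, False, True], kind="mergesort")
    ordered = list(t.index)
    top = list(t.index[t["q_hyper"] < alpha])
    return ordered, top


def run_mra(
    network,
    de_results: pd.DataFrame,
    signature_genes: set[str] | None = None,
    universe: set[str] | None = None,
    q_threshold: float = 0.05,
    n_gsea: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full MRA over an inferred network and a DE table.

    ``signature_genes`` defaults to the union of up- and down-regulated
    genes at q < q_threshold; the universe defaults to the DE table's
    genes. One-tail regulon GSEA (against the moderated-t ranking) is run
    for the ``n_gsea`` TFs with smallest q_hyper. Also reports
    per-direction overlaps (overlap_up / overlap_down).
    """
    universe = set(universe) if universe is not None else set(de_results.index)
    up = set(de_results.index[(de_results["q"] < q_threshold) & (de_results["effect"] > 0)])
    down = set(de_results.index[(de_results["q"] < q_threshold) & (de_results["effect"] < 0)])
    if signature_genes is None:
        signature_genes = up | down
    regulons = {tf: network.regulon_targets(tf) for tf in
                sorted(set(network.edges["regulator"]))}
    table = hypergeom_mra(regulons, signature_genes & universe, universe)
    table["overlap_up"] = [len((regulons[tf] & universe) & up) for tf in table.index]
    table["overlap_down"] = [len((regulons[tf] & universe) & down) for tf in table.index]

    ranked = de_results["t_mod"].astype(float)
    table["es"] = np.nan
    table["nes"] = np.nan
    table["p_gsea"] = np.nan
    prelim = table.sort_values(by=["q_hyper", "p_hyper"], kind="mergesort")
    root = np.random.SeedSequence(seed)
    children = root.spawn(min(n_gsea, len(prelim)))
    for child, tf in zip(children, prelim.index[:n_gsea]):
        res = regulon_gsea_1t(regulons[tf] & universe, ranked, n_perm=n_perm, seed=child)
        if res is not None:
            table.loc[tf, ["es", "nes", "p_gsea"]] = res
    return table
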