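"""Single-sample GSEA (ssGSEA) subtype scoring and resampling classification.

Each sample is scored against subtype signatures using the within-sample
gene ranking only, so scores are invariant to any strictly monotone
transform of the expression profile. Classification resamples size-matched
random gene sets to build an empirical null per signature ("equivalent
distribution resampling"); a sample's label is the signature with the
smallest empirical p-value. Concordance filtering retains samples on which
two classification schemes (e.g. MES/PN/CL and DEV/INJ) agree under a
declared label mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mesreg._util import sample_index_sets


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    @classmethod
    def from_list(cls, name: str, genes: Sequence[str]) -> "GeneSignature":
        return cls(name, frozenset(map(str, genes)))


@dataclass
class SubtypeCall:
    sample_id: str
    scores: dict[str, float]
    pvalues: dict[str, float]
    label: str


def _rank_profile(profile: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Return (gene ids, values) ordered by decreasing value, ties broken
    lexicographically by gene id (ascending) for determinism."""
    genes = profile.index.to_numpy(dtype=object)
    vals = profile.to_numpy(dtype=float)
    order = np.lexsort((genes, -vals))
    return genes[order], vals[order]


def _rank_statistic(n: int) -> np.ndarray:
    """Rank statistic per ranked position: N for the best gene down to 1."""
    return np.arange(n, 0, -1, dtype=float)


def ssgsea_score(
    profile: pd.Series, signature: GeneSignature, weight_exponent: float = 0.25
) -> float:
    """ssGSEA enrichment score of one signature in one sample.

    Genes are ranked by decreasing value; the score is the sum over ranked
    positions of (in-set weighted cumulative fraction - out-of-set uniform
    cumulative fraction). In-set weights are the rank statistic (N for the
    top-ranked gene down to 1) raised to weight_exponent, normalized to sum
    to 1 over in-set genes. Being purely rank-based, the score is invariant
    to strictly monotone transforms of the profile.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    if profile.size < 2:
        raise ValueError("profile needs >= 2 genes")
    genes, _ = _rank_profile(profile)
    inset = np.isin(genes, list(signature.genes))
    n_in = int(inset.sum())
    if n_in == 0:
        raise ValueError(f"signature {signature.name!r} shares no genes with the profile")
    if n_in == genes.size:
        raise ValueError(f"signature {signature.name!r} covers every profile gene")
    w = np.where(inset, _rank_statistic(genes.size) ** weight_exponent, 0.0)
    tot = w.sum()
    if tot == 0.0:
        w = inset / n_in
    else:
        w = w / tot
    cdf_in = np.cumsum(w)
    cdf_out = np.cumsum(~inset) / (genes.size - n_in)
    return float(np.sum(cdf_in - cdf_out))


def _scores_from_hit_positions(
    positions: np.ndarray, weights_at_rank: np.ndarray, n_genes: int
) -> np.ndarray:
    """Vectorized ssGSEA scores for many hit-position sets at once.

    ``positions``: (B, k) 0-based positions in the ranked profile;
    ``weights_at_rank``: (N,) |value|^exponent per ranked position.
    Uses the identity score = sum_j w_j (N - p_j) - [T - sum_j (N - p_j)]
    / n_out with T = N(N+1)/2, which follows from exchanging the order of
    the two cumulative sums. Rows whose weights all vanish fall back to
    uniform in-set weights, matching ssgsea_score.
    """
    b, k = positions.shape
    tail = n_genes - positions  # N - p_j, (B, k)
    wa = weights_at_rank[positions]
    wsum = wa.sum(axis=1, keepdims=True)
    uniform = np.full_like(wa, 1.0 / k)
    with np.errstate(invalid="ignore", divide="ignore"):
        wnorm = np.where(wsum > 0, wa / np.where(wsum > 0, wsum, 1.0), uniform)
    t_all = n_genes * (n_genes + 1) / 2.0
    in_part = (wnorm * tail).sum(axis=1)
    out_part = (t_all - tail.sum(axis=1)) / (n_genes - k)
    return in_part - out_part


def classify_sample(
    profile: pd.Series,
    signatures: Sequence[GeneSignature],
    n_perm: int = 1000,
    weight_exponent: float = 0.25,
    seed: int | np.random.SeedSequence = 0,
) -> SubtypeCall:
    """Score all signatures and attach empirical p-values by resampling.

    For each signature, n_perm size-matched gene sets are drawn uniformly
    without replacement from the profile's genes; the empirical p-value is
    (1 + #{null score >= observed}) / (n_perm + 1). The label is the
    signature with minimal p; ties go to the larger observed score, then
    signature order.
    """
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures to classify")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes, _ = _rank_profile(profile)
    n = genes.size
    weights_at_rank = _rank_statistic(n) ** weight_exponent

    scores: dict[str, float] = {}
    pvalues: dict[str, float] = {}
    null_cache: dict[int, np.ndarray] = {}
    for sig in signatures:
        obs = ssgsea_score(profile, sig, weight_exponent)
        k = len(sig.genes & set(genes))
        if k not in null_cache:
            pos = sample_index_sets(rng, n, k, n_perm)
            null_cache[k] = _scores_from_hit_positions(pos, weights_at_rank, n)
        null = null_cache[k]
        scores[sig.name] = obs
        pvalues[sig.name] = float((1 + np.sum(null >= obs)) / (n_perm + 1))

    names = [s.name for s in signatures]
    # argmin p; ties -> larger observed score, then signature order
    best = min(range(len(names)), key=lambda i: (pvalues[names[i]], -scores[names[i]], i))
    return SubtypeCall(str(profile.name), scores, pvalues, names[best])


def classify_matrix(
    values: pd.DataFrame,
    signatures: Sequence[GeneSignature],
    n_perm: int = 1000,
    weight_exponent: float = 0.25,
    seed: int = 0,
) -> list[SubtypeCall]:
    """Classify every column (sample) of a gene-by-sample matrix.

    Per-sample RNG streams are spawned from one SeedSequence so results do
    not depend on processing order.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(values.shape[1])
    calls = []
    for child, sample in zip(children, values.columns):
        profile = values[sample]
        profile.name = sample
        calls.append(classify_sample(profile, signatures, n_perm, weight_exponent, child))
    return calls


def calls_to_frame(calls: Sequence[SubtypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row: dict[str, object] = {"sample": c.sample_id, "label": c.label}
        for name, s in c.scores.items():
            row[f"score_{name}"] = s
        for name, p in c.pvalues.items():
            row[f"p_{name}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def concordance_filter(
    calls_a: Sequence[SubtypeCall],
    calls_b: Sequence[SubtypeCall],
    mapping: Mapping[str, set[str] | frozenset[str] | Sequence[str]],
) -> tuple[list[str], float]:
    """Retain samples whose two classifications agree under ``mapping``.

    ``mapping`` sends each scheme-A label to the set of scheme-B labels
    considered concordant (e.g. MES -> {INJ}, PN -> {DEV}, CL -> {DEV}).
    Returns (retained sample ids, concordance fraction).
    """
    by_id_b = {c.sample_id: c for c in calls_b}
    ids_a = [c.sample_id for c in calls_a]
    if set(ids_a) != set(by_id_b):
        raise ValueError("calls_a and calls_b cover different sample ids")
    retained = []
    for ca in calls_a:
        if ca.label not in mapping:
            raise ValueError(f"label {ca.label!r} missing from the concordance mapping")
        if by_id_b[ca.sample_id].label in set(mapping[ca.label]):
            retained.append(ca.sample_id)
    return retained, len(retained) / len(ids_a)
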