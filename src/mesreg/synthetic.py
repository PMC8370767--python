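"""Synthetic data with known ground truth for every pipeline stage.

The expression generator emulates the statistical structure the analysis
assumes: two latent transcriptional states (MES vs non-MES), TF-driven
co-expression modules (each planted regulon target tracks its TF up to
noise, with a random sign), background genes as independent noise, and
per-batch gene-wise affine distortions (additive shift + multiplicative
scale) standing in for platform effects. Survival times follow an
exponential model with a hazard ratio tied to a marker gene, and
limiting-dilution well counts follow the single-hit Poisson model.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mesreg import io
from mesreg.harmonize import ExpressionDataset

CONCORDANCE_MAPPING = {"MES": frozenset({"INJ"}), "NonMES": frozenset({"DEV"})}


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    subtype: dict[str, str]  # sample -> MES / NonMES
    batches: dict[str, str]  # sample -> batch id
    tf_list: list[str]
    mes_tfs: list[str]
    decoy_tfs: list[str]
    regulons: dict[str, dict[str, int]]  # tf -> {target: sign}
    effect: float
    noise_sd: float
    seed: int
    config: dict = field(default_factory=dict)

    def planted_edges(self) -> set[tuple[str, str]]:
        return {(tf, tgt) for tf, reg in self.regulons.items() for tgt in reg}

    def as_dict(self) -> dict:
        return {
            "subtype": self.subtype,
            "batches": self.batches,
            "tf_list": self.tf_list,
            "mes_tfs": self.mes_tfs,
            "decoy_tfs": self.decoy_tfs,
            "regulons": self.regulons,
            "effect": self.effect,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "config": self.config,
        }


def _noise(rng: np.random.Generator, size, sd: float, heavy_tails: bool) -> np.ndarray:
    if heavy_tails:
        return rng.standard_t(3, size=size) * sd / np.sqrt(3.0)
    return rng.normal(0.0, sd, size=size)


def gen_expression(
    n_genes: int = 2000,
    n_samples: int = 150,
    n_batches: int = 3,
    n_tfs: int = 100,
    n_mes_tfs: int = 5,
    regulon_size: int = 40,
    effect: float = 1.0,
    batch_shift: float = 1.0,
    batch_scale_sd: float = 0.2,
    noise_sd: float = 1.0,
    n_decoy_tfs: int = 10,
    heavy_tails: bool = False,
    seed: int = 0,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Multi-batch expression collection with planted subtypes and regulons.

    Half the samples (rounded down) are MES. Each of the ``n_mes_tfs``
    MES-driving TFs is shifted by ``effect`` in MES samples; each of its
    ``regulon_size`` targets equals sign * TF value + Gaussian noise of SD
    ``noise_sd``. ``n_decoy_tfs`` additional TFs carry regulons with no
    group effect; remaining TFs and background genes are independent
    noise. Per batch, every gene is distorted by an affine map
    (scale ~ logN(0, batch_scale_sd^2), shift ~ N(0, batch_shift^2)) that
    per-batch gene standardization removes exactly.
    """
    if n_mes_tfs > n_tfs or n_decoy_tfs > n_tfs - n_mes_tfs:
        raise ValueError("more regulon-bearing TFs requested than TFs available")
    n_reg_genes = (n_mes_tfs + n_decoy_tfs) * regulon_size
    if n_reg_genes + n_tfs > n_genes:
        raise ValueError(
            f"infeasible config: {n_tfs} TFs + {n_reg_genes} regulon targets "
            f"exceed {n_genes} genes"
        )
    if n_samples < 2 * n_batches:
        raise ValueError("need at least 2 samples per batch")
    rng = np.random.default_rng(seed)

    width = max(4, len(str(n_genes)))
    tf_names = [f"TF{str(i + 1).zfill(3)}" for i in range(n_tfs)]
    samples = [f"S{str(j + 1).zfill(4)}" for j in range(n_samples)]

    mes_samples = set(rng.choice(n_samples, size=n_samples // 2, replace=False).tolist())
    subtype = {s: ("MES" if j in mes_samples else "NonMES") for j, s in enumerate(samples)}
    is_mes = np.array([subtype[s] == "MES" for s in samples])

    perm = rng.permutation(n_samples)
    batch_of_idx = np.empty(n_samples, dtype=int)
    for b, chunk in enumerate(np.array_split(perm, n_batches)):
        batch_of_idx[chunk] = b
    batch_names = [f"B{b + 1}" for b in range(n_batches)]
    batches = {s: batch_names[batch_of_idx[j]] for j, s in enumerate(samples)}

    reg_tfs = rng.choice(n_tfs, size=n_mes_tfs + n_decoy_tfs, replace=False)
    mes_tfs = sorted(tf_names[i] for i in reg_tfs[:n_mes_tfs])
    decoy_tfs = sorted(tf_names[i] for i in reg_tfs[n_mes_tfs:])

    tf_vals = _noise(rng, (n_tfs, n_samples), 1.0, heavy_tails)
    for i, name in enumerate(tf_names):
        if name in mes_tfs:
            tf_vals[i] += effect * is_mes

    rows: list[np.ndarray] = [tf_vals]
    gene_names: list[str] = list(tf_names)
    regulons: dict[str, dict[str, int]] = {}
    tf_index = {name: i for i, name in enumerate(tf_names)}
    for tf in mes_tfs + decoy_tfs:
        signs = rng.choice([1, -1], size=regulon_size)
        targets = {}
        block = np.empty((regulon_size, n_samples))
        for k in range(regulon_size):
            tgt = f"TG_{tf}_{str(k + 1).zfill(2)}"
            block[k] = signs[k] * tf_vals[tf_index[tf]] + _noise(
                rng, n_samples, noise_sd, heavy_tails
            )
            targets[tgt] = int(signs[k])
        rows.append(block)
        gene_names.extend(targets)
        regulons[tf] = targets
    n_bg = n_genes - len(gene_names)
    rows.append(_noise(rng, (n_bg, n_samples), 1.0, heavy_tails))
    gene_names.extend(f"BG{str(i + 1).zfill(width)}" for i in range(n_bg))
    clean = np.vstack(rows)

    datasets = []
    for b, bname in enumerate(batch_names):
        cols = [j for j in range(n_samples) if batch_of_idx[j] == b]
        scale = np.exp(rng.normal(0.0, batch_scale_sd, size=n_genes))
        shift = rng.normal(0.0, batch_shift, size=n_genes)
        block = clean[:, cols] * scale[:, None] + shift[:, None]
        df = pd.DataFrame(block, index=gene_names, columns=[samples[j] for j in cols])
        datasets.append(ExpressionDataset(df, batch_id=bname, platform=f"synthetic-{bname}"))

    gt = GroundTruth(
        subtype=subtype,
        batches=batches,
        tf_list=tf_names,
        mes_tfs=mes_tfs,
        decoy_tfs=decoy_tfs,
        regulons=regulons,
        effect=effect,
        noise_sd=noise_sd,
        seed=seed,
        config={
            "n_genes": n_genes, "n_samples": n_samples, "n_batches": n_batches,
            "n_tfs": n_tfs, "n_mes_tfs": n_mes_tfs, "regulon_size": regulon_size,
            "batch_shift": batch_shift, "batch_scale_sd": batch_scale_sd,
            "n_decoy_tfs": n_decoy_tfs, "heavy_tails": heavy_tails,
        },
    )
    return datasets, gt


def make_subtype_signatures(
    gt: GroundTruth, size: int = 50, seed: int = 0
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Two signature schemes over the planted MES program.

    Scheme A (MES / NonMES) and scheme B (INJ / DEV) draw disjoint-ish
    random subsets from the genes planted up in MES (MES TFs and their
    positive-sign targets) and down in MES (negative-sign targets),
    mirroring two independent published classifiers that agree on truly
    polarized samples. Concordant pairs are MES<->INJ and NonMES<->DEV.
    """
    rng = np.random.default_rng(seed)
    up_pool = sorted(
        set(gt.mes_tfs)
        | {t for tf in gt.mes_tfs for t, s in gt.regulons[tf].items() if s > 0}
    )
    down_pool = sorted(
        {t for tf in gt.mes_tfs for t, s in gt.regulons[tf].items() if s < 0}
    )
    if not up_pool or not down_pool:
        raise ValueError("planted program lacks up or down genes; increase regulon size")

    def draw(pool: list[str]) -> list[str]:
        k = min(size, len(pool))
        return sorted(rng.choice(pool, size=k, replace=False).tolist())

    scheme_a = {"MES": draw(up_pool), "NonMES": draw(down_pool)}
    scheme_b = {"INJ": draw(up_pool), "DEV": draw(down_pool)}
    return scheme_a, scheme_b


def gen_survival(
    n: int = 400,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.0005,
    seed: int = 0,
    base_hazard: float = 0.001,
) -> tuple[pd.DataFrame, pd.Series]:
    """Survival records with event hazard tied to a marker gene.

    Marker values are standard normal; the upper half of samples by marker
    is the high group, whose exponential event hazard is multiplied by
    ``hazard_ratio``. Censoring is an independent exponential clock at
    ``censor_rate`` (0 disables it). Times are in days (base hazard 1e-3
    per day, i.e. a ~693-day median in the low group).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(seed)
    samples = [f"P{str(j + 1).zfill(4)}" for j in range(n)]
    marker = pd.Series(rng.normal(size=n), index=samples, name="marker")
    order = np.argsort(marker.to_numpy(), kind="stable")
    high = np.zeros(n, dtype=bool)
    high[order[n - n // 2 :]] = True
    rate = base_hazard * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    clinical = pd.DataFrame({"sample": samples, "time": time, "event": event})
    return clinical, marker


def gen_lda(
    doses: Sequence[float] = (1, 10, 100),
    wells_per_dose: int = 32,
    true_n_per_group: Mapping[str, float] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Limiting-dilution well counts under the single-hit model.

    Positive wells at dose d are Binomial(wells, 1 - exp(-d / true_N)) per
    group; ``true_N = inf`` yields all-negative wells.
    """
    if true_n_per_group is None:
        true_n_per_group = {"control": 3.0, "knockout": 28.6}
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(true_n_per_group):
        n_true = float(true_n_per_group[group])
        if n_true <= 0:
            raise ValueError("true_N must be positive")
        for d in doses:
            p_pos = 0.0 if np.isinf(n_true) else float(-np.expm1(-d / n_true))
            pos = int(rng.binomial(wells_per_dose, p_pos))
            rows.append({"dose": float(d), "tested": wells_per_dose,
                         "positive": pos, "group": group})
    return pd.DataFrame(rows)


def write_inputs(
    outdir: str | Path,
    datasets: Sequence[ExpressionDataset],
    gt: GroundTruth,
    signature_size: int = 50,
    signature_seed: int = 0,
) -> dict[str, str]:
    """Write every file the file-based pipeline consumes, plus the truth.

    Emits one matrix TSV per batch, a batch manifest, the TF list, two
    subtype-signature GMTs, and the ground-truth JSON. Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    manifest_rows = []
    for ds in datasets:
        p = outdir / f"expression_{ds.batch_id}.tsv"
        io.write_expression_tsv(ds.values, p)
        manifest_rows.append({"file": p.name, "batch_id": ds.batch_id, "platform": ds.platform})
        paths[f"expression_{ds.batch_id}"] = str(p)
    manifest = outdir / "batches.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)
    paths["batch_manifest"] = str(manifest)

    tf_path = outdir / "tf_list.txt"
    tf_path.write_text("\n".join(gt.tf_list) + "\n")
    paths["tf_list"] = str(tf_path)

    scheme_a, scheme_b = make_subtype_signatures(gt, size=signature_size, seed=signature_seed)
    pa, pb = outdir / "signatures_primary.gmt", outdir / "signatures_twostate.gmt"
    io.write_gmt(scheme_a, pa)
    io.write_gmt(scheme_b, pb)
    paths["signatures_primary"] = str(pa)
    paths["signatures_twostate"] = str(pb)

    gt_path = outdir / "ground_truth.json"
    io.write_json(gt.as_dict(), gt_path)
    paths["ground_truth"] = str(gt_path)
    return paths
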