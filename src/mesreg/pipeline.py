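"""End-to-end orchestration: config, stage sequencing, manifest.

A single global seed deterministically derives per-stage seeds by hashing
the stage name (CRC32), so any stage can be rerun in isolation and the
whole run is byte-reproducible. Every file written into the output
directory is a pure function of (config, seed); timings go to the log
stream only.
"""

from __future__ import annotations

import hashlib
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from mesreg import diffexp, elda, harmonize, io, mra, netinfer, subtype, survival

log = logging.getLogger("mesreg")

_PARAM_DEFAULTS = {
    "weight_exponent": 0.25,
    "n_perm_classify": 1000,
    "n_perm_network": 1000,
    "n_perm_gsea": 1000,
    "alpha": 0.05,
    "dpi_tolerance": 0.0,
    "q_threshold": 0.05,
    "top_n": 100,
    "high_fraction": 0.30,
    "low_fraction": 0.30,
    "mra_alpha": 1e-4,
    "n_gsea": 10,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by CRC32 of 'seed:stage' (stable across runs)."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; see configs in analysis/."""

    batch_manifest: str
    tf_list: str
    signatures_primary: str
    outdir: str
    seed: int = 0
    signatures_twostate: str | None = None
    concordance_mapping: dict[str, list[str]] | None = None
    mes_labels: list[str] = field(default_factory=lambda: ["MES"])
    probe_maps: dict[str, str] = field(default_factory=dict)
    clinical: str | None = None
    marker_gene: str | None = None
    lda: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(_PARAM_DEFAULTS)
        merged.update(self.params or {})
        self.params = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        for name in ("batch_manifest", "tf_list", "signatures_primary"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("signatures_twostate", "clinical", "lda"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for key in ("n_perm_classify", "n_perm_network", "n_perm_gsea"):
            if self.params[key] < 100:
                raise ValueError(f"{key} must be >= 100, got {self.params[key]}")
        for key in ("alpha", "q_threshold"):
            if not 0 < self.params[key] <= 1:
                raise ValueError(f"{key} must be in (0, 1]")
        if self.params["high_fraction"] + self.params["low_fraction"] > 1:
            raise ValueError("high_fraction + low_fraction must not exceed 1")
        if self.signatures_twostate and not self.concordance_mapping:
            raise ValueError("two-scheme classification requires a concordance_mapping")


def run_synthetic_analysis(
    seed: int,
    gen_kwargs: Mapping | None = None,
    n_perm: int = 1000,
    classify_n_perm: int = 1000,
    weight_exponent: float = 0.25,
    alpha: float = 0.05,
    q_threshold: float = 0.05,
    mra_alpha: float = 1e-4,
    n_gsea: int = 10,
    signature_size: int = 50,
) -> dict:
    """In-memory end-to-end run on one synthetic collection.

    Generates a multi-batch collection with planted ground truth, then runs
    harmonization, two-scheme ssGSEA classification with concordance
    filtering, moderated differential expression on the called subtypes,
    MI network inference and master-regulator ranking. Returns every
    intermediate plus recovery metrics against the planted truth.
    """
    from mesreg import synthetic  # deferred: synthetic imports harmonize

    gen_kwargs = dict(gen_kwargs or {})
    datasets, gt = synthetic.gen_expression(seed=seed, **gen_kwargs)
    hm = harmonize.harmonize(datasets)

    scheme_a, scheme_b = synthetic.make_subtype_signatures(
        gt, size=signature_size, seed=seed)
    sigs_a = [subtype.GeneSignature.from_list(n, g) for n, g in scheme_a.items()]
    sigs_b = [subtype.GeneSignature.from_list(n, g) for n, g in scheme_b.items()]
    calls_a = subtype.classify_matrix(
        hm.values, sigs_a, n_perm=classify_n_perm,
        weight_exponent=weight_exponent, seed=stage_seed(seed, "classify"))
    calls_b = subtype.classify_matrix(
        hm.values, sigs_b, n_perm=classify_n_perm,
        weight_exponent=weight_exponent, seed=stage_seed(seed, "classify_twostate"))
    retained, concordance = subtype.concordance_filter(
        calls_a, calls_b, synthetic.CONCORDANCE_MAPPING)

    label_of = {c.sample_id: c.label for c in calls_a}
    group = pd.Series(
        {s: ("MES" if label_of[s] == "MES" else "nonMES") for s in retained}
    ).loc[retained]
    design = diffexp.DesignInfo(group=group, batch=hm.batch_labels.loc[retained])
    fits = diffexp.fit_gene_models(hm.values[retained], design)
    de_results = diffexp.moderated_test(fits, design)

    network = netinfer.infer_network(
        hm.values[retained], gt.tf_list, n_perm=n_perm, alpha=alpha,
        seed=stage_seed(seed, "network"))
    mr_table = mra.run_mra(
        network, de_results, q_threshold=q_threshold, n_gsea=n_gsea,
        n_perm=n_perm, seed=stage_seed(seed, "mra"))
    ordered, top_sig = mra.rank_mrs(mr_table, alpha=mra_alpha)

    planted = gt.planted_edges()
    kept = {(r, t): s for r, t, s in
            zip(network.edges["regulator"], network.edges["target"],
                network.edges["sign"])}
    recovered = [e for e in planted if e in kept]
    true_sign = {(tf, t): s for tf, reg in gt.regulons.items() for t, s in reg.items()}
    sign_matches = sum(kept[e] == true_sign[e] for e in recovered)
    label_acc = sum(
        (label_of[s] == "MES") == (gt.subtype[s] == "MES") for s in hm.samples
    ) / len(hm.samples)

    return {
        "ground_truth": gt,
        "harmonized": hm,
        "calls": calls_a,
        "retained": retained,
        "concordance": concordance,
        "label_accuracy": label_acc,
        "de_results": de_results,
        "network": network,
        "mr_table": mr_table,
        "ranked_tfs": ordered,
        "significant_tfs": top_sig,
        "planted_in_top10": set(gt.mes_tfs) <= set(ordered[:10]),
        "edge_recall": len(recovered) / len(planted) if planted else float("nan"),
        "sign_accuracy": sign_matches / len(recovered) if recovered else float("nan"),
    }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_datasets(config: PipelineConfig) -> list[harmonize.ExpressionDataset]:
    manifest = pd.read_csv(config.batch_manifest, sep="\t", dtype=str)
    base = Path(config.batch_manifest).parent
    datasets = []
    for _, row in manifest.iterrows():
        values = io.read_expression_tsv(base / row["file"])
        datasets.append(
            harmonize.ExpressionDataset(
                values, batch_id=row["batch_id"], platform=row.get("platform", "") or ""
            )
        )
    return datasets


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute harmonize -> classify -> diffexp -> network -> mra, plus the
    optional survival and limiting-dilution stages; write all outputs and a
    manifest under config.outdir. Returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "seed": config.seed,
        "params": p,
        "stages": {},
        "inputs": {},
    }
    for name in ("batch_manifest", "tf_list", "signatures_primary",
                 "signatures_twostate", "clinical", "lda"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    current = "(none)"
    try:
        # ---- harmonize -------------------------------------------------
        current = "harmonize"
        t0 = time.perf_counter()
        datasets = load_datasets(config)
        probe_maps = {b: io.read_probe_map(path) for b, path in config.probe_maps.items()}
        hm = harmonize.harmonize(datasets, probe_maps or None)
        io.write_expression_tsv(hm.values, outdir / "harmonized.tsv")
        io.write_json(
            {
                "batch_labels": hm.batch_labels.to_dict(),
                "removed_genes": hm.removed_genes,
                "n_genes": int(hm.values.shape[0]),
                "n_samples": int(hm.values.shape[1]),
            },
            outdir / "harmonized.json",
        )
        manifest["stages"]["harmonize"] = {
            "status": "completed", "n_genes": int(hm.values.shape[0]),
            "n_samples": int(hm.values.shape[1]),
        }
        log.info("harmonize: %d genes x %d samples (%.1fs)",
                 hm.values.shape[0], hm.values.shape[1], time.perf_counter() - t0)

        # ---- subtype classification ------------------------------------
        current = "classify"
        t0 = time.perf_counter()
        sigs_a = [subtype.GeneSignature.from_list(n, g)
                  for n, g in io.read_gmt(config.signatures_primary).items()]
        calls_a = subtype.classify_matrix(
            hm.values, sigs_a, n_perm=p["n_perm_classify"],
            weight_exponent=p["weight_exponent"], seed=stage_seed(config.seed, "classify"),
        )
        subtype.calls_to_frame(calls_a).to_csv(outdir / "subtype_calls.tsv", sep="\t")
        retained = [c.sample_id for c in calls_a]
        concordance = 1.0
        if config.signatures_twostate:
            sigs_b = [subtype.GeneSignature.from_list(n, g)
                      for n, g in io.read_gmt(config.signatures_twostate).items()]
            calls_b = subtype.classify_matrix(
                hm.values, sigs_b, n_perm=p["n_perm_classify"],
                weight_exponent=p["weight_exponent"],
                seed=stage_seed(config.seed, "classify_twostate"),
            )
            subtype.calls_to_frame(calls_b).to_csv(
                outdir / "subtype_calls_twostate.tsv", sep="\t")
            mapping = {k: set(v) for k, v in config.concordance_mapping.items()}
            retained, concordance = subtype.concordance_filter(calls_a, calls_b, mapping)
        (outdir / "retained_samples.txt").write_text("\n".join(retained) + "\n")
        manifest["stages"]["classify"] = {
            "status": "completed", "n_retained": len(retained),
            "concordance_fraction": concordance,
        }
        log.info("classify: %d/%d samples retained (%.1fs)",
                 len(retained), hm.values.shape[1], time.perf_counter() - t0)

        # ---- differential expression -----------------------------------
        current = "diffexp"
        t0 = time.perf_counter()
        label_of = {c.sample_id: c.label for c in calls_a}
        group = pd.Series(
            {s: ("MES" if label_of[s] in set(config.mes_labels) else "nonMES")
             for s in retained}
        ).loc[retained]
        design = diffexp.DesignInfo(group=group, batch=hm.batch_labels.loc[retained])
        fits = diffexp.fit_gene_models(hm.values[retained], design)
        results = diffexp.moderated_test(fits, design)
        results.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene")
        up, down, top = diffexp.make_signature(results, p["q_threshold"], p["top_n"])
        sig_sets = {}
        if up:
            sig_sets["MES_up"] = up
        if down:
            sig_sets["MES_down"] = down
        sig_sets["top_de"] = top
        io.write_gmt(sig_sets, outdir / "de_signature.gmt")
        manifest["stages"]["diffexp"] = {
            "status": "completed", "n_up": len(up), "n_down": len(down),
            "d0": float(results.attrs["d0"]), "s0sq": float(results.attrs["s0sq"]),
        }
        log.info("diffexp: %d up, %d down at q<%.3g (%.1fs)",
                 len(up), len(down), p["q_threshold"], time.perf_counter() - t0)

        # ---- network inference -----------------------------------------
        current = "network"
        t0 = time.perf_counter()
        tfs = [t for t in Path(config.tf_list).read_text().split() if t]
        tfs = [t for t in tfs if t in set(hm.values.index)]
        network = netinfer.infer_network(
            hm.values[retained], tfs, n_perm=p["n_perm_network"], alpha=p["alpha"],
            dpi_tolerance=p["dpi_tolerance"], seed=stage_seed(config.seed, "network"),
        )
        network.edges.to_csv(outdir / "regulon_edges.tsv", sep="\t", index=False)
        io.write_gmt(network.to_gmt_sets(), outdir / "regulons.gmt")
        manifest["stages"]["network"] = {
            "status": "completed", "n_tfs": len(tfs),
            "n_edges": int(len(network.edges)),
        }
        log.info("network: %d edges over %d TFs (%.1fs)",
                 len(network.edges), len(tfs), time.perf_counter() - t0)

        # ---- master-regulator analysis ---------------------------------
        current = "mra"
        t0 = time.perf_counter()
        mr_table = mra.run_mra(
            network, results, q_threshold=p["q_threshold"], n_gsea=p["n_gsea"],
            n_perm=p["n_perm_gsea"], seed=stage_seed(config.seed, "mra"),
        )
        ordered, top_sig = mra.rank_mrs(mr_table, alpha=p["mra_alpha"])
        mr_table.loc[ordered].to_csv(outdir / "mra.tsv", sep="\t", index_label="tf")
        (outdir / "mra_ranked.txt").write_text("\n".join(ordered) + "\n")
        manifest["stages"]["mra"] = {
            "status": "completed", "n_significant": len(top_sig),
            "top10": ordered[:10],
        }
        log.info("mra: %d TFs below q<%.1g; top: %s (%.1fs)",
                 len(top_sig), p["mra_alpha"], ", ".join(ordered[:5]),
                 time.perf_counter() - t0)

        # ---- optional survival -----------------------------------------
        if config.clinical:
            current = "survival"
            t0 = time.perf_counter()
            clin = io.read_clinical_tsv(config.clinical)
            gene = config.marker_gene or ordered[0]
            if gene not in hm.values.index:
                raise ValueError(f"marker gene {gene!r} absent from the matrix")
            res = survival.analyze_marker(
                hm.values.loc[gene], clin,
                high_fraction=p["high_fraction"], low_fraction=p["low_fraction"],
            )
            res["labels"].to_frame().to_csv(outdir / "survival_groups.tsv", sep="\t")
            io.write_json({"gene": gene, "chi_square": res["chi_square"], "p": res["p"]},
                          outdir / "survival_test.json")
            manifest["stages"]["survival"] = {
                "status": "completed", "gene": gene, "p": res["p"]}
            log.info("survival: %s log-rank p=%.3g (%.1fs)", gene, res["p"],
                     time.perf_counter() - t0)

        # ---- optional limiting dilution --------------------------------
        if config.lda:
            current = "elda"
            t0 = time.perf_counter()
            well_data = io.read_lda_tsv(config.lda)
            comp = elda.compare_groups(well_data)
            io.write_json(
                {
                    "groups": {g: f.as_dict() for g, f in comp["fits"].items()},
                    "chi_square": comp["chi_square"], "df": comp["df"], "p": comp["p"],
                },
                outdir / "elda.json",
            )
            manifest["stages"]["elda"] = {"status": "completed", "p": comp["p"]}
            log.info("elda: chi2=%.2f p=%.3g (%.1fs)", comp["chi_square"], comp["p"],
                     time.perf_counter() - t0)

    except Exception as exc:
        manifest["stages"][current] = {"status": "FAILED", "error": str(exc)}
        io.write_json(manifest, outdir / "manifest.json")
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    io.write_json(manifest, outdir / "manifest.json")
    return manifest
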