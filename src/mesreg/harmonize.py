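"""Assemble heterogeneous per-platform expression matrices into one
standardized gene-by-sample matrix with batch labels.

The harmonization recipe mirrors common practice for merging microarray
and RNA-seq cohorts: collapse probes to genes by the per-sample median,
restrict to the genes shared by every dataset, z-score each gene within
each dataset (so platform-specific location/scale effects cancel), and
concatenate columns while remembering which batch every sample came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass
class ExpressionDataset:
    """One platform/batch matrix: rows are probes or genes, columns samples.

    Invariants enforced at construction: unique row and sample ids, at
    least two samples, and no missing values (unless ``impute=True``, in
    which case missing entries are filled with the per-row median).
    """

    values: pd.DataFrame
    batch_id: str
    platform: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[1] < 2:
            raise ValueError(f"dataset {self.batch_id!r} has {v.shape[1]} samples; need >= 2")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in {self.batch_id!r}: {dup[:5]}")
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].tolist()
            raise ValueError(f"duplicate row ids in {self.batch_id!r}: {dup[:5]}")
        if v.isna().any().any():
            raise ValueError(
                f"dataset {self.batch_id!r} contains missing values; "
                "reject or impute explicitly (see impute_missing)"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def impute_missing(values: pd.DataFrame, batch_id: str, platform: str = "") -> ExpressionDataset:
    """Build an ExpressionDataset filling missing entries with the row median.

    This is the explicit opt-in path; the default constructor rejects NaNs.
    """
    filled = values.apply(lambda row: row.fillna(row.median()), axis=1)
    if filled.isna().any().any():
        raise ValueError("rows with all values missing cannot be imputed")
    return ExpressionDataset(filled, batch_id=batch_id, platform=platform)


@dataclass
class HarmonizedMatrix:
    """Combined standardized matrix: rows common genes, columns all samples."""

    values: pd.DataFrame
    batch_labels: pd.Series  # sample id -> batch id
    removed_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def batch_of(self, sample: str) -> str:
        return str(self.batch_labels.loc[sample])


def collapse_probes(dataset: ExpressionDataset, probe_map: Mapping[str, str]) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene by the per-sample median.

    Probes absent from ``probe_map`` are dropped. With an even number of
    probes the median is the mean of the two middle values (the numpy
    convention).
    """
    if not probe_map:
        raise ValueError("empty probe->gene mapping")
    mapped = dataset.values.index.map(lambda p: probe_map.get(str(p)))
    keep = mapped.notna()
    if not keep.any():
        raise ValueError("no probes in the dataset map to a gene symbol")
    sub = dataset.values.loc[keep]
    collapsed = sub.groupby(pd.Index(mapped[keep], name="gene"), sort=True).median()
    assert not collapsed.index.duplicated().any()
    return ExpressionDataset(collapsed, batch_id=dataset.batch_id, platform=dataset.platform)


def intersect_genes(datasets: Sequence[ExpressionDataset]) -> list[str]:
    """Sorted list of genes present in every dataset.

    Raises with the first offending pair named if any two datasets share
    no genes at all.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to intersect")
    for i in range(len(datasets)):
        for j in range(i + 1, len(datasets)):
            if not set(datasets[i].genes) & set(datasets[j].genes):
                raise ValueError(
                    "empty gene overlap between datasets "
                    f"{datasets[i].batch_id!r} and {datasets[j].batch_id!r}"
                )
    common = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise ValueError("empty gene intersection across all datasets")
    return sorted(common)


def scale_and_assemble(
    datasets: Sequence[ExpressionDataset], genes: Iterable[str]
) -> HarmonizedMatrix:
    """Z-score each gene within each dataset and concatenate columns.

    Standardization uses the population SD (divisor n). Genes with zero
    variance in any dataset are removed from all datasets and reported in
    ``removed_genes``; downstream rank/MI steps cannot use them anyway.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    for ds in datasets:
        if ds.n_samples < 2:
            raise ValueError(f"dataset {ds.batch_id!r} has one sample; SD undefined")
        missing = set(genes) - set(ds.genes)
        if missing:
            raise ValueError(
                f"dataset {ds.batch_id!r} lacks {len(missing)} of the requested genes"
            )
    blocks = [ds.values.loc[genes] for ds in datasets]
    zero_var: set[str] = set()
    for ds, block in zip(datasets, blocks):
        sd = block.std(axis=1, ddof=0)
        zero_var |= set(block.index[sd.values == 0.0])
    keep = [g for g in genes if g not in zero_var]
    if not keep:
        raise ValueError("all genes have zero variance in some dataset")
    scaled = []
    labels = {}
    seen: set[str] = set()
    for ds, block in zip(datasets, blocks):
        b = block.loc[keep]
        mu = b.mean(axis=1)
        sd = b.std(axis=1, ddof=0)
        scaled.append(b.sub(mu, axis=0).div(sd, axis=0))
        clash = seen & set(ds.values.columns)
        if clash:
            raise ValueError(f"sample ids repeated across datasets: {sorted(clash)[:5]}")
        seen |= set(ds.values.columns)
        for s in ds.values.columns:
            labels[s] = ds.batch_id
    combined = pd.concat(scaled, axis=1)
    batch = pd.Series(labels, name="batch").loc[combined.columns]
    return HarmonizedMatrix(combined, batch, removed_genes=sorted(zero_var))


def harmonize(
    datasets: Sequence[ExpressionDataset],
    probe_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> HarmonizedMatrix:
    """Full harmonization: optional probe collapse, intersection, scaling.

    ``probe_maps`` maps batch_id -> probe->gene table for datasets still at
    probe level; datasets without an entry are assumed gene-level.
    """
    prepared = []
    for ds in datasets:
        if probe_maps and ds.batch_id in probe_maps:
            ds = collapse_probes(ds, probe_maps[ds.batch_id])
        prepared.append(ds)
    genes = intersect_genes(prepared)
    return scale_and_assemble(prepared, genes)
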