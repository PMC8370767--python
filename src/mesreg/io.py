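"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are tab-separated with the first column holding row
identifiers (probes or genes) and the header row holding sample ids.
Gene sets use the GMT convention (name, description, then one gene per
field). Clinical and limiting-dilution tables are column-named TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample (or probe-by-sample) TSV matrix.

    First column = row identifier, header = sample ids; values numeric.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe, gene) -> probe->gene mapping.

    A header line is optional; it is detected by the literal column name
    'probe' in the first field.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if str(df.iloc[0, 0]).lower() == "probe":
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered mapping name -> gene list."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        name, genes = fields[0], [g for g in fields[2:] if g]
        if not genes:
            raise ValueError(f"empty gene set {name!r} in {path}")
        sets[name] = genes
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Clinical table with columns sample, time, event (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def read_lda_tsv(path: str | Path) -> pd.DataFrame:
    """Limiting-dilution well counts: dose, tested, positive, group."""
    df = pd.read_csv(path, sep="\t")
    required = {"dose", "tested", "positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LDA table missing columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = "all"
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
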