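"""Readers and writers for the plain-text formats the screen consumes.

All tabular data travel as TSV (genes as rows, first column ``gene_id``),
genomic intervals as 6-column BED (0-based, half-open), gene sets as GMT and
ranked lists as two-column RNK files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

# Matrices ------------------------------------------------------------------


def read_matrix_tsv(path: str | Path, index_label: str = "gene_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != index_label:
        raise ValueError(
            f"{path}: expected first column {index_label!r}, found {df.columns[0]!r}"
        )
    return df.set_index(index_label)


def write_matrix_tsv(
    df: pd.DataFrame, path: str | Path, index_label: str = "gene_id"
) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_groups_tsv(path: str | Path) -> pd.Series:
    """Two-column file (id, label) -> Series mapping id to label."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")


def write_groups_tsv(
    labels: pd.Series, path: str | Path, id_name: str = "sample_id"
) -> None:
    out = labels.rename("label").rename_axis(id_name).reset_index()
    out.to_csv(path, sep="\t", index=False)


# Survival ------------------------------------------------------------------


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    """Columns: sample_id, time, event, then one column per covariate gene."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {required - set(df.columns)}")
    return df.set_index("sample_id")


def write_survival_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


# BED intervals -------------------------------------------------------------


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least chrom/start/end")
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["score"] = df["score"].astype(float)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[BED_COLUMNS].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.10g"
    )


# Gene sets and ranked lists ------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _description, *genes = fields
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "metric"])
    return pd.Series(df["metric"].values, index=df["gene_id"].values, name="metric")


def write_rnk(metric: pd.Series, path: str | Path) -> None:
    metric.rename("metric").rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", header=False, index=False, float_format="%.10g"
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
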