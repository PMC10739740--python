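"""Readers and writers for the pipeline's plain-text formats.

All genomic intervals are 0-based half-open internally (BED convention);
readers for 1-based inputs take an explicit ``one_based`` flag.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix

SUMSTATS_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "beta", "se", "maf", "n"]
BED_COLUMNS = ["chr", "start", "end", "gene", "score", "strand"]
BEDPE_COLUMNS = ["chr1", "start1", "end1", "chr2", "start2", "end2", "gene"]


def read_counts(path, layer: str = "raw") -> ExpressionMatrix:
    """Counts TSV: genes as rows, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ExpressionMatrix(df, layer=layer)


def write_counts(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"chr": str, "a1": str, "a2": str}, float_precision="round_trip"
    )
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stat file {path} missing columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("summary stats contain non-positive standard errors")
    return df[SUMSTATS_COLUMNS]


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path, one_based: bool = False) -> pd.DataFrame:
    """Gene models BED (chr, start, end, gene, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, dtype={"chr": str})
    if one_based:
        df["start"] = df["start"] - 1
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path, one_based: bool = False) -> pd.DataFrame:
    """Promoter-capture interactions: bait interval + gene, other-end interval."""
    df = pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLUMNS, dtype={"chr1": str, "chr2": str})
    if one_based:
        df["start1"] = df["start1"] - 1
        df["start2"] = df["start2"] - 1
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    df[BEDPE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_ppi(path) -> pd.DataFrame:
    from .simulate import PPI_CHANNELS

    df = pd.read_csv(path, sep="\t")
    required = ["protein1", "protein2", *PPI_CHANNELS, "combined"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"PPI file {path} missing columns: {missing}")
    return df[required]


def write_ppi(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then gene ids (tab-separated).

    Duplicate genes within a set are dropped, order preserved.
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, genes = parts[0], parts[2:]
        sets[name] = list(dict.fromkeys(g for g in genes if g))
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *dict.fromkeys(genes)]) + "\n")


def read_proxy_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in ("lead", "proxy", "r2") if c not in df.columns]
    if missing:
        raise ValueError(f"proxy table missing columns: {missing}")
    return df
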