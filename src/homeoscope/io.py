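"""Readers and writers for every tabular/interval format the pipeline touches.

Conventions
-----------
* TSV with a header row for counts, design, pairs, GO map and truth tables.
* BED-style headerless TSV for gene catalogs and HE (homoeologous exchange)
  regions; intervals are 0-based half-open, the standard BED convention.
* Readers validate strictly and raise :class:`~homeoscope.exceptions.FormatError`
  (naming the offending row) rather than coercing; writers round-trip exactly.

In-memory containers are plain pandas objects:

* gene catalog  -- ``DataFrame`` indexed by ``gene_id`` with columns
  ``subgenome`` (A/D), ``chromosome`` ("unplaced" allowed), ``start``, ``end``
  (0-based half-open) and ``transcript_length``.
* count matrix  -- integer ``DataFrame``, genes x samples.
* sample design -- ``DataFrame`` indexed by ``sample`` with columns
  ``genotype``, ``condition``, ``replicate``.
* pair table    -- ``DataFrame`` with columns ``a_gene``, ``d_gene``.
* HE regions    -- ``DataFrame`` with columns ``chromosome``, ``start``,
  ``end``, ``line``, ``multiplier``.
* GO map        -- ``DataFrame`` with columns ``gene_id``, ``term_id``.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError

GENOTYPES = ("parentA", "parentD", "Mix", "EUP", "X190")
CONDITIONS = ("mock-2d", "PEG6000-2d", "mock-5d", "NaCl-5d")
SUBGENOMES = ("A", "D")
UNPLACED = "unplaced"


# ---------------------------------------------------------------------------
# helpers


def _require(path: str) -> None:
    if not os.path.exists(path):
        raise FormatError(f"input file not found: {path}")


def _read_tsv(path: str) -> pd.DataFrame:
    _require(path)
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc


def _check_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# count matrix


def read_counts(path: str) -> pd.DataFrame:
    """Read a gene x sample count matrix (TSV, first column ``gene_id``)."""
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        row = int(df.index[df["gene_id"] == dup][1]) + 2
        raise FormatError(f"{path}: duplicate gene id {dup!r} at row {row}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no sample columns")
    out = df.set_index("gene_id")
    for col in out.columns:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            gene = out.index[bad.to_numpy()][0]
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise FormatError(
                f"{path}: non-negative integer required in column {col!r}, "
                f"row {row} (gene {gene!r})"
            )
        out[col] = vals.astype(np.int64)
    return out


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample design


def read_design(path: str) -> pd.DataFrame:
    """Read the sample design sheet (sample, genotype, condition, replicate)."""
    df = _read_tsv(path)
    _check_columns(df, ["sample", "genotype", "condition", "replicate"], path)
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    for i, row in df.iterrows():
        if row["genotype"] not in GENOTYPES:
            raise FormatError(f"{path}: row {i + 2}: unknown genotype {row['genotype']!r}")
        if row["condition"] not in CONDITIONS:
            raise FormatError(f"{path}: row {i + 2}: unknown condition {row['condition']!r}")
    key = df[["genotype", "condition", "replicate"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise FormatError(f"{path}: duplicate (genotype, condition, replicate) triple {key[key.duplicated()].iloc[0]}")
    out = df.set_index("sample")
    out["replicate"] = out["replicate"].astype(int)
    return out


def write_design(design: pd.DataFrame, path: str) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def check_design_matches_counts(design: pd.DataFrame, counts: pd.DataFrame) -> None:
    """Every count column must have exactly one design row, and vice versa."""
    cols = set(counts.columns)
    rows = set(design.index)
    if cols != rows:
        missing = sorted(cols - rows)[:5]
        extra = sorted(rows - cols)[:5]
        raise ConsistencyError(
            f"design/count-matrix mismatch: columns without design row {missing}, "
            f"design rows without column {extra}"
        )


# ---------------------------------------------------------------------------
# gene catalogs (BED-like, headerless: chrom start end gene_id transcript_length)


def read_genes(path: str) -> pd.DataFrame:
    """Read a gene catalog BED file; subgenome is inferred from chromosome
    names ending in A/D and may be overridden with :func:`tag_subgenome`."""
    _require(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "gene_id", "transcript_length"],
        dtype=str,
    )
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end, tl = int(row.start), int(row.end), int(row.transcript_length)
        except ValueError:
            raise FormatError(f"{path}: row {i}: non-integer coordinate or length")
        if tl <= 0:
            raise FormatError(f"{path}: row {i}: transcript_length must be > 0")
        if row.chromosome != UNPLACED and not start < end:
            raise FormatError(f"{path}: row {i}: start must be < end for placed gene {row.gene_id!r}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    out = df.set_index("gene_id")
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    out["transcript_length"] = out["transcript_length"].astype(np.int64)
    out["subgenome"] = [
        "A" if c.endswith("A") else ("D" if c.endswith("D") else UNPLACED)
        for c in out["chromosome"]
    ]
    return out[["subgenome", "chromosome", "start", "end", "transcript_length"]]


def write_genes(catalog: pd.DataFrame, path: str) -> None:
    catalog.reset_index()[
        ["chromosome", "start", "end", "gene_id", "transcript_length"]
    ].to_csv(path, sep="\t", header=False, index=False)


def tag_subgenome(catalog: pd.DataFrame, subgenome: str) -> pd.DataFrame:
    """Force the subgenome label (needed for unplaced scaffold genes, whose
    chromosome carries no A/D suffix)."""
    if subgenome not in SUBGENOMES:
        raise ConsistencyError(f"unknown subgenome {subgenome!r}")
    out = catalog.copy()
    out["subgenome"] = subgenome
    return out


def merge_catalogs(catalog_a: pd.DataFrame, catalog_d: pd.DataFrame) -> pd.DataFrame:
    """Concatenate the two parental catalogs into the joint gene bookkeeping
    table (the in-memory analogue of mapping to a concatenated reference
    genome). Gene ids must not collide."""
    overlap = catalog_a.index.intersection(catalog_d.index)
    if len(overlap):
        raise ConsistencyError(f"gene ids present in both catalogs, e.g. {overlap[0]!r}")
    return pd.concat([catalog_a, catalog_d])


# ---------------------------------------------------------------------------
# homoeolog pairs


def read_pairs(path: str) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_columns(df, ["a_gene", "d_gene"], path)
    flat = pd.concat([df["a_gene"], df["d_gene"]])
    if flat.duplicated().any():
        dup = flat[flat.duplicated()].iloc[0]
        raise FormatError(f"{path}: gene {dup!r} appears in more than one pair (1:1 violated)")
    return df.reset_index(drop=True)


def write_pairs(pairs: pd.DataFrame, path: str) -> None:
    pairs[["a_gene", "d_gene"]].to_csv(path, sep="\t", index=False)


def check_pairs_resolve(pairs: pd.DataFrame, catalog: pd.DataFrame) -> None:
    for col in ("a_gene", "d_gene"):
        unknown = ~pairs[col].isin(catalog.index)
        if unknown.any():
            raise ConsistencyError(
                f"pair table references unknown gene {pairs.loc[unknown, col].iloc[0]!r}"
            )


# ---------------------------------------------------------------------------
# HE regions (headerless BED-like: chrom start end line multiplier)


def read_intervals(path: str) -> pd.DataFrame:
    _require(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "line", "multiplier"],
        dtype=str,
    )
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
            mult = float(row.multiplier)
        except ValueError:
            raise FormatError(f"{path}: row {i}: malformed interval")
        if not start < end:
            raise FormatError(f"{path}: row {i}: start must be < end")
        if mult < 0:
            raise FormatError(f"{path}: row {i}: multiplier must be non-negative")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["multiplier"] = df["multiplier"].astype(float)
    return df


def write_intervals(intervals: pd.DataFrame, path: str) -> None:
    intervals[["chromosome", "start", "end", "line", "multiplier"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def interval_contains(start: int, end: int, position: int) -> bool:
    """Membership under the 0-based half-open convention: start inclusive,
    end exclusive."""
    return start <= position < end


# ---------------------------------------------------------------------------
# GO annotation


def read_go(path: str) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_columns(df, ["gene_id", "term_id"], path)
    dup = df.duplicated()
    if dup.any():
        i = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise FormatError(f"{path}: duplicate (gene, term) annotation at row {i}")
    return df.reset_index(drop=True)


def write_go(go_map: pd.DataFrame, path: str) -> None:
    go_map[["gene_id", "term_id"]].to_csv(path, sep="\t", index=False)


def go_gene_to_terms(go_map: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, term in zip(go_map["gene_id"], go_map["term_id"]):
        out.setdefault(gene, set()).add(term)
    return out
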