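"""Annotation-table I/O, quality filtering, and best-hit classification.

The central exchange format of the pipeline is a tab-separated *annotation
table* with one row per annotated feature (protein-coding region) per
sample.  Each row carries the hit count, alignment-quality fields
(e-value, percent identity, alignment length), a six-rank taxonomic
lineage, a four-level functional hierarchy (the leaf carries the EC/KEGG
identifier), and an opaque subject id used only for deterministic
tie-breaking.  Missing values are encoded as ``NA``.

Filtering follows the conventions of shotgun-metagenome annotation
servers: a maximum e-value of 1e-5, a minimum alignment length of 15 bp,
and a minimum percent identity of 60% for taxonomic profiling or 80% for
functional profiling.  Only features assigned to the Bacteria domain are
retained.  All comparisons are inclusive on the "keep" side.
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass

import pandas as pd

#: Column order of the on-disk dialect (tab-separated, "NA" = missing).
COLUMNS = [
    "feature_id", "sample_id", "hits", "evalue", "identity_pct", "aln_len",
    "domain", "phylum", "class", "order", "family", "genus",
    "func_l1", "func_l2", "func_l3", "func_l4", "subject_id",
]

#: Taxonomic ranks, broadest first.
TAX_RANKS = ["domain", "phylum", "class", "order", "family", "genus"]

#: Functional hierarchy levels, broadest first; func_l4 carries the EC id.
FUNC_LEVELS = ["func_l1", "func_l2", "func_l3", "func_l4"]

_INT_COLS = {"hits", "aln_len"}
_FLOAT_COLS = {"evalue", "identity_pct"}


class ParseError(ValueError):
    """Malformed annotation-table row; the message names the line number."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Annotation-quality and significance thresholds.

    Parameters
    ----------
    evalue_max : float
        Maximum alignment e-value (default 1e-5).
    aln_len_min : int
        Minimum alignment length in bp (default 15).
    identity_min_tax, identity_min_fun : float
        Minimum percent identity for taxonomic (60) and functional (80)
        profiling.
    q_alpha : float
        Significance level applied to BH-adjusted q-values (default 0.05).
    eta2_min : float
        Effect-size floor for multi-group comparisons (default 0.01).
    """

    evalue_max: float = 1e-5
    aln_len_min: int = 15
    identity_min_tax: float = 60.0
    identity_min_fun: float = 80.0
    q_alpha: float = 0.05
    eta2_min: float = 0.01

    def __post_init__(self) -> None:
        if not (self.evalue_max > 0):
            raise ValueError("evalue_max must be positive")
        if self.aln_len_min < 1:
            raise ValueError("aln_len_min must be >= 1")
        for name in ("identity_min_tax", "identity_min_fun"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100]")
        if not (0 < self.q_alpha < 1):
            raise ValueError("q_alpha must be in (0, 1)")
        if not (0 <= self.eta2_min <= 1):
            raise ValueError("eta2_min must be in [0, 1]")

    def identity_min(self, mode: str) -> float:
        if mode == "taxonomic":
            return self.identity_min_tax
        if mode == "functional":
            return self.identity_min_fun
        raise ValueError(f"unknown mode {mode!r}; expected 'taxonomic' or 'functional'")


def _parse_row(fields: list[str], lineno: int) -> dict:
    if len(fields) != len(COLUMNS):
        raise ParseError(
            f"line {lineno}: expected {len(COLUMNS)} columns, got {len(fields)}"
        )
    rec: dict = {}
    for col, raw in zip(COLUMNS, fields):
        if raw == "NA":
            rec[col] = None
            continue
        if col in _INT_COLS:
            try:
                rec[col] = int(raw)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer {col} {raw!r}") from None
        elif col in _FLOAT_COLS:
            try:
                rec[col] = float(raw)
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric {col} {raw!r}") from None
        else:
            rec[col] = raw
    # invariants
    for col in ("feature_id", "sample_id", "hits", "evalue", "identity_pct", "aln_len"):
        if rec[col] is None:
            raise ParseError(f"line {lineno}: missing required field {col}")
    if rec["hits"] < 1:
        raise ParseError(f"line {lineno}: hits must be >= 1, got {rec['hits']}")
    if not (rec["evalue"] > 0) or math.isnan(rec["evalue"]):
        raise ParseError(f"line {lineno}: evalue must be > 0, got {rec['evalue']}")
    if not (0 <= rec["identity_pct"] <= 100):
        raise ParseError(
            f"line {lineno}: identity_pct must be in [0, 100], got {rec['identity_pct']}"
        )
    if rec["aln_len"] < 1:
        raise ParseError(f"line {lineno}: aln_len must be >= 1, got {rec['aln_len']}")
    # lineage prefix-consistency: a missing rank implies all lower ranks missing
    seen_missing = False
    for rank in TAX_RANKS:
        if rec[rank] is None:
            seen_missing = True
        elif seen_missing:
            raise ParseError(
                f"line {lineno}: lineage not prefix-consistent ({rank} present "
                "below a missing rank)"
            )
    return rec


def read_annotation_table(source) -> pd.DataFrame:
    """Read an annotation table from a path or text stream.

    Returns a DataFrame with the dialect's columns in order; missing
    values are ``None``/``NaN``.  Raises :class:`ParseError` (naming the
    offending line) on malformed rows.
    """
    if hasattr(source, "read"):
        return _read_stream(source)
    with open(source, "r", encoding="utf-8", newline="") as fh:
        return _read_stream(fh)


def _read_stream(fh) -> pd.DataFrame:
    reader = csv.reader(fh, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty file: missing header") from None
    if header != COLUMNS:
        raise ParseError(f"bad header: expected {COLUMNS}, got {header}")
    rows = [_parse_row(fields, lineno) for lineno, fields in enumerate(reader, start=2)]
    df = pd.DataFrame(rows, columns=COLUMNS)
    if df.empty:
        df = _empty_table()
    return _with_dtypes(df)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})


def _with_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _INT_COLS:
        df[col] = df[col].astype("int64") if len(df) else df[col]
    for col in _FLOAT_COLS:
        df[col] = df[col].astype("float64") if len(df) else df[col]
    df.index = pd.RangeIndex(len(df))
    return df


def _format_value(col: str, v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if col in _INT_COLS:
        return str(int(v))
    if col in _FLOAT_COLS:
        return repr(float(v))
    return str(v)


def write_annotation_table(table: pd.DataFrame, dest) -> None:
    """Write *table* in the TSV dialect (deterministic: input row order,
    fixed column order, ``repr`` floats, UTF-8, "NA" for missing)."""
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")

    def _write(fh) -> None:
        fh.write("\t".join(COLUMNS) + "\n")
        for row in table[COLUMNS].itertuples(index=False):
            fh.write("\t".join(_format_value(c, v) for c, v in zip(COLUMNS, row)) + "\n")

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def apply_annotation_filters(
    table: pd.DataFrame, thresholds: ThresholdConfig | None = None, mode: str = "taxonomic"
) -> pd.DataFrame:
    """Apply the annotation-quality thresholds and the Bacteria-domain filter.

    Retains records with ``evalue <= evalue_max``, ``aln_len >= aln_len_min``,
    ``identity_pct >= identity_min`` for *mode* ("taxonomic": 60%,
    "functional": 80%), and ``domain == "Bacteria"``; row order preserved.
    Idempotent.
    """
    thresholds = thresholds or ThresholdConfig()
    idmin = thresholds.identity_min(mode)
    mask = (
        (table["evalue"] <= thresholds.evalue_max)
        & (table["aln_len"] >= thresholds.aln_len_min)
        & (table["identity_pct"] >= idmin)
        & (table["domain"] == "Bacteria")
    )
    return table.loc[mask].copy()


def domain_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample percentage of hits annotated to each domain.

    Intended to be computed *before* :func:`apply_annotation_filters`, so
    the share of Bacteria-domain features among all annotated features
    can be reported alongside QC summaries.
    """
    dom = table["domain"].fillna("unclassified")
    counts = (
        table.assign(_dom=dom)
        .groupby(["sample_id", "_dom"], sort=True)["hits"]
        .sum()
        .unstack(fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def best_hit_classification(table: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (feature_id, sample_id): the best-scoring hit.

    Best = smallest e-value; ties broken by largest identity, then
    largest alignment length, then lexicographically smallest subject_id.
    Surviving records keep their input order and are unaltered.
    """
    if table.empty:
        return table.copy()
    ranked = table.assign(
        _neg_id=-table["identity_pct"],
        _neg_aln=-table["aln_len"],
        _subj=table["subject_id"].fillna(""),
    ).sort_values(
        ["evalue", "_neg_id", "_neg_aln", "_subj"], kind="mergesort"
    )
    keep = ranked.drop_duplicates(subset=["feature_id", "sample_id"], keep="first").index
    return table.loc[sorted(keep)].copy()
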