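"""Count matrices at taxonomic ranks / functional levels, normalization.

Best-hit annotation tables are aggregated into features x samples count
matrices at any lineage rank (domain..genus) or functional level
(func_l1..func_l4).  Records missing the label are pooled into an
"unclassified" row so matrix totals are conserved.

Normalization uses median-of-ratios size factors (the normalization step
of the negative-binomial count-model approach): the reference profile is
the per-feature geometric mean over samples, computed over features
positive in all samples, and each sample's factor is the median ratio of
its counts to the reference, rescaled so the factors have geometric mean
1.  Exact tests downstream always consume the raw integer counts;
normalized or relative-abundance matrices feed ordination and heatmap
outputs only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile_io import FUNC_LEVELS, TAX_RANKS

UNCLASSIFIED = "unclassified"

VALID_LEVELS = tuple(TAX_RANKS + FUNC_LEVELS)


@dataclass
class AbundanceMatrix:
    """A features x samples abundance matrix at one hierarchy level.

    ``counts`` rows are feature labels, columns sample ids; entries are
    non-negative (integers before normalization).  ``size_factors``, when
    present, are per-sample positive reals with geometric mean 1.
    """

    level: str
    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.counts, dtype=float) < 0).any():
            raise ValueError("abundance matrix has negative entries")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")
        if self.size_factors is not None:
            sf = np.asarray(self.size_factors, dtype=float)
            if (sf <= 0).any():
                raise ValueError("size factors must be positive")
            gmean = float(np.exp(np.mean(np.log(sf))))
            if abs(gmean - 1.0) > 1e-9:
                raise ValueError("size factors must have geometric mean 1")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def total(self) -> float:
        return float(self.counts.to_numpy().sum())


def aggregate_counts(table: pd.DataFrame, level: str) -> AbundanceMatrix:
    """Aggregate a best-hit annotation table at *level*.

    Entry (r, s) is the summed ``hits`` of records in sample s whose
    label at *level* is r; records missing the label are pooled into the
    ``unclassified`` row, so the matrix total equals the table's total
    hits.
    """
    if level not in VALID_LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {VALID_LEVELS}")
    labels = table[level].fillna(UNCLASSIFIED) if len(table) else pd.Series(dtype=object)
    counts = (
        table.assign(_label=labels)
        .groupby(["_label", "sample_id"], sort=True)["hits"]
        .sum()
        .unstack(fill_value=0)
        if len(table)
        else pd.DataFrame()
    )
    counts.index.name = level
    counts.columns.name = "sample_id"
    return AbundanceMatrix(level=level, counts=counts)


def size_factors(matrix: AbundanceMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only features with strictly positive counts in every sample enter
    the reference profile; raises ``ValueError("no common features")``
    when none exists.
    """
    x = matrix.counts.to_numpy(dtype=float)
    common = (x > 0).all(axis=1)
    if not common.any():
        raise ValueError("no common features: no feature is positive in all samples")
    logx = np.log(x[common])
    logref = logx.mean(axis=1)  # log geometric mean per feature
    logratios = logx - logref[:, None]
    logfac = np.median(logratios, axis=0)
    logfac = logfac - logfac.mean()  # geometric mean 1
    return pd.Series(np.exp(logfac), index=matrix.counts.columns, name="size_factor")


def normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample's counts by its median-of-ratios size factor."""
    sf = size_factors(matrix)
    return AbundanceMatrix(
        level=matrix.level, counts=matrix.counts.div(sf, axis=1), size_factors=sf
    )


def to_relative(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Convert to per-sample proportions (columns sum to 1)."""
    totals = matrix.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero column(s): {bad}")
    return AbundanceMatrix(level=matrix.level, counts=matrix.counts.div(totals, axis=1))


def write_matrix(matrix: AbundanceMatrix, tsv_path, meta_path=None) -> None:
    """Write the matrix as TSV (first column = feature label) plus an
    optional companion JSON with the level and size factors."""
    matrix.counts.to_csv(tsv_path, sep="\t")
    if meta_path is not None:
        meta = {
            "level": matrix.level,
            "size_factors": None
            if matrix.size_factors is None
            else {k: float(v) for k, v in matrix.size_factors.items()},
        }
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_matrix(tsv_path, level: str | None = None, meta_path=None) -> AbundanceMatrix:
    """Read a matrix TSV (and companion JSON, if given) back."""
    counts = pd.read_csv(tsv_path, sep="\t", index_col=0)
    sf = None
    if meta_path is not None:
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        level = meta.get("level", level)
        if meta.get("size_factors"):
            sf = pd.Series(meta["size_factors"]).reindex(counts.columns)
    return AbundanceMatrix(level=level or counts.index.name or "unknown",
                           counts=counts, size_factors=sf)
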