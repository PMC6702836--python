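"""Taxon-function linkage: redundancy spectrum, genus contributions,
dual-role partition.

Given a best-hit annotation table (functional mode) and the set of
differentially abundant enzymes, the linkage join connects each enzyme
to the bacterial genera whose reads carry it, on the same feature row
(read), yielding (enzyme, genus, group, hits) edges.  From the edges:

* the **redundancy spectrum** counts, for each enzyme, the number of
  distinct genera harboring it (pooled over groups) and bins the
  enzymes into {1, 2-4, 5-10, >=11} genus-count classes — the
  community's functional-redundancy profile;
* **genus contributions** give each genus's share of all linkage hits,
  its distinct-enzyme count and per-group (sex) hit split — the
  mirror-bar-plot table — plus top-k cumulative share and the fraction
  of genera carrying exactly one enzyme;
* the **dual-role partition** intersects the genera that are themselves
  differentially abundant with the genera providing differential
  functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default genus-count bins of the redundancy spectrum: an enzyme found in a
#: single genus, in 2-4, in 5-10, or in 11 or more genera.
DEFAULT_BINS = ((1, 1), (2, 4), (5, 10), (11, None))


def bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f"{lo}+"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


EDGE_COLUMNS = ["enzyme", "genus", "group", "hits"]


@dataclass
class LinkageResult:
    """Edge list linking differential enzymes to genera, per group."""

    edges: pd.DataFrame          # columns enzyme, genus, group, hits
    unassigned_hits: int = 0     # qualifying hits with unresolved genus

    def total_hits(self) -> int:
        return int(self.edges["hits"].sum()) if len(self.edges) else 0


def build_linkage_edges(
    table: pd.DataFrame,
    diff_enzymes,
    merge_groups: dict | None = None,
) -> LinkageResult:
    """Join differential enzymes to the genera harboring them.

    One edge per (enzyme in *diff_enzymes*, genus, group) with hits
    summed over qualifying records; genus and function must sit on the
    same feature row.  *merge_groups* optionally maps sample ids to
    merged group labels (e.g. pooling the two Ixodes species per sex);
    unmapped samples keep their own id.  Records with an unresolved
    genus are tallied separately, not emitted as edges.
    """
    diff = set(diff_enzymes)
    if not diff:
        raise ValueError("diff_enzymes must be non-empty")
    merge_groups = merge_groups or {}
    qualifying = table[table["func_l4"].isin(diff)]
    unassigned = int(qualifying.loc[qualifying["genus"].isna(), "hits"].sum())
    linked = qualifying[qualifying["genus"].notna()]
    if linked.empty:
        warnings.warn("no qualifying genus-resolved records; empty edge set")
        return LinkageResult(
            edges=pd.DataFrame(columns=EDGE_COLUMNS), unassigned_hits=unassigned
        )
    group = linked["sample_id"].map(lambda s: merge_groups.get(s, s))
    edges = (
        linked.assign(group=group)
        .groupby(["func_l4", "genus", "group"], sort=True)["hits"]
        .sum()
        .reset_index()
        .rename(columns={"func_l4": "enzyme"})
    )
    edges["hits"] = edges["hits"].astype(np.int64)
    return LinkageResult(edges=edges[EDGE_COLUMNS], unassigned_hits=unassigned)


@dataclass
class RedundancySpectrum:
    """Per-enzyme genus counts and their binned fractions."""

    per_enzyme: pd.Series        # enzyme -> number of distinct genera
    binned_fractions: dict       # bin label -> fraction of enzymes
    n_enzymes: int
    bins: tuple = DEFAULT_BINS

    def to_frame(self) -> pd.DataFrame:
        return self.per_enzyme.rename("n_genera").rename_axis("enzyme").reset_index()


def _edge_frame(edges) -> pd.DataFrame:
    df = edges.edges if isinstance(edges, LinkageResult) else pd.DataFrame(edges)
    if df.empty:
        raise ValueError("empty edge set")
    return df


def redundancy_spectrum(edges, bins=DEFAULT_BINS) -> RedundancySpectrum:
    """Number of distinct genera per enzyme, binned into redundancy classes.

    Genus counts pool all groups (one count per enzyme regardless of
    sex/species grouping); binned fractions are over distinct enzymes.
    """
    df = _edge_frame(edges)
    per_enzyme = df.groupby("enzyme")["genus"].nunique().sort_index()
    n = len(per_enzyme)
    fractions = {}
    for lo, hi in bins:
        upper = np.inf if hi is None else hi
        in_bin = ((per_enzyme >= lo) & (per_enzyme <= upper)).sum()
        fractions[bin_label(lo, hi)] = in_bin / n
    return RedundancySpectrum(
        per_enzyme=per_enzyme, binned_fractions=fractions, n_enzymes=n, bins=tuple(bins)
    )


@dataclass
class GenusContribution:
    """Per-genus hit shares and enzyme counts from a linkage edge set."""

    per_genus: pd.DataFrame          # total_hits, share_pct, n_enzymes, group cols
    top_k: int
    top_k_share_pct: float           # cumulative share of the k largest
    single_enzyme_fraction_pct: float  # % of genera with exactly one enzyme


def genus_contributions(edges, top_k: int = 5) -> GenusContribution:
    """Quantify each genus's contribution to the linkage hits.

    Hit share(g) = 100 * hits(g) / total hits; the summary reports the
    cumulative share of the *top_k* genera and the percentage of genera
    carrying exactly one distinct enzyme.  Per-group hit splits are kept
    as extra columns for mirror-plot output.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    df = _edge_frame(edges)
    total = df["hits"].sum()
    per_genus = df.groupby("genus").agg(
        total_hits=("hits", "sum"), n_enzymes=("enzyme", "nunique")
    )
    per_genus["share_pct"] = 100.0 * per_genus["total_hits"] / total
    splits = df.pivot_table(
        index="genus", columns="group", values="hits", aggfunc="sum", fill_value=0
    )
    splits.columns = [f"hits_{g}" for g in splits.columns]
    per_genus = per_genus.join(splits).sort_values(
        ["total_hits", "genus"], ascending=[False, True], kind="mergesort"
    )
    top_share = float(per_genus["share_pct"].iloc[:top_k].sum())
    single = float(100.0 * (per_genus["n_enzymes"] == 1).mean())
    return GenusContribution(
        per_genus=per_genus, top_k=top_k,
        top_k_share_pct=top_share, single_enzyme_fraction_pct=single,
    )


@dataclass
class DualRolePartition:
    """Genera split by taxonomic-only / functional-only / dual role."""

    taxonomic_only: frozenset
    functional_only: frozenset
    overlap: frozenset


def dual_role_partition(diff_taxa_genera, provider_genera) -> DualRolePartition:
    """Partition genera by differential-abundance vs function-provider role.

    ``overlap`` holds the dual-role genera (differentially abundant AND
    providers of differentially abundant functions); the two "only" sets
    are the respective set differences.
    """
    taxa = set(diff_taxa_genera)
    providers = set(provider_genera)
    return DualRolePartition(
        taxonomic_only=frozenset(taxa - providers),
        functional_only=frozenset(providers - taxa),
        overlap=frozenset(taxa & providers),
    )
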