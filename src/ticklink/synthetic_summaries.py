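"""Synthetic worked-example linkage tables for tick gut microbiomes.

These edge lists are synthetic stand-ins constructed to realize the
published per-genus summary statistics of the tick gut taxon-function
linkage analyses (they are not the underlying per-read data, which is
not redistributable here): for *Amblyomma variegatum* (AV) the top five
genera -- Haemophilus (29.3%), Aggregatibacter (22.8%), Proteus
(16.7%), Pasteurella (11.7%), Coxiella (9.4%) -- jointly hold 89.9% of
linkage hits among 23 genera, 13 of which (56.5%) carry a single
enzyme; for the pooled *Ixodes* species the top five genera --
Rickettsia (39.1%), Candidatus Protochlamydia (16.3%), Chlamydophila
(11.7%), Waddlia (10.9%), Chlamydia (9.8%) -- hold 87.8% of hits among
35 genera, while the single-enzyme fraction is quoted on a 31-genus
list (26/31 = 83.9%); the two Ixodes builders reflect that reported
split.

Hit counts are expressed in tenths of a percent of the total (total =
10,000) so the genus shares reproduce the quoted percentages exactly.
"""

from __future__ import annotations

import pandas as pd

from .linkage import EDGE_COLUMNS

_AV_TOP5 = [
    ("Haemophilus", 2930),
    ("Aggregatibacter", 2280),
    ("Proteus", 1670),
    ("Pasteurella", 1170),
    ("Coxiella", 940),
]

_IXODES_TOP5 = [
    ("Rickettsia", 3910),
    ("Candidatus Protochlamydia", 1630),
    ("Chlamydophila", 1170),
    ("Waddlia", 1090),
    ("Chlamydia", 980),
]


def _spread(total: int, n: int) -> list[int]:
    """Split *total* hits over n genera, each >= 1, deterministically."""
    base, extra = divmod(total, n)
    return [base + (1 if i < extra else 0) for i in range(n)]


def _build_edges(top5, n_genera: int, n_single: int, group: str) -> pd.DataFrame:
    """Edge list with the given top-5 hit counts over *n_genera* genera,
    of which exactly *n_single* carry one distinct enzyme.

    The top-5 genera and the other multi-enzyme genera get two enzymes
    each (one edge per enzyme); single-enzyme genera get one edge.
    """
    n_rest = n_genera - len(top5)
    rest_total = 10000 - sum(h for _, h in top5)
    rest_hits = _spread(rest_total, n_rest)
    rest_names = [f"Genus_{i + 1:02d}" for i in range(n_rest)]
    n_multi_rest = (n_genera - n_single) - len(top5)
    if n_multi_rest < 0:
        raise ValueError("more multi-enzyme genera than non-top genera")

    rows = []
    enzyme_no = 0

    def next_enzyme() -> str:
        nonlocal enzyme_no
        enzyme_no += 1
        return f"1.1.1.{enzyme_no}"

    for name, hits in top5:
        e1, e2 = next_enzyme(), next_enzyme()
        h1 = hits // 2
        rows.append((e1, name, group, h1))
        rows.append((e2, name, group, hits - h1))
    for i, (name, hits) in enumerate(zip(rest_names, rest_hits)):
        if i < n_multi_rest and hits >= 2:
            e1, e2 = next_enzyme(), next_enzyme()
            rows.append((e1, name, group, hits - 1))
            rows.append((e2, name, group, 1))
        else:
            rows.append((next_enzyme(), name, group, hits))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def synthetic_av_linkage_edges() -> pd.DataFrame:
    """AV worked example: 23 genera, top-5 share 89.9%, 13/23 single-enzyme."""
    return _build_edges(_AV_TOP5, n_genera=23, n_single=13, group="AV")


def synthetic_ixodes_linkage_edges() -> pd.DataFrame:
    """Ixodes worked example for genus shares: 35 genera, top-5 share 87.8%."""
    return _build_edges(_IXODES_TOP5, n_genera=35, n_single=30, group="Ix")


def synthetic_ixodes_single_enzyme_edges() -> pd.DataFrame:
    """Ixodes worked example for the single-enzyme fraction: 26 of 31 genera
    carry exactly one enzyme (83.9%)."""
    return _build_edges(_IXODES_TOP5, n_genera=31, n_single=26, group="Ix")
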