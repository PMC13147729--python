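"""Cross-study overlap counts, the eight-indicator "score of interest",
and biomarker selection.

Each candidate gene is scored by eight binary indicators:

    icr        linked to an imprint control region
    co         listed by at least three other published studies
    multi_cpg  carries >= 2 significant age-related DMCs
    top90      at least one DMC in the per-subgroup top-30 union
    ma         at least one DMC with |ΔM| > 0.1 per year
    op         opposite-direction change: a DMC increasing at a UM site
               or decreasing at an FM site
    is_island  at least one DMC at a CpG island
    pr         at least one DMC at a promoter region

The integer sum of the eight is the score of interest (0-8).  Selection
keeps ICR-linked ASD genes unconditionally and non-ICR ASD genes with a
score at or above a threshold (default 3), dropping pseudogenes and genes
whose only significant evidence sits on cross-reactive probes.
"""

from __future__ import annotations

from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_COLUMNS",
    "overlap_counts",
    "compute_indicators",
    "score_of_interest",
    "select_biomarkers",
    "load_published_scorecard",
]

INDICATOR_COLUMNS = ("icr", "co", "multi_cpg", "top90", "ma", "op",
                     "is_island", "pr")


def load_published_scorecard() -> pd.DataFrame:
    """Packaged scorecard of 28 ASD-linked (predicted) imprinted genes.

    Transcribed from a published sperm ageing study's ranking table: per
    gene, a representative probe, the eight binary indicators and the
    printed score.  Used as a worked example and regression fixture.
    """
    ref = resources.files("spermage.data") / "asd_imprinted_scorecard.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("gene")


def overlap_counts(gene_lists: dict[str, set[str] | list[str]]) -> dict:
    """How many genes appear in >= k of the supplied study lists.

    Returns ``at_least``: {k: n_genes for k = 1..N} and, for up to five
    lists, ``venn``: exact region counts keyed by frozenset of list names.
    """
    if len(gene_lists) < 2:
        raise ValueError("need at least 2 gene lists")
    sets = {name: {str(g).strip().upper() for g in genes}
            for name, genes in gene_lists.items()}
    union: set[str] = set().union(*sets.values())
    membership = pd.Series(
        {g: sum(g in s for s in sets.values()) for g in union})
    at_least = {k: int((membership >= k).sum())
                for k in range(1, len(sets) + 1)}
    out = {"at_least": at_least, "n_union": len(union)}
    if len(sets) <= 5:
        venn: dict[frozenset, int] = {}
        names = list(sets)
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inside = set.intersection(*(sets[n] for n in combo))
                outside = set().union(*(sets[n] for n in names
                                        if n not in combo)) if r < len(names) else set()
                venn[frozenset(combo)] = len(inside - outside)
        out["venn"] = venn
    return out


def compute_indicators(gene: str,
                       dmc_table: pd.DataFrame,
                       annotation: pd.DataFrame,
                       labels: pd.Series,
                       top90_probes: set | pd.Index,
                       icr_genes: set[str],
                       external_lists: dict[str, set[str]],
                       magnitude_threshold: float = 0.1,
                       co_min_lists: int = 3) -> pd.Series:
    """Evaluate the eight indicators for one gene.

    ``dmc_table`` must hold the gene's significant DMCs only (rows are the
    probes annotated to the gene), with ``slope_age`` present;
    ``annotation`` and ``labels`` are indexed by probe.
    """
    gene = gene.strip().upper()
    if dmc_table.empty:
        raise ValueError(f"gene {gene} has no significant DMC")
    probes = dmc_table.index
    ann = annotation.loc[probes]
    lab = labels.reindex(probes)
    slope = dmc_table["slope_age"]

    n_co = sum(gene in {g.upper() for g in lst}
               for lst in external_lists.values())
    opposite = ((lab == "UM") & (slope > 0)) | ((lab == "FM") & (slope < 0))
    return pd.Series({
        "icr": int(gene in {g.upper() for g in icr_genes}),
        "co": int(n_co >= co_min_lists),
        "multi_cpg": int(len(probes) >= 2),
        "top90": int(any(p in set(top90_probes) for p in probes)),
        "ma": int((slope.abs() > magnitude_threshold).any()),
        "op": int(opposite.any()),
        "is_island": int((ann["island_relation"] == "island").any()),
        "pr": int((ann["functional_region"] == "promoter").any()),
    }, name=gene)


def score_of_interest(indicators) -> int:
    """Sum of the eight binary indicators (0-8)."""
    if isinstance(indicators, (pd.Series, dict)):
        values = [indicators[c] for c in INDICATOR_COLUMNS]
    else:
        values = list(indicators)
        if len(values) != len(INDICATOR_COLUMNS):
            raise ValueError(f"expected {len(INDICATOR_COLUMNS)} indicators, "
                             f"got {len(values)}")
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("indicators must be binary 0/1")
    return int(arr.sum())


def select_biomarkers(scorecards: pd.DataFrame,
                      asd_genes: set[str],
                      icr_linked: set[str] | None = None,
                      pseudogenes: set[str] = frozenset(),
                      crossreactive_only: set[str] = frozenset(),
                      threshold: int = 3) -> list[str]:
    """Final biomarker list from per-gene scorecards.

    selected = (ASD ∩ ICR-linked) ∪ (ASD non-ICR with score >= threshold),
    minus pseudogenes, minus genes whose only significant DMCs are
    cross-reactive probes.  Ordered by score descending, then symbol.
    """
    cards = scorecards.copy()
    cards.index = cards.index.str.strip().str.upper()
    if "score" not in cards.columns:
        cards["score"] = [score_of_interest(cards.loc[g, list(INDICATOR_COLUMNS)])
                          for g in cards.index]
    asd = {g.strip().upper() for g in asd_genes}
    if icr_linked is None:
        icr_set = set(cards.index[cards["icr"] == 1])
    else:
        icr_set = {g.strip().upper() for g in icr_linked}
    pseudo = {g.strip().upper() for g in pseudogenes}
    cr_only = {g.strip().upper() for g in crossreactive_only}

    keep = []
    for gene in cards.index:
        if gene not in asd or gene in pseudo or gene in cr_only:
            continue
        if gene in icr_set or cards.at[gene, "score"] >= threshold:
            keep.append(gene)
    keep = sorted(set(keep),
                  key=lambda g: (-int(cards.at[g, "score"]), g))
    return keep
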