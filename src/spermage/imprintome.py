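"""Mapping of DMCs to imprinted genes and imprint control regions (ICRs).

Imprinted genes are expressed from a single parental allele; the governing
methylation marks sit in imprint control regions, whose catalogued set is
the "imprintome".  This module matches significant probes to a supplied
imprinted-gene list (by uppercased symbol) and to ICR intervals (BED
convention: half-open, with probe point positions compared directly
against the interval), and summarises hits by expressed allele and
parent-of-origin of the ICR methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "ImprintHits",
    "IcrHits",
    "map_genes",
    "map_icrs",
    "parent_of_origin_summary",
]

ORIGINS = ("paternal", "maternal", "unknown")
EXPRESSED_ALLELES = ("M", "P", "I")   # maternally/paternally expressed, isoform


def _explode_genes(annotation: pd.DataFrame, probes: pd.Index) -> pd.Series:
    """probe -> one row per annotated gene symbol, uppercased/stripped."""
    genes = annotation.loc[probes, "genes"].fillna("")
    exploded = genes.str.split(";").explode().str.strip().str.upper()
    return exploded[exploded != ""]


@dataclass
class ImprintHits:
    pairs: pd.DataFrame            # columns: probe_id, gene
    n_dmcs_total: int
    imprinted_meta: pd.DataFrame | None = None

    @property
    def n_dmcs_matched(self) -> int:
        return self.pairs["probe_id"].nunique()

    @property
    def n_genes_matched(self) -> int:
        return self.pairs["gene"].nunique()

    @property
    def pct_dmcs_matched(self) -> float:
        if self.n_dmcs_total == 0:
            return 0.0
        return 100.0 * self.n_dmcs_matched / self.n_dmcs_total

    def genes_by_expressed_allele(self) -> pd.Series:
        """Matched gene counts per expressed allele (M, P, I)."""
        if self.imprinted_meta is None or "expressed_allele" not in self.imprinted_meta:
            return pd.Series(dtype=int)
        matched = self.imprinted_meta.loc[
            self.imprinted_meta.index.intersection(
                pd.Index(self.pairs["gene"].unique()))]
        return (matched["expressed_allele"].value_counts()
                .reindex(EXPRESSED_ALLELES, fill_value=0))


def map_genes(dmcs: pd.DataFrame, annotation: pd.DataFrame,
              imprinted: pd.DataFrame | set[str]) -> ImprintHits:
    """Match DMC probes to imprinted genes by symbol.

    ``imprinted`` is either a set of symbols or a frame indexed by gene
    with columns ``status`` and ``expressed_allele``.  A probe annotated
    to multiple genes matches each of them; an empty intersection is a
    valid result.
    """
    if isinstance(imprinted, pd.DataFrame):
        meta = imprinted.copy()
        meta.index = meta.index.str.strip().str.upper()
        symbols = set(meta.index)
    else:
        meta = None
        symbols = {g.strip().upper() for g in imprinted}
    exploded = _explode_genes(annotation, dmcs.index)
    hits = exploded[exploded.isin(symbols)]
    pairs = (hits.rename("gene").rename_axis("probe_id").reset_index()
             .drop_duplicates())
    return ImprintHits(pairs=pairs, n_dmcs_total=len(dmcs),
                       imprinted_meta=meta)


@dataclass
class IcrHits:
    pairs: pd.DataFrame            # columns: probe_id, icr_index, gene, origin
    n_dmcs_total: int
    icrs: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_dmcs_matched(self) -> int:
        return self.pairs["probe_id"].nunique()

    @property
    def n_icrs_matched(self) -> int:
        return self.pairs["icr_index"].nunique()

    def summary_by_origin(self) -> pd.DataFrame:
        """DMC, ICR and nearest-gene counts per parent-of-origin class.

        A probe inside two overlapping ICRs contributes one DMC count per
        origin class it touches but a pairing for each ICR.
        """
        rows = {}
        for origin in ORIGINS:
            sub = self.pairs[self.pairs["origin"] == origin]
            rows[origin] = {
                "n_dmcs": sub["probe_id"].nunique(),
                "n_icrs": sub["icr_index"].nunique(),
                "n_genes": sub["gene"].nunique(),
            }
        out = pd.DataFrame(rows).T
        out.loc["total"] = [
            self.n_dmcs_matched, self.n_icrs_matched,
            self.pairs["gene"].nunique(),
        ]
        return out.astype(int)


def map_icrs(dmcs: pd.DataFrame, annotation: pd.DataFrame,
             icrs: pd.DataFrame, flank: int = 0) -> IcrHits:
    """Intersect DMC probe positions with ICR intervals.

    A probe at position p hits the ICR [start, end) iff start <= p < end:
    the point position is compared against the half-open interval, so the
    end coordinate itself is never a hit.  ``flank`` widens every interval
    by that many bases on both sides ("adjacent to an ICR" with a
    configurable window, default 0).
    """
    required = {"chr", "pos"}
    missing_cols = required - set(annotation.columns)
    if missing_cols:
        raise ValueError(f"annotation lacks columns {sorted(missing_cols)}")
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(icrs.itertuples(index=False)):
        chrom = str(row.chr).removeprefix("chr")
        trees.setdefault(chrom, IntervalTree()).addi(
            row.start - flank, row.end + flank, i)

    ann = annotation.loc[dmcs.index]
    records = []
    for probe_id, chrom, pos in zip(ann.index, ann["chr"], ann["pos"]):
        tree = trees.get(str(chrom).removeprefix("chr"))
        if tree is None:
            continue
        for iv in tree[int(pos)]:              # start <= pos < end
            icr = icrs.iloc[iv.data]
            records.append((probe_id, iv.data, icr["gene"], icr["origin"]))
    pairs = pd.DataFrame(records,
                         columns=["probe_id", "icr_index", "gene", "origin"])
    return IcrHits(pairs=pairs, n_dmcs_total=len(dmcs), icrs=icrs)


def parent_of_origin_summary(gene_hits: ImprintHits,
                             icr_hits: IcrHits | None = None) -> pd.DataFrame:
    """Gene counts by expressed allele, with ICR origins where available.

    One row per matched gene: expressed allele (if known), the set of ICR
    origins the gene's DMCs hit, and a ``multi_origin`` flag for genes
    whose DMCs fall in ICRs of more than one parent-of-origin class.
    """
    genes = pd.Index(sorted(gene_hits.pairs["gene"].unique()), name="gene")
    out = pd.DataFrame(index=genes)
    out["n_dmcs"] = gene_hits.pairs.groupby("gene")["probe_id"].nunique()
    if gene_hits.imprinted_meta is not None and "expressed_allele" in gene_hits.imprinted_meta:
        out["expressed_allele"] = gene_hits.imprinted_meta[
            "expressed_allele"].reindex(genes)
    if icr_hits is not None and len(icr_hits.pairs):
        origin_sets = icr_hits.pairs.groupby("gene")["origin"].agg(
            lambda s: ";".join(sorted(set(s))))
        out["icr_origins"] = origin_sets.reindex(genes).fillna("")
        out["multi_origin"] = out["icr_origins"].str.contains(";")
    return out
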