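"""Methylation-subgroup assignment, Δβ back-transformation and summaries.

CpG sites are partitioned by their mean β across subjects: unmethylated
(UM, mean β < 0.20), hemi-methylated (HM, 0.20 ≤ mean β ≤ 0.80, boundaries
inclusive) and fully methylated (FM, mean β > 0.80).  Regression effects
estimated on the M scale are mapped back to the β scale with the intercept
method:

    Δβ = 2^(M0+ΔM) / (1 + 2^(M0+ΔM)) − 2^M0 / (1 + 2^M0)

where M0 is the probe's baseline M (by default its observed mean M across
subjects) and ΔM the fitted slope per year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arraydata import m_to_beta

__all__ = [
    "assign_subgroups",
    "delta_beta_from_m",
    "summarize_dmcs",
    "crosstab_genomic",
    "select_top",
]

SUBGROUPS = ("UM", "HM", "FM")
UM_UPPER = 0.20
FM_LOWER = 0.80


def assign_subgroups(mean_betas) -> pd.Series:
    """Three-way UM/HM/FM partition of probes by mean β (HM inclusive)."""
    values = pd.Series(mean_betas, dtype=float)
    arr = values.to_numpy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("mean β-values must lie within [0, 1]")
    labels = np.where(arr < UM_UPPER, "UM",
                      np.where(arr > FM_LOWER, "FM", "HM"))
    return pd.Series(pd.Categorical(labels, categories=SUBGROUPS),
                     index=values.index, name="subgroup")


def delta_beta_from_m(m0, delta_m):
    """Intercept-method back-transform of an M-scale effect to the β scale."""
    m0 = np.asarray(m0, dtype=float)
    delta_m = np.asarray(delta_m, dtype=float)
    if not (np.all(np.isfinite(m0)) and np.all(np.isfinite(delta_m))):
        raise ValueError("m0 and delta_m must be finite")
    out = m_to_beta(m0 + delta_m) - m_to_beta(m0)
    return float(out) if out.ndim == 0 else out


def summarize_dmcs(fits: pd.DataFrame, labels: pd.Series,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-subgroup and overall DMC counts and percentages.

    ``fits`` needs columns ``slope_age``, ``p_adj`` (or a precomputed
    ``significant`` flag).  Output rows all/UM/HM/FM carry: n_sites,
    n_dmcs, n_negative, n_positive, pct_of_dmcs (share of all DMCs),
    pct_of_sites (DMC rate within the row's sites), and the direction
    percentages among the row's DMCs.  Percentages are full precision;
    round only at report time.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels = labels.reindex(fits.index)
    if labels.isna().any():
        raise ValueError("labels must cover all probes in fits")
    sig = (fits["significant"] if "significant" in fits
           else fits["p_adj"] < alpha).astype(bool)
    neg = fits["slope_age"] < 0

    def row(mask: pd.Series) -> dict:
        n_sites = int(mask.sum())
        d = sig & mask
        n_dmcs = int(d.sum())
        n_negative = int((d & neg).sum())
        n_positive = n_dmcs - n_negative
        total_dmcs = int(sig.sum())
        return {
            "n_sites": n_sites, "n_dmcs": n_dmcs,
            "n_negative": n_negative, "n_positive": n_positive,
            "pct_of_dmcs": 100.0 * n_dmcs / total_dmcs if total_dmcs else 0.0,
            "pct_of_sites": 100.0 * n_dmcs / n_sites if n_sites else 0.0,
            "pct_negative": 100.0 * n_negative / n_dmcs if n_dmcs else 0.0,
            "pct_positive": 100.0 * n_positive / n_dmcs if n_dmcs else 0.0,
        }

    everything = pd.Series(True, index=fits.index)
    out = {"all": row(everything)}
    for sg in SUBGROUPS:
        out[sg] = row(labels == sg)
    return pd.DataFrame(out).T.astype(
        {c: int for c in ("n_sites", "n_dmcs", "n_negative", "n_positive")})


def crosstab_genomic(dmcs: pd.DataFrame, annotation: pd.DataFrame,
                     labels: pd.Series | None = None) -> dict[str, pd.DataFrame]:
    """Cross-tabulate DMCs by genomic context and direction of change.

    Returns ``island``: counts by island relation × direction (with the
    ∞-safe negative:positive ratio; NaN where the positive count is 0) and
    ``functional``: counts by functional region.  When subgroup labels are
    given, per-subgroup island tables are added under ``island_UM`` etc.
    Probes annotated to several functional regions are expected to carry
    the single category ``multiple`` and are therefore never double-counted.
    """
    missing = dmcs.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"DMCs missing annotation: {list(missing[:10])}")
    ann = annotation.loc[dmcs.index]
    direction = np.where(dmcs["slope_age"] < 0, "negative", "positive")

    def island_table(idx) -> pd.DataFrame:
        tab = pd.crosstab(ann.loc[idx, "island_relation"],
                          pd.Series(direction, index=dmcs.index).loc[idx])
        for col in ("negative", "positive"):
            if col not in tab:
                tab[col] = 0
        from .arraydata import ISLAND_RELATIONS

        tab = tab.reindex(ISLAND_RELATIONS, fill_value=0)[
            ["negative", "positive"]]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = tab["negative"] / tab["positive"]
        tab["neg_pos_ratio"] = ratio.replace([np.inf], np.nan)
        return tab

    out = {"island": island_table(dmcs.index)}
    func = ann["functional_region"].value_counts()
    out["functional"] = func.rename_axis("functional_region").to_frame("n_dmcs")
    if labels is not None:
        lab = labels.reindex(dmcs.index)
        for sg in SUBGROUPS:
            out[f"island_{sg}"] = island_table(dmcs.index[lab == sg])
    return out


def select_top(dmcs: pd.DataFrame, labels: pd.Series,
               k_per_subgroup: int = 30,
               magnitude_threshold: float = 0.1) -> pd.DataFrame:
    """Top-k most significant DMCs per subgroup; their union is the top 90.

    Ranking is by adjusted p ascending with ties broken by raw p then
    probe id (stable).  Rows with |ΔM| strictly above the magnitude
    threshold are flagged ``high_magnitude``.  If a subgroup has fewer than
    k significant rows, all of them are returned (with a warning).
    """
    if k_per_subgroup < 1:
        raise ValueError("k_per_subgroup must be >= 1")
    labels = labels.reindex(dmcs.index)
    sig = dmcs[(dmcs["significant"] if "significant" in dmcs
                else dmcs["p_adj"] < 0.05).astype(bool)]
    pieces = []
    for sg in SUBGROUPS:
        sub = sig[labels.loc[sig.index] == sg].copy()
        sub = sub.assign(_pid=sub.index.astype(str)).sort_values(
            ["p_adj", "p_raw", "_pid"], kind="stable").drop(columns="_pid")
        if len(sub) < k_per_subgroup:
            import warnings

            warnings.warn(f"subgroup {sg}: only {len(sub)} significant rows "
                          f"(< k={k_per_subgroup})", stacklevel=2)
        sub = sub.head(k_per_subgroup)
        sub.insert(0, "subgroup", sg)
        pieces.append(sub)
    top = pd.concat(pieces)
    top["high_magnitude"] = top["slope_age"].abs() > magnitude_threshold
    return top
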