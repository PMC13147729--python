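"""Pipeline orchestration: run every analysis stage from a single config.

The stages mirror the study workflow: (1) global methylation by age,
(2) per-CpG EWAS with moderated statistics and BH correction,
(3) UM/HM/FM subgrouping, (4) per-subgroup top lists, (5) genomic
allocation cross-tabs, (6) imprinted-gene and ICR mapping, (7) cross-study
overlap counts, (8) indicator scoring of candidate genes, (9) biomarker
selection, (10) plot-ready table export.  All outputs are CSV; a manifest
records the configuration, seed and package version for exact reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arraydata import Dataset, FilterPolicy, beta_to_m, filter_probes, load_dataset
from .biomarker import INDICATOR_COLUMNS, compute_indicators, overlap_counts, \
    score_of_interest, select_biomarkers
from .classify import assign_subgroups, crosstab_genomic, delta_beta_from_m, \
    select_top, summarize_dmcs
from .ewas import global_methylation_tests, run_ewas
from .imprintome import map_genes, map_icrs, parent_of_origin_summary
from .synthetic import GeneratorConfig, make_annotation, make_beta_matrix, \
    make_covariates

logger = logging.getLogger("spermage")

__all__ = ["PipelineConfig", "run_pipeline", "export_plot_tables"]

_CHR_ORDER = [str(c) for c in range(1, 23)] + ["X"]


@dataclass
class PipelineConfig:
    """Everything a run needs; either file paths or a synthetic block."""

    beta_path: str | None = None
    covariate_path: str | None = None
    annotation_path: str | None = None
    icr_path: str | None = None
    detection_p_path: str | None = None
    gene_list_paths: dict = field(default_factory=dict)
    imprinted_gene_list: str | None = None
    asd_gene_list: str | None = None
    pseudogene_list: str | None = None
    external_study_lists: dict = field(default_factory=dict)
    synthetic: dict | None = None
    alpha: float = 0.05
    k_top: int = 30
    magnitude_threshold: float = 0.1
    filter_policy: dict = field(default_factory=dict)
    outdir: str = "spermage_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.synthetic is None and self.beta_path is None:
            raise ValueError("config needs input paths or a synthetic block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _synthetic_dataset(config: PipelineConfig) -> tuple[Dataset, pd.DataFrame]:
    params = dict(config.synthetic or {})
    params.setdefault("seed", config.seed)
    gen = GeneratorConfig(**params)
    cov = make_covariates(config=gen)
    ann, icrs = make_annotation(config=gen)
    beta, truth = make_beta_matrix(ann, cov, gen)
    imprinted = set(icrs["gene"])
    ds = Dataset(beta=beta, covariates=cov, annotation=ann, icrs=icrs,
                 gene_lists={"imprinted": imprinted})
    return ds, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the bundle of result tables.

    Writes every table as CSV under ``config.outdir`` together with
    ``manifest.json``; a stage failure aborts with the stage named in the
    exception.
    """
    os.makedirs(config.outdir, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    bundle: dict = {}
    stage = "load"
    try:
        if config.synthetic is not None:
            ds, truth = _synthetic_dataset(config)
            bundle["truth"] = truth
        else:
            gene_lists = dict(config.gene_list_paths)
            for name, key in (("imprinted", "imprinted_gene_list"),
                              ("asd", "asd_gene_list"),
                              ("pseudogenes", "pseudogene_list")):
                p = getattr(config, key)
                if p:
                    gene_lists[name] = p
            gene_lists.update(config.external_study_lists)
            ds = load_dataset(config.beta_path, config.covariate_path,
                              config.annotation_path, config.icr_path,
                              gene_lists, config.detection_p_path)
        logger.info("loaded %d probes x %d subjects",
                    ds.beta.shape[0], ds.beta.shape[1])

        stage = "filter"
        policy = FilterPolicy(**config.filter_policy)
        beta, filt_report = filter_probes(ds.beta, ds.detection_p,
                                          ds.annotation, policy)
        bundle["filter_report"] = filt_report

        stage = "subgroups"
        mean_beta = beta.mean(axis=1)
        labels = assign_subgroups(mean_beta)
        bundle["subgroups"] = labels

        stage = "global"
        bundle["global"] = global_methylation_tests(beta, ds.covariates,
                                                    labels)

        stage = "ewas"
        m = beta_to_m(beta)
        table, prior = run_ewas(m, ds.covariates, alpha=config.alpha)
        table["delta_beta"] = delta_beta_from_m(table["mean_m"],
                                                table["slope_age"])
        bundle["fits"] = table
        bundle["prior"] = prior
        logger.info("EWAS: %d/%d significant at FDR<%g",
                    int(table["significant"].sum()), len(table), config.alpha)

        stage = "summaries"
        bundle["subgroup_summary"] = summarize_dmcs(table, labels,
                                                    config.alpha)
        dmcs = table[table["significant"]]
        bundle["top"] = select_top(table, labels, config.k_top,
                                   config.magnitude_threshold)
        bundle["crosstabs"] = crosstab_genomic(dmcs, ds.annotation, labels)

        stage = "imprintome"
        imprinted = ds.gene_lists.get("imprinted", set())
        gene_hits = map_genes(dmcs, ds.annotation, imprinted)
        bundle["imprint_hits"] = gene_hits
        if ds.icrs is not None:
            icr_hits = map_icrs(dmcs, ds.annotation, ds.icrs)
            bundle["icr_hits"] = icr_hits
            bundle["origin_summary"] = parent_of_origin_summary(gene_hits,
                                                                icr_hits)
        else:
            icr_hits = None

        stage = "overlap"
        study_lists = {k: v for k, v in ds.gene_lists.items()
                       if k not in ("imprinted", "asd", "pseudogenes")}
        if len(study_lists) >= 2:
            bundle["overlap"] = overlap_counts(study_lists)

        stage = "scoring"
        icr_genes = (set(icr_hits.pairs["gene"]) if icr_hits is not None
                     and len(icr_hits.pairs) else set())
        external = {k: v for k, v in ds.gene_lists.items()
                    if k not in ("imprinted", "asd", "pseudogenes")}
        top90 = set(bundle["top"].index)
        gene_probe = gene_hits.pairs.groupby("gene")["probe_id"].agg(list)
        cards = []
        for gene, probes in gene_probe.items():
            sub = dmcs.loc[[p for p in probes if p in dmcs.index]]
            if sub.empty:
                continue
            vec = compute_indicators(gene, sub, ds.annotation, labels,
                                     top90, icr_genes, external,
                                     config.magnitude_threshold)
            vec["score"] = score_of_interest(vec)
            cards.append(vec)
        scorecards = (pd.DataFrame(cards).rename_axis("gene")
                      if cards else pd.DataFrame(
                          columns=[*INDICATOR_COLUMNS, "score"]))
        bundle["scorecards"] = scorecards

        stage = "selection"
        asd = ds.gene_lists.get("asd", set(scorecards.index))
        pseudo = ds.gene_lists.get("pseudogenes", set())
        cr_only = set()
        if len(scorecards) and "crossreactive" in ds.annotation:
            for gene, probes in gene_probe.items():
                probes = [p for p in probes if p in dmcs.index]
                if probes and ds.annotation.loc[probes, "crossreactive"].all():
                    cr_only.add(gene)
        if len(scorecards):
            bundle["biomarkers"] = select_biomarkers(
                scorecards, asd, None, pseudo, cr_only, threshold=3)
        else:
            bundle["biomarkers"] = []

        stage = "export"
        _write_bundle(bundle, ds, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
    return bundle


def export_plot_tables(fits: pd.DataFrame, annotation: pd.DataFrame,
                       outdir, alpha: float = 0.05,
                       imprinted_genes: set[str] = frozenset()) -> dict[str, str]:
    """Write volcano- and Miami-plot ready CSVs.

    volcano: probe_id, delta_beta, neg_log10_p_adj, significant,
    highlight_gene.  miami: chr (ordered 1..22, X), pos, delta_beta,
    direction, imprinted_flag.
    """
    if "delta_beta" not in fits.columns:
        raise ValueError("fits table lacks delta_beta; back-transform first")
    os.makedirs(outdir, exist_ok=True)
    ann = annotation.reindex(fits.index)
    imprinted_upper = {g.upper() for g in imprinted_genes}

    def first_imprinted(genes: str) -> str:
        for g in str(genes).split(";"):
            if g.strip().upper() in imprinted_upper:
                return g.strip().upper()
        return ""

    highlight = ann["genes"].fillna("").map(first_imprinted) \
        if "genes" in ann else ""
    with np.errstate(divide="ignore"):
        neg_log = -np.log10(fits["p_adj"].clip(lower=1e-300))
    volcano = pd.DataFrame({
        "probe_id": fits.index,
        "delta_beta": fits["delta_beta"],
        "neg_log10_p_adj": neg_log,
        "significant": fits.get("significant", fits["p_adj"] < alpha),
        "highlight_gene": highlight,
    }).reset_index(drop=True)

    miami = pd.DataFrame({
        "chr": ann["chr"].astype(str),
        "pos": ann["pos"],
        "delta_beta": fits["delta_beta"].to_numpy(),
        "direction": np.where(fits["delta_beta"] >= 0, "up", "down"),
        "imprinted_flag": (pd.Series(highlight, index=fits.index) != "")
        .astype(int).to_numpy(),
    })
    miami["chr"] = pd.Categorical(miami["chr"], categories=_CHR_ORDER,
                                  ordered=True)
    miami = miami.sort_values(["chr", "pos"]).reset_index(drop=True)

    paths = {"volcano": os.path.join(outdir, "volcano.csv"),
             "miami": os.path.join(outdir, "miami.csv")}
    volcano.to_csv(paths["volcano"], index=False)
    miami.to_csv(paths["miami"], index=False)
    return paths


def _write_bundle(bundle: dict, ds: Dataset, config: PipelineConfig) -> None:
    out = config.outdir
    bundle["fits"].to_csv(os.path.join(out, "ewas_full.csv"))
    rounded = bundle["fits"].copy()
    for col in ("slope_age", "mod_t", "delta_beta", "mean_m", "mean_beta"):
        if col in rounded:
            rounded[col] = rounded[col].map(lambda v: float(f"{v:.4g}"))
    rounded.to_csv(os.path.join(out, "ewas.csv"))
    bundle["subgroup_summary"].round(2).to_csv(
        os.path.join(out, "subgroup_summary.csv"))
    bundle["top"].to_csv(os.path.join(out, "top90.csv"))
    bundle["global"].to_csv(os.path.join(out, "global_methylation.csv"))
    for name, tab in bundle["crosstabs"].items():
        tab.to_csv(os.path.join(out, f"crosstab_{name}.csv"))
    if "origin_summary" in bundle:
        bundle["origin_summary"].to_csv(
            os.path.join(out, "imprint_origin_summary.csv"))
    bundle["scorecards"].to_csv(os.path.join(out, "scorecards.csv"))
    pd.Series(bundle["biomarkers"], name="gene").to_csv(
        os.path.join(out, "biomarkers.csv"), index=False)
    export_plot_tables(bundle["fits"], ds.annotation, out, config.alpha,
                       ds.gene_lists.get("imprinted", set()))

    cfg = dataclasses.asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"config": cfg, "config_sha256": digest,
                "seed": config.seed, "spermage_version": __version__,
                "n_probes": int(bundle["fits"].shape[0]),
                "n_significant": int(bundle["fits"]["significant"].sum())}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
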