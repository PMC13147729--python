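"""Synthetic 450K-like methylation data with known planted age effects.

The generator emulates the study conditions of a sperm ageing cohort:
63 men aged 18–35 (mean ≈ 25.5), overweight (BMI ≥ 25) more likely at
older ages (marginal rate ≈ 0.318), fertility-clinic patients more likely
at younger ages (marginal rate ≈ 0.238).  Probes fall into three
methylation archetypes — unmethylated (UM), hemi-methylated (HM), fully
methylated (FM) — mixed at the array-wide proportions 46.95 / 10.03 /
43.02 %.  A configurable fraction of probes carries a linear age effect
planted additively on the M (log2-odds) scale; the sign of each effect is
drawn per subgroup, mostly negative (hypomethylation with age).

Every draw flows from a single master seed through named substreams, so a
fixture set is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .arraydata import (
    FUNCTIONAL_REGIONS,
    ISLAND_RELATIONS,
    beta_to_m,
    m_to_beta,
    write_icr_bed,
)

__all__ = [
    "GeneratorConfig",
    "make_covariates",
    "make_annotation",
    "make_beta_matrix",
    "write_fixture",
]

_CHROMS = [str(c) for c in range(1, 23)] + ["X"]


@dataclass
class GeneratorConfig:
    """Tunable knobs of the simulator; defaults are the study conditions.

    subgroup_weights: UM/HM/FM mixture proportions of probe baselines.
    beta_archetypes: per-subgroup (mean, concentration) of a beta
        distribution on (0,1) from which probe baseline β is drawn.
    effect_fraction: fraction of probes given a true linear age effect.
    effect_size_mean: mean |ΔM| per year of planted effects (gamma law,
        shape 2, so magnitudes spread over roughly 0.01–0.15 M/yr).
    direction_probs: per-subgroup probability a planted effect is negative.
    residual_sd_m: subject-level Gaussian noise sd on the M scale.
    """

    n_subjects: int = 63
    n_probes: int = 50_000
    subgroup_weights: tuple[float, float, float] = (0.4695, 0.1003, 0.4302)
    beta_archetypes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "UM": (0.08, 50.0), "HM": (0.50, 8.0), "FM": (0.92, 50.0),
        })
    effect_fraction: float = 0.03
    effect_size_mean: float = 0.06
    effect_size_dist: str = "gamma"   # "gamma" (shape 2) or "fixed"
    direction_probs: dict[str, float] = field(
        default_factory=lambda: {"UM": 0.9184, "HM": 0.7473, "FM": 0.5327})
    residual_sd_m: float = 0.30
    # covariate model
    age_range: tuple[int, int] = (18, 35)
    age_mean_target: float = 25.48
    overweight_rate: float = 0.318
    overweight_age_coef: float = 0.25
    patient_rate: float = 0.238
    patient_age_coef: float = -0.35
    abnormal_sperm_rate: float = 0.254
    # annotation model
    island_props: tuple[float, float, float, float] = (
        0.3091, 0.2331, 0.0950, 0.3628)  # island, shore, shelf, open sea
    region_props: tuple[float, ...] = (0.20, 0.10, 0.05, 0.31, 0.04, 0.25, 0.05)
    snp_rate: float = 0.15
    crossreactive_rate: float = 0.06
    n_genes: int = 2000
    n_imprinted_genes: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.subgroup_weights, dtype=float)
        if w.shape != (3,) or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("subgroup_weights must be 3 non-negative "
                             "proportions summing to 1")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")
        for sg, p in self.direction_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"direction_probs[{sg}] must be in [0, 1]")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (lo, hi) with lo <= hi")

def _stream(config: GeneratorConfig, name: str) -> np.random.Generator:
    """Named substream of the master seed (crc32 keeps it process-stable)."""
    import zlib

    return np.random.default_rng([config.seed, zlib.crc32(name.encode())])


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_covariates(n_subjects: int | None = None,
                    config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw a subject table with age-linked BMI and patient status.

    Ages are discrete uniform on the configured range, resampled (up to 200
    tries, keeping the best) until the sample mean is within 0.5 years of
    the target.  Overweight and patient status follow logistic links in
    centred age whose intercepts hit the configured marginal rates.
    """
    config = config or GeneratorConfig()
    n = int(n_subjects if n_subjects is not None else config.n_subjects)
    if n < 3:
        raise ValueError("n_subjects must be >= 3")
    lo, hi = config.age_range
    rng = _stream(config, "covariates")

    best_ages, best_err = None, np.inf
    for _ in range(200):
        ages = rng.integers(lo, hi + 1, size=n)
        err = abs(ages.mean() - config.age_mean_target)
        if err < best_err:
            best_ages, best_err = ages, err
        if err <= 0.5 or lo == hi:
            break
    ages = best_ages.astype(float)
    centred = ages - ages.mean()

    def calibrated_probs(target: float, coef: float) -> np.ndarray:
        # intercept solved so the marginal over the realized ages hits the
        # target exactly (sigmoid averaging would otherwise inflate it)
        from scipy.optimize import brentq

        if coef == 0.0 or np.ptp(centred) == 0:
            return np.full(n, target)
        b0 = brentq(lambda b: _logistic(b + coef * centred).mean() - target,
                    -30.0, 30.0)
        return _logistic(b0 + coef * centred)

    p_over = calibrated_probs(config.overweight_rate,
                              config.overweight_age_coef)
    overweight = rng.random(n) < p_over
    bmi = np.where(
        overweight,
        np.clip(rng.normal(28.0, 2.5, n), 25.0, 45.0),
        np.clip(rng.normal(22.5, 1.8, n), 18.0, 24.9),
    )

    p_pat = calibrated_probs(config.patient_rate, config.patient_age_coef)
    patient = (rng.random(n) < p_pat).astype(int)
    sperm_quality = (rng.random(n) < config.abnormal_sperm_rate).astype(int)

    return pd.DataFrame(
        {"age": ages, "bmi": np.round(bmi, 1), "patient": patient,
         "sperm_quality": sperm_quality},
        index=pd.Index([f"S{i:03d}" for i in range(1, n + 1)],
                       name="subject_id"),
    )


def make_annotation(n_probes: int | None = None,
                    config: GeneratorConfig | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a probe annotation table and a matching ICR interval set.

    Returns ``(annotation, icrs)``.  Positions are uniform per chromosome
    (probe densities are not calibrated).  A subset of genes is tagged
    imprinted; each imprinted gene gets one ICR interval that covers the
    positions of the probes annotated to it, so generated overlaps are
    guaranteed to be recoverable by interval lookup.
    """
    config = config or GeneratorConfig()
    n = int(n_probes if n_probes is not None else config.n_probes)
    if n < 1:
        raise ValueError("n_probes must be >= 1")
    rng = _stream(config, "annotation")

    probe_ids = [f"cg{i:08d}" for i in range(1, n + 1)]
    chroms = rng.choice(_CHROMS, size=n)
    pos = rng.integers(1, 150_000_000, size=n)
    island = rng.choice(ISLAND_RELATIONS, size=n, p=config.island_props)
    region = rng.choice(FUNCTIONAL_REGIONS, size=n, p=config.region_props)
    snp = rng.random(n) < config.snp_rate
    crossreactive = rng.random(n) < config.crossreactive_rate

    gene_pool = np.array([f"GENE{i:04d}" for i in range(1, config.n_genes + 1)])
    n_gene_tags = rng.choice([0, 1, 2], size=n, p=[0.25, 0.65, 0.10])
    genes = []
    for k in n_gene_tags:
        genes.append(";".join(rng.choice(gene_pool, size=k, replace=False)))

    ann = pd.DataFrame(
        {"chr": chroms, "pos": pos, "island_relation": island,
         "functional_region": region, "genes": genes,
         "snp": snp, "crossreactive": crossreactive},
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # ICRs: one interval per imprinted gene, spanning that gene's probes
    n_imp = min(config.n_imprinted_genes, config.n_genes)
    imprinted = rng.choice(gene_pool, size=n_imp, replace=False)
    origins = rng.choice(["paternal", "maternal", "unknown"], size=n_imp,
                         p=[0.25, 0.30, 0.45])
    exploded = ann["genes"].str.split(";").explode()
    icr_rows = []
    for gene, origin in zip(imprinted, origins):
        hits = exploded.index[exploded == gene]
        if len(hits) > 0:
            sub = ann.loc[hits]
            chrom = sub["chr"].iloc[0]
            sub = sub[sub["chr"] == chrom]
            start = int(sub["pos"].min()) - 1          # BED 0-based
            end = int(sub["pos"].max()) + 500
        else:
            chrom = str(rng.choice(_CHROMS))
            start = int(rng.integers(0, 149_000_000))
            end = start + int(rng.integers(500, 5000))
        icr_rows.append((chrom, start, end, gene, origin))
    icrs = pd.DataFrame(icr_rows,
                        columns=["chr", "start", "end", "gene", "origin"])
    return ann, icrs


def make_beta_matrix(annotation: pd.DataFrame,
                     covariates: pd.DataFrame,
                     config: GeneratorConfig | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the β matrix and the ground-truth table of planted effects.

    Per probe: subgroup ~ subgroup_weights; baseline β ~ subgroup beta
    archetype; baseline M = logit2(β).  For planted probes the subject-level
    value is ``M = baseline + ΔM·(age − mean age) + N(0, residual_sd_m)``,
    then mapped back with the base-2 logistic, so β is strictly inside
    (0, 1) by construction.
    """
    config = config or GeneratorConfig()
    if annotation.empty or covariates.empty:
        raise ValueError("annotation and covariates must be non-empty")
    if annotation.index.duplicated().any():
        raise ValueError("duplicate probe ids in annotation")
    rng = _stream(config, "beta")

    n_probes = annotation.shape[0]
    n_subj = covariates.shape[0]
    sg_names = np.array(["UM", "HM", "FM"])
    sg_idx = rng.choice(3, size=n_probes, p=np.asarray(config.subgroup_weights))
    subgroup = sg_names[sg_idx]

    baseline_beta = np.empty(n_probes)
    for k, name in enumerate(sg_names):
        mean, conc = config.beta_archetypes[name]
        mask = sg_idx == k
        baseline_beta[mask] = rng.beta(mean * conc, (1 - mean) * conc,
                                       mask.sum())
    baseline_m = np.asarray(beta_to_m(baseline_beta))

    planted = rng.random(n_probes) < config.effect_fraction
    if config.effect_size_dist == "gamma":
        magnitude = rng.gamma(2.0, config.effect_size_mean / 2.0,
                              size=n_probes)
    elif config.effect_size_dist == "fixed":
        magnitude = np.full(n_probes, config.effect_size_mean)
    else:
        raise ValueError(f"unknown effect_size_dist "
                         f"{config.effect_size_dist!r}")
    neg_prob = np.array([config.direction_probs[s] for s in subgroup])
    sign = np.where(rng.random(n_probes) < neg_prob, -1.0, 1.0)
    delta_m = np.where(planted, sign * magnitude, 0.0)

    ages = covariates["age"].to_numpy(float)
    centred_age = ages - ages.mean()
    m = (baseline_m[:, None]
         + delta_m[:, None] * centred_age[None, :]
         + rng.normal(0.0, config.residual_sd_m, size=(n_probes, n_subj)))
    beta = m_to_beta(m)

    beta_df = pd.DataFrame(beta, index=annotation.index,
                           columns=covariates.index)
    truth = pd.DataFrame(
        {"planted": planted, "true_delta_m_per_year": delta_m,
         "true_subgroup": subgroup},
        index=annotation.index,
    )
    return beta_df, truth


def write_fixture(outdir, config: GeneratorConfig | None = None) -> dict[str, str]:
    """Generate a full fixture set and write it to ``outdir``.

    Emits β-matrix TSV, covariate CSV, annotation CSV, ICR BED, an
    imprinted-gene list, a truth CSV and a small JSON manifest recording
    the configuration.  Returns the path of each file by role.
    """
    config = config or GeneratorConfig()
    cov = make_covariates(config=config)
    ann, icrs = make_annotation(config=config)
    if ann.empty:
        raise ValueError("refusing to write an empty fixture")
    beta, truth = make_beta_matrix(ann, cov, config)

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "beta": os.path.join(outdir, "beta.tsv"),
        "covariates": os.path.join(outdir, "covariates.csv"),
        "annotation": os.path.join(outdir, "annotation.csv"),
        "icrs": os.path.join(outdir, "icrs.bed"),
        "imprinted_genes": os.path.join(outdir, "imprinted_genes.txt"),
        "truth": os.path.join(outdir, "truth.csv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    beta.to_csv(paths["beta"], sep="\t", float_format="%.6f")
    cov.to_csv(paths["covariates"])
    ann.to_csv(paths["annotation"])
    write_icr_bed(icrs, paths["icrs"])
    with open(paths["imprinted_genes"], "w") as fh:
        fh.write("# synthetic imprinted-gene list\n")
        for gene in icrs["gene"]:
            fh.write(gene + "\n")
    truth.to_csv(paths["truth"])
    import json

    cfg = asdict(config)
    cfg["beta_archetypes"] = {k: list(v) for k, v in cfg["beta_archetypes"].items()}
    with open(paths["manifest"], "w") as fh:
        json.dump({"config": cfg}, fh, indent=2, default=str)
    return paths
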