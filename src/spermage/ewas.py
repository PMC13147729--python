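"""Per-CpG linear modelling of M-values on age with empirical-Bayes moderation.

Each probe's M-values are regressed on age plus covariates (default
``M ~ age + bmi + patient``) by ordinary least squares.  Residual variances
are then shrunk towards a common prior by the empirical-Bayes scheme of the
moderated t-statistic: a scaled inverse-chi-square prior (d0, s0²) is fitted
to the observed variances by moment matching on the log scale, and each
probe's posterior variance is the degrees-of-freedom-weighted convex
combination

    s²_post = (d0·s0² + d·s²) / (d0 + d)

The moderated t is the age slope over its posterior standard error, referred
to a t distribution on d + d0 degrees of freedom.  P-values are adjusted
across all probes jointly by Benjamini-Hochberg; a probe with adjusted
p < 0.05 is called a differentially methylated CpG (DMC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .arraydata import Dataset, beta_to_m, filter_probes, FilterPolicy

__all__ = [
    "ShrinkageParams",
    "fit_probe_models",
    "moderate_statistics",
    "adjust_fdr",
    "run_ewas",
    "global_methylation_tests",
    "sensitivity_rerun",
]

DEFAULT_FORMULA = ("age", "bmi", "patient")
_VAR_FLOOR = 1e-12


@dataclass
class ShrinkageParams:
    """Fitted prior of the variance shrinkage: d0 may be +inf."""

    prior_df: float
    prior_variance: float


def _design_matrix(covariates: pd.DataFrame,
                   formula: tuple[str, ...] = DEFAULT_FORMULA) -> np.ndarray:
    cols = [np.ones(len(covariates))]
    for term in formula:
        if term not in covariates.columns:
            raise ValueError(f"covariate {term!r} not in table")
        cols.append(covariates[term].to_numpy(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the error message
        names = ["intercept", *formula]
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1))
               == np.linalg.matrix_rank(X)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}")
    return X


def fit_probe_models(m: pd.DataFrame, covariates: pd.DataFrame,
                     formula: tuple[str, ...] = DEFAULT_FORMULA,
                     age_term: str = "age") -> pd.DataFrame:
    """OLS of every probe's M-values on the covariates, vectorised.

    Returns one row per probe with the age slope (ΔM per year), residual
    variance s², residual degrees of freedom d, and per-probe mean M and
    mean β.
    """
    covariates = covariates.loc[m.columns]
    X = _design_matrix(covariates, formula)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} subjects for {p} parameters")
    Y = m.to_numpy(float).T                       # subjects × probes
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    df_resid = n - p
    s2 = (resid ** 2).sum(axis=0) / df_resid
    age_idx = 1 + formula.index(age_term)

    XtX_inv = np.linalg.inv(X.T @ X)
    se_unit = np.sqrt(XtX_inv[age_idx, age_idx])  # se = se_unit * s

    mean_m = Y.mean(axis=0)
    from .arraydata import m_to_beta

    mean_beta = m_to_beta(m).mean(axis=1).to_numpy()
    return pd.DataFrame(
        {"slope_age": coef[age_idx], "s2": s2,
         "df_resid": float(df_resid), "se_unit": se_unit,
         "mean_m": mean_m, "mean_beta": mean_beta},
        index=m.index,
    )


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y                 # good starting value for all y > 0
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> ShrinkageParams:
    """Fit (d0, s0²) by method of moments on log residual variances.

    With s² | σ² ~ σ²·χ²_d/d and σ² ~ s0²·d0/χ²_d0, e = log s² has
    mean log s0² + ψ(d/2) − log(d/2) − ψ(d0/2) + log(d0/2) and excess
    variance ψ'(d0/2) beyond the sampling term ψ'(d/2); matching the two
    moments gives the prior.  Infinite d0 (no excess spread) is allowed.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), _VAR_FLOOR)
    df = np.asarray(df, dtype=float)
    if np.all(s2 <= _VAR_FLOOR):
        raise ValueError("all residual variances are zero; nothing to moderate")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    excess = e_var - np.mean(polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(np.array([excess]))[0]
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return ShrinkageParams(prior_df=float(d0), prior_variance=s0_sq)


def moderate_statistics(fits: pd.DataFrame,
                        prior: ShrinkageParams | None = None,
                        ) -> tuple[pd.DataFrame, ShrinkageParams]:
    """Shrink variances and compute moderated t and raw p per probe.

    ``prior`` may be forced (e.g. d0=0 for ordinary t, d0=inf for complete
    shrinkage); by default it is estimated from the fits.
    """
    if fits.shape[0] < 2:
        raise ValueError("need at least 2 probes to moderate")
    s2 = np.maximum(fits["s2"].to_numpy(float), _VAR_FLOOR)
    d = fits["df_resid"].to_numpy(float)
    if prior is None:
        prior = estimate_prior(s2, d)
    d0, s0_sq = prior.prior_df, prior.prior_variance

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(d, np.inf)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d + d0

    se = fits["se_unit"].to_numpy(float) * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits["slope_age"].to_numpy(float) / se
    finite_df = np.where(np.isinf(df_total), 1e12, df_total)
    p = 2.0 * stats.t.sf(np.abs(t), finite_df)

    out = fits.copy()
    out["s2_post"] = s2_post
    out["mod_t"] = t
    out["df_total"] = df_total
    out["p_raw"] = p
    return out, prior


def adjust_fdr(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be within [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def run_ewas(m: pd.DataFrame, covariates: pd.DataFrame,
             formula: tuple[str, ...] = DEFAULT_FORMULA,
             alpha: float = 0.05,
             prior: ShrinkageParams | None = None,
             ) -> tuple[pd.DataFrame, ShrinkageParams]:
    """Fit, moderate and adjust in one call; adds p_adj and significance."""
    fits = fit_probe_models(m, covariates, formula)
    table, prior = moderate_statistics(fits, prior)
    table["p_adj"] = adjust_fdr(table["p_raw"])
    table["significant"] = table["p_adj"] < alpha
    return table, prior


# ---------------------------------------------------------------------------
# Global methylation
# ---------------------------------------------------------------------------

def global_methylation_tests(beta: pd.DataFrame, covariates: pd.DataFrame,
                             subgroups: pd.Series | None = None) -> pd.DataFrame:
    """Per-subject global mean β vs age, overall and within UM/HM/FM.

    For each stratum of probes: Pearson r (and p) of the global mean
    against age, plus Mann-Whitney U tests of the global mean across three
    binary splits of the subjects (age above/below median, patient status,
    BMI >= 25).  A constant global mean yields r flagged undefined rather
    than NaN propagation.
    """
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 subjects")
    covariates = covariates.loc[beta.columns]
    age = covariates["age"].to_numpy(float)
    strata: dict[str, pd.Index | None] = {"all": None}
    if subgroups is not None:
        for name in ("UM", "HM", "FM"):
            strata[name] = subgroups.index[subgroups == name]

    splits = {
        "age_above_median": age > np.median(age),
        "patient": covariates["patient"].to_numpy(float) > 0.5,
        "overweight": covariates["bmi"].to_numpy(float) >= 25.0,
    }

    rows = []
    for name, probe_idx in strata.items():
        sub = beta if probe_idx is None else beta.loc[probe_idx]
        if sub.shape[0] == 0:
            continue
        gmean = sub.mean(axis=0).to_numpy(float)
        row: dict = {"stratum": name, "n_probes": sub.shape[0],
                     "global_mean": gmean.mean()}
        if np.ptp(gmean) == 0 or np.ptp(age) == 0:
            row["pearson_r"] = np.nan
            row["pearson_p"] = np.nan
            row["undefined"] = True
        else:
            r, p = stats.pearsonr(gmean, age)
            row["pearson_r"], row["pearson_p"] = r, p
            row["undefined"] = False
        for split_name, mask in splits.items():
            a, b = gmean[mask], gmean[~mask]
            if len(a) == 0 or len(b) == 0:
                row[f"u_p_{split_name}"] = np.nan
                continue
            _, up = stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic")
            row[f"u_p_{split_name}"] = up
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


# ---------------------------------------------------------------------------
# Sensitivity scenarios
# ---------------------------------------------------------------------------

def _global_outliers(beta: pd.DataFrame, n_mad: float = 3.0) -> pd.Index:
    """Subjects whose global mean β is beyond n_mad MADs from the median."""
    gmean = beta.mean(axis=0)
    med = gmean.median()
    mad = (gmean - med).abs().median()
    if mad == 0:
        return pd.Index([])
    return gmean.index[(gmean - med).abs() > n_mad * mad]


def sensitivity_rerun(dataset: Dataset, scenario: str,
                      main_table: pd.DataFrame | None = None,
                      formula: tuple[str, ...] = DEFAULT_FORMULA,
                      alpha: float = 0.05) -> dict:
    """Refit the EWAS under an exclusion/extension scenario.

    scenario: one of drop_outliers, drop_patients, drop_snp_probes,
    drop_crossreactive, add_sperm_quality.  Returns the refit table plus,
    when a main-analysis table is supplied, the sign agreement and Spearman
    rank correlation of the age slopes on the shared probes.
    """
    beta, cov = dataset.beta, dataset.covariates
    if scenario == "drop_outliers":
        drop = _global_outliers(beta)
        beta = beta.drop(columns=drop)
        cov = cov.drop(index=drop)
    elif scenario == "drop_patients":
        keep = cov.index[cov["patient"] == 0]
        beta, cov = beta[keep], cov.loc[keep]
        # patient is constant (0) after the exclusion; drop it from the model
        formula = tuple(t for t in formula if t != "patient")
    elif scenario == "drop_snp_probes":
        beta, _ = filter_probes(beta, None, dataset.annotation,
                                FilterPolicy(detection=False, snp=True))
    elif scenario == "drop_crossreactive":
        beta, _ = filter_probes(beta, None, dataset.annotation,
                                FilterPolicy(detection=False,
                                             crossreactive=True))
    elif scenario == "add_sperm_quality":
        if "sperm_quality" not in cov.columns:
            raise ValueError("covariates lack sperm_quality")
        formula = (*formula, "sperm_quality")
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    n_params = len(formula) + 1
    if beta.shape[1] < n_params + 1:
        raise ValueError(
            f"scenario {scenario!r} leaves too few subjects "
            f"({beta.shape[1]} < {n_params + 1})")

    m = beta_to_m(beta)
    table, prior = run_ewas(m, cov, formula, alpha)
    result = {"scenario": scenario, "table": table, "prior": prior,
              "n_subjects": beta.shape[1], "n_probes": beta.shape[0]}
    if main_table is not None:
        shared = table.index.intersection(main_table.index)
        a = table.loc[shared, "slope_age"]
        b = main_table.loc[shared, "slope_age"]
        result["sign_agreement"] = float((np.sign(a) == np.sign(b)).mean())
        result["rank_correlation"] = float(stats.spearmanr(a, b).statistic)
    return result
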