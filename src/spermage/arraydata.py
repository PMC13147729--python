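"""Array data containers, β↔M transforms, file IO and probe-level filters.

Methylation arrays report, per CpG probe and subject, a β-value: the
proportion of cells methylated at that site, in (0, 1).  Regression is done
on the M-value scale, the log2-odds ``M = log2(β / (1 − β))``, which is
approximately homoscedastic.  Matrices are pandas DataFrames with probes as
rows and subjects as columns throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "FilterPolicy",
    "FilterReport",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "load_dataset",
    "load_gene_list",
    "load_icr_bed",
    "write_icr_bed",
]

DEFAULT_EPSILON = 1e-6

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
FUNCTIONAL_REGIONS = (
    "promoter", "5utr", "1stexon", "body", "3utr", "intergenic", "multiple",
)


class AlignmentError(ValueError):
    """Subject or probe identifiers do not line up across input tables."""


@dataclass
class FilterPolicy:
    """Which probe-removal rules to apply.

    detection: drop probes with detection p > 0.01 in at least one subject.
    snp: drop probes flagged as overlapping a SNP.
    crossreactive: drop probes flagged as cross-reactive.
    """

    detection: bool = True
    snp: bool = False
    crossreactive: bool = False


@dataclass
class FilterReport:
    n_input: int
    n_removed_detection: int = 0
    n_removed_snp: int = 0
    n_removed_crossreactive: int = 0

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.n_removed_detection
                - self.n_removed_snp - self.n_removed_crossreactive)


@dataclass
class Dataset:
    """Aligned bundle of one study's inputs.

    beta: probes × subjects β-values; covariates: one row per subject
    (index ``subject_id``) with at least ``age``, ``bmi``, ``patient``;
    annotation: one row per probe (index ``probe_id``); icrs: imprint
    control region intervals (BED convention, 0-based half-open);
    gene_lists: named sets of uppercased gene symbols.
    """

    beta: pd.DataFrame
    covariates: pd.DataFrame
    annotation: pd.DataFrame
    icrs: pd.DataFrame | None = None
    gene_lists: dict[str, set[str]] = field(default_factory=dict)
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.beta.columns) != list(self.covariates.index):
            missing = set(self.beta.columns) ^ set(self.covariates.index)
            raise AlignmentError(
                "subjects in β matrix and covariate table differ: "
                f"{sorted(map(str, missing))}"
            )
        extra = set(self.beta.index) - set(self.annotation.index)
        if extra:
            raise AlignmentError(
                f"probes missing from annotation: {sorted(map(str, extra))[:10]}"
            )


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """Logit-transform β-values to M-values, ``M = log2(β/(1−β))``.

    β is clipped to ``[epsilon, 1 − epsilon]`` first so the result is finite
    even at the boundaries.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    clipped = np.clip(beta, epsilon, 1.0 - epsilon)
    with np.errstate(divide="ignore"):
        m = np.log2(clipped / (1.0 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    return m


def m_to_beta(m):
    """Inverse logit: ``β = 2^M / (1 + 2^M)``, the logistic in base 2."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("M-values must be finite")
    # expit form avoids overflow for large |M|
    from scipy.special import expit

    beta = expit(arr * np.log(2.0))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(beta)
    return beta


def filter_probes(beta: pd.DataFrame,
                  detection_p: pd.DataFrame | None,
                  annotation: pd.DataFrame,
                  policy: FilterPolicy | None = None,
                  detection_threshold: float = 0.01,
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply probe-level quality filters and return the retained matrix.

    Removal precedence is detection > SNP > cross-reactive, so the report's
    counts partition the removed probes: a probe failing several rules is
    counted once, under the first rule that caught it.
    """
    policy = policy or FilterPolicy()
    report = FilterReport(n_input=beta.shape[0])
    removed = pd.Series(False, index=beta.index)

    if policy.detection and detection_p is not None:
        if detection_p.shape != beta.shape:
            raise ValueError(
                f"detection-p shape {detection_p.shape} != β shape {beta.shape}"
            )
        bad = (detection_p.to_numpy() > detection_threshold).any(axis=1)
        bad = pd.Series(bad, index=beta.index)
        report.n_removed_detection = int(bad.sum())
        removed |= bad

    ann = annotation.reindex(beta.index)
    if policy.snp and "snp" in ann:
        bad = ann["snp"].fillna(False).astype(bool) & ~removed
        report.n_removed_snp = int(bad.sum())
        removed |= bad
    if policy.crossreactive and "crossreactive" in ann:
        bad = ann["crossreactive"].fillna(False).astype(bool) & ~removed
        report.n_removed_crossreactive = int(bad.sum())
        removed |= bad

    return beta.loc[~removed], report


# ---------------------------------------------------------------------------
# File IO.  Dialects match the fixture writer in spermage.synthetic:
#   β matrix    TSV, probes as rows, first column probe_id
#   covariates  CSV, header subject_id,age,bmi,patient[,...]
#   annotation  CSV, genes semicolon-separated, pos 1-based
#   ICRs        6-column BED, name = gene|origin
#   gene lists  one symbol per line, '#' comments
# ---------------------------------------------------------------------------

def _read_indexed(path, sep: str, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if index_col not in df.columns:
        raise ValueError(f"{path}: missing required column {index_col!r}")
    if df[index_col].duplicated().any():
        dupes = df.loc[df[index_col].duplicated(), index_col].tolist()[:5]
        raise ValueError(f"{path}: duplicate {index_col} values {dupes}")
    return df.set_index(index_col)


def load_beta_matrix(path) -> pd.DataFrame:
    return _read_indexed(path, "\t", "probe_id").astype(float)


def load_covariates(path) -> pd.DataFrame:
    cov = _read_indexed(path, ",", "subject_id")
    for col in ("age", "bmi", "patient"):
        if col not in cov.columns:
            raise ValueError(f"{path}: covariate table missing {col!r}")
        if cov[col].isna().any():
            raise ValueError(f"{path}: missing values in {col!r}")
    return cov


def load_annotation(path) -> pd.DataFrame:
    ann = _read_indexed(path, ",", "probe_id")
    if "genes" in ann.columns:
        ann["genes"] = ann["genes"].fillna("")
    for col in ("snp", "crossreactive"):
        if col in ann.columns:
            ann[col] = ann[col].astype(bool)
    return ann


def load_icr_bed(path) -> pd.DataFrame:
    """Read ICR intervals from 6-column BED (0-based, half-open).

    The name field carries ``gene|origin`` with origin in
    {paternal, maternal, unknown}.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, name = parts[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: start >= end")
            gene, _, origin = name.partition("|")
            origin = origin or "unknown"
            if origin not in ("paternal", "maternal", "unknown"):
                raise ValueError(f"{path}:{lineno}: bad origin {origin!r}")
            rows.append((chrom.removeprefix("chr"), start_i, end_i,
                         gene.strip().upper(), origin))
    return pd.DataFrame(rows, columns=["chr", "start", "end", "gene", "origin"])


def write_icr_bed(icrs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in icrs.itertuples(index=False):
            fh.write(f"chr{row.chr}\t{row.start}\t{row.end}\t"
                     f"{row.gene}|{row.origin}\t0\t+\n")


def load_gene_list(path) -> set[str]:
    """One gene symbol per line; '#' comments; matching is uppercased."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                genes.add(sym.upper())
    return genes


def load_dataset(beta_path, covariate_path, annotation_path,
                 icr_path=None, gene_list_paths: dict | None = None,
                 detection_p_path=None) -> Dataset:
    """Load and align a full input set; raises on id mismatches."""
    beta = load_beta_matrix(beta_path)
    cov = load_covariates(covariate_path)
    ann = load_annotation(annotation_path)
    icrs = load_icr_bed(icr_path) if icr_path else None
    detp = None
    if detection_p_path:
        detp = _read_indexed(detection_p_path, "\t", "probe_id").astype(float)
    gene_lists = {
        name: load_gene_list(p) for name, p in (gene_list_paths or {}).items()
    }
    cov = cov.reindex(beta.columns)
    if cov.isna().all(axis=1).any():
        missing = cov.index[cov.isna().all(axis=1)].tolist()
        raise AlignmentError(f"covariates missing for subjects {missing}")
    return Dataset(beta=beta, covariates=cov, annotation=ann,
                   icrs=icrs, gene_lists=gene_lists, detection_p=detp)
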