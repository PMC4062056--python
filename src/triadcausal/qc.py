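"""Metabolomics quality control and trait pre-processing.

The cascade mirrors standard practice for targeted metabolomics panels
measured on multi-plate LC-MS/MS runs:

1. metabolite-level filters — mean coefficient of variation (CV) of
   five-replicate reference measurements per plate, and missing-value
   rate; metabolites with mean CV > 25% or missingness > 5% are dropped
   (strict inequalities: exact ties are retained);
2. outlier handling on log concentrations — cells more than 5 SD from
   the column mean are flagged; within a sample, flagged cells whose
   metabolites correlate at >= 0.70 are counted as one *independent*
   outlying point; samples with more than three independent outlying
   points are excluded, otherwise only the flagged cells are blanked;
3. chained-equation imputation of the remaining missing cells;
4. trait transformation — natural log of all metabolites and of TG;
   LDL-C, HDL-C and TC stay untransformed;

plus lipid unit harmonisation (mmol/L -> mg/dl) and Friedewald
derivation of LDL-C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CV_THRESHOLD = 0.25
MISSING_THRESHOLD = 0.05
OUTLIER_SD = 5.0
INDEPENDENCE_CORR = 0.70
MAX_INDEPENDENT_OUTLIERS = 3
FRIEDEWALD_TG_CEILING = 400.0  # mg/dl, conventional validity bound

#: mmol/L -> mg/dl conversion factors
LIPID_UNIT_FACTORS = {"TC": 38.67, "LDL-C": 38.67, "HDL-C": 38.67, "TG": 87.5}

CHOLESTEROL_TRAITS = ("TC", "LDL-C", "HDL-C")


class QCError(ValueError):
    pass


@dataclass
class ReferenceMeasurements:
    """Replicate reference-sample concentrations: one reference blood
    sample measured five times on each plate.

    ``values`` has shape (n_plates, n_metabolites, 5).
    """

    plate_ids: Sequence[str]
    metabolites: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.plate_ids), len(self.metabolites), 5)
        if self.values.shape != expected:
            raise QCError(
                f"reference values must have shape {expected} "
                f"(plates x metabolites x 5 replicates), got {self.values.shape}"
            )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ReferenceMeasurements":
        """Build from a long table with columns (plate, metabolite, value),
        five rows per plate-metabolite cell."""
        plates = sorted(df["plate"].unique())
        mets = sorted(df["metabolite"].unique())
        arr = np.full((len(plates), len(mets), 5), np.nan)
        for (p, m), g in df.groupby(["plate", "metabolite"]):
            vals = g["value"].to_numpy(dtype=float)
            if vals.size != 5:
                raise QCError(f"plate {p}, metabolite {m}: expected 5 replicates, got {vals.size}")
            arr[plates.index(p), mets.index(m), :] = vals
        if np.isnan(arr).any():
            raise QCError("incomplete reference grid: every plate needs all metabolites")
        return cls(plates, mets, arr)


@dataclass
class QCReport:
    cv_per_metabolite: pd.Series | None = None
    excluded_metabolites: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)
    excluded_samples: list[tuple[str, int]] = field(default_factory=list)  # (sample, n independent)
    outlier_cells: list[tuple[str, str]] = field(default_factory=list)
    imputed_cells: int = 0
    skewness_per_metabolite: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "cv_per_metabolite": None
            if self.cv_per_metabolite is None
            else self.cv_per_metabolite.round(6).to_dict(),
            "excluded_metabolites": self.excluded_metabolites,
            "excluded_samples": self.excluded_samples,
            "n_outlier_cells": len(self.outlier_cells),
            "imputed_cells": self.imputed_cells,
            "skewness_per_metabolite": None
            if self.skewness_per_metabolite is None
            else self.skewness_per_metabolite.round(4).to_dict(),
        }


# --------------------------------------------------------------------------
# metabolite-level filters


def compute_cv(refs: ReferenceMeasurements) -> pd.Series:
    """Mean CV per metabolite over plates.

    Per plate, CV = sample SD (ddof=1) / mean of the five replicate
    reference measurements; the returned value averages per-plate CVs.
    A zero plate mean makes the metabolite's CV undefined (NaN), which
    flags it for exclusion downstream.
    """
    means = refs.values.mean(axis=2)  # plates x metabolites
    sds = refs.values.std(axis=2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, sds / means, np.nan)
    # plain mean over plates: one undefined plate leaves the CV undefined
    return pd.Series(cv.mean(axis=0), index=list(refs.metabolites), name="cv")


def filter_metabolites(
    matrix: pd.DataFrame,
    cv: pd.Series | None = None,
    cv_threshold: float = CV_THRESHOLD,
    missing_threshold: float = MISSING_THRESHOLD,
    report: QCReport | None = None,
) -> pd.DataFrame:
    """Drop metabolites with mean CV > 25% or missing rate > 5%.

    Both thresholds are strict: a metabolite at exactly the threshold is
    retained.  A NaN CV (undefined) excludes the metabolite.
    """
    if matrix.empty:
        raise QCError("empty metabolite matrix")
    report = report if report is not None else QCReport()
    report.cv_per_metabolite = cv
    keep = []
    for m in matrix.columns:
        if cv is not None and m in cv.index:
            v = cv[m]
            if np.isnan(v) or v > cv_threshold:
                report.excluded_metabolites.append((m, "CV"))
                continue
        if matrix[m].isna().mean() > missing_threshold:
            report.excluded_metabolites.append((m, "missingness"))
            continue
        keep.append(m)
    return matrix[keep]


# --------------------------------------------------------------------------
# outliers


def detect_outliers(
    log_matrix: pd.DataFrame,
    corr_threshold: float = INDEPENDENCE_CORR,
    sd_threshold: float = OUTLIER_SD,
    max_independent: int = MAX_INDEPENDENT_OUTLIERS,
) -> tuple[list[tuple[str, str]], list[tuple[str, int]]]:
    """Flag cells > ``sd_threshold`` SD from the column mean and decide
    sample exclusion by the independence rule.

    Column means/SDs use non-missing values of the matrix as given
    (single pass; no re-computation after blanking).  Within a sample,
    flagged cells are grouped greedily in column order: a cell joins an
    existing group if its metabolite's Pearson correlation with *any*
    group member is >= ``corr_threshold``, else it founds a new group.
    The number of groups is the sample's independent-outlier count;
    samples with count > ``max_independent`` are listed for exclusion,
    the rest have only the flagged cells blanked.  Constant columns
    (SD = 0) yield no flags.

    Returns ``(cells_to_blank, samples_to_drop)``; cells belonging to a
    dropped sample are not listed separately.
    """
    X = log_matrix.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (X - mu) / sd, 0.0)
    flagged = np.abs(z) > sd_threshold
    flagged &= np.isfinite(X)

    corr = log_matrix.corr(method="pearson").to_numpy()
    cells: list[tuple[str, str]] = []
    drops: list[tuple[str, int]] = []
    cols = list(log_matrix.columns)
    for i, sample in enumerate(log_matrix.index):
        hits = np.nonzero(flagged[i])[0]
        if hits.size == 0:
            continue
        groups: list[list[int]] = []
        for j in hits:  # column order
            for g in groups:
                if any(abs(corr[j, k]) >= corr_threshold for k in g):
                    g.append(j)
                    break
            else:
                groups.append([j])
        if len(groups) > max_independent:
            drops.append((sample, len(groups)))
        else:
            cells.extend((sample, cols[j]) for j in hits)
    return cells, drops


def apply_outlier_decisions(
    log_matrix: pd.DataFrame,
    cells: Sequence[tuple[str, str]],
    drops: Sequence[tuple[str, int]],
) -> pd.DataFrame:
    out = log_matrix.drop(index=[s for s, _ in drops])
    for sample, met in cells:
        if sample in out.index:
            out.loc[sample, met] = np.nan
    return out


# --------------------------------------------------------------------------
# imputation


def impute_missing(
    log_matrix: pd.DataFrame, seed=0, n_cycles: int = 10
) -> pd.DataFrame:
    """Chained-equation imputation with posterior-predictive noise.

    Columns with missing cells are visited in ascending missingness
    order for ``n_cycles`` cycles; each is regressed (OLS with
    intercept) on all other columns using the rows where it was
    originally observed, and its missing cells are replaced by the
    linear prediction plus Gaussian noise at the residual SD.  Missing
    cells are mean-initialised before the first cycle.  Fully observed
    input is returned unchanged.
    """
    X = log_matrix.to_numpy(dtype=float).copy()
    miss = ~np.isfinite(X)
    if not miss.any():
        return log_matrix.copy()
    n, p = X.shape
    obs_counts = (~miss).sum(axis=0)
    short = np.nonzero(obs_counts < 2)[0]
    if short.size:
        raise QCError(
            f"column(s) {[log_matrix.columns[j] for j in short]} have fewer than 2 observed values"
        )
    rng = np.random.default_rng(seed)
    col_order = np.argsort(miss.sum(axis=0))
    col_order = [j for j in col_order if miss[:, j].any()]

    # mean initialisation
    mu = np.nanmean(np.where(miss, np.nan, X), axis=0)
    for j in range(p):
        X[miss[:, j], j] = mu[j]

    for _ in range(n_cycles):
        for j in col_order:
            obs = ~miss[:, j]
            others = np.delete(np.arange(p), j)
            design = np.column_stack([np.ones(n), X[:, others]])
            beta, *_ = np.linalg.lstsq(design[obs], X[obs, j], rcond=None)
            fitted = design @ beta
            resid = X[obs, j] - fitted[obs]
            dof = max(obs.sum() - design.shape[1], 1)
            sigma = float(np.sqrt((resid**2).sum() / dof))
            mrows = miss[:, j]
            X[mrows, j] = fitted[mrows] + sigma * rng.standard_normal(mrows.sum())
    return pd.DataFrame(X, index=log_matrix.index, columns=log_matrix.columns)


# --------------------------------------------------------------------------
# transformations


def transform_traits(
    lipids: pd.DataFrame, metabolites: pd.DataFrame, skew_band: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Log-transform all metabolites and TG; flag asymmetric metabolites.

    Returns (analysis-ready lipids, log metabolites, per-metabolite
    skewness).  Skewness outside ``[-skew_band, skew_band]`` indicates a
    metabolite whose post-log distribution is still asymmetric; the
    values are reported, not filtered on.  Nonpositive values in a trait
    marked for log raise with the offending samples listed.
    """
    logged_lipids = lipids.copy()
    if "TG" in lipids.columns:
        _check_positive(lipids["TG"], "TG")
        logged_lipids["TG"] = np.log(lipids["TG"])
    for m in metabolites.columns:
        _check_positive(metabolites[m], m)
    log_mets = np.log(metabolites)
    skew = pd.Series(
        stats.skew(log_mets.to_numpy(dtype=float), axis=0, nan_policy="omit"),
        index=metabolites.columns,
        name="skewness",
    )
    return logged_lipids, log_mets, skew


def _check_positive(col: pd.Series, name: str) -> None:
    bad = col.index[(col <= 0) & col.notna()]
    if len(bad):
        raise QCError(
            f"{name} must be strictly positive for log transform; "
            f"offending samples: {list(bad[:10])}"
        )


def harmonize_lipid_units(lipids: pd.DataFrame, unit: str) -> pd.DataFrame:
    """Convert lipids to mg/dl: cholesterol traits x38.67, TG x87.5.

    ``unit`` is the cohort's input unit label ('mg/dl' or 'mmol/L');
    mg/dl input passes through unchanged.
    """
    unit_norm = unit.lower().replace(" ", "")
    if unit_norm in ("mg/dl", "mgdl"):
        return lipids.copy()
    if unit_norm not in ("mmol/l", "mmoll"):
        raise QCError(f"unknown lipid unit label {unit!r}")
    out = lipids.copy()
    for trait in lipids.columns:
        factor = LIPID_UNIT_FACTORS.get(trait)
        if factor is None:
            raise QCError(f"no unit conversion factor for trait {trait!r}")
        out[trait] = lipids[trait] * factor
    return out


def friedewald_ldl(tc, hdl, tg, tg_ceiling: float = FRIEDEWALD_TG_CEILING):
    """LDL-C = TC - HDL-C - TG/5 (all mg/dl).

    Above the triglyceride validity ceiling (default 400 mg/dl) the
    derivation is unreliable; such entries come back missing with a
    warning.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    ldl = tc - hdl - tg / 5.0
    over = tg > tg_ceiling
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} sample(s) exceed TG {tg_ceiling} mg/dl; "
            "Friedewald LDL-C set to missing",
            stacklevel=2,
        )
        ldl = np.where(over, np.nan, ldl)
    if ldl.ndim == 0:
        return float(ldl)
    return ldl


# --------------------------------------------------------------------------
# cascade


def run_qc(
    metabolites: pd.DataFrame,
    refs: ReferenceMeasurements | None = None,
    cv: pd.Series | None = None,
    seed=0,
    cv_threshold: float = CV_THRESHOLD,
    missing_threshold: float = MISSING_THRESHOLD,
    sd_threshold: float = OUTLIER_SD,
    corr_threshold: float = INDEPENDENCE_CORR,
    max_independent: int = MAX_INDEPENDENT_OUTLIERS,
) -> tuple[pd.DataFrame, QCReport]:
    """Full metabolite QC: CV/missingness filters, then outlier and
    sample handling on the log scale, then imputation.

    Returns the completed log-scale metabolite matrix and the report.
    """
    report = QCReport()
    if refs is not None and cv is None:
        cv = compute_cv(refs)
    filtered = filter_metabolites(
        metabolites, cv, cv_threshold, missing_threshold, report
    )
    for m in filtered.columns:
        _check_positive(filtered[m], m)
    log_mets = np.log(filtered)
    cells, drops = detect_outliers(
        log_mets, corr_threshold, sd_threshold, max_independent
    )
    report.outlier_cells = cells
    report.excluded_samples = drops
    blanked = apply_outlier_decisions(log_mets, cells, drops)
    report.imputed_cells = int(blanked.isna().to_numpy().sum())
    completed = impute_missing(blanked, seed=seed)
    skew = pd.Series(
        stats.skew(completed.to_numpy(dtype=float), axis=0),
        index=completed.columns,
        name="skewness",
    )
    report.skewness_per_metabolite = skew
    return completed, report
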