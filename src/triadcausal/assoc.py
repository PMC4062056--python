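"""Association evidence layer.

Covers covariate adjustment, the Spearman metabolite-lipid screen,
per-cohort linear SNP-trait association, inverse-variance fixed-effect
meta-analysis, selection of cross-associated SNP-MET-LIP triads, and
ACE twin heritability.

Default significance thresholds follow the two-cohort candidate-SNP
design: the metabolite-lipid screen is Bonferroni-corrected for
4 lipids x 151 metabolites (0.05/604 ~ 8.3e-5), the SNP-metabolite
meta-analysis for 102 SNPs x 151 metabolites (0.05/15402 ~ 3.3e-6) with
nominal significance (p < 0.05) required in each cohort separately, and
SNP-lipid pairs are retained at meta p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .datasets import TriadSet, TwinPanel

N_LIPIDS = 4
N_METABOLITES = 151
N_CANDIDATE_SNPS = 102


def spearman_alpha(n_lipids: int = N_LIPIDS, n_metabolites: int = N_METABOLITES) -> float:
    """Bonferroni-corrected screen threshold, 0.05 / (lipids x metabolites)."""
    return 0.05 / (n_lipids * n_metabolites)


def metabolite_meta_alpha(
    n_snps: int = N_CANDIDATE_SNPS, n_metabolites: int = N_METABOLITES
) -> float:
    """SNP-metabolite meta-analysis threshold, 0.05 / (SNPs x metabolites)."""
    return 0.05 / (n_snps * n_metabolites)


@dataclass
class AssociationResult:
    cohort: str
    predictor: str
    outcome: str
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class MetaAnalysisResult:
    beta: float
    se: float
    p: float
    per_cohort: list[AssociationResult] = field(default_factory=list)

    @property
    def predictor(self) -> str:
        return self.per_cohort[0].predictor

    @property
    def outcome(self) -> str:
        return self.per_cohort[0].outcome


@dataclass
class CorrelationResult:
    metabolite: str
    lipid: str
    rho: dict[str, float]  # per cohort
    p: dict[str, float]

    @property
    def concordant_sign(self) -> bool:
        signs = {np.sign(r) for r in self.rho.values()}
        return len(signs) == 1 and 0.0 not in signs


# --------------------------------------------------------------------------
# covariate adjustment


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + age + sex + batch indicator contrasts."""
    cols = [np.ones(len(covariates))]
    for c in covariates.columns:
        if covariates[c].dtype == object or str(covariates[c].dtype) == "category":
            dummies = pd.get_dummies(covariates[c], drop_first=True)
            cols.extend(dummies[d].to_numpy(dtype=float) for d in dummies.columns)
        else:
            cols.append(covariates[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    return X


def residualize(trait: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of a trait on intercept + age + sex + batch.

    Residuals are orthogonal to every covariate column (including the
    batch contrasts), which equalises batch means exactly.
    """
    X = _design_matrix(covariates.loc[trait.index])
    y = trait.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=trait.index, name=trait.name)


def residualize_block(block: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    X = _design_matrix(covariates.loc[block.index])
    Y = block.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(Y - X @ beta, index=block.index, columns=block.columns)


# --------------------------------------------------------------------------
# Spearman screen


def _spearman(x: np.ndarray, y: np.ndarray, exact_below: int = 30, seed: int = 0):
    """Tie-aware Spearman rho with a t-approximation p-value; small
    samples (n < exact_below) use a seeded permutation p instead."""
    n = len(x)
    rho, p = stats.spearmanr(x, y)
    if n < exact_below and np.isfinite(rho):
        rng = np.random.default_rng(seed)
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(rho)
        count = 0
        n_perm = 5000
        for _ in range(n_perm):
            perm_rho = stats.pearsonr(rx, rng.permutation(ry)).statistic
            if abs(perm_rho) >= obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return rho, p


def spearman_screen(
    cohorts: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    alpha: float | None = None,
) -> tuple[list[CorrelationResult], list[tuple[str, str]]]:
    """Rank-correlate every metabolite with every lipid in each cohort.

    ``cohorts`` maps cohort label -> (residualized metabolite block,
    residualized lipid block).  A pair is significant iff its p-value is
    below ``alpha`` (default 0.05/604) in *every* cohort and the signs
    of rho agree across cohorts.  Constant vectors make the correlation
    undefined; such pairs are skipped with a warning.
    """
    if alpha is None:
        alpha = spearman_alpha()
    first = next(iter(cohorts.values()))
    met_names, lip_names = list(first[0].columns), list(first[1].columns)
    results: list[CorrelationResult] = []
    significant: list[tuple[str, str]] = []
    for met in met_names:
        for lip in lip_names:
            rhos, ps = {}, {}
            skip = False
            for cohort, (mets, lips) in cohorts.items():
                x = mets[met].to_numpy(dtype=float)
                y = lips[lip].to_numpy(dtype=float)
                mask = np.isfinite(x) & np.isfinite(y)
                if np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                    warnings.warn(
                        f"constant vector for ({met}, {lip}) in {cohort}; pair skipped",
                        stacklevel=2,
                    )
                    skip = True
                    break
                rhos[cohort], ps[cohort] = _spearman(x[mask], y[mask])
            if skip:
                continue
            res = CorrelationResult(met, lip, rhos, ps)
            results.append(res)
            if all(p < alpha for p in ps.values()) and res.concordant_sign:
                significant.append((met, lip))
    return results, significant


# --------------------------------------------------------------------------
# SNP-trait association


def snp_trait_assoc(
    genotype: pd.Series,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    cohort: str = "",
    predictor: str | None = None,
    outcome: str | None = None,
) -> AssociationResult:
    """Per-allele linear association: OLS of trait on dosage, adjusting
    for age, sex and batch when covariates are supplied.

    The reported beta is the dosage coefficient (trait units per copy of
    the counted allele) with its two-sided t-test p-value.
    """
    df = pd.DataFrame({"g": genotype, "y": trait}).dropna()
    g = df["g"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("monomorphic SNP")
    if covariates is not None:
        C = _design_matrix(covariates.loc[df.index])
    else:
        C = np.ones((len(df), 1))
    X = np.column_stack([g, C])
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"too few samples ({n}) for {k} parameters")
    fit = sm.OLS(y, X).fit()
    se = float(fit.bse[0])
    p = float(fit.pvalues[0])
    beta = fit.params
    return AssociationResult(
        cohort=cohort,
        predictor=predictor or str(genotype.name),
        outcome=outcome or str(trait.name),
        beta=float(beta[0]),
        se=se,
        p=max(p, np.finfo(float).tiny),
        n=n,
    )


def inverse_variance_meta(results: Sequence[AssociationResult]) -> MetaAnalysisResult:
    """Fixed-effect meta-analysis with inverse-variance weights.

    beta = sum(w_i b_i) / sum(w_i) with w_i = 1/se_i^2,
    se = (sum w_i)^(-1/2), and a two-sided p from the normal
    approximation on beta/se.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("meta-analysis needs at least two cohort results")
    keys = {(r.predictor, r.outcome) for r in results}
    if len(keys) > 1:
        raise ValueError(f"mixed predictor/outcome pairs in meta-analysis: {keys}")
    se = np.array([r.se for r in results])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    beta = float(np.sum(w * [r.beta for r in results]) / w.sum())
    meta_se = float(w.sum() ** -0.5)
    z = beta / meta_se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaAnalysisResult(beta, meta_se, max(p, np.finfo(float).tiny), results)


# --------------------------------------------------------------------------
# triad selection


def select_triads(
    met_meta: Iterable[MetaAnalysisResult],
    lip_meta: Iterable[MetaAnalysisResult],
    meta_alpha: float | None = None,
    nominal_alpha: float = 0.05,
    lip_alpha: float = 0.05,
) -> list[TriadSet]:
    """Cross significant SNP-metabolite pairs with retained SNP-lipid
    pairs into unique SNP-MET-LIP triads.

    A SNP-metabolite pair qualifies when its meta p is below
    ``meta_alpha`` (default 0.05/(102*151)) *and* each cohort reaches
    nominal significance (p < 0.05); a SNP-lipid pair is retained at
    meta p < 0.05.  Every qualifying (SNP, MET) is crossed with every
    retained lipid of the same SNP; each triple appears exactly once,
    in a deterministic (snp, met, lip) sort order.
    """
    if meta_alpha is None:
        meta_alpha = metabolite_meta_alpha()
    met_hits = [
        m
        for m in met_meta
        if m.p < meta_alpha and all(r.p < nominal_alpha for r in m.per_cohort)
    ]
    lip_hits: dict[str, list[MetaAnalysisResult]] = {}
    for m in lip_meta:
        if m.p < lip_alpha:
            lip_hits.setdefault(m.predictor, []).append(m)
    triads: dict[tuple[str, str, str], TriadSet] = {}
    for mh in met_hits:
        for lh in lip_hits.get(mh.predictor, []):
            key = (mh.predictor, mh.outcome, lh.outcome)
            triads.setdefault(
                key,
                TriadSet(
                    snp=mh.predictor,
                    met=mh.outcome,
                    lip=lh.outcome,
                    met_evidence=mh,
                    lip_evidence=lh,
                ),
            )
    return [triads[k] for k in sorted(triads)]


# --------------------------------------------------------------------------
# ACE heritability


@dataclass
class HeritabilityEstimate:
    a2: float
    c2: float
    e2: float
    loglik: float
    converged: bool

    @property
    def h2(self) -> float:
        """Narrow-sense heritability: additive fraction of the phenotypic
        variance."""
        return self.a2

    def summary(self) -> str:
        return (
            f"ACE decomposition: a2={self.a2:.3f} c2={self.c2:.3f} e2={self.e2:.3f} "
            f"(h2={self.h2:.3f}, loglik={self.loglik:.2f})"
        )


class TwinAceModel:
    """Maximum-likelihood ACE variance decomposition from MZ/DZ pairs.

    The phenotype is standardized, then the bivariate-normal likelihood
    is maximised over nonnegative variance components (A, C, E) with
    within-pair covariance A + C for MZ and A/2 + C for DZ pairs and
    common marginal variance A + C + E.  Estimates are reported as
    fractions of the fitted phenotypic variance, so h2 = a2.
    """

    def __init__(self, panel: TwinPanel, min_pairs: int = 20):
        if panel.n_mz < min_pairs or panel.n_dz < min_pairs:
            raise ValueError(
                f"need at least {min_pairs} pairs of each zygosity "
                f"(got MZ={panel.n_mz}, DZ={panel.n_dz})"
            )
        self.panel = panel

    @staticmethod
    def _pair_loglik(pairs: np.ndarray, var: float, cov: float) -> float:
        det = var**2 - cov**2
        if det <= 0 or var <= 0:
            return -np.inf
        inv11 = var / det
        inv12 = -cov / det
        x, y = pairs[:, 0], pairs[:, 1]
        quad = inv11 * (x**2 + y**2) + 2 * inv12 * x * y
        n = len(pairs)
        return float(-0.5 * (n * (2 * np.log(2 * np.pi) + np.log(det)) + quad.sum()))

    def loglik(self, components: np.ndarray, mz: np.ndarray, dz: np.ndarray) -> float:
        va, vc, ve = components
        var = va + vc + ve
        return self._pair_loglik(mz, var, va + vc) + self._pair_loglik(dz, var, va / 2 + vc)

    def fit(self) -> HeritabilityEstimate:
        mz = self.panel.values("MZ")
        dz = self.panel.values("DZ")
        allv = np.concatenate([mz.ravel(), dz.ravel()])
        mu, sd = allv.mean(), allv.std(ddof=1)
        mz = (mz - mu) / sd
        dz = (dz - mu) / sd

        def neg(x):
            return -self.loglik(x, mz, dz)

        r_mz = np.corrcoef(mz.T)[0, 1]
        r_dz = np.corrcoef(dz.T)[0, 1]
        a0 = float(np.clip(2 * (r_mz - r_dz), 0.01, 0.95))  # Falconer start
        c0 = float(np.clip(2 * r_dz - r_mz, 0.01, 0.95 - a0))
        starts = [
            np.array([a0, c0, max(1 - a0 - c0, 0.05)]),
            np.array([1 / 3, 1 / 3, 1 / 3]),
        ]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                neg,
                x0,
                method="L-BFGS-B",
                bounds=[(0.0, None), (0.0, None), (1e-6, None)],
            )
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        if not np.isfinite(best.fun):
            raise RuntimeError(f"ACE likelihood failed to converge: {best.message}")
        va, vc, ve = best.x
        total = va + vc + ve
        return HeritabilityEstimate(
            a2=va / total,
            c2=vc / total,
            e2=ve / total,
            loglik=-float(best.fun),
            converged=bool(best.success),
        )


def estimate_ace(panel: TwinPanel) -> HeritabilityEstimate:
    """Convenience wrapper: fit the ACE model on one twin panel."""
    return TwinAceModel(panel).fit()
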