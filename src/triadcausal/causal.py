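"""Conditional (mediation) analysis and Mendelian randomization.

Conditional analysis compares the SNP coefficient in

    LIP ~ SNP           (unadjusted)
    LIP ~ SNP + MET     (adjusted for the metabolite)

and summarises the attenuation as the effect-size change
``(beta_adj - beta) / beta``: a change near -100% with a non-significant
adjusted coefficient (p >= 0.05) is consistent with full mediation
through the metabolite.

Mendelian randomization uses the SNP as an instrumental variable to
estimate the unconfounded causal effect of the metabolite on the lipid
by the Wald ratio

    beta_MET->LIP = beta_SNP->LIP / beta_SNP->MET ,

equivalent to two-stage least squares for a single instrument.
Confidence intervals come from percentile bootstrap over individuals
(default 1,000 replicates, 95% and 90% levels); instrument strength is
monitored by the first-stage F statistic with the conventional F < 10
weak-instrument warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

WEAK_INSTRUMENT_F = 10.0
DENOMINATOR_TOL = 1e-8


class WeakInstrumentError(ValueError):
    pass


# --------------------------------------------------------------------------
# conditional analysis


@dataclass
class ConditionalResult:
    beta_unadj: float
    beta_adj: float
    gamma_adj: float
    p_unadj: float
    p_adj: float
    n: int
    effect_size_change: float | None

    @property
    def no_direct_association(self) -> bool:
        """True when the adjusted SNP coefficient loses significance
        (p_adj >= 0.05), i.e. a direct SNP->LIP path is unlikely."""
        return self.p_adj >= 0.05

    def summary(self) -> str:
        change = (
            "undefined"
            if self.effect_size_change is None
            else f"{100 * self.effect_size_change:+.0f}%"
        )
        return (
            f"LIP~SNP: beta={self.beta_unadj:.4f} (p={self.p_unadj:.3g}); "
            f"LIP~SNP+MET: beta={self.beta_adj:.4f} (p={self.p_adj:.3g}), "
            f"gamma={self.gamma_adj:.4f}; change={change}"
        )


def effect_size_change(beta: float, beta_adj: float) -> float | None:
    """(beta_adj - beta) / beta; undefined (None) when beta is zero to
    machine precision."""
    if abs(beta) < np.finfo(float).eps:
        return None
    return (beta_adj - beta) / beta


def _ols(y: np.ndarray, X: np.ndarray):
    fit = sm.OLS(y, X).fit()
    return fit.params, fit.bse, int(fit.df_resid)


def conditional_analysis(data: pd.DataFrame) -> ConditionalResult:
    """Fit the unadjusted and metabolite-adjusted SNP-lipid regressions
    on the same complete-case sample.

    ``data`` must carry SNP, MET and LIP columns (traits already
    covariate-adjusted upstream).
    """
    df = data.loc[:, ["SNP", "MET", "LIP"]].dropna()
    n = len(df)
    y = df["LIP"].to_numpy(dtype=float)
    g = df["SNP"].to_numpy(dtype=float)
    m = df["MET"].to_numpy(dtype=float)
    ones = np.ones(n)

    b_u, se_u, dof_u = _ols(y, np.column_stack([ones, g]))
    b_a, se_a, dof_a = _ols(y, np.column_stack([ones, g, m]))
    p_u = float(2 * stats.t.sf(abs(b_u[1] / se_u[1]), dof_u))
    p_a = float(2 * stats.t.sf(abs(b_a[1] / se_a[1]), dof_a))
    return ConditionalResult(
        beta_unadj=float(b_u[1]),
        beta_adj=float(b_a[1]),
        gamma_adj=float(b_a[2]),
        p_unadj=p_u,
        p_adj=p_a,
        n=n,
        effect_size_change=effect_size_change(float(b_u[1]), float(b_a[1])),
    )


# --------------------------------------------------------------------------
# Mendelian randomization


def wald_ratio(beta_gx: float, beta_gy: float, tol: float = DENOMINATOR_TOL) -> float:
    """Wald-ratio causal estimate beta_gy / beta_gx.

    ``beta_gx`` is the instrument->exposure (SNP->MET) coefficient and
    ``beta_gy`` the instrument->outcome (SNP->LIP) coefficient.  A
    denominator below ``tol`` in magnitude raises, since the ratio is
    then dominated by weak-instrument noise.
    """
    if abs(beta_gx) < tol:
        raise WeakInstrumentError(
            f"instrument-exposure coefficient {beta_gx!r} is below tolerance {tol}"
        )
    return beta_gy / beta_gx


@dataclass
class MRResult:
    wald_estimate: float
    ci95: tuple[float, float]
    ci90: tuple[float, float]
    n_boot: int
    seed: int
    f_stat: float
    n: int
    n_excluded: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def significant_95(self) -> bool:
        lo, hi = self.ci95
        return lo > 0 or hi < 0

    @property
    def significant_90(self) -> bool:
        lo, hi = self.ci90
        return lo > 0 or hi < 0

    def summary(self) -> str:
        return (
            f"MET->LIP = {self.wald_estimate:.4f}; "
            f"95% CI ({self.ci95[0]:.4f}, {self.ci95[1]:.4f}); "
            f"90% CI ({self.ci90[0]:.4f}, {self.ci90[1]:.4f}); "
            f"first-stage F = {self.f_stat:.1f}; "
            f"{self.n_boot} bootstrap replicates ({self.n_excluded} excluded)"
        )


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def first_stage_f(g: np.ndarray, m: np.ndarray) -> float:
    """F statistic of the instrument in the exposure regression
    MET ~ SNP (1 numerator df)."""
    n = len(g)
    gc = g - g.mean()
    mc = m - m.mean()
    beta = float(gc @ mc / (gc @ gc))
    resid = mc - beta * gc
    rss = float(resid @ resid)
    tss = float(mc @ mc)
    if rss <= 0:
        return np.inf
    return (tss - rss) / (rss / (n - 2))


class MendelianRandomization:
    """Single-instrument MR for one triad, statsmodels-style.

    Built from a data frame with SNP, MET and LIP columns; ``fit``
    returns an :class:`MRResult` with the Wald point estimate and
    bootstrap percentile intervals.
    """

    def __init__(self, data: pd.DataFrame, min_n: int = 100):
        df = data.loc[:, ["SNP", "MET", "LIP"]].dropna()
        if len(df) < min_n:
            raise ValueError(f"MR needs at least {min_n} complete cases, got {len(df)}")
        self.g = df["SNP"].to_numpy(dtype=float)
        self.m = df["MET"].to_numpy(dtype=float)
        self.y = df["LIP"].to_numpy(dtype=float)
        self.n = len(df)

    def point_estimate(self) -> float:
        return wald_ratio(_slope(self.g, self.m), _slope(self.g, self.y))

    def fit(
        self,
        n_boot: int = 1000,
        levels: tuple[float, ...] = (0.95, 0.90),
        seed: int = 0,
        weak_f_threshold: float = WEAK_INSTRUMENT_F,
    ) -> MRResult:
        """Bootstrap individuals (jointly resampling all three
        variables), recompute both regressions and the ratio per
        replicate, and take percentile intervals.

        Replicates whose instrument-exposure slope falls below the
        denominator tolerance are excluded and counted; more than 5%
        exclusions attaches a warning, more than 50% raises.
        """
        f = first_stage_f(self.g, self.m)
        msgs: list[str] = []
        if f < weak_f_threshold:
            msg = f"weak instrument: first-stage F = {f:.2f} < {weak_f_threshold}"
            msgs.append(msg)
            warnings.warn(msg, stacklevel=2)
        estimate = self.point_estimate()

        rng = np.random.default_rng(seed)
        idx = rng.integers(0, self.n, size=(n_boot, self.n))
        G, M, Y = self.g[idx], self.m[idx], self.y[idx]
        Gc = G - G.mean(axis=1, keepdims=True)
        denom_gg = np.einsum("ij,ij->i", Gc, Gc)
        b_gx = np.einsum("ij,ij->i", Gc, M - M.mean(axis=1, keepdims=True)) / denom_gg
        b_gy = np.einsum("ij,ij->i", Gc, Y - Y.mean(axis=1, keepdims=True)) / denom_gg
        ok = np.abs(b_gx) >= DENOMINATOR_TOL
        n_excluded = int((~ok).sum())
        if n_excluded > 0.5 * n_boot:
            raise WeakInstrumentError(
                f"{n_excluded}/{n_boot} bootstrap replicates had a near-zero "
                "instrument-exposure slope"
            )
        if n_excluded > 0.05 * n_boot:
            msg = f"{n_excluded}/{n_boot} bootstrap replicates excluded (near-zero denominator)"
            msgs.append(msg)
            warnings.warn(msg, stacklevel=2)
        ratios = b_gy[ok] / b_gx[ok]

        def interval(level: float) -> tuple[float, float]:
            lo, hi = np.quantile(ratios, [(1 - level) / 2, (1 + level) / 2])
            return float(lo), float(hi)

        cis = {level: interval(level) for level in levels}
        return MRResult(
            wald_estimate=estimate,
            ci95=cis.get(0.95, interval(0.95)),
            ci90=cis.get(0.90, interval(0.90)),
            n_boot=n_boot,
            seed=seed,
            f_stat=f,
            n=self.n,
            n_excluded=n_excluded,
            warnings=msgs,
        )


def bootstrap_ci(
    data: pd.DataFrame, n_boot: int = 1000, levels=(0.95, 0.90), seed: int = 0
) -> MRResult:
    """Functional wrapper around :class:`MendelianRandomization`."""
    return MendelianRandomization(data).fit(n_boot=n_boot, levels=tuple(levels), seed=seed)
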