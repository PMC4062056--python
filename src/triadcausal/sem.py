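"""Structural equation modelling over a SNP-MET-LIP triad.

The structural model is the linear system ``v = A v + u`` on the three
observed variables (SNP exogenous, MET and LIP endogenous), with residual
covariance ``Psi = E[u u']``.  Its implied covariance is

    Sigma(theta) = (I - A)^{-1} Psi (I - A)^{-T}

and a candidate path model is fitted to a sample covariance ``S`` by
minimising the maximum-likelihood discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p ,   p = 3,

with ``chi2 = (n - 1) F_min`` referred to a chi-square distribution on
``df = 6 - n_free_params`` degrees of freedom.

The catalog enumerates the ten directed path models possible for a
cross-associated triple once every model is conditioned on paths
originating from the SNP: the SNP-edge subset is one of {SNP->MET},
{SNP->LIP}, {SNP->MET, SNP->LIP}, crossed with the MET-LIP relation
(MET->LIP, LIP->MET, or none).  The two three-edge graphs plus the
two-edge graph with a free MET-LIP residual covariance are saturated
(df = 0, Models 1-3, Markov equivalent); the remaining seven (Models
4-10) are testable.  Models 4 (SNP->MET->LIP, full mediation),
8 (SNP->LIP->MET, reverse mediation) and 10 (MET<-SNP->LIP, independent
pleiotropy) are the scientifically anchored topologies; the ids of the
other testable models follow the deterministic ordering documented in
:func:`enumerate_models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import TRIAD_VARS, Edge, check_positive_definite, parse_edge

_IDX = {v: i for i, v in enumerate(TRIAD_VARS)}
_P = 3  # observed variables


@dataclass(frozen=True)
class PathModel:
    """One directed path model among {SNP, MET, LIP}.

    ``residual_cov`` adds a free MET-LIP residual covariance (used by the
    saturated Model 3 only).  Free parameters are the edge coefficients,
    the three residual variances, and the optional covariance; degrees of
    freedom are ``6 - n_free_params`` (six distinct entries in a 3x3
    covariance).
    """

    model_id: int
    edges: tuple[Edge, ...]
    residual_cov: bool = False

    def __post_init__(self) -> None:
        for parent, child in self.edges:
            if child == "SNP":
                raise ValueError("SNP is exogenous; no edge may point into it")
        if self._has_cycle():
            raise ValueError(f"model {self.model_id} edge set {self.edges} contains a cycle")

    def _has_cycle(self) -> bool:
        # 3 nodes: a cycle requires both MET->LIP and LIP->MET
        return ("MET", "LIP") in self.edges and ("LIP", "MET") in self.edges

    @property
    def n_free_params(self) -> int:
        return len(self.edges) + 3 + (1 if self.residual_cov else 0)

    @property
    def df(self) -> int:
        return 6 - self.n_free_params

    @property
    def saturated(self) -> bool:
        return self.df == 0

    def describe(self) -> str:
        parts = [f"{p}->{c}" for p, c in self.edges]
        if self.residual_cov:
            parts.append("MET<->LIP")
        return f"Model {self.model_id} ({', '.join(parts)})"

    def topological_order(self) -> list[str]:
        parents: dict[str, set[str]] = {v: set() for v in TRIAD_VARS}
        for p, c in self.edges:
            parents[c].add(p)
        order: list[str] = []
        remaining = set(TRIAD_VARS)
        while remaining:
            ready = sorted(v for v in remaining if parents[v] <= set(order))
            if not ready:  # pragma: no cover - guarded by cycle check
                raise ValueError("cyclic model")
            order.append(ready[0])
            remaining.discard(ready[0])
        return order


def enumerate_models() -> list[PathModel]:
    """Build the ten-model catalog.

    Ordering convention for ids: saturated models first (1: both SNP
    edges + MET->LIP; 2: both SNP edges + LIP->MET; 3: both SNP edges +
    free residual covariance), then testable models by SNP-edge subset
    ({SNP->MET}, {SNP->LIP}, {SNP->MET, SNP->LIP}) crossed with the
    MET-LIP relation in the order MET->LIP, LIP->MET, none.  This fixes
    Model 4 = SNP->MET->LIP, Model 8 = SNP->LIP->MET and
    Model 10 = MET<-SNP->LIP.
    """
    sm, sl = ("SNP", "MET"), ("SNP", "LIP")
    ml, lm = ("MET", "LIP"), ("LIP", "MET")
    catalog = [
        PathModel(1, (sm, sl, ml)),
        PathModel(2, (sm, sl, lm)),
        PathModel(3, (sm, sl), residual_cov=True),
        PathModel(4, (sm, ml)),
        PathModel(5, (sm, lm)),
        PathModel(6, (sm,)),
        PathModel(7, (sl, ml)),
        PathModel(8, (sl, lm)),
        PathModel(9, (sl,)),
        PathModel(10, (sm, sl)),
    ]
    return catalog


_CATALOG = {m.model_id: m for m in enumerate_models()}


def get_model(model_id: int) -> PathModel:
    try:
        return _CATALOG[model_id]
    except KeyError:
        raise KeyError(f"model_id must be 1-10, got {model_id}") from None


def testable_models() -> list[PathModel]:
    """The seven models with df >= 1 (Models 4-10)."""
    return [m for m in enumerate_models() if not m.saturated]


# --------------------------------------------------------------------------
# implied covariance


def _build_A_Psi(model: PathModel, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = len(model.edges)
    paths = theta[:k]
    variances = theta[k : k + 3]
    if np.any(variances <= 0):
        raise ValueError("residual variances must be positive")
    A = np.zeros((_P, _P))
    for coef, (parent, child) in zip(paths, model.edges):
        A[_IDX[child], _IDX[parent]] = coef
    Psi = np.diag(variances)
    if model.residual_cov:
        cov = theta[k + 3]
        Psi[_IDX["MET"], _IDX["LIP"]] = Psi[_IDX["LIP"], _IDX["MET"]] = cov
    return A, Psi


def implied_covariance(model: PathModel | int, theta: Sequence[float]) -> np.ndarray:
    """Model-implied covariance Sigma(theta) = (I-A)^{-1} Psi (I-A)^{-T}.

    ``theta`` is laid out as [path coefficients in edge order, residual
    variances (SNP, MET, LIP), optional MET-LIP residual covariance].
    """
    if isinstance(model, int):
        model = get_model(model)
    theta = np.asarray(theta, dtype=float)
    if theta.size != model.n_free_params:
        raise ValueError(
            f"theta must have {model.n_free_params} entries for {model.describe()}, got {theta.size}"
        )
    A, Psi = _build_A_Psi(model, theta)
    ImA = np.eye(_P) - A
    inv = np.linalg.solve(ImA, np.eye(_P))
    sigma = inv @ Psi @ inv.T
    return 0.5 * (sigma + sigma.T)


# --------------------------------------------------------------------------
# fitting


@dataclass
class SemFitResult:
    """Fitted parameters and fit statistics for one path model."""

    model: PathModel
    theta_hat: np.ndarray
    implied_sigma: np.ndarray
    f_min: float
    chi2: float
    df: int
    p: float
    n: int
    converged: bool
    gfi: float = np.nan
    rmsea: float = np.nan
    bic: float = np.nan
    n_iter: int = 0

    @property
    def path_estimates(self) -> dict[str, float]:
        return {
            f"{p}->{c}": float(v)
            for (p, c), v in zip(self.model.edges, self.theta_hat)
        }

    @property
    def residual_variances(self) -> dict[str, float]:
        k = len(self.model.edges)
        return {v: float(x) for v, x in zip(TRIAD_VARS, self.theta_hat[k : k + 3])}

    def summary(self) -> str:
        lines = [
            self.model.describe(),
            f"  chi2 = {self.chi2:.4f} on df = {self.df}, p = {self.p:.4g}",
            f"  GFI = {self.gfi:.4f}  RMSEA = {self.rmsea:.4f}  BIC = {self.bic:.4f}",
            f"  converged: {self.converged}",
            "  paths: " + ", ".join(f"{k} = {v:.4f}" for k, v in self.path_estimates.items()),
        ]
        return "\n".join(lines)


def _discrepancy(sigma: np.ndarray, S: np.ndarray, logdet_S: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        tr = float(np.trace(np.linalg.solve(sigma, S)))
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.inf
    return logdet + tr - logdet_S - _P


def _regression_start(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Per-equation least-squares start computed from S: each endogenous
    variable regressed on its parents.  For recursive models with
    uncorrelated residuals this is already the ML solution."""
    parents: dict[str, list[str]] = {v: [] for v in TRIAD_VARS}
    for p, c in model.edges:
        parents[c].append(p)
    coefs: dict[Edge, float] = {}
    resid_var = {}
    for child in TRIAD_VARS:
        ps = parents[child]
        ci = _IDX[child]
        if not ps:
            resid_var[child] = S[ci, ci]
            continue
        pi = [_IDX[p] for p in ps]
        b = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, ci])
        for p, bb in zip(ps, b):
            coefs[(p, child)] = float(bb)
        resid_var[child] = float(S[ci, ci] - S[ci, pi] @ b)
    theta = [coefs[e] for e in model.edges]
    variances = [max(resid_var[v], 1e-8 * S[_IDX[v], _IDX[v]]) for v in TRIAD_VARS]
    theta += variances
    if model.residual_cov:
        # residual covariance of MET and LIP after removing SNP effects
        aM = coefs.get(("SNP", "MET"), 0.0)
        aL = coefs.get(("SNP", "LIP"), 0.0)
        cov = S[1, 2] - aM * aL * S[0, 0]
        cap = 0.99 * np.sqrt(variances[1] * variances[2])
        theta.append(float(np.clip(cov, -cap, cap)))
    return np.asarray(theta, dtype=float)


def _pack(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Raw theta -> unconstrained optimiser coordinates (log variances,
    atanh residual correlation)."""
    k = len(model.edges)
    x = theta.copy()
    x[k : k + 3] = np.log(theta[k : k + 3])
    if model.residual_cov:
        rho = theta[k + 3] / np.sqrt(theta[k + 1] * theta[k + 2])
        x[k + 3] = np.arctanh(np.clip(rho, -0.999, 0.999))
    return x


def _unpack(model: PathModel, x: np.ndarray) -> np.ndarray:
    k = len(model.edges)
    theta = x.copy()
    theta[k : k + 3] = np.exp(np.clip(x[k : k + 3], -40, 40))
    if model.residual_cov:
        rho = np.tanh(x[k + 3])
        theta[k + 3] = rho * np.sqrt(theta[k + 1] * theta[k + 2])
    return theta


def fit_model(
    model: PathModel | int,
    S: np.ndarray,
    n: int,
    gtol: float = 1e-6,
    compute_indices: bool = True,
) -> SemFitResult:
    """Fit one path model to a sample covariance by quasi-Newton ML.

    Two starts are tried (zero paths with variances from diag(S); the
    per-equation regression solution) and the best converged optimum is
    kept.  Variances are log-parameterised so the optimiser is
    unconstrained.
    """
    if isinstance(model, int):
        model = get_model(model)
    S = check_positive_definite(S, "S")
    if n <= 10:
        raise ValueError("n must exceed 10")
    logdet_S = float(np.linalg.slogdet(S)[1])

    def objective(x: np.ndarray) -> float:
        theta = _unpack(model, x)
        try:
            sigma = implied_covariance(model, theta)
        except ValueError:
            return np.inf
        return _discrepancy(sigma, S, logdet_S)

    k = len(model.edges)
    start_zero = np.concatenate(
        [np.zeros(k), np.diag(S), [0.0] if model.residual_cov else []]
    )
    starts = [start_zero, _regression_start(model, S)]

    best: optimize.OptimizeResult | None = None
    for theta0 in starts:
        res = optimize.minimize(
            objective, _pack(model, theta0), method="BFGS", options={"gtol": gtol}
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    converged = bool(np.isfinite(best.fun)) and (
        best.success or float(np.max(np.abs(best.jac))) < 1e-4
    )
    theta_hat = _unpack(model, best.x)
    sigma_hat = implied_covariance(model, theta_hat)
    f_min = max(float(best.fun), 0.0)
    chi2 = (n - 1) * f_min
    df = model.df
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    fit = SemFitResult(
        model=model,
        theta_hat=theta_hat,
        implied_sigma=sigma_hat,
        f_min=f_min,
        chi2=chi2,
        df=df,
        p=p,
        n=n,
        converged=converged,
        n_iter=int(best.nit),
    )
    if compute_indices:
        fit.gfi, fit.rmsea, fit.bic = fit_indices(fit, S, n)
    return fit


def fit_indices(fit: SemFitResult, S: np.ndarray, n: int) -> tuple[float, float, float]:
    """GFI, RMSEA and the negative-convention BIC for a fitted model.

    GFI = 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2] (the ML form);
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))), 0 for saturated models;
    BIC = chi2 - df ln(n), so more negative indicates better parsimonious
    fit and a saturated model scores 0.
    """
    W = np.linalg.solve(fit.implied_sigma, S)
    gfi = 1.0 - np.trace((W - np.eye(_P)) @ (W - np.eye(_P))) / np.trace(W @ W)
    df = fit.df
    if df == 0:
        return float(gfi), 0.0, 0.0
    rmsea = float(np.sqrt(max(fit.chi2 - df, 0.0) / (df * (n - 1))))
    bic = float(fit.chi2 - df * np.log(n))
    return float(gfi), rmsea, bic


# --------------------------------------------------------------------------
# selection


@dataclass
class ModelSelection:
    """Outcome of the four-criterion selection over the testable models.

    A model is admissible when its goodness-of-fit p >= 0.05,
    0.9 < GFI <= 1 and RMSEA <= 0.05; among admissible models the one
    with the smallest (most negative) BIC is selected only if it beats
    the runner-up by at least the BIC margin (default 2 units),
    otherwise no model is selected.
    """

    per_model: list[SemFitResult]
    admissible: list[int]
    selected: int | None
    bic_margin: float | None = None

    @property
    def verdict(self) -> str:
        if self.selected is None:
            return "none"
        return get_model(self.selected).describe()

    def summary(self) -> pd.DataFrame:
        rows = []
        for fit in self.per_model:
            rows.append(
                {
                    "model": fit.model.model_id,
                    "edges": ", ".join(f"{p}->{c}" for p, c in fit.model.edges),
                    "chi2": fit.chi2,
                    "df": fit.df,
                    "p": fit.p,
                    "GFI": fit.gfi,
                    "RMSEA": fit.rmsea,
                    "BIC": fit.bic,
                    "converged": fit.converged,
                    "admissible": fit.model.model_id in self.admissible,
                    "selected": fit.model.model_id == self.selected,
                }
            )
        return pd.DataFrame(rows).set_index("model")


def select_best_model(
    fits: Sequence[SemFitResult],
    p_min: float = 0.05,
    gfi_min: float = 0.9,
    rmsea_max: float = 0.05,
    bic_margin: float = 2.0,
) -> ModelSelection:
    """Apply the four acceptance criteria and the BIC-margin rule."""
    fits = list(fits)
    admissible = [
        f.model.model_id
        for f in fits
        if f.converged and f.p >= p_min and gfi_min < f.gfi <= 1.0 and f.rmsea <= rmsea_max
    ]
    if not admissible:
        return ModelSelection(fits, admissible, None)
    by_bic = sorted(
        (f for f in fits if f.model.model_id in admissible), key=lambda f: f.bic
    )
    if len(by_bic) == 1:
        return ModelSelection(fits, admissible, by_bic[0].model.model_id)
    margin = by_bic[1].bic - by_bic[0].bic
    selected = by_bic[0].model.model_id if margin >= bic_margin else None
    return ModelSelection(fits, admissible, selected, bic_margin=margin)


# --------------------------------------------------------------------------
# model-facing API


class SemModel:
    """Covariance-structure model for one triad, statsmodels-style.

    Construct from a 3x3 sample covariance plus n, or from a data frame
    with SNP/MET/LIP columns via :meth:`from_dataframe`; ``fit`` fits a
    single catalog model, ``fit_testable`` fits Models 4-10, ``select``
    runs the full selection.
    """

    def __init__(self, S: np.ndarray, n: int):
        self.S = check_positive_definite(S, "S")
        self.n = int(n)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SemModel":
        missing = [c for c in TRIAD_VARS if c not in df.columns]
        if missing:
            raise ValueError(f"data frame lacks columns {missing}")
        data = df.loc[:, list(TRIAD_VARS)].dropna()
        S = np.cov(data.to_numpy(dtype=float), rowvar=False, ddof=1)
        return cls(S, len(data))

    def fit(self, model: PathModel | int, **kwargs) -> SemFitResult:
        return fit_model(model, self.S, self.n, **kwargs)

    def fit_testable(self) -> list[SemFitResult]:
        return [self.fit(m) for m in testable_models()]

    def select(self, **kwargs) -> ModelSelection:
        return select_best_model(self.fit_testable(), **kwargs)
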