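import numpy as np
import pandas as pd
import pytest

import triadcausal as tc


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def mediation_data():
    """One triad simulated under full mediation (SNP -> MET -> LIP),
    n = 2,000, paths 0.3 / 0.5."""
    spec = tc.TrueModelSpec(
        4, {"SNP->MET": 0.3, "MET->LIP": 0.5}, maf=0.3, seed=11
    )
    return tc.simulate_triad(spec, 2000)


@pytest.fixture(scope="session")
def big_mediation_data():
    """Same generative model at n = 50,000 for consistency checks."""
    spec = tc.TrueModelSpec(
        4, {"SNP->MET": 0.3, "MET->LIP": 0.5}, maf=0.3, seed=7
    )
    return tc.simulate_triad(spec, 50_000)


@pytest.fixture(scope="session")
def qc_fixture():
    """A 163-metabolite cohort engineered for the QC cascade: 11
    metabolites with reference CV > 25%, one with > 5% missing values,
    and gross (>= 6 SD) outliers injected at recorded positions.

    Returns (concentrations, refs, injected_outlier_cells).
    """
    rng = np.random.default_rng(424242)
    n, p = 600, 163
    names = [f"M{j:03d}" for j in range(p)]
    high_cv = names[:11]
    high_missing = names[11]

    log_x = rng.standard_normal((n, p)) * 0.5 + 2.0
    conc = pd.DataFrame(
        np.exp(log_x), columns=names,
        index=pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id"),
    )

    # reference replicates: noisy plates for the high-CV metabolites
    plates = [f"P{k}" for k in range(10)]
    vals = np.empty((10, p, 5))
    good = np.array([1.0, 0.99, 1.01, 1.0, 1.02])  # CV ~ 1%
    bad = np.array([1.0, 1.0, 1.0, 1.0, 2.0])  # CV ~ 37%
    for j in range(p):
        vals[:, j, :] = bad if names[j] in high_cv else good
    refs = tc.ReferenceMeasurements(plates, names, vals)

    # > 5% missing in one metabolite
    miss_rows = rng.choice(n, size=int(0.06 * n), replace=False)
    conc.iloc[miss_rows, names.index(high_missing)] = np.nan

    # gross outliers, >= 6 SD on the log scale, in the surviving block
    keep = [m for m in names if m not in high_cv and m != high_missing]
    log_keep = np.log(conc[keep].to_numpy())
    mu, sd = log_keep.mean(axis=0), log_keep.std(axis=0, ddof=1)
    cells = []
    mask = rng.random(log_keep.shape) < 0.004
    rows, cols = np.nonzero(mask)
    for i, j in zip(rows, cols):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        log_keep[i, j] = mu[j] + sign * (6.0 + rng.random()) * sd[j]
        cells.append((conc.index[i], keep[j]))
    conc.loc[:, keep] = np.exp(log_keep)
    return conc, refs, cells


def two_stage_least_squares(g, m, y):
    """Independent 2SLS oracle: first stage MET ~ SNP by OLS, second
    stage LIP ~ fitted(MET) by OLS; returns the second-stage slope."""
    g = np.asarray(g, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    X1 = np.column_stack([np.ones_like(g), g])
    b1, *_ = np.linalg.lstsq(X1, m, rcond=None)
    m_hat = X1 @ b1
    X2 = np.column_stack([np.ones_like(m_hat), m_hat])
    b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    return float(b2[1])
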