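"""Synthetic two-cohort data with known causal ground truth.

Emulates the study design the pipeline targets: a KORA-like cohort
(n = 1,797, three measurement batches) and a TwinsUK-like cohort
(n = 845 unrelated samples, two batches, plus MZ/DZ twin pairs for
heritability), 151 metabolites that are approximately log-normal, the
four main serum lipids, and bi-allelic SNPs in Hardy-Weinberg
equilibrium.  Each SNP-MET-LIP triad can be planted with a configurable
true path model; forward simulation follows the same linear system
``v = A v + u`` that the SEM engine fits, so the generative covariance
is exactly the engine's implied covariance.

Metabolites are generated on the log scale (where downstream analysis
operates) and exponentiated into concentration units; lipids are kept
in mg/dl.  Age and sex receive small effects on traits so covariate
adjustment is exercised without inducing confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import TRIAD_VARS, CohortDataset, TrueModelSpec, TwinPanel
from .sem import get_model


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, maf: float, seed) -> np.ndarray:
    """Draw hard-call dosages {0,1,2} under Hardy-Weinberg proportions
    ((1-q)^2, 2q(1-q), q^2) for minor-allele frequency q."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
    return _rng(seed).choice(3, size=n, p=probs).astype(float)


def simulate_triad(spec: TrueModelSpec, n: int, seed=None) -> pd.DataFrame:
    """Forward-sample one (SNP, MET, LIP) triple from its true path model.

    Variables are generated in topological order of the model's DAG: the
    SNP from Hardy-Weinberg proportions, each endogenous variable as the
    linear combination of its parents plus a Gaussian residual with the
    stated SD.  A nonzero ``confounder_effect`` adds a shared latent
    standard-normal U to both MET and LIP with that loading.
    MET and LIP here are on the analysis (log-metabolite / trait) scale.
    """
    model = get_model(spec.model_id)
    rng = _rng(spec.seed if seed is None else seed)
    coeffs = dict(spec.path_coefficients)
    values: dict[str, np.ndarray] = {}
    u = rng.standard_normal(n) if spec.confounder_effect != 0.0 else None
    order = model.topological_order()
    # SNP drawn first regardless of order position (it has no parents)
    probs = [(1 - spec.maf) ** 2, 2 * spec.maf * (1 - spec.maf), spec.maf**2]
    values["SNP"] = rng.choice(3, size=n, p=probs).astype(float)
    for var in order:
        if var == "SNP":
            continue
        sd = float(spec.residual_sds.get(var, 1.0))
        x = rng.standard_normal(n) * sd
        for (parent, child), beta in coeffs.items():
            if child == var:
                x = x + beta * values[parent]
        if u is not None:
            x = x + spec.confounder_effect * u
        values[var] = x
    return pd.DataFrame({v: values[v] for v in TRIAD_VARS})


@dataclass
class CohortSpec:
    """Configuration of one simulated cohort.

    ``triads`` maps a label to (TrueModelSpec, met_column, lip_column):
    the triad's SNP becomes a genotype column named after the label's
    SNP id, its MET/LIP components are written into the named metabolite
    and lipid columns (on their native scales).
    """

    cohort_id: str = "COHORT"
    n_samples: int = 1000
    n_metabolites: int = 151
    n_null_snps: int = 20
    batches: tuple[str, ...] = ("B1", "B2")
    maf_null: float = 0.3
    age_range: tuple[int, int] = (30, 75)
    age_effect: float = 0.002
    sex_effect: float = 0.05
    lipid_scale: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "TC": (200.0, 35.0),
            "LDL-C": (125.0, 30.0),
            "HDL-C": (55.0, 14.0),
            "TG": (110.0, 0.45),  # TG: log-normal, (median, log-SD)
        }
    )
    triads: dict[str, tuple[TrueModelSpec, str, str]] = field(default_factory=dict)
    seed: int = 0


def simulate_cohort(spec: CohortSpec) -> CohortDataset:
    """Build a full cohort: genotypes, metabolites (µM), lipids (mg/dl),
    covariates, with any planted triads embedded in the named columns."""
    rng = _rng(spec.seed)
    n = spec.n_samples
    index = pd.Index([f"{spec.cohort_id}_{i:05d}" for i in range(n)], name="sample_id")

    # covariates
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(int)
    batch = np.sort(rng.choice(list(spec.batches), size=n))
    covariates = pd.DataFrame({"age": age, "sex": sex, "batch": batch}, index=index)
    cov_shift = spec.age_effect * (age - age.mean()) + spec.sex_effect * (sex - 0.5)

    # metabolites: log-scale latent with mild correlation then exponentiated
    met_names = [f"MET{j:03d}" for j in range(spec.n_metabolites)]
    shared = rng.standard_normal(n)
    log_mets = (
        0.3 * shared[:, None]
        + np.sqrt(1 - 0.3**2) * rng.standard_normal((n, spec.n_metabolites))
    ) * 0.4 + rng.uniform(1.0, 4.0, size=spec.n_metabolites)

    # lipids
    lipids = {}
    for lip, (loc, scale) in spec.lipid_scale.items():
        if lip == "TG":
            lipids[lip] = np.exp(np.log(loc) + scale * rng.standard_normal(n))
        else:
            lipids[lip] = loc + scale * rng.standard_normal(n)
    lipid_df = pd.DataFrame(lipids, index=index)

    # genotypes: null SNPs plus one per planted triad
    geno = {}
    for j in range(spec.n_null_snps):
        geno[f"null_snp{j:02d}"] = simulate_genotypes(
            n, spec.maf_null, rng.integers(2**31)
        )

    truth: dict[str, TrueModelSpec] = {}
    met_df_log = pd.DataFrame(log_mets, index=index, columns=met_names)
    for snp_id, (tspec, met_col, lip_col) in spec.triads.items():
        triad = simulate_triad(tspec, n, seed=rng.integers(2**31))
        geno[snp_id] = triad["SNP"].to_numpy()
        if met_col not in met_df_log.columns:
            raise KeyError(f"unknown metabolite column {met_col}")
        # planted values replace the latent column (log scale)
        met_df_log[met_col] = triad["MET"].to_numpy() + 2.0
        lipid_df[lip_col] = _to_lipid_scale(triad["LIP"].to_numpy(), lip_col, spec)
        truth[f"{snp_id}|{met_col}|{lip_col}"] = tspec

    # covariate effects on traits (additive on analysis scale)
    met_df_log = met_df_log.add(cov_shift, axis=0)
    for lip in lipid_df.columns:
        if lip == "TG":
            lipid_df[lip] = lipid_df[lip] * np.exp(cov_shift)
        else:
            lipid_df[lip] = lipid_df[lip] + 20.0 * cov_shift

    metabolites = np.exp(met_df_log)
    genotypes = pd.DataFrame(geno, index=index)
    return CohortDataset(
        cohort_id=spec.cohort_id,
        genotypes=genotypes,
        metabolites=metabolites,
        lipids=lipid_df,
        covariates=covariates,
        truth=truth,
    )


def _to_lipid_scale(values: np.ndarray, lip: str, spec: CohortSpec) -> np.ndarray:
    """Map a planted analysis-scale LIP variable onto the lipid's native
    scale (log mg/dl for TG, mg/dl otherwise) around the cohort mean."""
    loc, _ = spec.lipid_scale.get(lip, (150.0, 25.0))
    if lip == "TG":
        return np.exp(np.log(loc) + values)
    return loc + 20.0 * values


# --------------------------------------------------------------------------
# measurement artifacts


@dataclass
class InjectionRecord:
    """Sidecar of injected artifact positions for test assertions."""

    outliers: list[tuple[str, str]] = field(default_factory=list)  # (sample, metabolite)
    missing: list[tuple[str, str]] = field(default_factory=list)
    batch_shifts: dict[str, float] = field(default_factory=dict)


def inject_artifacts(
    data: CohortDataset,
    batch_shifts: Mapping[str, float] | None = None,
    outlier_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed=0,
    outlier_sd: float = 6.0,
) -> tuple[CohortDataset, InjectionRecord]:
    """Degrade a clean cohort with batch mean shifts, gross outliers and
    missing cells, recording every injected position.

    Batch shifts are additive on the log-metabolite scale.  Outliers are
    displaced at least ``outlier_sd`` (default 6) log-SDs from the column
    mean, guaranteeing detection by a 5-SD rule.  Rates apply per cell,
    Bernoulli-independently, and must not exceed 0.2.
    """
    for name, rate in (("outlier_rate", outlier_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= rate <= 0.2):
            raise ValueError(f"{name} must lie in [0, 0.2], got {rate}")
    rng = _rng(seed)
    record = InjectionRecord(batch_shifts=dict(batch_shifts or {}))
    log_mets = np.log(data.metabolites.to_numpy(dtype=float))
    index = data.metabolites.index
    columns = data.metabolites.columns

    if batch_shifts:
        batch = data.covariates["batch"].to_numpy()
        for b, shift in batch_shifts.items():
            log_mets[batch == b] += shift

    if outlier_rate > 0:
        mask = rng.random(log_mets.shape) < outlier_rate
        mu = np.nanmean(log_mets, axis=0)
        sd = np.nanstd(log_mets, axis=0, ddof=1)
        signs = np.where(rng.random(log_mets.shape) < 0.5, -1.0, 1.0)
        rows, cols = np.nonzero(mask)
        log_mets[rows, cols] = (
            mu[cols] + signs[rows, cols] * (outlier_sd + rng.random(rows.size)) * sd[cols]
        )
        record.outliers = [(index[i], columns[j]) for i, j in zip(rows, cols)]

    if missing_rate > 0:
        mask = rng.random(log_mets.shape) < missing_rate
        rows, cols = np.nonzero(mask)
        log_mets[rows, cols] = np.nan
        record.missing = [(index[i], columns[j]) for i, j in zip(rows, cols)]

    degraded = CohortDataset(
        cohort_id=data.cohort_id,
        genotypes=data.genotypes.copy(),
        metabolites=pd.DataFrame(np.exp(log_mets), index=index, columns=columns),
        lipids=data.lipids.copy(),
        covariates=data.covariates.copy(),
        truth=dict(data.truth),
    )
    return degraded, record


# --------------------------------------------------------------------------
# twins


def simulate_twin_panel(
    n_mz: int, n_dz: int, a2: float, c2: float, seed=0
) -> TwinPanel:
    """Simulate standardized trait pairs under the ACE model.

    Pairs are bivariate normal with unit variances; the within-pair
    correlation is a2 + c2 for MZ twins and a2/2 + c2 for DZ twins.
    """
    if a2 < 0 or c2 < 0:
        raise ValueError("a2 and c2 must be nonnegative")
    if a2 + c2 > 1:
        raise ValueError(f"a2 + c2 must not exceed 1, got {a2 + c2}")
    rng = _rng(seed)

    def draw(n: int, r: float) -> np.ndarray:
        cov = np.array([[1.0, r], [r, 1.0]])
        return rng.multivariate_normal([0.0, 0.0], cov, size=n)

    mz = draw(n_mz, a2 + c2)
    dz = draw(n_dz, a2 / 2 + c2)
    pairs = pd.DataFrame(
        {
            "twin1": np.concatenate([mz[:, 0], dz[:, 0]]),
            "twin2": np.concatenate([mz[:, 1], dz[:, 1]]),
            "zygosity": ["MZ"] * n_mz + ["DZ"] * n_dz,
        }
    )
    return TwinPanel(pairs, truth=(a2, c2, 1.0 - a2 - c2))


# --------------------------------------------------------------------------
# genotype export (minimal VCF 4.2, GT only)


def write_vcf(genotypes: pd.DataFrame, path) -> None:
    """Write hard-call dosages as a minimal VCF 4.2 with GT fields only.

    Dosage d counts ALT alleles: 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, NaN -> ./.
    SNPs are placed on a synthetic contig at consecutive positions.
    """
    samples = list(genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##contig=<ID=1>',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for pos, snp in enumerate(genotypes.columns, start=1):
        calls = [
            gt_map.get(float(v), "./.") if np.isfinite(v) else "./."
            for v in genotypes[snp].to_numpy(dtype=float)
        ]
        lines.append(
            f"1\t{pos}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
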