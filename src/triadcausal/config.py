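"""Run configuration: every analysis threshold in one place.

Defaults are the study thresholds the engines assume: CV 25%,
missingness 5%, 5-SD outliers with a 0.70 independence correlation and
at most 3 independent outlying points per sample, Spearman screen alpha
0.05/(4*151), metabolite meta-analysis alpha 0.05/(102*151) with 0.05
nominal per-cohort significance, lipid meta alpha 0.05, the four SEM
admissibility criteria with a 2-unit BIC margin, and 1,000 bootstrap
replicates for MR intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assoc import metabolite_meta_alpha, spearman_alpha


@dataclass
class Thresholds:
    cv: float = 0.25
    missingness: float = 0.05
    outlier_sd: float = 5.0
    independence_corr: float = 0.70
    max_independent_outliers: int = 3
    spearman_alpha: float = field(default_factory=spearman_alpha)
    metabolite_meta_alpha: float = field(default_factory=metabolite_meta_alpha)
    nominal_alpha: float = 0.05
    lipid_meta_alpha: float = 0.05
    sem_p_min: float = 0.05
    sem_gfi_min: float = 0.9
    sem_rmsea_max: float = 0.05
    bic_margin: float = 2.0
    n_bootstrap: int = 1000
    friedewald_tg_ceiling: float = 400.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class SimulatedCohortConfig:
    """Simulation spec for one cohort in a fully synthetic run."""

    cohort_id: str = "COHORT"
    n_samples: int = 1000
    n_metabolites: int = 151
    n_null_snps: int = 20
    batches: list[str] = field(default_factory=lambda: ["B1", "B2"])
    # planted triads: list of dicts with keys snp, met, lip, model_id,
    # path_coefficients (edge string -> float), maf
    triads: list[dict] = field(default_factory=list)
    batch_shifts: dict[str, float] = field(default_factory=dict)
    outlier_rate: float = 0.0
    missing_rate: float = 0.0


@dataclass
class RunConfig:
    cohorts: list[SimulatedCohortConfig] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    output_dir: str = "triadcausal_output"

    # ------------------------------------------------------------- serde
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohorts = [SimulatedCohortConfig(**c) for c in d.get("cohorts", [])]
        thresholds = Thresholds(**d.get("thresholds", {}))
        return cls(
            cohorts=cohorts,
            thresholds=thresholds,
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir", "triadcausal_output"),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


def demo_config(seed: int = 17) -> RunConfig:
    """Packaged demo: two cohorts mirroring the study's scale (a larger
    three-batch cohort and a smaller two-batch one), one planted
    full-mediation triad (SNP -> MET -> LIP) and null SNPs."""
    triad = {
        "snp": "rs_demo",
        "met": "MET007",
        "lip": "TG",
        "model_id": 4,
        "path_coefficients": {"SNP->MET": 0.3, "MET->LIP": 0.5},
        "maf": 0.35,
    }
    return RunConfig(
        cohorts=[
            SimulatedCohortConfig(
                cohort_id="CohortA",
                n_samples=1797,
                batches=["B1", "B2", "B3"],
                triads=[dict(triad)],
                batch_shifts={"B2": 0.3},
                outlier_rate=0.0005,
                missing_rate=0.002,
            ),
            SimulatedCohortConfig(
                cohort_id="CohortB",
                n_samples=845,
                batches=["B1", "B2"],
                triads=[dict(triad)],
                batch_shifts={"B2": -0.2},
                outlier_rate=0.0005,
                missing_rate=0.002,
            ),
        ],
        seed=seed,
    )
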