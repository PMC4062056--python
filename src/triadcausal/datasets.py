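"""Core data containers shared across the pipeline.

The analysis operates on per-cohort tables sharing one sample index:
additive genotype dosages, metabolite concentrations (µM), the four main
serum lipids (TC, LDL-C, HDL-C, TG; mg/dl), and covariates (age, sex,
batch).  Twin data for heritability estimation are carried separately as
trait pairs with zygosity labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LIPID_NAMES = ("TC", "LDL-C", "HDL-C", "TG")

#: canonical variable order used by every engine: instrument, exposure, outcome
TRIAD_VARS = ("SNP", "MET", "LIP")

Edge = tuple[str, str]


def parse_edge(edge: str | Edge) -> Edge:
    """Normalise an edge given either as a (parent, child) pair or as
    a 'PARENT->CHILD' string."""
    if isinstance(edge, str):
        parent, _, child = edge.partition("->")
        parent, child = parent.strip(), child.strip()
    else:
        parent, child = edge
    if parent not in TRIAD_VARS or child not in TRIAD_VARS or parent == child:
        raise ValueError(f"invalid edge {edge!r}; variables must be distinct members of {TRIAD_VARS}")
    return (parent, child)


@dataclass
class TrueModelSpec:
    """Ground-truth generative model for one SNP-MET-LIP triad.

    Parameters
    ----------
    model_id
        Identifier into the path-model catalog (1-10, see :mod:`triadcausal.sem`).
    path_coefficients
        Map edge -> effect size.  Edges may be ``"SNP->MET"`` strings or
        ``("SNP", "MET")`` tuples and must be a subset of the named
        model's edge set.
    maf
        Minor-allele frequency of the instrument, in (0, 0.5].
    residual_sds
        Residual standard deviation per variable (all positive).  The SNP
        entry is ignored (genotypes follow Hardy-Weinberg proportions).
    confounder_effect
        Loading of a shared latent standard-normal confounder U on both
        MET and LIP; 0 disables confounding.
    seed
        Seed for forward simulation.
    """

    model_id: int
    path_coefficients: Mapping[str | Edge, float]
    maf: float
    residual_sds: Mapping[str, float] = field(
        default_factory=lambda: {"MET": 1.0, "LIP": 1.0}
    )
    confounder_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        for name, sd in self.residual_sds.items():
            if sd <= 0:
                raise ValueError(f"residual SD for {name} must be positive, got {sd}")
        coeffs = {parse_edge(e): float(v) for e, v in self.path_coefficients.items()}
        # late import: the catalog lives in the sem module
        from .sem import get_model

        model = get_model(self.model_id)
        extra = set(coeffs) - set(model.edges)
        if extra:
            raise ValueError(
                f"edges {sorted(extra)} are not part of model {self.model_id} "
                f"(edges {model.edges})"
            )
        self.path_coefficients = coeffs

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(self.path_coefficients)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "path_coefficients": {f"{p}->{c}": v for (p, c), v in self.path_coefficients.items()},
            "maf": self.maf,
            "residual_sds": dict(self.residual_sds),
            "confounder_effect": self.confounder_effect,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrueModelSpec":
        return cls(**d)


@dataclass
class CohortDataset:
    """One cohort's aligned data blocks (samples as rows everywhere)."""

    cohort_id: str
    genotypes: pd.DataFrame
    metabolites: pd.DataFrame
    lipids: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict[str, TrueModelSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.genotypes.index
        for name, block in (
            ("metabolites", self.metabolites),
            ("lipids", self.lipids),
            ("covariates", self.covariates),
        ):
            if not block.index.equals(idx):
                raise ValueError(f"{name} index does not match genotype index")
        if idx.has_duplicates:
            raise ValueError("duplicated sample IDs")
        geno = self.genotypes.to_numpy(dtype=float)
        finite = geno[np.isfinite(geno)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("genotype dosages must lie within [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def triad_frame(self, snp: str, met: str, lip: str) -> pd.DataFrame:
        """Extract one (SNP, MET, LIP) triple as a 3-column frame with
        complete cases only."""
        df = pd.DataFrame(
            {
                "SNP": self.genotypes[snp],
                "MET": self.metabolites[met],
                "LIP": self.lipids[lip],
            }
        )
        return df.dropna()

    # ------------------------------------------------------------------ I/O
    def write(self, directory: str | Path) -> None:
        """Write the cohort as TSV tables plus a JSON truth sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, block in (
            ("genotypes", self.genotypes),
            ("metabolites", self.metabolites),
            ("lipids", self.lipids),
            ("covariates", self.covariates),
        ):
            block.to_csv(directory / f"{name}.tsv", sep="\t", index_label="sample_id")
        sidecar = {k: v.to_dict() for k, v in self.truth.items()}
        (directory / "truth.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, directory: str | Path, cohort_id: str | None = None) -> "CohortDataset":
        directory = Path(directory)
        blocks = {
            name: pd.read_csv(directory / f"{name}.tsv", sep="\t", index_col="sample_id")
            for name in ("genotypes", "metabolites", "lipids", "covariates")
        }
        truth_path = directory / "truth.json"
        truth = {}
        if truth_path.exists():
            truth = {
                k: TrueModelSpec.from_dict(v)
                for k, v in json.loads(truth_path.read_text()).items()
            }
        return cls(cohort_id or directory.name, truth=truth, **blocks)


@dataclass
class TwinPanel:
    """Trait values for MZ/DZ twin pairs used by the ACE variance
    decomposition."""

    pairs: pd.DataFrame  # columns: twin1, twin2, zygosity in {"MZ", "DZ"}
    truth: tuple[float, float, float] | None = None  # (a2, c2, e2)

    def __post_init__(self) -> None:
        required = {"twin1", "twin2", "zygosity"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"pairs frame must have columns {sorted(required)}")
        bad = set(self.pairs["zygosity"]) - {"MZ", "DZ"}
        if bad:
            raise ValueError(f"unknown zygosity labels {sorted(bad)}")
        if self.truth is not None:
            a2, c2, e2 = self.truth
            if min(a2, c2, e2) < 0 or abs(a2 + c2 + e2 - 1.0) > 1e-9:
                raise ValueError("truth fractions must be nonnegative and sum to 1")

    @property
    def n_mz(self) -> int:
        return int((self.pairs["zygosity"] == "MZ").sum())

    @property
    def n_dz(self) -> int:
        return int((self.pairs["zygosity"] == "DZ").sum())

    def values(self, zygosity: str) -> np.ndarray:
        sel = self.pairs[self.pairs["zygosity"] == zygosity]
        return sel[["twin1", "twin2"]].to_numpy(dtype=float)


@dataclass
class TriadSet:
    """A cross-associated (SNP, MET, LIP) triple with its selection
    evidence (meta-analysis rows for SNP->MET and SNP->LIP)."""

    snp: str
    met: str
    lip: str
    met_evidence: "object | None" = None  # MetaAnalysisResult
    lip_evidence: "object | None" = None

    @property
    def label(self) -> str:
        return f"{self.snp} - {self.met} - {self.lip}"

    def to_json(self) -> str:
        def _ev(ev):
            if ev is None:
                return None
            return {"beta": ev.beta, "se": ev.se, "p": ev.p}

        return json.dumps(
            {
                "snp": self.snp,
                "met": self.met,
                "lip": self.lip,
                "met_evidence": _ev(self.met_evidence),
                "lip_evidence": _ev(self.lip_evidence),
            }
        )


def check_positive_definite(S: np.ndarray, name: str = "matrix") -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    return S
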