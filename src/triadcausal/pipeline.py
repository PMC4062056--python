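"""End-to-end orchestration: simulate -> QC -> screen -> associate ->
meta-analyse -> select triads -> conditional / MR / SEM per triad.

Every stage logs counts in and out to a machine-readable event list;
given the same configuration and seed the whole run is deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import assoc, causal, qc, sem
from .config import RunConfig, SimulatedCohortConfig
from .datasets import CohortDataset, TriadSet, TrueModelSpec
from .simulate import CohortSpec, inject_artifacts, simulate_cohort

logger = logging.getLogger("triadcausal")


@dataclass
class PipelineResult:
    config: RunConfig
    cohorts: dict[str, CohortDataset]
    qc_reports: dict[str, qc.QCReport]
    association_table: pd.DataFrame
    meta_table: pd.DataFrame
    triads: list[TriadSet]
    triad_report: pd.DataFrame
    events: list[dict] = field(default_factory=list)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.association_table.to_csv(directory / "associations.tsv", sep="\t", index=False)
        self.meta_table.to_csv(directory / "meta_analysis.tsv", sep="\t", index=False)
        self.triad_report.to_csv(directory / "triad_report.tsv", sep="\t", index=False)
        with open(directory / "triads.jsonl", "w") as fh:
            for t in self.triads:
                fh.write(t.to_json() + "\n")
        with open(directory / "qc_report.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in self.qc_reports.items()}, fh, indent=2)
        with open(directory / "events.json", "w") as fh:
            json.dump(self.events, fh, indent=2)
        with open(directory / "run_manifest.json", "w") as fh:
            json.dump({"config": self.config.to_dict(), "seed": self.config.seed}, fh, indent=2)


def _log(events: list[dict], stage: str, **info) -> None:
    events.append({"stage": stage, **info})
    logger.info("%s: %s", stage, info)


def _build_cohort(cfg: SimulatedCohortConfig, seed: int) -> CohortDataset:
    triads = {}
    for t in cfg.triads:
        spec = TrueModelSpec(
            model_id=t["model_id"],
            path_coefficients=t["path_coefficients"],
            maf=t.get("maf", 0.3),
            residual_sds=t.get("residual_sds", {"MET": 1.0, "LIP": 1.0}),
            confounder_effect=t.get("confounder_effect", 0.0),
            seed=seed,
        )
        triads[t["snp"]] = (spec, t["met"], t["lip"])
    cohort_spec = CohortSpec(
        cohort_id=cfg.cohort_id,
        n_samples=cfg.n_samples,
        n_metabolites=cfg.n_metabolites,
        n_null_snps=cfg.n_null_snps,
        batches=tuple(cfg.batches),
        triads=triads,
        seed=seed,
    )
    clean = simulate_cohort(cohort_spec)
    degraded, _ = inject_artifacts(
        clean,
        batch_shifts=cfg.batch_shifts,
        outlier_rate=cfg.outlier_rate,
        missing_rate=cfg.missing_rate,
        seed=seed + 1,
    )
    return degraded


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis on the configured (simulated) cohorts."""
    th = config.thresholds
    events: list[dict] = []
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.cohorts) + 2)

    # ---------------------------------------------------------- simulate
    cohorts: dict[str, CohortDataset] = {}
    for cfg, ss in zip(config.cohorts, seeds):
        cohort = _build_cohort(cfg, int(ss.generate_state(1)[0] % 2**31))
        cohorts[cohort.cohort_id] = cohort
        _log(events, "simulate", cohort=cohort.cohort_id, n_samples=cohort.n_samples)

    # ---------------------------------------------------------------- QC
    qc_reports: dict[str, qc.QCReport] = {}
    analysis: dict[str, dict[str, pd.DataFrame]] = {}
    for name, cohort in cohorts.items():
        completed_log_mets, report = qc.run_qc(
            cohort.metabolites,
            seed=config.seed + 101,
            cv_threshold=th.cv,
            missing_threshold=th.missingness,
            sd_threshold=th.outlier_sd,
            corr_threshold=th.independence_corr,
            max_independent=th.max_independent_outliers,
        )
        qc_reports[name] = report
        kept = completed_log_mets.index
        lipids = cohort.lipids.loc[kept]
        lipids_t, _, _ = qc.transform_traits(lipids, cohort.metabolites.loc[kept, completed_log_mets.columns])
        covs = cohort.covariates.loc[kept]
        mets_adj = assoc.residualize_block(completed_log_mets, covs)
        lips_adj = assoc.residualize_block(lipids_t, covs)
        analysis[name] = {
            "metabolites": mets_adj,
            "lipids": lips_adj,
            "genotypes": cohort.genotypes.loc[kept],
            "covariates": covs,
        }
        _log(
            events,
            "qc",
            cohort=name,
            samples_in=cohort.n_samples,
            samples_out=len(kept),
            metabolites_out=completed_log_mets.shape[1],
            excluded_metabolites=len(report.excluded_metabolites),
            imputed_cells=report.imputed_cells,
        )

    # ------------------------------------------------------------ screen
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, sig_pairs = assoc.spearman_screen(
            {n: (a["metabolites"], a["lipids"]) for n, a in analysis.items()},
            alpha=th.spearman_alpha,
        )
    _log(events, "spearman_screen", significant_pairs=len(sig_pairs))

    # ------------------------------------------------- association + meta
    rows = []
    per_pair: dict[tuple[str, str], list[assoc.AssociationResult]] = {}
    first = next(iter(analysis.values()))
    snp_names = list(first["genotypes"].columns)
    for name, a in analysis.items():
        traits = pd.concat([a["metabolites"], a["lipids"]], axis=1)
        for snp_id in snp_names:
            g = a["genotypes"][snp_id]
            for trait_id in traits.columns:
                try:
                    res = assoc.snp_trait_assoc(
                        g, traits[trait_id], cohort=name,
                        predictor=snp_id, outcome=trait_id,
                    )
                except ValueError:
                    continue
                per_pair.setdefault((snp_id, trait_id), []).append(res)
                rows.append(
                    {
                        "snp": snp_id, "trait": trait_id, "cohort": name,
                        "beta": res.beta, "se": res.se, "p": res.p, "n": res.n,
                    }
                )
    association_table = pd.DataFrame(rows)
    _log(events, "association", tests=len(rows))

    lipid_names = set(first["lipids"].columns)
    met_meta, lip_meta, meta_rows = [], [], []
    for (snp_id, trait_id), results in per_pair.items():
        if len(results) < 2:
            continue
        meta = assoc.inverse_variance_meta(results)
        meta_rows.append(
            {"snp": snp_id, "trait": trait_id, "cohort": "meta",
             "beta": meta.beta, "se": meta.se, "p": meta.p,
             "n": sum(r.n for r in results)}
        )
        (lip_meta if trait_id in lipid_names else met_meta).append(meta)
    meta_table = pd.DataFrame(meta_rows)
    _log(events, "meta_analysis", pairs=len(meta_rows))

    # ----------------------------------------------------- triad selection
    triads = assoc.select_triads(
        met_meta,
        lip_meta,
        meta_alpha=th.metabolite_meta_alpha,
        nominal_alpha=th.nominal_alpha,
        lip_alpha=th.lipid_meta_alpha,
    )
    _log(events, "select_triads", triads=len(triads))

    # -------------------------------------------- causal engines per triad
    report_rows = []
    for triad in triads:
        row: dict = {"snp": triad.snp, "met": triad.met, "lip": triad.lip}
        for name, a in analysis.items():
            frame = pd.DataFrame(
                {
                    "SNP": a["genotypes"][triad.snp],
                    "MET": a["metabolites"][triad.met],
                    "LIP": a["lipids"][triad.lip],
                }
            ).dropna()
            cond = causal.conditional_analysis(frame)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mr = causal.MendelianRandomization(frame).fit(
                    n_boot=th.n_bootstrap, seed=config.seed + 7
                )
            selection = sem.SemModel.from_dataframe(frame).select(
                p_min=th.sem_p_min,
                gfi_min=th.sem_gfi_min,
                rmsea_max=th.sem_rmsea_max,
                bic_margin=th.bic_margin,
            )
            change = cond.effect_size_change
            row.update(
                {
                    f"{name}_beta_unadj": cond.beta_unadj,
                    f"{name}_beta_adj": cond.beta_adj,
                    f"{name}_change_pct": "NA" if change is None else round(100 * change),
                    f"{name}_mr_estimate": mr.wald_estimate,
                    f"{name}_mr_ci95": f"{mr.ci95[0]:.3f}, {mr.ci95[1]:.3f}",
                    f"{name}_mr_ci90": f"{mr.ci90[0]:.3f}, {mr.ci90[1]:.3f}",
                    f"{name}_best_model": selection.verdict,
                }
            )
        report_rows.append(row)
    triad_report = pd.DataFrame(report_rows)
    _log(events, "causal_engines", triads=len(report_rows))

    return PipelineResult(
        config=config,
        cohorts=cohorts,
        qc_reports=qc_reports,
        association_table=association_table,
        meta_table=meta_table,
        triads=triads,
        triad_report=triad_report,
        events=events,
    )


# --------------------------------------------------------------------------
# genotype input


def read_genotypes(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a samples x SNPs additive-dosage matrix from TSV, or convert
    a VCF's GT fields to ALT-allele dosages.

    Multi-allelic VCF records are skipped with a warning; missing
    genotypes propagate as NaN.
    """
    path = Path(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0)
    if fmt != "vcf":
        raise ValueError(f"unknown genotype format {fmt!r}")
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record {var.ID or var.POS}", stacklevel=2)
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.array(
            [{0: 0.0, 1: 1.0, 3: 2.0}.get(t, np.nan) for t in var.gt_types]
        )
        data[var.ID or f"{var.CHROM}:{var.POS}"] = dosage
    return pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))


def _read_vcf_text(path: Path) -> pd.DataFrame:
    """Plain-text fallback parser for minimal GT-only VCFs."""
    samples: list[str] = []
    data: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if "," in fields[4]:
                warnings.warn(f"skipping multi-allelic record {fields[2]}", stacklevel=2)
                continue
            calls = []
            for entry in fields[9:]:
                gt = entry.split(":")[0].replace("|", "/")
                if "." in gt:
                    calls.append(np.nan)
                else:
                    calls.append(float(sum(int(x) for x in gt.split("/"))))
            data[fields[2] or f"{fields[0]}:{fields[1]}"] = np.array(calls)
    return pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
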