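"""Published two-cohort summary statistics for the FADS1 / GCKR / LPA
lipid loci, used as worked examples and arithmetic cross-checks.

These are reported (rounded) summary numbers from the KORA / TwinsUK
candidate-SNP analysis of 151 Biocrates metabolites and the four main
serum lipids: per-cohort association betas, conditional-analysis beta
pairs with their printed effect-size-change percentages, and the
Mendelian-randomization worked example at FADS1.  They let the
arithmetic layers (inverse-variance meta-analysis, effect-size change,
Wald ratio) be exercised against published values without any
individual-level data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Per-cohort SNP-metabolite association rows (log-metabolite units per
# effect-allele copy): (locus, snp, metabolite, cohort, beta, se)

SNP_METABOLITE_ASSOCIATIONS = pd.DataFrame(
    [
        ("GCKR", "rs1260326", "PC aa C40:5", "KORA", 0.032, 0.009),
        ("GCKR", "rs1260326", "PC aa C40:5", "TwinsUK", 0.047, 0.014),
        ("LPA", "rs1564348", "C3", "KORA", 0.049, 0.013),
        ("LPA", "rs1564348", "C3", "TwinsUK", 0.062, 0.019),
        ("LPA", "rs1564348", "C8:1", "KORA", 0.064, 0.020),
        ("LPA", "rs1564348", "C8:1", "TwinsUK", 0.143, 0.029),
        ("FADS1", "rs174546", "PC aa C38:4", "KORA", -0.136, 0.008),
        ("FADS1", "rs174546", "PC aa C38:4", "TwinsUK", -0.144, 0.014),
        ("FADS1", "rs174546", "PC ae C38:5", "KORA", -0.071, 0.007),
        ("FADS1", "rs174546", "PC ae C38:5", "TwinsUK", -0.092, 0.012),
    ],
    columns=["locus", "snp", "metabolite", "cohort", "beta", "se"],
)

#: published meta-analysis row for the GCKR SNP-metabolite pair
#: (combined beta, SE) for cross-checking inverse-variance pooling
GCKR_META_PUBLISHED = {"beta": 0.037, "se": 0.008}

# --------------------------------------------------------------------------
# Conditional analysis: published unadjusted / metabolite-adjusted SNP
# coefficients on the lipid, with the printed effect-size-change
# percentages, for all 38 cross-associated triads.
# Columns: kora_beta = LIP~SNP, kora_beta_adj = LIP~SNP+MET (KORA),
# *_pct = printed rounded percentage change; likewise for TwinsUK.

_ROWS = [
    # locus, snp, met, lip, kora_b, kora_badj, kora_pct, tw_b, tw_badj, tw_pct
    ("GCKR", "rs1260326", "PC aa C40:5", "TC", 2.789, 0.685, -75, 4.770, 2.747, -42),
    ("GCKR", "rs1260326", "PC aa C40:5", "TG", 0.081, 0.054, -33, 0.075, 0.058, -24),
    ("LPA", "rs1564348", "C3", "HDL-C", 1.095, 1.640, 50, 0.248, 1.171, 372),
    ("LPA", "rs1564348", "C8:1", "HDL-C", 1.095, 1.328, 21, 0.248, 1.319, 432),
    ("FADS1", "rs174546", "PC aa C32:0", "TG", 0.043, 0.061, 43, 0.048, 0.050, 3),
    ("FADS1", "rs174546", "PC aa C32:2", "TG", 0.043, 0.017, -61, 0.048, 0.034, -29),
    ("FADS1", "rs174546", "PC aa C34:2", "TG", 0.043, 0.006, -87, 0.048, 0.037, -22),
    ("FADS1", "rs174546", "PC aa C34:3", "TG", 0.043, 0.021, -50, 0.048, 0.035, -27),
    ("FADS1", "rs174546", "PC aa C34:4", "TG", 0.043, 0.102, 139, 0.048, 0.076, 58),
    ("FADS1", "rs174546", "PC aa C36:2", "TG", 0.043, 0.004, -90, 0.048, 0.041, -15),
    ("FADS1", "rs174546", "PC aa C36:3", "TG", 0.043, -0.016, -138, 0.048, 0.022, -54),
    ("FADS1", "rs174546", "PC aa C36:4", "TG", 0.043, 0.157, 268, 0.048, 0.084, 75),
    ("FADS1", "rs174546", "PC aa C36:5", "TG", 0.043, 0.077, 79, 0.048, 0.054, 13),
    ("FADS1", "rs174546", "PC aa C36:6", "TG", 0.043, 0.060, 40, 0.048, 0.053, 10),
    ("FADS1", "rs174546", "PC aa C38:4", "TG", 0.043, 0.177, 315, 0.048, 0.097, 102),
    ("FADS1", "rs174546", "PC aa C38:5", "TG", 0.043, 0.131, 206, 0.048, 0.069, 44),
    ("FADS1", "rs174546", "PC aa C40:4", "TG", 0.043, 0.103, 140, 0.048, 0.076, 58),
    ("FADS1", "rs174546", "PC aa C40:5", "TG", 0.043, 0.115, 168, 0.048, 0.077, 60),
    ("FADS1", "rs174546", "PC aa C40:6", "TG", 0.043, 0.071, 65, 0.048, 0.055, 14),
    ("FADS1", "rs174546", "PC aa C42:0", "TG", 0.043, 0.025, -41, 0.048, 0.030, -37),
    ("FADS1", "rs174546", "PC aa C42:1", "TG", 0.043, 0.016, -62, 0.048, 0.030, -38),
    ("FADS1", "rs174546", "PC aa C42:4", "TG", 0.043, 0.054, 26, 0.048, 0.051, 6),
    ("FADS1", "rs174546", "PC aa C42:6", "TG", 0.043, 0.067, 57, 0.048, 0.048, 0),
    ("FADS1", "rs174546", "PC ae C36:2", "TG", 0.043, 0.058, 36, 0.048, 0.054, 12),
    ("FADS1", "rs174546", "PC ae C36:3", "TG", 0.043, 0.069, 61, 0.048, 0.062, 29),
    ("FADS1", "rs174546", "PC ae C36:4", "TG", 0.043, 0.044, 2, 0.048, 0.037, -23),
    ("FADS1", "rs174546", "PC ae C36:5", "TG", 0.043, 0.031, -29, 0.048, 0.016, -66),
    ("FADS1", "rs174546", "PC ae C38:4", "TG", 0.043, 0.036, -16, 0.048, 0.044, -8),
    ("FADS1", "rs174546", "PC ae C38:5", "TG", 0.043, 0.030, -30, 0.048, 0.022, -55),
    ("FADS1", "rs174546", "PC ae C38:6", "TG", 0.043, 0.039, -10, 0.048, 0.030, -37),
    ("FADS1", "rs174546", "PC ae C40:1", "TG", 0.043, 0.056, 30, 0.048, 0.046, -3),
    ("FADS1", "rs174546", "PC ae C40:4", "TG", 0.043, 0.013, -71, 0.048, 0.049, 2),
    ("FADS1", "rs174546", "PC ae C40:5", "TG", 0.043, 0.014, -68, 0.048, 0.042, -13),
    ("FADS1", "rs174546", "PC ae C40:6", "TG", 0.043, 0.037, -13, 0.048, 0.034, -29),
    ("FADS1", "rs174546", "PC ae C42:1", "TG", 0.043, 0.060, 41, 0.048, 0.051, 6),
    ("FADS1", "rs174546", "PC ae C42:5", "TG", 0.043, -0.003, -106, 0.048, 0.031, -36),
    ("FADS1", "rs174546", "PC ae C44:5", "TG", 0.043, -0.001, -102, 0.048, 0.022, -54),
    ("FADS1", "rs174546", "PC ae C44:6", "TG", 0.043, -0.007, -117, 0.048, 0.006, -87),
]

CONDITIONAL_ANALYSIS = pd.DataFrame(
    _ROWS,
    columns=[
        "locus",
        "snp",
        "metabolite",
        "lipid",
        "kora_beta",
        "kora_beta_adj",
        "kora_change_pct",
        "twins_beta",
        "twins_beta_adj",
        "twins_change_pct",
    ],
)

# --------------------------------------------------------------------------
# Mendelian-randomization worked example at FADS1: rs174546 as instrument
# for the causal effect of PC ae C38:5 on TG in KORA.  beta_gx is the
# published SNP->metabolite coefficient, beta_gy the published SNP->TG
# coefficient, and the published Wald estimate was -0.62
# (95% CI -1.18 to -0.05).

MR_EXAMPLE = {
    "snp": "rs174546",
    "metabolite": "PC ae C38:5",
    "lipid": "TG",
    "cohort": "KORA",
    "beta_gx": -0.071,
    "beta_gy": 0.043,
    "published_estimate": -0.62,
    "published_ci95": (-1.18, -0.05),
}


def reproducible_conditional_rows(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rows of the conditional-analysis table whose printed (rounded)
    beta pairs reproduce the printed percentage exactly in *both*
    cohorts under round-half-to-even.

    Rounding the published betas to three decimals loses precision, so
    only a subset of rows round-trips; this selects that subset
    deterministically for exact arithmetic checks.
    """
    t = CONDITIONAL_ANALYSIS if table is None else table
    recomputed_k = np.round(100 * (t["kora_beta_adj"] - t["kora_beta"]) / t["kora_beta"])
    recomputed_t = np.round(
        100 * (t["twins_beta_adj"] - t["twins_beta"]) / t["twins_beta"]
    )
    mask = (recomputed_k == t["kora_change_pct"]) & (recomputed_t == t["twins_change_pct"])
    return t[mask].reset_index(drop=True)
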