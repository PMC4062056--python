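# Methods

This note documents the models implemented in `triadcausal`, the
defaults and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## The scientific setting

The package targets the two-cohort mQTL design in which candidate
lipid-associated SNPs, a targeted metabolomics panel (163 assayed
species, 151 surviving QC) and the four main serum lipids (TC, LDL-C,
HDL-C, TG) are measured on the same individuals. Once a SNP, a
metabolite and a lipid are pairwise associated, three engines
interrogate the direction of the metabolite–lipid relationship. All
engines are linear and operate on covariate-adjusted traits:
log-metabolites and log-TG (TG is right-skewed; the cholesterol traits
are approximately normal and stay untransformed), residualized on age,
sex and measurement batch.

## Quality control

*CV filter.* One reference blood sample measured five times per plate
gives, per plate, CV = sd/mean (sample sd, n−1 denominator — the
replicate count is small enough that the choice matters and the
unbiased-variance convention is used). The per-metabolite CV is the
plain mean over plates; a plate with zero mean leaves the CV undefined
and excludes the metabolite. Metabolites with mean CV > 0.25 or
missing rate > 0.05 are dropped; both inequalities are strict, so a
metabolite exactly at a threshold is retained.

*Outliers.* On the log scale, cells more than 5 SD from their column
mean are flagged, with column means/SDs computed once on the matrix as
given (a single pass keeps the rule deterministic; iterating
mean/SD re-estimation after each blanking can cascade on heavy-tailed
columns). Within a sample, flagged cells are grouped greedily in
column order: a cell joins the first existing group containing any
metabolite whose Pearson correlation with it is ≥ 0.70, else it opens
a new group. The group count is the number of *independent* outlying
points; samples with more than three are excluded entirely, the rest
only have the flagged cells blanked. The greedy rule is the simplest
deterministic reading of "correlated outliers count once"; it is
order-dependent only in contrived near-threshold configurations.

*Imputation.* Remaining missing cells are filled by chained equations:
columns visited in ascending missingness order for 10 cycles, each
regressed on all other columns over its originally observed rows, with
imputations drawn from the predictive normal (fitted value plus
residual-SD noise), all driven by one seed. Ten cycles is ample for
the near-linear dependence structure of log-metabolite panels.

*Lipid handling.* Cohorts reporting mmol/L are converted to mg/dl
(×38.67 for cholesterol traits, ×87.5 for TG). LDL-C can be derived by
the Friedewald equation LDL = TC − HDL − TG/5, declared invalid above
TG = 400 mg/dl (the standard clinical ceiling); such samples come back
missing with a warning.

## Association evidence

SNP–trait association is OLS of the trait on additive dosage with
intercept (plus age/sex/batch covariates when the trait has not been
pre-residualized; the pipeline pre-residualizes, which for these
orthogonal designs gives numerically indistinguishable betas). Cohorts
are combined by fixed-effect inverse-variance weighting,
w = 1/se², with a normal-approximation p on β/se — the standard
convention for fixed-effect pooling of per-cohort OLS estimates.

A triad enters the causal stage when the SNP–metabolite meta p is
below 0.05/(102·151) with nominal p < 0.05 in each cohort separately
(guarding against one-cohort artifacts), and the SNP–lipid meta p is
below 0.05. The Spearman metabolite–lipid screen uses tie-corrected
rho with the t approximation (a seeded permutation p below n = 30,
where the approximation frays) at α = 0.05/(4·151) in both cohorts
with concordant sign.

*Twin heritability.* The ACE decomposition is fitted by maximising the
bivariate-normal pair likelihood with within-pair covariance A + C
(MZ) and A/2 + C (DZ) and common variance A + C + E, components
bounded at zero (L-BFGS-B, Falconer-initialised plus an equal-thirds
restart). The trait is standardized first and components are reported
as fractions, so h² = a² and the estimate is scale-invariant.

## Conditional analysis

Both regressions (`LIP ~ SNP`, `LIP ~ SNP + MET`) are fitted on the
same complete-case sample. The attenuation statistic
(β̂_adj − β̂)/β̂ is −1 exactly at full attenuation and is undefined
(reported missing) when β̂ is zero to machine precision. An adjusted
p ≥ 0.05 flags the absence of evidence for a direct SNP→LIP path.
Because MET enters only as a regressor, the statistic is invariant to
linear rescaling of the metabolite.

## Mendelian randomization

The causal effect of MET on LIP is the Wald ratio
β̂_SNP→LIP / β̂_SNP→MET, identical to two-stage least squares for a
single instrument (asserted in the test suite to machine precision
against an independent 2SLS implementation). Confidence intervals are
percentile bootstrap over individuals — resampling the (SNP, MET, LIP)
rows jointly preserves their joint distribution — with 1,000
replicates by default and both 95% and 90% levels always computed.
Percentile intervals are the plainest choice consistent with a bare
replicate count; BCa would need the acceleration constant and adds
little at these sample sizes. Replicates whose first-stage slope falls
below 10⁻⁸ are excluded and counted (> 5% excluded warns, > 50%
errors). Instrument strength is summarised by the first-stage F with
the conventional F < 10 warning; a point estimate with |β̂_SNP→MET|
below 10⁻⁸ is refused outright.

## Structural equation modelling

The triad is modelled as v = Av + u with SNP exogenous, giving
Σ(θ) = (I−A)⁻¹Ψ(I−A)⁻ᵀ. The catalog conditions on the paths
originating at the SNP: SNP-edge subset ∈ {S→M}, {S→L}, {S→M, S→L}
crossed with the MET–LIP relation (M→L, L→M, none). The two
three-edge graphs and the two-SNP-edge graph with a free MET–LIP
residual covariance are saturated (df = 0) and Markov equivalent —
they reproduce any S exactly and share one maximised likelihood — so
only the seven models with df ≥ 1 are tested. Models 4 (S→M→L),
8 (S→L→M) and 10 (M←S→L) are the anchored, scientifically named
topologies; ids 5, 6, 7, 9 follow the deterministic enumeration order
above and are carried in output metadata, since only the anchored
three have conventional names.

Fitting minimises the ML discrepancy
F(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − 3 by BFGS with variances
log-parameterised (and the residual covariance parameterised through
atanh of the residual correlation, keeping Ψ positive definite). Two
starts are used: zero paths with variances from diag(S), and the
per-equation regression solution — for recursive models with diagonal
Ψ the latter is already the ML optimum, so the optimiser typically
verifies rather than searches. Convergence requires gradient norm
below 10⁻⁶. The test statistic is χ² = (n−1)·F_min on df = 6 − (free
parameters), the standard Wishart-likelihood scaling.

Fit indices: GFI = 1 − tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²] (the ML form);
RMSEA = √(max(χ²−df, 0)/(df·(n−1))), defined as 0 for saturated
models; BIC = χ² − df·ln n in the negative convention (more negative =
better; a saturated model scores 0). Selection requires p ≥ 0.05,
0.9 < GFI ≤ 1 and RMSEA ≤ 0.05; among admissible models the smallest
BIC wins only when it beats the runner-up by ≥ 2 units, otherwise no
model is selected — abstention is a first-class outcome.

Fitting operates on the raw (unstandardized) covariance so path
coefficients keep their trait units; χ² is invariant to separate
rescaling of MET and LIP because the residual variances are free.
Covariance-based ML coincides with full-information ML for complete
data, which is the situation after imputation.

## Synthetic data: what it emulates, what it does not

The generator forward-samples the same linear system the SEM engine
fits, so generative covariance equals implied covariance by
construction — this identity is the package's deepest internal oracle.
Defaults mirror the motivating design: a 1,797-sample cohort with
three batches and an 845-sample (unrelated) cohort with two; 151
metabolites generated on the log scale around one shared latent factor
(mild positive inter-metabolite correlation) and exponentiated;
lipids at population-typical locations (TC 200 ± 35, LDL-C 125 ± 30,
HDL-C 55 ± 14 mg/dl, TG log-normal about 110 mg/dl); bi-allelic
hard-call genotypes under Hardy–Weinberg equilibrium; twin panels of
configurable MZ/DZ counts with ACE-implied pair correlations. Age and
sex receive small additive effects on traits so that covariate
adjustment is exercised without creating confounding. Batch-effect
magnitudes are not pinned down by the design being emulated, so they
are configuration-driven; defaults (0.2–0.5 log-units) are chosen to
be comfortably visible to the QC and adjustment machinery. Injected
outliers are displaced ≥ 6 SD so a 5-SD rule must find them.

Not emulated: linkage disequilibrium and multi-SNP haplotypes,
population stratification, genotype-imputation dosage uncertainty,
assay-chemistry artifacts beyond additive batch shifts, and family
structure beyond twin pairs. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
assumptions, not robustness to those unmodelled features of real
cohort data.

## Problem sizes used in validation

The validation suites run at sizes chosen to make Monte-Carlo error
negligible relative to the tolerances while staying lightweight:
forward-simulation versus implied-covariance checks at n = 2×10⁵;
Wald/2SLS equivalence on 100 random datasets; bootstrap coverage over
500 simulations of n = 2,000 with 1,000 replicates each; SEM selection
recovery over 200 seeds per generating topology at n = 2,000 (paths
0.3/0.5); ACE recovery at 2,000 + 2,000 pairs; QC fidelity on a
600 × 163 panel engineered with 11 high-CV and 1 high-missingness
metabolites.

## Known limitations

- Single-instrument MR only; no multi-instrument median/Egger
  estimators, hence no protection against pleiotropy of the one
  instrument beyond what SEM's model comparison provides.
- SEM assumes linearity, multivariate normality of residuals and no
  latent confounding (beyond the one saturated residual-covariance
  model); an unmodelled confounder of MET and LIP can masquerade as a
  causal path.
- BIC-margin selection is conservative by design: with weak paths or
  small n it abstains rather than guesses.
- The QC independence rule's greedy grouping is one of several
  defensible formalisations of "correlated outliers count once";
  alternatives differ only at correlation values straddling 0.70.
- Related individuals are not modelled in association; the intended
  workflow analyses the unrelated subset of a family cohort, with twin
  pairs used only for the ACE decomposition.
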