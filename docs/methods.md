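# Methods

`cardiohi` implements a functional-biomarker analysis for transthyretin
amyloidosis (ATTR): neonatal rat cardiomyocytes are cultured in a
patient's plasma, stimulated (or not) with phenylephrine (PE), and the
attenuation of the hypertrophic growth response — the Hypertrophic Index
(HI) — is used as a prognostic marker for cardiac events. This note
documents the models, the defaults, and what the synthetic data do and
do not establish.

## The assay model

Each subject's plasma is applied at two concentrations (5% and 20% v/v)
with and without PE (50 µM), in quadruplicate wells across three
independent cardiomyocyte preparations ("experiments"). Plates carry
fetal-calf-serum (FCS) treated control wells. Segmented single cells are
filtered for vitality, averaged per well, and normalized per plate to
the FCS control mean (FCS ≙ 100%).

### Single-cell QC (`cardiohi.qc`)

A cell is retained when

* cell area / nucleus area ≥ `ratio_min` (default **1.5**, inclusive), and
* its nuclear (DAPI) stain intensity is *adequate*.

"Adequate" has no universal definition; the default is plate-local and
robust: median ± 3·MAD of the intensities in the plate's FCS wells,
where MAD is the raw (unscaled) median absolute deviation. This is
insensitive to the ≤ ~10% dead-cell contamination expected in control
wells, and can be overridden with absolute bounds. Wells retaining fewer
than `min_cells_per_well` cells (default **30**, our choice; it
stabilizes the well mean without discarding typically populated wells)
are dropped and logged. Wells are summarized by the arithmetic **mean**
of retained cell areas; the aggregate statistic is not dictated by the
assay, and the mean matches the downstream model estimates.

Filtering is pure flagging: no value is modified, no row silently
dropped, and the retained-cell set is monotone in `ratio_min`.

### The Hypertrophic Index (`cardiohi.hi`)

With S the normalized size of a PE well and U the experiment-level mean
of the same sample/concentration's unstimulated wells,

    linear mode:  HI = (S − U) / U
    log mode:     HI = (ln S − ln U) / ln U

Log mode is the inferential scale; linear mode exists for display
parity. Two choices deserve comment:

* **Order of operations.** Sizes are first scaled to percent-of-FCS and
  then logged. On the percent scale ln U ≈ ln 100 ≈ 4.6, comfortably
  away from zero, so the ratio of logs is numerically stable; a
  fraction-of-FCS scale (ln U ≈ 0) would blow up. It also brings
  log-mode HI magnitudes to the few-percent scale on which the
  dichotomization cutoff lives, versus the ~28–39% linear-display
  values.
* **Pairing.** PE wells are unpaired within an experiment, so each PE
  well is compared with the experiment's unstimulated mean, giving up to
  experiments × wells-per-condition (12) well-wise values per
  sample × concentration. The base of the logarithm cancels in the ratio
  (verified to < 1e−12).

A patient-level HI is the **median** of the well-wise values.

### Optimal-cutoff stratification (`cardiohi.cutpoint`)

Incremental candidate cutoffs are the midpoints between consecutive
distinct observed values — every achievable dichotomy is visited exactly
once. At each candidate a Cox proportional-hazards model of the chosen
endpoint (default: the composite MACE) on the high/low indicator is
fitted; the default `well_level` mode replicates each well-wise value as
a row and uses a sandwich variance clustered by patient for the Wald
test, accounting for within-patient correlation of replicate wells. A
`patient_level` mode (one row per patient median) is exposed for
sensitivity analysis. Candidates leaving either patient group below
`min_group_frac` (default 0.1) of the cohort are inadmissible;
candidates whose fit is degenerate (monotone likelihood/separation,
detected as |log HR| > 15, or an underflowed p) are flagged and
excluded. The selected cutoff minimizes the Wald p, ties broken toward
the smaller cutoff; patients are high iff their median HI ≥ cutoff.

The minimized p is reported **without multiplicity correction**. Under
the null this is anti-conservative — the test suite measures a
rejection rate well above the nominal 5% across 400 null simulations —
so a cutoff selected this way is exploratory and needs independent
confirmation.

### Survival analysis (`cardiohi.survival`)

Endpoints: HTX (death of any cause or heart transplantation), DMP
(hospitalization for cardiac decompensation), MACE (first of either).
Cox fits use Efron's tie approximation (the default of standard
survival software and the better approximation under ties); Wald
p-values for uni-/multivariate fits (cluster-robust on request),
likelihood-ratio p-values for Kaplan–Meier group comparisons. Median
follow-up is the reverse Kaplan–Meier median (censoring as the event);
a Cox model on the censoring distribution is additionally exposed for
group differences in follow-up. NTproBNP is adjusted for renal function
as adjusted = measured / exp(1.892 − 0.025·GFR), which leaves the value
unchanged at GFR = 75.68 ml/min and increases with GFR. cTnT positivity
is strictly > 50 pg/ml (1 ng/l ≡ 1 pg/ml; the loader normalizes either
unit header). Age-band NTproBNP cutoffs are deliberately **mandatory
configuration**: the published band values are not reproduced here and
no defaults are invented.

### Group comparisons (`cardiohi.group_stats`)

Well-level values are compared across groups with a linear mixed model —
group fixed effects, patient random intercept, REML — because replicate
wells are correlated. Estimates are reported as model means ± SE with
Wald contrasts against the control group. If no patient has more than
one well the random intercept is unidentifiable and an OLS fallback is
used with an explicit warning. Cohort characteristics use Pearson
chi-squared (no continuity correction) for categorical variables and
one-way ANOVA for continuous ones, at α = 0.05.

## The synthetic cohort (`cardiohi.synthetic`)

The generator emulates the study design so the full pipeline is testable
without any patient data. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| group sizes | 16 / 23 / 36 / 30 | Ctrl / ATTRv-PN / ATTRv-CA / ATTRwt |
| group latent HI means | 0.39 / 0.36 / 0.32 / 0.28 | linear-scale PE growth per group |
| latent SD | 0.06 | patient scatter; yields group-mean SEs ≈ 0.01–0.02 |
| plasma | {5, 20}% | PE response at 20% attenuated ×0.4 |
| design | 3 experiments × 4 wells ×(±PE) | 48 wells/patient |
| cells measured/well | Poisson(400) | of 20,000 seeded (metadata) |
| area dispersion σ | 0.40 | log-normal single-cell areas, median 2000 units |
| plate effect SD | 0.08 | multiplicative per-plate scale |
| dead fraction | 0.10 | low-quality cells injected for QC |
| HR high vs low | 0.24 | protective effect of preserved response |
| baseline event rate | 0.028 /month | MACE hazard of the low-HI stratum |
| HTX share | 0.3 | split of the MACE hazard into HTX vs DMP clocks |
| latent threshold | 0.29 | ≈ 30% of patients in the low (high-risk) stratum |
| follow-up horizon | 24 months | administrative censoring |

Choices of note, all made on design grounds:

* **Latent-to-observed link.** PE multiplies the median cell area by
  1 + latent HI, so the linear-display HI recovers the latent value and
  calibration is transparent.
* **Plate layout.** One plate per (experiment, batch of ≤ 8 samples)
  with 4 FCS wells each; plate maps are rarely published and the layout
  is configurable. Plate effects draw from their own RNG stream so runs
  differing only in `plate_effect_sd` share identical cell-level draws
  (this makes the plate-normalization invariant exactly testable).
* **Dead-cell model.** A low-quality cell gets an inflated nucleus
  (ratio < 1.5) with probability 0.7 and an out-of-range stain intensity
  with probability 0.5, conditioned on at least one, so every injected
  cell is actually filterable and both QC rules are exercised. Live-cell
  intensities are uniform on center ± halfwidth; since 3·MAD of a
  uniform is 1.5× its half-range, a clean plate passes the default
  bounds entirely — `dead_fraction = 0` implies 100% QC pass, exactly.
* **Outcomes.** Two independent exponential clocks (HTX, DMP) per
  patient with rates r·0.3 and r·0.7, both multiplied by 0.24 in the
  high-HI stratum and censored at 24 months; MACE is their composite by
  construction. r = 0.028/month was set by closed form to give ≈ 25
  MACE events per cohort at the default effect size.
* **Biomarkers.** Group-wise summaries (mean ± SE, SE→SD via √n) drive
  the draws; strictly positive markers (GFR, cTnT, NTproBNP) use
  moment-matched lognormals so positivity invariants hold, and age is
  clipped to the 19–89 inclusion range. The implied GFR dispersion is
  wide; these covariates exist to exercise the adjustment and subcohort
  machinery, not to mimic a clinical GFR distribution.

**What the generator does not emulate:** staggered accrual (median
follow-up equals the horizon when no events occur; the real cohort's
median follow-up is shorter than the horizon), informative censoring,
competing risks, inter-laboratory variation in absolute cell size,
per-field imaging structure within wells, and any dependence of the
measured biomarkers on the latent response. Passing tests therefore
demonstrate the *statistical machinery* is correct and calibrated under
the assumed data-generating process — not that the biology behaves this
way.

## Numerical choices

* Cox fits: Newton iterations to a step-norm precision of 1e−11 (so the
  log-HR matches an independent maximization of the partial likelihood
  to < 1e−6 on small fixtures); Efron ties.
* Scan degeneracy: |log HR| > 15 ⇒ separation, candidate excluded.
* Classification tie: patient HI exactly equal to the cutoff is "high".
* Selection tie: equal minimal p ⇒ smaller cutoff.
* Median of an even number of wells: mean of the two central values.
* CSV floats are written with 17 significant digits: byte-identical
  reruns at a fixed seed, and read-back exact to well below 1e−12.
* All randomness flows from one integer seed through per-stage
  `numpy.random.SeedSequence` spawns.

## Monte-Carlo problem sizes

The statistical acceptance tests run at sizes chosen to give informative
rates on a single CPU in minutes: CI-coverage of the true HR over 200
cohorts at the full study size (n = 105); cutoff-scan/brute-force
equivalence on 20 cohorts with ≤ 100 candidates; null calibration of the
minimized p over 400 simulations of 40-patient cohorts; cutoff
localization over 100 strong-effect cohorts at n = 105. The unit suite
uses a scaled-down design (12 patients, ~60 cells/well).

## Known limitations

* The one-step cutoff-localization target is not met under the default
  event rate (~20–25 events): the Wald-p curve has a flat bottom
  spanning several adjacent candidates because reclassifying a
  non-event patient barely moves the partial likelihood. The scan is
  exact (it matches brute force), but the *estimand* is intrinsically
  unstable at this resolution; the acceptance test documents the
  measured rate rather than relaxing the check.
* The minimized p is anti-conservative by construction; no
  permutation-adjusted p for the selected cutoff is provided (noted as
  an extension).
* `well_level` scans refit a Cox model per candidate (~1,260 candidates
  at full design); a full scan takes tens of seconds.
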