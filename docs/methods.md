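# Methods

`dpcrkit` quantifies the outcome of a targeted nuclease edit from droplet
digital PCR (dPCR) droplet counts, and models the kinetics of cleavage and
repair with a compartmental ODE. This note records the models, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Poisson partition statistics

A dPCR well partitions the reaction into `n` droplets (default 20 000).
With molecules loaded independently, the count per droplet is Poisson and
the mean load is recovered from the negative fraction:

    lambda = ln(n_total / n_negative_in_channel)

Absolute copies in the analysed partition set are `lambda * n_total`. All
downstream quantities are ratios of copies, so the per-droplet scale is
kept throughout; conversion to copies/µL through the partition volume
(default 0.85 nL) is provided for reporting only.

**Linkage.** Two probed sequences on one physical DNA molecule co-occupy
droplets, producing double-positive counts above the rate expected by
chance. With free FAM molecules (λ_F), free HEX molecules (λ_H) and linked
pairs (λ_L), the three negative fractions give the closed form

    λ_L = ln f_neg − ln f_FAM− − ln f_HEX−

which is exact on expected counts (verified to 1e-10 over a concentration
grid). Sampling noise can push λ_L or the free-channel remainders slightly
negative; estimates are floored at 0 (concentrations are physical
non-negatives) and the raw values retained for diagnostics.

**Uncertainty.** 95% CIs for per-channel copies come from a nonparametric
bootstrap (default 1000 resamples) of the four-class droplet vector as a
multinomial; resamples that saturate a channel receive a half-droplet
continuity correction. Measured coverage at λ = 0.3 in 20k droplets is
≥ 93% (test suite).

## Assays and double normalisation

Four duplex assay families decompose the edited locus:

* **edge** — FAM probe on the cut site (wildtype only), HEX probe ~25 bp
  away (wildtype + indel): `wt = f_FAM`, `indel = f_HEX − f_FAM`,
  `other = 1 − f_HEX`.
* **flanking** — 5′ (FAM) and 3′ (HEX) amplicons around the cut in one
  well. One-sided copy loss is end trimming, labelled a large deletion when
  the assay's primer/probe distance exceeds a configurable threshold
  (default 25 bp). Unresolved DSBs appear as loss of linkage.
* **aneuploidy** — sub-telomeric p/q-arm assays; signed percent change.
* **TI/episomal** — junction assay (integrations) and donor-internal assay
  (all donor copies); VCN = ploidy · donor/reference; an optional
  single-cut digested well gives the concatemer ratio.

Every fraction `f` above is **double normalised**: assay copies are divided
by the mean of the reference-assay copies in the same replicate, and that
ratio is divided by the replicate-averaged identical ratio in the unedited
mock. The second step cancels per-assay efficiency differences, making the
result an absolute fraction of loci. Donor-specific assays skip the mock
term (the mock carries no donor) and are normalised to references only.

**DSB statistic.** The default readout is the *co-presence* statistic

    dsb = max(0, (f5 + f3 − 1) − f_linked)

i.e. the fraction of loci with both sides present minus the fraction still
linked. The side average `mean(f5, f3) − f_linked` (and `min`) are exposed
as `dsb_statistic` options, but both are biased upward in the presence of
one-sided copy loss: a 10% one-sided large deletion inflates the mean rule
by 5 points while leaving the co-presence rule unbiased (the round-trip
tests demonstrate this). The co-presence form is therefore the default.

**Overlap resolution.** Edge "other" copy loss subsumes the DSBs and large
deletions the flanking assay resolves, so the combined summary reports
`other_aberration = max(0, edge_other − large_del − dsb)`, with clamping
logged. The stacked total `wt + indel + large_del + dsb + other + ti` is
flagged when outside [90, 110] — accumulated assay error legitimately moves
it off 100. Targeted-integration loci physically disrupt the edge amplicon;
they are quantified through the TI assay path, and mixtures with
substantial TI should not rely on the combined edge-other decomposition.

When an episomal donor with locus-identical homology arms is present the
flanking assay cannot be interpreted; `flanking_valid: false` suppresses
its outputs for those samples.

Wells are technical replicates (default n = 3); summaries report
mean ± sd (n−1) across replicates.

## Detection limits

    LoB = mean(blanks) + 1.645 · sd(blanks)
    LoD = LoB + 1.645 · sd(lowest level whose mean exceeds LoB)

using the sample (n−1) standard deviation throughout — the standard
convention for these one-sided 95% bounds. Measurements are
reference-normalised and dilution-corrected before comparison. The defining
calibration property — ~5% of blank measurements exceed the LoB formed from
their own batch — holds for Gaussian blanks in batches of 20 (the in-batch
construction; a fresh independent draw exceeds at ~6% for n = 20 because of
estimation noise in mean and sd). A linearity check (OLS of observed on
expected over the whole series, slope/intercept/R²) accompanies the LoD.

## Cleavage/repair kinetics

Three-state first-order model in percent of genome copies:

    dWT/dt  = −k_dsb·D(t)·WT + k_pr·DSB
    dDSB/dt =  k_dsb·D(t)·WT − K·DSB,   K = k_pr + k_in + k_ld + k_ti
    dIN/dt  = k_in·DSB,  dLD/dt = k_ld·DSB,  dTI/dt = k_ti·DSB

with nuclear-trafficking delay `D(t) = 1 − exp(−t/τ)` (default; a
one-parameter `hill` form `t/(t+τ)` is the configurable alternative — both
are smooth, monotone, D(0)=0, D(∞)=1). Auxiliary integrals DSB_cum and
PR_cum count cumulative cleavage and precise-repair events; both exceed
100% in the recurrent-cleavage regime.

Precisely repaired loci are indistinguishable from never-cut wildtype, so
the observable WT maps to the model WT state and k_pr is identified by the
repair-inhibitor contrast: k_dsb and τ are shared between the untreated and
inhibited conditions (the inhibitors do not alter nuclease activity), all
four repair coefficients are condition-specific (the data show k_in itself
changes ~20-fold under inhibition, so restricting condition-specificity to
k_pr alone would be inconsistent).

**Integration.** Fixed-step classical RK4 compiled with numba (default 200
sub-steps/h for simulation, 40/h inside the optimiser; ~0.2 ms per 24-h
trajectory). Runge–Kutta methods preserve linear invariants exactly, so
WT+DSB+IN+LD+TI = 100 holds to machine precision by construction; accuracy
against an adaptive implicit oracle (Radau, rtol 1e-10) is better than 1e-5
percent over the tested coefficient range, and the τ→0 equal-rate chain
matches the analytic solution to 1e-6.

**Fitting.** Bounded nonlinear least squares (scipy TRF) on all replicate
observations of all states and conditions simultaneously, unweighted, in
percent units (the replicate noise is approximately homoscedastic on that
scale). Rates bounded to [0, 20] h⁻¹, τ to [0.001, 5] h. Multi-start
(default 10) with log-uniform starts in [1e-4, 10] h⁻¹ guards against local
minima. Per-state R² = 1 − SS_res/SS_tot pooled across conditions.

**Bootstrap.** Replicate values are resampled with replacement per
condition/state/timepoint and the model refit from the point estimate
(default 1000 draws; 200 in the acceptance run). Resampling n replicates
understates the sampling sd of their mean by √((n−1)/n), which with n = 3
is a 18% narrowing; bootstrap deviations around the point estimate are
therefore inflated by √(n/(n−1)) before percentile intervals are formed.
With this correction, 95% intervals cover the generating coefficients in
~92% of repetitions in the 50-repetition recovery suite (2-point replicate
noise); without it coverage sits just below 90%. All stochastic routines
take explicit seeds and are bit-reproducible.

**Derived statistics** (per condition):

* generation half-life ln2/k_dsb and resolution half-life ln2/K, computed
  from coefficients (ignoring the delay window; a delay-inclusive numeric
  time-to-50%-cleaved is reported as a diagnostic);
* one-hour resolution likelihoods p_x = (k_x/K)(1 − e^(−K)) and
  p_unresolved = e^(−K) (a pure-ratio k_x/K variant, conditional on
  resolution, is an option) — these sum to 1 exactly;
* cleavage events per product K/k_x (absent when k_x = 0); the reciprocals
  over repair classes sum to 1 exactly — this identity is what lets the
  precise-repair burden be inferred from the mutation-class burdens;
* peak event velocities (percent/min) and times from the flux curves
  k_dsb·D·WT and k_x·DSB on a 0.01 h grid;
* times at which DSB_cum and PR_cum cross 100%, and the peak of standing
  precisely-repaired loci (WT minus the never-cut pool
  WT₀·exp(−k_dsb·∫D)).

**Recurrence.** The aggregate model expands into cohorts WT_c (precisely
repaired c times) and DSB_c (broken after the c-th cut):

    dWT_c/dt = k_pr·DSB_c − k_dsb·D·WT_c        (WT_0 starts at 100)
    dDSB_c/dt = k_dsb·D·WT_{c−1} − K·DSB_c

with the terminal cohort absorbing overflow (a warning suggests a larger
`c_max` when it holds more than the reporting threshold at t_end). By
linearity the cohort sums reproduce the aggregate trajectories exactly
(tested to 1e-6). Cumulative influx per cohort counts how many cleavage
cycles are populated above a threshold (default 0.1% of copies).

## Synthetic data

The generator is the package's study-condition authority:

* droplet wells: 20 000 droplets, 3 technical replicates, ~0.5 mean locus
  copies per droplet (5000 diploid cells); molecular species per outcome
  class are loaded by independent Poisson placement and classified by
  presence/absence per channel. Class→species maps: wildtype carries both
  edge probes on one molecule; indels keep only the distal probe; DSBs
  yield two independent flanking fragments; one-sided large deletions drop
  one flank; "other" aberrations (inversions, large insertions) destroy the
  edge amplicon but keep both flanks present and linked. An optional
  per-molecule shear probability (default 0) emulates random gDNA
  fragmentation between probe sites.
* kinetics series: the ODE model at 12 timepoints over 24 h (5 min to
  24 h), two conditions, additive Gaussian observation noise (default sd 2
  percentage points, clipped at 0), 3 replicates.
* dilution series: levels 100…0.4% with Gaussian noise sd 0.005 and 4
  replicates, floored at 0.

Not modelled: fluorescence amplitudes, rain or threshold ambiguity, PCR
efficiency and probe-mismatch thermodynamics, per-cell stochasticity,
cell-cycle dependence, or donor washout after 24 h. Passing round-trip
tests therefore show the *estimators* are unbiased and correctly scaled
under ideal Poisson partitioning — not that instrument-level artefacts are
handled.

## Problem sizes in the shipped test and acceptance runs

Round trips use 20 seeds × 20k droplets × 3 replicates; coverage suites use
50 repetitions with a 200-draw bootstrap and 4 starts; LoB calibration uses
10 000 batches of 20. These sizes make the full suite complete in a few
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* The combined stacked summary assumes the TI class is negligible or
  quantified separately (see overlap resolution above).
* Flanking trims report `max(trim5, trim3)` as the large-deletion class;
  two-sided independent deletions would be undercounted.
* The delay forms are phenomenological; only their monotone saturation
  matters for the fits.
* The bootstrap quantifies replicate sampling error only — it does not
  propagate droplet-level Poisson error from the upstream quantification.
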