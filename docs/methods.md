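# Methods

## Signal model

A spin-lock preparation applied at amplitude FSL (Hz) for duration TSL
(ms) imposes rotating-frame relaxation: the prepared magnetisation decays
as

    S(TSL) = S0 · exp(−TSL / T1ρ(FSL)),

with S0 the equilibrium signal and T1ρ the spin–lattice relaxation time
in the rotating frame.  In a multislice acquisition each slice's
spin-lock pulse also saturates the longitudinal magnetisation of every
other slice; when the per-slice recovery delay τ is comparable to T1 the
magnetisation settles into a steady state with available fraction

    Mz/M0 = Msat · (1 − e^(−τ/T1)) / (1 − Msat · e^(−τ/T1)),
    Msat  = exp(−TSL / T2ρ,eff),      1/T2ρ,eff = ½ (1/T1 + 1/T2).

The correction divides the measured signal at each TSL by Mz/M0 before
fitting.  It is applied with a single (cohort-average) T1/T2 per tissue
class, matching a study design in which per-session relaxometry maps are
unavailable; a per-voxel mode exists for sensitivity analysis (pass
single-voxel class masks).  Skipping the correction (`correction_on =
False`) reproduces the "uncorrected" analysis: because Mz/M0 decreases
monotonically with TSL, the uncorrected apparent decay is too fast and
T1ρ is biased low everywhere.

## Acquisition protocol (simulator defaults)

TSL = {1, 15, 30, 45, 60, 75, 90, 105} ms; FSL = {100, 500, 1000, 2000}
Hz; τ = 2000 ms per slice; TE = 4.59 ms (metadata only); ten 1 mm axial
slices with 0.2 mm gaps.  Volumes live on a shared, cropped
15.94 × 15.94 mm FOV: a 60×60 anatomical grid for ROI drawing and a
34×34 grid for the spin-lock series.  A single τ is used for all slices
regardless of interleaving order; the steady-state form absorbs the
ordering.

## Fitting

`fit_monoexponential` (single curve) is bounded trust-region least
squares on (S0, T1ρ), T1ρ ∈ [1, 2000] ms, S0 ∈ (0, 10 × max signal],
tolerance 1e−8, initialised from the closed-form log-linear fit; signals
are normalised by their maximum internally so the fit is exactly
scale-equivariant.  Plain (unweighted) least squares on magnitudes is
used deliberately — no Rician bias correction — matching the standard
monoexponential mapping practice this package models; the Rician floor
is a property of the simulator, not the fitter.

`fit_map` (volumes) solves the same least-squares problem by variable
projection: for fixed T1ρ the optimal S0 is closed-form, leaving a 1-D
profiled sum of squares in T1ρ that is bracketed on a 60-point log grid
over the bounds and refined by 60 golden-section iterations, fully
vectorised across voxels (≈10 µs/voxel, ~100× faster than per-voxel
trust-region calls).  The bracket-then-refine scheme converges far below
1e−6 relative error and is cross-checked voxel-by-voxel against the
single-curve fitter in the test suite.  Quality control: voxels that end
on a T1ρ bound or with R² < 0.5 (configurable) are set to missing and
excluded from ROI means; counts of exclusions are reported.  A flat
(non-decaying) curve legitimately drives T1ρ to the upper bound and is
reported as a boundary solution rather than an error.

## Phantom and cohort generator

The phantom is deliberately schematic: an ellipsoidal healthy-tissue
region (semi-axes 2.4 × 2.4 × 7.2 mm, central-slice area ≈ 18 mm²,
matching the observed healthy-brain ROI size of 18 ± 2 mm²) with an
optional spherical tumour just right of the midline (default centre
x = +1.0 mm; radius 1.0–1.4 mm by week, per-slice areas within the
observed 13 ± 10 mm² range but near its lower end, because the tumour
must fit inside the small healthy-region ellipsoid).  Voxels are
labelled by centre inclusion on the fine anatomical grid.  The
coarse-grid tissue class of a spin-lock voxel is defined by the same
≥50% area-majority rule used to transfer ROIs between grids, so a
voxel's true class and its ROI assignment agree; without this the
tumour-ROI boundary voxels dilute the tumour mean and bias ΔT1ρ toward
zero.

ROI masks mimic manual delineation: the tumour ROI is the tumour label;
the healthy ROI is the contralateral (x < −0.3 mm) part of the brain
label.  Mask transfer to the spin-lock grid uses exact area-overlap
resampling with an inclusive ≥50% threshold (ties at exactly 50% go to
the higher label id, i.e. tumour); the rule is deterministic and has an
exact brute-force oracle in the tests.

Noise is Rician: independent Gaussian noise of standard deviation σ on
both quadrature channels before magnitude.  SNR is defined as S0/σ
(default S0 = 100, SNR = 50).  Gaussian and noise-free models exist for
oracle tests.  The saturation in the forward model is the steady-state
Msat form (exactly invertible by the correction); an alternative
`sat_model="t1rho_decay"` replaces Msat with exp(−TSL/T1ρ) to probe the
correction's bias when its assumed mechanism is wrong.

Cohort draws: per measurement (mouse-week) and FSL, brain T1ρ is drawn
from the group's per-FSL normal distribution.  Tumour values follow the
default "delta" model: a per-measurement tumour-vs-brain percent
difference Δ is drawn from the group's per-FSL Δ distribution and the
tumour value set to brain × (1 + Δ/100).  This makes the cohort's
per-measurement Δ distribution match its configured mean ± SD exactly in
expectation — the right property for a generator parameterised from
pooled per-measurement Δ statistics, which a bivariate normal on the
brain/tumour marginals cannot reproduce (the mean of ratios differs
from the ratio of means once pairing structure is lost).  A
`tumour_model="bivariate"` mode draws correlated brain/tumour pairs
(default correlation 0.5) for sensitivity analyses.  Draws within a
measurement are correlated 0.5 across FSLs; measurements are otherwise
exchangeable within group (no explicit between-mouse variance component
— the analysis pools measurements, so only the pooled distribution
matters).  Optional linear weekly drifts of the group means are off by
default.

The default schedule reproduces the study design's pooled weeks-2–4
tumour/brain measurement counts of 0/15 (naive), 9/14 (wild-type) and
7/12 (mutant): five mice per group, tumours MRI-visible from week 3
(one early mutant tumour at week 2), early exits for some tumour-bearing
mice, naive mice imaged through week 6.

What the generator does *not* emulate: anatomically realistic tissue
(single compartment per class, no intra-ROI heterogeneity, oedema or
necrosis), B0/B1 inhomogeneity, EPI distortion or ghosting, motion, and
partial-volume mixing of relaxation parameters within a voxel.  Passing
recovery tests therefore demonstrate correctness of the correction,
fitting, ROI transfer and statistics under the stated noise model — not
robustness to physiological confounds.

## Statistics

Measurements are pooled across weeks 2–4 and compared with two-sided
Mann–Whitney U tests.  P-values are exact (full null distribution)
whenever n1 + n2 ≤ 20 and the pooled sample is tie-free, otherwise the
normal approximation with tie and continuity corrections is used; the
mode is recorded in every output row (the exact distribution assumes
continuous data, so ties force the approximation).  Benjamini–Hochberg
at FDR 5% is applied within each four-FSL comparison family, not across
families.  The six dispersion-ratio comparisons share FSLs and are not
independent, so they use a Bonferroni threshold 0.05/6 ≈ 0.0083 on raw
p-values.  The naive-group age screen fits OLS slopes of brain T1ρ
against week per mouse and FSL (t-test of zero slope, BH across the four
FSLs per mouse); a constant series returns slope 0 with p = 1, an exact
zero-residual non-constant fit returns p = 0.

Derived metrics: ΔT1ρ = 100 · (tumour − brain)/brain is computed per
measurement and then averaged within group (not as a ratio of group
means); dispersion ratios (T1ρ(high) − T1ρ(low))/T1ρ(low) are computed
per tumour ROI for all six ordered FSL pairs.

## Numerical choices and degenerate inputs

* T1ρ bounds [1, 2000] ms; fit tolerance 1e−8; R² threshold 0.5.
* Grid coordinates are pixel-centre aligned with the FOV origin at the
  volume centre; slice 0 is most inferior.  Metadata lives in JSON
  sidecars rather than NIfTI header extensions.
* Mask resampling ties (exactly 50/50) resolve to the higher label id.
* ROI SD uses the n−1 denominator and is 0 for a single voxel.
* All times are in ms and amplitudes in Hz throughout; τ is stored as
  2000 ms.
* Every cohort/pipeline run is driven by one integer seed;
  deterministic stages re-run byte-identically (NIfTI gzip streams are
  written deterministically).

## Problem sizes used in the shipped analyses

The acceptance script recovers group-mean ΔT1ρ from 192 tumour-bearing
measurements per glioma group (simulated and fitted in chunks of 32);
this replicate count puts the Monte-Carlo standard error of the group
mean near 0.9 percentage points while the estimator itself is unbiased
at any n.  The test suite uses 12 measurements per group for the same
experiment, with tolerances of three standard errors computed from the
configured distribution SDs.

## Known limitations

* The fitted T1ρ retains a small positive Rician-floor bias at SNR 50
  (≈ +0.5–1% at T1ρ ≈ 100–160 ms); it largely cancels in ΔT1ρ
  (residual ≈ −0.2 percentage points on the wild-type group).
* At SNR 50 the Cramér–Rao bound for this 8-TSL schedule already implies
  a median voxelwise |relative T1ρ error| of ≈ 2.4% (≈ 3.4% after the
  correction's noise amplification); ROI averaging, not voxel accuracy,
  is what makes the cohort metrics precise.
* With the configured group distributions and pooled sample sizes
  (9/14, 7/12), the weakest tumour-vs-brain comparison (mutant group at
  100 Hz, effect size d ≈ 1.2) has ≈ 0.6 power at the BH-adjusted level,
  so the full significance-star pattern reproduces in only ≈ half of
  seeded cohort replicates; the ΔT1ρ genotype separation itself is the
  robust finding.
* Dispersion ratios are reported but, as in comparable studies, carry
  little discriminative power at these sample sizes.
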