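# t1rho

Quantitative spin-lock (T1ρ) MRI analysis for preclinical glioma
imaging, built around one question: can the tumour-vs-brain T1ρ
difference act as a non-invasive marker of IDH1 mutation status?

T1ρ — the spin–lattice relaxation time in the rotating frame — is
measured by applying a spin-lock pulse of amplitude FSL for duration TSL
and fitting the monoexponential decay

    S(TSL) = S0 · e^(−TSL/T1ρ)

voxel by voxel.  In a multislice acquisition with a recovery delay τ on
the order of T1, the measured signal must first be divided by the
steady-state saturation factor

    Mz/M0 = Msat(1 − e^(−τ/T1)) / (1 − Msat·e^(−τ/T1)),
    Msat = e^(−TSL/T2ρ,eff),   1/T2ρ,eff = ½(1/T1 + 1/T2).

The biomarker is the per-measurement percent difference of ROI means,

    ΔT1ρ = 100 · (T1ρ(tumour) − T1ρ(brain)) / T1ρ(brain),

which normalises away between-animal variation: IDH1-mutant tumours run
≈ +29% against contralateral brain while wild-type tumours run ≈ +3%.
T1ρ dispersion — the relative change of T1ρ between two spin-lock
amplitudes — is computed for all six pairs of the four-FSL protocol.

The package is aimed at quantitative-MRI researchers who want a tested,
reproducible reference pipeline: a digital mouse-brain phantom and
cohort simulator with known ground truth, the saturation correction,
fast vectorised voxelwise fitting, ROI transfer between acquisition
grids, and the rank-based cohort statistics (Mann–Whitney U with
Benjamini–Hochberg FDR control, Bonferroni for the dispersion family,
and an age-trend screen).

## Worked example

```python
import numpy as np
from t1rho import (SpinLockProtocol, saturation_factor, DecayCurve,
                   correct_series, fit_monoexponential, mz_over_m0)

# steady-state saturation for mutant-group brain (T1=882 ms, T2=120 ms)
cf = saturation_factor(882.0, 120.0, tsl_ms=105.0, tau_ms=2000.0)
print(f"T2rho_eff = {cf.t2rho_eff_ms:.1f} ms, Mz/M0 = {cf.mz_over_m0:.3f}")

# simulate one noisy decay (T1rho = 98 ms, Rician SNR 50), correct, fit
proto = SpinLockProtocol()          # TSL 1..105 ms, FSL 100..2000 Hz
tsl = proto.tsl_array()
rng = np.random.default_rng(0)
f = mz_over_m0(882.0, 120.0, tsl, 2000.0)
clean = 100.0 * f * np.exp(-tsl / 98.0)
noisy = np.hypot(clean + 2.0 * rng.standard_normal(8),
                 2.0 * rng.standard_normal(8))
fit = fit_monoexponential(correct_series(DecayCurve(tsl, noisy),
                                         882.0, 120.0, 2000.0))
print(f"fitted T1rho = {fit.t1rho_hat_ms:.1f} ms, R^2 = {fit.r_squared:.4f}")
```

prints

```
T2rho_eff = 211.3 ms, Mz/M0 = 0.582
fitted T1rho = 104.4 ms, R^2 = 0.9946
```

— at TSL = 105 ms only 58% of the magnetisation is available, and a
single voxel at SNR 50 recovers T1ρ to within a few percent (ROI
averaging does the rest).  A whole recovery experiment — simulate
tumour-bearing cohorts from the default group distributions, fit every
voxel, reduce to ROI means and ΔT1ρ:

```python
from t1rho.pipeline import delta_recovery_study
df = delta_recovery_study(seed=1, n_per_group=12)
for g, name in ((2, "wild-type"), (3, "mutant")):
    d = df[df.group == g]
    print(f"group {g} ({name}): mean dT1rho = {d.delta.mean():+.1f}% "
          f"(truth {d.true_delta.mean():+.1f}%)")
```

```
group 2 (wild-type): mean dT1rho = +3.8% (truth +3.9%)
group 3 (mutant): mean dT1rho = +31.5% (truth +31.5%)
```

The fitted group means track the simulated ground truth to a fraction
of a percentage point; the genotypes separate by ≈ 28 points.

## Command line

```sh
t1rho run-all --seed 1 --out study/          # simulate -> fit -> metrics -> stats
t1rho simulate --seed 1 --out study/         # or stage by stage
t1rho fit --out study/ [--no-correction]
t1rho metrics --out study/
t1rho stats --out study/
```

A study directory contains the simulated cohort (4-D NIfTI series with
JSON sidecars, ROI label masks, study table), `measurements.csv` /
`metrics.csv` (long-format per-measurement values), the comparison
tables (`tests_t1rho_delta.csv`, `tests_dispersion.csv`,
`group_summary.csv`, `age_trends.csv`) and a `manifest.json` recording
the configuration hash and seed.

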