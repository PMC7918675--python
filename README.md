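# lipidmsot

Non-invasive postprandial lipid profiling with multispectral optoacoustic
tomography (MSOT), for researchers studying lipid metabolism and
cardiometabolic risk. After a high-fat meal, blood and tissue lipid levels
rise from their fasting baseline to a peak a few hours later; MSOT images
acquired at 930 nm — the NIR absorption peak of lipids — let that response
be tracked non-invasively in four forearm compartments at once: cephalic
vein, radial artery, skeletal muscle, and subcutaneous fat.

The package provides:

- **Synthetic study generation** (`lipidmsot.phantom`, `lipidmsot.simulate`):
  a seeded layered forearm phantom (coupling medium, skin, fat, muscle, with
  an embedded vein and artery), NIR chromophore spectra (Hb, HbO₂, lipid,
  water) on the 700–970 nm / 10 nm acquisition grid, a gamma-variate
  postprandial lipid kinetic
  `m(t) = 1 + A·(t/tₚ)^α·exp(α(1 − t/tₚ))`, and a forward model
  (absorption × depth-dependent fluence, Gaussian PSF, additive noise)
  emitting full time × wavelength image stacks with ground-truth masks.
- **ROI analysis** (`lipidmsot.roi`): mean ROI intensity on raw 930-nm
  frames, time-course extraction and max-normalization, **relative
  increase** `100·(max − v₀)/v₀` and **peak time** (argmax of the measured
  series, earliest tie wins), and half-max profile-line bands.
- **Agreement** (`lipidmsot.agreement`): pixelwise Cohen's kappa
  `κ = (p_o − p_e)/(1 − p_e)` between two raters' masks, with the 2×2 table.
- **Cohort statistics** (`lipidmsot.cohort`): per-compartment means and
  peak-time variability (sample SD, n−1) for per-subject records; the
  packaged four-subject pilot records ship as `lipidmsot.data`.
- A CLI (`lipidmsot simulate|analyze|summarize|kappa`) and numbered analysis
  drivers under `analysis/`.

## Worked example

```sh
python analysis/01_simulate_study.py --seed 1   # 13 x 28 frames, 2% noise
python analysis/02_extract_timecourses.py
```

prints, for the simulated cohort-mean kinetics:

```
compartment        rater  peak_time_min  relative_increase_pct
       vein ground_truth          180.0              78.705222
     artery ground_truth          240.0              64.566521
     muscle ground_truth          180.0             119.868067
        fat ground_truth          210.0              32.886073
```

i.e. the injected kinetics (vein +83.9% at 187.5 min, artery +63.4% at
232.5 min, muscle +120.8% at 180 min, fat +32.8% at 217.5 min) are
recovered on the 30-min sampling grid: peak times land on the schedule
step nearest the true peak, and increases match within a few percent (the
vein reads slightly low because the point-spread function mixes a little
of the surrounding fat signal into the lumen ROI; see `docs/methods.md`).

```sh
python analysis/03_cohort_summary.py
```

aggregates the per-subject pilot records into the compartment means
(vein 187.5 min / 83.9%, artery 232.5 min / 63.4%, muscle 180 min /
120.8%, fat 217.5 min / 32.8%) and the peak-time variability per subject
(28.7 / 45 / 78.9 / 57.4 min) and per compartment (artery lowest, 37.7 min).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch — phantom, simulation, ROI
extraction, cohort summary — and writes its JSON result to `--out`.
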