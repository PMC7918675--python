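# Methods

## The measurement being modelled

Postprandial lipemia is the transient rise of lipid levels in blood and
soft tissue after a fatty meal. In multispectral optoacoustic tomography
(MSOT) the reconstructed signal at a pixel is proportional to the locally
absorbed optical energy — absorption coefficient times light fluence — so
single-wavelength images read out chromophore contrast: 750 nm is weighted
toward deoxygenated hemoglobin, 850 nm toward oxygenated hemoglobin, and
930 nm sits on the NIR absorption peak of lipids. The analysis tracked
here is deliberately simple and assumption-light, mirroring how such pilot
data are actually processed: the arithmetic mean of the raw pixel values
inside a manually segmented ROI on the 930-nm frame, one value per
scheduled time point (fasting scan at t = 0, then every 30 min for 6 h),
no filtering, no fluence correction. From each series two numbers are
reported per compartment: the **peak time** (scheduled time of the global
maximum, earliest tie wins) and the **relative increase**
`100·(max − v₀)/v₀` over the fasting baseline, both computed on measured
values; division by the series maximum is a display normalization only.

## Spectral model

Absorption values for Hb, HbO₂, lipid and water are compiled from standard
literature extinction/absorption curves, resampled to the 28-point
700–970 nm grid and rescaled to comparable relative units (hemoglobin
extinctions divided by 10³). Only relative signals are analysed anywhere
in the pipeline, so no absolute μₐ calibration is attempted and the
package asserts only the qualitative orderings that the tissue
identification rests on: lipid(930) > lipid(750), lipid(850);
Hb(750) > HbO₂(750); HbO₂(850) > Hb(850). Lookups are exact grid lookups —
acquisition happens on the 10-nm grid, so interpolation is refused rather
than silently applied. `unmix_linear` (non-negative least squares via
`scipy.optimize.nnls`) is provided as plumbing for multispectral
appearance checks; the analysis itself uses single wavelengths.

## Phantom and forward model

The phantom is a probe's-eye forearm cross-section: coupling medium above
a flat skin line, then skin (1.5 mm), subcutaneous fat (thickness drawn
per seed from 5–9 mm), and muscle, with a superficial elliptical vein in
the fat (radius 1.2–1.8 mm, i.e. ~2.4–3.6 mm across, typical of the
cephalic vein) and a deeper artery in the muscle (radius 1.1–1.4 mm,
matching the radial artery). Default field of view 4 × 4 cm at
0.1 mm/pixel. Vessel placements are validated: a vessel outside its host
layer is a hard error.

Per frame, signal = μₐ(compartment, λ) × Φ(λ, depth), with
Φ = exp(−μ_eff·depth) and depth measured from the skin line (the coupling
medium neither absorbs nor attenuates meaningfully). μ_eff is a single
bulk value per wavelength, declining linearly from 0.10 mm⁻¹ at 700 nm to
~0.06 mm⁻¹ at 970 nm — soft-tissue scale; since the analysis applies no
fluence correction, only the relative depth weighting matters. The frame
is then blurred with a Gaussian PSF of 0.3 mm FWHM (the system resolution
being emulated) and additive zero-mean Gaussian noise is applied, with
sigma specified as a fraction (default 2%) of the mean noise-free skin
signal at 930 nm. The Grüneisen factor and all instrument scale factors
are absorbed into the arbitrary signal unit. All randomness flows from a
single integer seed through `numpy.random.SeedSequence`; the same seed
reproduces a study bit for bit.

### Kinetics

Each lipid-responsive compartment carries a gamma-variate multiplier
`m(t) = 1 + A·(t/tₚ)^α·exp(α(1 − t/tₚ))`: m(0) = 1 at fasting, maximum
1 + A exactly at t = tₚ, smooth single-peak rise and decay. A and tₚ are
exactly the two quantities the analysis reports, which makes ground truth
trivially comparable to pipeline output. The shape α (default 3) sets the
bolus width; defaults for the four compartments are the pilot-cohort
means (vein A = 0.839, tₚ = 187.5 min; artery 0.634/232.5; muscle
1.208/180; fat 0.328/217.5).

**Design choice — what the multiplier scales.** The multiplier scales the
compartment's whole absorption (all chromophores), not the lipid
concentration alone. Physically the postprandial change is in the lipid
component, but scaling only lipid would make the measured 930-nm increase
A times the lipid share of the compartment's 930-nm absorption (~7% of A
in a realistic vein mixture), so the simulated "true" amplitude would be
unrecoverable by the very analysis the simulator exists to validate.
Bulk scaling keeps the compartment-mean 930-nm signal exactly
proportional to m(t) — the property the validation tests assert — at the
cost of spectral realism in how the change is distributed across
wavelengths; the analysis only consumes 930 nm, so nothing downstream
depends on that distribution. The multiplier is wavelength-flat, so all
static spectral-contrast orderings are preserved at every time point.

### What the generator does and does not emulate

It emulates: the acquisition schedule (including shortened or irregular
ones), the wavelength grid, depth-dependent signal loss, finite
resolution, additive noise, compartment-specific spectral contrast, and
single-peak postprandial kinetics. It does not emulate: acoustic
reconstruction artifacts, motion/breathing, probe repositioning between
time points, speckle or structured noise, intra-compartment heterogeneity,
or rater variability in segmentation (ground-truth masks are exact
compartment supports). A green end-to-end test therefore establishes that
the analysis correctly inverts this stated world, not that it is robust
to every clinical nuisance.

## Analysis conventions

- Baseline is the single t = 0 fasting measurement; the schedule has
  exactly one pre-meal scan.
- Peak search includes the baseline point; ties break to the earliest
  time. A flat or decaying series yields a 0% increase.
- ROI means are computed on raw frame values. The optional
  `average_frames` pre-step (mean of k repeat frames) is available for
  burst recordings but is not applied by default.
- Profile lines are straight, sampled at nearest-pixel (Bresenham)
  coordinates; the half-max band is the maximal contiguous run containing
  the argmax with intensity ≥ 50% (configurable) of the line maximum.
  Pixel coordinates are 0-based row-major, origin top-left; intervals are
  inclusive.
- Cohen's kappa is computed over all image pixels, background included;
  the 2×2 agreement table is returned so restricted supports can be
  audited. κ is undefined (raised as an error) when both raters give the
  same constant label.
- Variability uses the sample SD (n−1); this convention is what
  reproduces the pilot cohort's printed values (the population SD does
  not). Display rounding is half-away-from-zero to 1 decimal; unrounded
  values are retained.

## Numerical notes

- Frames are float32 in memory and on disk by default; pass
  `dtype=np.float64` to `simulate_study` when asserting exact
  proportionality (the ~1e-9 checks in the tests), since float32 caps
  agreement near 1e-7.
- The exact-proportionality check is run with PSF and noise disabled: the
  PSF mixes neighbouring compartments into ROI edge pixels by design,
  which is also why the vein (bright fat neighbourhood, small lumen)
  reads a few percent low at the default 0.3 mm FWHM — a faithful
  partial-volume effect, kept within the ±10% recovery tolerance by
  using anatomically realistic vessel calibers.
- Noise-free background pixels are exactly zero before the PSF; after
  blurring, a thin halo of signal bleeds above the skin line, as in real
  reconstructions.

## Known limitations

- n = 4 subjects in the packaged records: cohort "means" are means of
  four values; no inferential statistics are offered, matching the
  descriptive scope of the source data.
- The raters' clinical masks are not public, so the cohort kappa cannot
  be reproduced; the kappa implementation is validated against worked
  examples and scikit-learn instead.
- Fig-style absolute spectra are not asserted — axes of published
  absorption plots are display-normalized — only orderings are.
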