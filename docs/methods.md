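# Methods

This note documents the models implemented in `sirtdosim`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical choices a maintainer would want to know about.

## Dose model

Dosimetry uses the local energy deposition (LED) assumption: the activity
measured in a voxel deposits its absorbed dose entirely in that voxel, so

    D_voxel = 50 Gy/(GBq/kg) × a_voxel / m_voxel

for ⁹⁰Y. LED is appropriate when the image's spatial blur (PSF plus
respiratory motion, of order 1 cm) is comparable to or larger than the mean
β range in tissue; transporting dose with point kernels or Monte Carlo
would only re-blur an already blurred signal. The package deliberately
implements no kernel/Monte-Carlo transport and no dose–volume histograms.

The administered activity is partitioned over the **whole grid**
proportionally to voxel intensity, not only over the liver. This makes the
dose maps invariant to the emission image's absolute calibration, and it
means signal imaged outside the liver (mostly motion spill-out toward the
lungs) dilutes in-liver doses; the spilled fraction is reported per study
as `out_of_liver_fraction` so that this bias is visible rather than hidden.
Activity measured after administration can be brought back to
administration time with `decay_correct` (half-life 64.05 h, the physical
constant for ⁹⁰Y).

Tissue density defaults to 1.03 g/mL (soft tissue) and is configurable;
all mass/volume conversions go through it. Masks are binary: a voxel
belongs to a VOI iff its label matches (no partial-voxel weighting in
patient VOIs).

The partition model (`partition_model_plan`) is the standard compartmental
split: the non-shunted activity divides between tumor and normal liver as
`r·m_T : m_N` for uptake ratio `r`; LED then gives `D_T / D_N = r`
identically. It is exposed as a planning calculator together with its
algebraic inverse (activity for a target normal-liver dose); it is not
calibrated against any cohort.

## Partial-volume correction

Recovery coefficients are measured on a synthetic sphere phantom: per
insert, RC = (mean measured concentration over the true sphere mask) /
(expected concentration). The implementation also checks the equivalent
total-activity formulation; over the same mask the two are algebraically
identical, and the check guards against mask/unit plumbing errors.

Two choices deserve explanation:

- **Expected concentration.** The calibration pipeline references the
  *truth grid's own in-mask mean*, not the nominal fill concentration.
  The digital phantom's surface voxels carry partial concentrations, so
  referencing the nominal fill would fold a ~2–6% discretization term into
  the RC that has nothing to do with the scanner; referencing the digital
  ground truth makes RC = 1 exactly at zero blur and isolates the
  acquisition's effect. `compute_rc` accepts any expected values, so a
  nominal-fill calibration remains available.
- **Curve axis and interpolation.** RC is indexed by sphere volume (the
  clinical lookup is "by estimated lesion mass"; mass converts to volume
  through the configured density). Interpolation is linear in log-volume —
  the standard sphere set spans 0.5–26.5 mL, nearly two decades — and is
  clamped to the end nodes outside the calibrated range. Clamping at the
  large end is conservative compared to extrapolating toward 1; clamping at
  the small end avoids inventing recovery below the smallest measured
  sphere. Looked-up values are additionally clamped to ≤ 1 because noisy
  large-sphere nodes can measure slightly above unity; node values are
  stored as measured.

Only **lesion** mean doses are RC-corrected. The non-tumor liver is large
compared to the PSF and gets no correction. Because LED is linear in
activity, correcting the VOI mean dose equals correcting the VOI activity
before conversion; a test asserts this identity.

Whether calibration includes motion blur and noise is configurable
(`calibrate_with_noise`, per-modality motion); the default calibrates with
deterministic blur only, which keeps the RC curves noise-free and
monotone.

## Synthetic data: what it emulates, what it does not

The generator stands in for clinical images that are not available, and its
defaults are the study conditions the package targets:

- **Phantom**: an elliptical-cylinder body (260 × 200 × 160 mm) with the
  six standard sphere inserts (10, 13, 17, 22, 28, 37 mm) on a 57.2 mm
  ring in the central transaxial plane, on a 2 mm grid. The fill uses an
  8:1 sphere-to-background ratio (40 / 5 kBq/mL). The true fill
  concentrations of the emulated experiment are not published; these
  defaults are assumptions and are fully configurable.
- **Acquisition**: isotropic Gaussian PSF — 10 mm FWHM SPECT-like, 5 mm
  PET-like — then an optional box blur along z for cranio-caudal breathing
  excursion (1–2 cm amplitudes are realistic), then optional Poisson
  resampling at a configurable counts-per-(kBq/mL) level (default 2 in the
  study pipeline, i.e. a few hundred counts per normal-liver voxel). No
  scatter, attenuation, detector geometry or iterative reconstruction is
  modelled, and no DICOM is emulated. Consequences: passing tests show the
  pipeline handles resolution loss, motion and counting noise correctly;
  they do not show robustness to reconstruction artifacts,
  scatter-correction differences between scanners, or registration error,
  all of which affect real data.
- **Patients**: an ellipsoidal liver (semi-axes 70 × 50 × 60 mm) bearing
  1–4 spherical lesions on a 3 mm grid. Lesion diameters are log-normal
  with median 1.8 cm truncated to [0.8, 5.7] cm, uptake ratios log-normal
  with median 3.8 truncated to [2.5, 10], administered activities
  log-normal with median 1.5 GBq truncated to [0.8, 4.1] GBq; the
  log-sigmas (0.55, 0.58, 0.5) reproduce the mean/median spread of the
  emulated cohort. The default cohort is 12 patients and 32 lesions so the
  agreement statistics run at a comparable n.
- **Predicted vs delivered discrepancy**: in the delivered grid each
  lesion's uptake is multiplied by `exp(N(0, σ²))` and the grid is
  renormalized to the same total. The default σ = 0.25 (lesion uptake
  typically within ±25–30% between MAA and microspheres) is a modelling
  choice, not a published value; σ = 0 makes predicted and delivered
  distributions identical, which the tests exploit as a limiting case.

Truth-grid lesions are filled binarily (voxel-center membership) so that
the measured uptake ratio equals the configured one to machine precision;
subvoxel occupancy handling is reserved for the phantom, where volume
accuracy matters. Phantom surface voxels are filled by 3×3×3 subvoxel
sampling with a one-subvoxel antialiasing ramp and a second-order curvature
correction (a planar ramp overestimates a convex surface by ≈ w²/12r);
this keeps sphere-volume errors below 0.2% on the default grid, against
roughly 1.5% for binary subvoxel counting.

## Statistics

Lin's concordance correlation coefficient uses population (divisor-n)
moments, Lin's original estimator:

    ρ_c = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²),   C_b = ρ_c / ρ .

Bland–Altman uses the sample (n−1) SD and a fixed 1.96 multiplier for the
95% limits of agreement. The emulated analysis states neither convention;
these are the conventional pairings. Differences are taken as
**delivered − predicted**, so a negative mean difference reads as "the
prediction overestimated" — matching how such results are usually phrased.
Spearman correlation uses mid-ranks for ties (delegated to scipy);
Kruskal–Wallis group comparison is likewise delegated.

Response thresholds are the criteria's published conventions (the emulated
analysis names the criteria without printing thresholds): RECIST/mRECIST
−30%/+20% on (enhancing) diameter with a 0.5 cm absolute minimum increase
for progression; WHO/EASL −50%/+25% on (enhancing) area; vRECIST −65%/+73%
on volume (the spherical equivalents of the RECIST cuts, as convention
rounds them — note +73% sits just above 1.2³ − 1 = 72.8%, so sphere
consistency with RECIST holds only away from that boundary); EORTC ±25% on
SUV (mean by default, configurable). All thresholds are configurable.
Boundary values classify into the category whose threshold they meet
(PR at exactly −30%, PD at exactly +20%). Complete response requires the
criterion's measure — for enhancement criteria, the enhancing measure — to
reach zero. Patient-level classification sums the target-lesion measures.

SUV is body-weight normalized; SUVpeak is the mean over a 1 mL sphere
(radius 6.2 mm) centered on the hottest voxel, by voxel-center inclusion,
and the sphere is anatomic — voxels outside the lesion mask still count,
a documented choice where conventions differ. The "SUVlbm peak" reported
alongside SUVbw in the emulated cohort is treated as the SUVbw-based peak;
lean-body-mass scaling needs height/sex fields that are not modelled. The
42% segmentation keeps the 26-connected component containing the maximum.

The study pipeline draws response categories **independently of dose**
(frequencies CR/PR/SD/PD = 0.10/0.30/0.45/0.15): the cohort it emulates
found no dose–response association, so the synthetic cohort is built under
that null, and a dedicated test checks the pipeline does not conjure an
association out of it.

## Numerical choices and degenerate inputs

- Blur kernels use zero-padding (`mode="constant"`); signal is conserved
  to < 1% provided the object sits ≥ 3 FWHM from the grid edge
  (`PhantomSpec.grid_padding_mm` exists for exactly this). The motion box
  width is rounded to the nearest odd voxel count to keep the kernel
  centered; filtered values a few ulp below zero are clipped.
- Every stochastic step takes an explicit seed; the study pipeline derives
  all per-patient seeds from the single config seed, and full runs are
  bit-reproducible (asserted in the tests).
- Degenerate inputs fail loudly: empty masks, zero-variance vectors,
  all-zero emission images, non-positive RC, overlapping or out-of-liver
  lesions all raise `ValueError`. Dose–response strata with a single
  category or constant doses are flagged `degenerate` with NaN statistics
  instead of a spurious p-value.
- Lesion placement is greedy rejection sampling (largest first, 500 tries,
  then the lesion is shrunk by 10% and retried) so cohort generation cannot
  dead-lock; shrinkage is rare at the default densities.
- Default problem sizes (2 mm phantom grid ≈ 1.0 M voxels, 3 mm patient
  grids ≈ 150 k voxels) keep a full 12-patient study under a few seconds
  while leaving ≥ 4 voxels across the smallest default lesion.

## Known limitations

- No reconstruction, scatter, attenuation or registration modelling — the
  simulated resolution loss is an idealized stand-in (see above).
- Spherical lesions and an ellipsoidal liver; no heterogeneous intratumoral
  uptake, necrosis, or lesion-shape effects on the RC lookup.
- The RC correction is VOI-level only; voxel-level deconvolution is out of
  scope by design.
- Lung shunt is a planning input only; lung dose is not computed.
- Survival analysis is out of scope; the response layer stops at
  CR/PR/SD/PD cross-tabulation.
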