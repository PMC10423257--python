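# sirtdosim

Voxel dosimetry for selective internal radiation therapy (SIRT) of liver
tumors with ⁹⁰Y microspheres, built to compare **predictive** dosimetry
(from a ⁹⁹ᵐTc-MAA SPECT/CT surrogate acquired at simulation angiography)
with **post-treatment** dosimetry (from ⁹⁰Y PET/CT acquired right after
administration). It is aimed at medical-physics and imaging researchers who
want a tested, reproducible implementation of the whole analysis chain on
synthetic phantom and patient images.

## What it computes

**Local energy deposition (LED) dosimetry.** The administered activity
*A* is partitioned over the emission image proportionally to voxel
intensity, `a_i = A · v_i / Σ v`, and each voxel's activity is assumed to
deposit its energy locally:

    D_i = 50 Gy/(GBq/kg) · a_i / m_i ,   m_i = ρ · V_voxel

with tissue density ρ = 1.03 g/mL by default. VOI dosimetry is the mean of
`D_i` over a label mask.

**Recovery-coefficient (RC) partial-volume correction.** A NEMA/IEC
NU-2-style sphere phantom (10–37 mm inserts) is imaged at SPECT-like
(10 mm FWHM) and PET-like (5 mm FWHM) resolution; per insert,
RC = measured / expected mean activity concentration. Lesion mean doses
are divided by the RC interpolated (linearly in log-volume) at the lesion
volume: `D_corr = D / RC(V)`.

**Agreement statistics.** Predicted vs delivered doses are compared with
Lin's concordance correlation coefficient ρ_c = ρ · C_b (precision ρ ×
accuracy C_b), Bland–Altman mean difference ± SD with 95% limits of
agreement (mean ± 1.96 SD, differences taken as delivered − predicted),
and predicted-to-actual dose ratios.

**Tumor response.** RECIST 1.1, mRECIST, WHO, EASL, vRECIST and EORTC
classification (CR/PR/SD/PD) plus SUVbw max/mean/peak, 42%-of-maximum
lesion segmentation, TLG, and dose–response cross-tabulation with Spearman
rank correlation and a Kruskal–Wallis group test.

**Synthetic data.** Because the analysis is exercised end-to-end without
clinical images, the package generates its own ground truth: the sphere
phantom, and livers bearing 1–4 spherical metastases with a configurable
tumor-to-normal uptake ratio (default median 3.8) and a per-lesion
log-normal discrepancy between the predicted and delivered activity
distributions. Acquisition is simulated as Gaussian point-spread blur,
optional axial respiratory motion blur, and Poisson noise.

## Worked example

Run the full synthetic study (phantom calibration → 12-patient cohort with
32 lesions → dual-modality dosimetry ± RC correction → agreement):

```sh
sirtdosim study --seed 5 --out study_out
```

which prints (abridged):

```
tumor_uncorrected: n=32 rho=0.911 rho_c=0.745 C_b=0.817 mean_diff=110.93 sd=138.48 LOA=(-160.5, 382.3)
tumor_corrected:   n=32 rho=0.932 rho_c=0.915 C_b=0.982 mean_diff=3.30  sd=133.01 LOA=(-257.4, 264.0)
non_tumor_liver:   n=12 rho=0.999 rho_c=0.997 C_b=0.998 mean_diff=2.26  sd=2.46  LOA=(-2.6, 7.1)

predicted-to-actual dose ratio medians (with RC: 1.02, without RC: 0.78)
```

Reading: without partial-volume correction the predictive dosimetry
underestimates lesion doses (ratio median 0.78, large positive mean
difference in Gy); applying the phantom-derived RC removes most of the bias
(ratio median 1.02, mean difference ~3 Gy) and lifts the accuracy
coefficient C_b from 0.82 to 0.98, while the non-tumor liver — large and
barely affected by partial-volume losses — agrees almost perfectly.
`study_out/` holds the per-lesion dose table, RC curves, agreement JSON,
dose–response cross-tabs and a run report echoing the seed.

The same stages are available piecewise (`phantom`, `acquire`,
`calibrate-rc`, `dose`, `agree`, `respond`) and as library functions
(`make_nema_phantom`, `simulate_acquisition`, `compute_rc`,
`build_activity_map`, `led_dose_map`, `lin_ccc`, …).

## Layout

- `src/sirtdosim/grids.py` — image/label containers, NIfTI I/O
- `src/sirtdosim/synthetic.py` — phantom, acquisition simulation, patients
- `src/sirtdosim/pvc.py` — RC calibration, lookup, dose correction
- `src/sirtdosim/dosimetry.py` — activity partitioning, LED dose, partition model
- `src/sirtdosim/uptake.py` — SUV, 42% segmentation, SUVpeak, TLG
- `src/sirtdosim/agreement.py` — Lin CCC, Bland–Altman, ratios, Spearman
- `src/sirtdosim/response.py` — response criteria, dose–response tables
- `src/sirtdosim/pipeline.py` — study orchestration
- `docs/methods.md` — models, assumptions, parameter choices, limitations
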