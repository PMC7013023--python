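# spectrc

Quantitative ¹⁷⁷Lu SPECT/CT systems differ in collimator response,
reconstruction algorithm and default settings, so the *recovery
coefficient* (RC) — the ratio of imaged to true activity concentration in
a structure — can vary substantially between sites for the same lesion
size. This matters directly for dosimetry in radionuclide therapy:
inter-system RC differences translate one-to-one into absorbed-dose
differences. `spectrc` implements the analysis chain of a multi-centre
phantom comparison — camera cross-calibration, background-corrected
isocontour segmentation, recovery coefficients with repeatability, the
inter-system variability metric, and logistic recovery-curve fitting —
together with a synthetic phantom/acquisition/OSEM simulator that stands
in for the physical scanners, so that the whole pipeline is testable on a
desk.

The package is aimed at medical-physics groups who harmonize quantitative
SPECT between systems and want a reproducible, scriptable reference
implementation of the phantom analysis.

## The model

**Phantom.** A cylindrical phantom (Ø 216 mm × 186 mm interior, ≈ 6.7 l
background) carries six spherical inserts of inner diameter 9.9, 15.4,
19.8, 24.8, 31.3 and 60.0 mm, filled at a 10:1 sphere-to-background
concentration contrast (nominally 750 / 75 kBq/ml ¹⁷⁷Lu, half-life
159.53 h).

**Calibration factor.** For a uniform phantom of known concentration *C*,

    CF [(cps/ml)/(kBq/ml)] = ( μ / (t · n · ν) ) / C

with μ the mean voxel value (counts) in a VOI, *t* the time per
projection, *n* the number of projections, ν the voxel volume. CF in
these units equals cps/kBq, i.e. 1000 × the conventional cps/MBq figure.

**Segmentation.** Each sphere VOI is grown from a seed as the connected
region at or above the background-corrected 50 % isocontour

    VOI_thresh,j = 0.5 · (VOI_max,j + VOI_mean,bg)

where VOI_mean,bg comes from a cylindrical background VOI (Ø 90 mm ×
50 mm) in a uniform part of the phantom.

**Recovery coefficients.** With A_i the imaged concentration averaged over
repeated measurements and A_a the actual (decay-corrected) concentration,

    RC_mean,j = A_i,j / A_a,j        RC_max,j = A_i,max,j / A_a,j

**Inter-system variability.** For each sphere *j*,

    Range_j = RC_j,max − RC_j,min

over systems, plus the percent quantification difference
(max − min)/min × 100. Ranges are compared between *vendor-specific*
reconstructions (each system's own settings) and a *vendor-neutral*
reconstruction (the same raw data reconstructed with one standardized
setting: 5 iterations × 16 subsets OSEM, 5 mm Gaussian, 4.8 mm voxels).

**Recovery curve.** RC versus sphere volume V is fitted with a
3-parameter logistic

    RC(V) = A / (1 + (V50 / V)^γ)

with free asymptote A, half-volume V50 and steepness γ; goodness of fit
is the squared Pearson correlation between observed and fitted RC, and
confidence/prediction bands come from a seeded smoothed residual
bootstrap.

## Worked example

```python
from spectrc import pipeline

cfg = pipeline.ExperimentConfig(seed=1, out_dir="results_quickstart")
result = pipeline.run(cfg)

print(result.per_sphere.head(3)[["system", "recon_mode", "sphere_label",
                                 "rc_mean", "rc_max"]])
for key, fit in sorted(result.fits.items()):
    print(f"{key}: R^2={fit['r2']:.4f}")
```

On the bundled four-system experiment (master seed 1) this prints, among
others:

```
discovery_nm670_pro/vendor_neutral: R^2=0.9776
discovery_nm670_pro/vendor_specific: R^2=0.9956
symbia_intevo_bold/vendor_neutral: R^2=0.9943
symbia_intevo_bold/vendor_specific: R^2=0.9912
symbia_t16_system1/vendor_neutral: R^2=0.9908
symbia_t16_system1/vendor_specific: R^2=0.9894
symbia_t16_system2/vendor_neutral: R^2=0.9745
symbia_t16_system2/vendor_specific: R^2=0.9745
```

i.e. every simulated recovery curve is fitted with R² ≥ 0.96. The
`comparison.csv` output shows the harmonization effect; at seed 1 the
worst per-sphere RC_mean range across systems drops from 0.163
(vendor-specific) to 0.070 (vendor-neutral), and the range shrinks for
every sphere. The RC_mean for the 9.9 mm sphere is ~0.2–0.34 (severe
partial-volume loss) while RC_max for the larger spheres exceeds 1
(Gibbs overshoot from resolution-modelled OSEM) — both behaviours the
physical systems show. The background-compartment recovery stays within
a few percent of unity (1.01–1.04 at seed 1).

The same chain is scriptable from a shell:

```
spectrc all --config configs/quickstart.yaml --seed 1 --out results_quickstart
```

Subcommands `simulate`, `calibrate`, `quantify` (ingest of NIfTI + JSON
sidecar exports), `compare`, `fit` and `init-config` expose the
individual stages.

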