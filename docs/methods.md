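# Methods

This note documents the models, algorithms and design choices behind
`spectrc`, in the order the pipeline runs them.

## Phantom model

The phantom is described analytically: a cylinder (default interior
Ø 216 mm × 186 mm, 6.82 l gross) with six spherical inserts of inner
diameter 9.9–60.0 mm. Background volume is computed by exact bookkeeping
(cylinder minus spheres, ≈ 6.67 l); sphere wall thickness is ignored.
Sphere centres default to a 65 mm-radius ring at mid-height (the sphere
plane, z = 0), 60° apart, ordered by diameter — the physical phantom
fixes only the ordering, so the layout is configurable. The 15.4 mm and
19.8 mm inserts are catalogued as 2.0 and 4.0 ml; the analytic (π/6)d³
volumes (1.91, 4.06 ml) are used throughout, the catalogue values being
nominal.

Activity bookkeeping uses a single reference time. The ¹⁷⁷Lu half-life
defaults to the physical 159.53 h (6.647 d) and is configurable. Decay is
applied per acquisition timestamp, and the per-projection time is
inflated by the reciprocal decay factor, so expected counts are
timestamp-independent — the decay-adjustment scheme used when a phantom
circulates between sites over days. The default schedule spreads the
4 systems × 3 repeats evenly over 74.7 h.

## Synthetic acquisition and reconstruction

The simulator is a deliberately reduced physical model whose purpose is
to reproduce the *mechanisms* behind inter-system RC differences
(partial-volume loss, resolution-recovery overshoot, reconstruction-
setting dependence), not any scanner's absolute performance.

**Rasterization.** The analytic phantom is voxelized on a fine grid
(2.4 mm default) with subvoxel averaging (oversample² ³ points per
voxel), so boundary voxels take fractional values.

**Projector.** A rotation-based parallel-beam projector works
slice-by-slice transaxially: for each of the 128 evenly spaced angles the
volume is rotated (bilinear, precomputed gather weights), multiplied by
the attenuation factor, summed along the ray axis, and rebinned onto a
fixed detector grid (128 transaxial × 28 axial bins of 4.8 mm) by
interval-overlap (boxcar) rebinning, which conserves counts and is free
of beat-frequency ripple between incommensurate grid spacings. The
Gaussian collimator-detector PSF (a single distance-independent FWHM per
system, 11.6–12.3 mm at the phantom centre) is applied in the projection
domain. Attenuation is uniform water (μ = 0.137 cm⁻¹ at 208 keV) over
the cylinder support; because the cylinder is rotationally symmetric one
2-D attenuation map serves every angle. The same map is used in the
reconstruction — ideal CT-based attenuation correction. Scatter is not
simulated and no energy-window scatter correction exists.

The axial field of view is a 134.4 mm slab positioned to contain the
sphere plane and the background-VOI region. Because the projector
treats transaxial slices independently, reconstructing this sub-slab is
exact; activity outside the slab is invisible (idealized axial
collimation). This is the dominant runtime economy.

**Counting statistics.** Expected counts per bin are
(sensitivity/10⁶)·t·ν·(attenuated line integral); with ~500 MBq in the
calibration phantom and 40 s projections this yields tens of thousands
of counts per view, matching clinical count levels. Noise is an
independent Poisson draw per bin. Every random stream derives
deterministically from the master seed via a CRC-32 mix of
(seed, system name, repeat index), kept below 2³¹ and stable across
versions.

**OSEM.** A standard multiplicative ordered-subsets EM update with
per-subset sensitivity images. Angles are partitioned round-robin, which
stays balanced when the subset count does not divide the projection
count (the Discovery preset's 10 subsets vs 128 angles; a warning is
emitted). When resolution modelling is on, the reconstruction's forward
model includes a Gaussian PSF of `model_psf_fraction` × the true FWHM.
The default fraction is 0.5: clinical resolution recovery is incomplete
(the distance-dependent response is approximated and scatter tails are
unmodelled), and a fully matched model produces edge (Gibbs) overshoot
far stronger than physical systems show. With the default, simulated
RC_mean curves are monotone with RC_max slightly above 1 for the larger
spheres — the qualitative behaviour of resolution-modelled clinical
reconstructions. A matched model (fraction 1.0) is used in the
self-consistency tests (count conservation, uniform-phantom recovery).

**System presets.** Four profiles named after the study systems carry
the published reconstruction settings (iterations × subsets,
post-filter, voxel size: 9×10/none/2.0 mm; 6×8/5 mm/4.9 mm;
4×8/4 mm/4.8 mm; 5×16/5 mm/4.8 mm) and published sensitivities
(6.2, 10.2, 10.3, 10.1 cps/MBq). The per-system PSF FWHMs (12.3, 11.6,
11.9, 12.1 mm) are the package's own choice: no measured PSFs are
published, all four cameras are the same hardware class (dual-head NaI
with medium-energy collimation), so a narrow spread is assumed; the
values place the simulated recovery curves inside the plausible band of
the measured ones. The "vendor-neutral" mode reconstructs the *same*
noisy sinogram per (system, repeat) with the standardized settings
(5×16, 5 mm Gaussian, 4.8 mm voxels) while keeping the acquiring
system's PSF and sensitivity — exactly the study's design, where raw
projections were re-reconstructed in one common package.

## Calibration

`simulate_calibration_phantom` images a homogeneous 6.8 l cylinder with
500 MBq; `measure_cf` applies the CF formula over a centred cylindrical
VOI (60 % of the phantom diameter, 50 % of its height — large enough to
average noise, clear of edge ringing). The CF uncertainty is the
quadrature of the dose-calibrator uncertainty (default 5 %) and the
repeat scatter of the VOI mean when repeats are provided. The chain
closes: on noiseless converged simulations the measured CF reproduces
the preset sensitivity to within ~0.5 %. Dose-calibrator cross-checks
are plain deviation ratios with a 5 % flag. The pipeline can also run
with `calibration="nominal"` (bookkeeping CF = sensitivity), which
removes the small measured-CF bias from all RCs at the cost of realism.

## Quantification

Concentration images are voxel counts / (t·n·ν·CF). The background VOI
(Ø 90 mm × 50 mm cylinder) defaults to on-axis, centred 57.5 mm below
the sphere plane, which clears the bounding box of the 60 mm sphere; its
placement is validated against the phantom definition. Voxel membership
is by voxel-centre inclusion, no partial weighting.

Segmentation is two-pass: VOI_max is the maximum within a ball of 1.5 ×
the nominal sphere radius around the seed (bounding the search keeps a
neighbouring sphere's maximum out); the threshold is
0.5·(VOI_max + VOI_mean,bg); the mask is the connected component ≥
threshold containing the seed, 26-connectivity by default (6 available).
The seed is the hottest voxel within a ball around the expected sphere
centre (known from the phantom definition, as the physical analysis knew
the sphere order from CT), ties broken to the smallest (z, y, x) index.
Failure modes are explicit errors: empty masks raise, border-touching
masks warn, and the pipeline records failed segmentations per
(system, repeat, sphere) instead of dropping them silently. The 9.9 mm
sphere is genuinely unreliable at 10:1 contrast — its 50 % isocontour on
~12 mm-FWHM data is several times the true volume, and under noise the
segmentation may fail outright; this is reported, not hidden.

RC aggregation follows the mean-concentration-then-divide convention:
per repeat, the mask mean (max) is divided by the actual concentration
decayed to that repeat's timestamp; RC_mean (RC_max) is the mean of the
per-repeat values. A_i,max uses the mean over repeats of per-repeat
maxima by default (symmetric with RC_mean); the overall-maximum variant
is available behind `max_aggregation="max"`. Per-repeat RC lists with
median and range are kept for repeatability reporting.

## Harmonization metrics

Per sphere and metric (RC_mean, RC_max), the range max − min over
systems and the percent quantification difference. The percent formula
is (max − min)/min × 100 — the reading consistent with the published
pairings of range ≈ 0.41 with ≈ 118 % and range ≈ 0.10 with ≈ 11 % on
curves of this shape; (max − min)/mean is available behind a flag. A
same-vendor scope is emitted for every hardware group with ≥ 2 systems
(the three Siemens-class presets share a group).

## Recovery-curve fit

RC(V) = A/(1 + (V50/V)^γ), a sigmoid in log-volume with free asymptote
(the data plateau below 1, so A is not pinned). Parameters are kept
positive via a log transform; initialization is A₀ = max RC,
V50₀ = median volume, multi-start over γ₀ ∈ {0.5, 1, 2}; the smallest
residual wins, making the fit deterministic given the data. R² is the
squared Pearson correlation of fitted vs observed RC. The fit is against
volume; plots conventionally use diameter.

Bands use a smoothed residual bootstrap: with only ~6 points and 3
parameters the empirical residual distribution is too coarse for 95 %
tail quantiles, so replicates draw Gaussian noise with scale
s = √(SSR/(n−3)), and each replicate's scale is itself drawn from the
χ² sampling distribution of s (t-like tails for the few degrees of
freedom). The CI band is the percentile envelope of refitted curves;
the prediction band adds observation noise and is forced to contain the
CI band pointwise. Calibration was verified by simulation: empirical
95 % prediction-interval coverage of held-out points is ≈ 96 %.

## Workbench

`ExperimentConfig` (pydantic-validated; the master seed is mandatory)
drives `run` (simulate → calibrate → quantify → harmonize → fit →
CSV/JSON/report) and `ingest` (the same chain starting from NIfTI +
JSON-sidecar exports; reconstructions are stored as float64 so ingest of
a run's own exports reproduces its outputs bit-for-bit). Every number
in the markdown report is taken from exactly one upstream artefact. The
CLI (`spectrc`) is a thin wrapper with subcommands `all`, `simulate`,
`calibrate`, `quantify`, `compare`, `fit`, `init-config`.

## What the simulator does and does not show

The generator reproduces: partial-volume RC loss with its sigmoid
volume-dependence, repeat scatter from counting noise, decay-adjusted
multi-day scheduling, reconstruction-setting-driven inter-system spread,
and the reduction of that spread under a standardized reconstruction.
It does not model scatter, septal penetration, distance-dependent
resolution, dead time, CT imperfections or real collimator spectra, so
passing tests demonstrate the correctness and behaviour of the *analysis
chain* and the qualitative harmonization effect — not absolute agreement
with any physical camera's RC values. Headline measured numbers of a
physical multi-centre study (specific ranges, percent differences)
depend on those unmodelled effects and are outside what a desk-scale
simulation reproduces.

## Problem sizes and numerical choices

The bundled experiment runs 128 projections × 28 axial bins, truth grid
2.4 mm, reconstruction grids at each profile's voxel size, 3 repeats ×
4 systems × 2 modes (~5–7 minutes on one CPU). Property tests use
reduced sizes (64 projections, one repeat, 3.0 mm truth) chosen so the
checked behaviour is already stable. OSEM guards: zero-expectation bins
contribute nothing (0/0 → 0); sensitivity-image entries below 10⁻⁹ of
the maximum leave the voxel untouched; the multiplicative update keeps
images non-negative exactly. Rebinning drops out-of-span samples rather
than clamping, keeping simulation and reconstruction fields of view
identical — clamping would pile truncated activity into edge bins and
bias the reconstruction. Rotation adjointness is approximate (pull
rotation by −θ), standard for rotation-based projectors; the count-
consistency test bounds the residual mismatch at the 1 % level.
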