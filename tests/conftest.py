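"""Shared fixtures: expensive simulated experiments are session-scoped.

Three tiers of simulation are used:

* ``full_run`` — the bundled four-system experiment at full acquisition
  size (128 projections, 3 repeats, noise, both reconstruction modes),
  the conditions the headline recovery-curve checks are stated for;
* ``noiseless_run`` — the same systems at reduced size (64 projections,
  one repeat, no noise) for deterministic ordering/convergence checks;
* ``harmonization_runs`` — five reduced-size noisy replicas under
  different master seeds for the vendor-neutral-vs-specific variability
  properties.
"""

from __future__ import annotations

import numpy as np
import pytest

from spectrc import pipeline


@pytest.fixture(scope="session")
def full_run() -> pipeline.RunResult:
    cfg = pipeline.ExperimentConfig(seed=1, out_dir="scratch_unused")
    return pipeline.run(cfg, write=False)


@pytest.fixture(scope="session")
def noiseless_run() -> pipeline.RunResult:
    cfg = pipeline.ExperimentConfig(
        seed=1, n_repeats=1, n_projections=64, truth_voxel_mm=3.0,
        noise=False, calibration="nominal", out_dir="scratch_unused")
    return pipeline.run(cfg, write=False)


@pytest.fixture(scope="session")
def harmonization_runs() -> list[pipeline.RunResult]:
    out = []
    for seed in (1, 2, 3, 4, 5):
        cfg = pipeline.ExperimentConfig(
            seed=seed, n_repeats=1, n_projections=64, truth_voxel_mm=3.0,
            noise=True, calibration="nominal", out_dir="scratch_unused")
        out.append(pipeline.run(cfg, write=False))
    return out


@pytest.fixture(scope="session")
def prediction_coverage() -> float:
    """Empirical prediction-band coverage: 200 logistic-curve replicates with
    Gaussian noise sigma = 0.02, bands from the smoothed residual bootstrap,
    coverage counted on an independently drawn held-out curve per replicate."""
    from spectrc import rcfit
    volumes = np.array([0.508, 1.912, 4.064, 7.986, 16.056, 113.097])
    truth = rcfit.logistic_rc(volumes, 1.0, 4.0, 1.2)
    rng = np.random.default_rng(2024)
    sigma = 0.02
    hits, total = 0, 0
    for _ in range(200):
        rc = truth + rng.normal(0.0, sigma, size=len(volumes))
        fit = rcfit.fit_logistic(volumes, rc)
        bands = rcfit.fit_bands(fit, volumes, n_boot=150,
                                seed=int(rng.integers(2**31)))
        held_out = truth + rng.normal(0.0, sigma, size=len(volumes))
        hits += int(((held_out >= bands["pi_lo"]) & (held_out <= bands["pi_hi"])).sum())
        total += len(held_out)
    return 100.0 * hits / total


def rc_mean_ranges(result: pipeline.RunResult, mode: str):
    """Per-sphere RC_mean range over all systems for one mode, keyed by diameter."""
    c = result.comparison
    sub = c[(c["metric"] == "rc_mean") & (c["scope"] == "all") & (c["mode"] == mode)]
    return dict(zip(sub["diameter_mm"], sub["range"]))
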