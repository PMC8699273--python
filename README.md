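# dotiqa

Objective numerical assessment of diffuse optical tomography (DOT)
reconstructions with structural-similarity metrics.

DOT reconstructs the absorption (μa) and reduced scattering (μs′)
coefficients inside tissue from near-infrared light measured at the
boundary, and is studied for breast tumor imaging: a tumor appears as an
inclusion of contrasting optical properties.  Whether an inclusion is
*visible* in a reconstructed image is usually judged by eye.  `dotiqa`
implements a computer-observer alternative: it scores each reconstruction
against a homogeneous reference image with four full-reference
structural-similarity metrics and classifies inclusions as
visible/invisible by a median score threshold.  The package is aimed at
researchers developing DOT reconstruction or image-quality-assessment
methods who need a reproducible, end-to-end simulated test bed.

## What it computes

**Forward model.** Frequency-domain photon fluence Φ on a 40 mm-radius
disc, from the diffusion equation with a Robin boundary condition,

    −∇·(D∇Φ) + (μa + iω/c)Φ = S₀,   D = 1/(3(μs′ + μa)),   −D∂Φ/∂n = αΦ,

discretized with P1 finite elements (4225-node mesh, 16 sources + 16
detectors interleaved on the boundary, 256 log-amplitude/phase records per
acquisition).

**Inverse solver.** Tikhonov-damped Gauss–Newton updates of nodal (μa, D)
on a coarser 817-node mesh (inverse-crime avoidance), solving
(JᵀJ + λ²I)Δχ = JᵀΔΦ with an adjoint-method Jacobian, plus
homogeneous-reference data calibration and discrepancy-principle stopping
under noise.

**Metrics.** Over 8-bit rasterized image pairs (reference X = homogeneous
reconstruction, test Y):

* `mssim` — mean SSIM, 9×9 Gaussian window (σ = 1.5): mean of l·c·s;
* `ms_ssim` — multiscale SSIM over K = 5 dyadic scales with weights
  β = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333);
* `missim_s` — improved SSIM with split-σ structure term s̃ and a
  sharpness term h from the mean-removed window: mean of l·c·s̃·h;
* `ms_issim_s` — multiscale ISSIM-S: the MS-SSIM pooled product times the
  across-scale mean of the pooled sharpness term,
  (1/K)Σₖh̄ₖ · l̄_K^α_K · Πₖ c̄ₖ^βₖ s̄ₖ^γₖ.

**Evaluation.** Tie-corrected Spearman rank correlation between metric
scores and (synthetic or user-supplied) mean opinion scores, per
(case, noise, property) group of 21 images, and median-threshold
visibility classification.

See `docs/methods.md` for parameter choices, numerical conventions and
limitations.

## Worked example

Simulate the visible demonstration case (10 mm inclusion at 90°,
μa = 0.02 mm⁻¹ and μs′ = 3 mm⁻¹ against the 0.01/1.0 background) and
reconstruct it:

```python
import numpy as np
from dotiqa.config import StudyConfig
from dotiqa.study import (build_study_meshes, simulate_measurements,
                          discretization_calibration, apply_calibration)
from dotiqa.forward_model import OpticalProperties
from dotiqa.inverse_solver import reconstruct, circular_profile
from dotiqa.phantoms import table1_cases

cfg = StudyConfig()
meshes = build_study_meshes(cfg)
spec = table1_cases("A1")[2]            # visible: 10 mm inclusion at 90°
data = simulate_measurements(spec, meshes, cfg.fd)

calib = discretization_calibration(meshes, cfg)
init = OpticalProperties.homogeneous(meshes.coarse.n_nodes, 0.01, 1.0)
result = reconstruct(apply_calibration(data, calib), meshes.coarse, init,
                     cfg.fd, meshes.coarse_layout, cfg.gauss_newton)
angle, profile = circular_profile(result.mua, meshes.coarse, 20.0)
```

which prints (via the accompanying `print` statements):

```
forward mesh: 4225 nodes, 8192 elements
inverse mesh: 817 nodes, 1536 elements
measurements: 256 source-detector records
reconstruction: 13 iterations, chi2 123 -> 5.56e-05
peak mua 0.0264 1/mm at 90 deg (true: 0.02 at 90 deg)
```

The data misfit χ² falls by six orders of magnitude and the recovered
absorption peak sits at the true inclusion angle; the ~30% overshoot of
the peak value is typical of Tikhonov-regularized DOT.  Scoring the
rasterized reconstruction against the homogeneous reference
(`dotiqa.metrics.compute_metric`) then quantifies how far the image has
moved from "no inclusion": in the 1%-noise B1 study, MS-ISSIM-S falls
monotonically from 0.92 (2.5 mm inclusion, μs′ = 2) to 0.30 (10 mm,
μs′ = 3), while an invisible 2.5 mm inclusion leaves no profile contrast
above 10% of the true perturbation.

## Command line

The `dotiqa` console script exposes each pipeline stage and the full
study:

```bash
dotiqa full-study --seed 12345 --out study_out     # 168 images, ~2 min
dotiqa metric ref.png test.png                     # JSON metric scores
dotiqa fixtures --out fx                           # synthetic MOS + toys
```

Stages (`simulate`, `reconstruct`, `rasterize`, `assess`, `evaluate`) can
be run individually against the same output directory; every stage writes
a manifest with the configuration hash, and a stored config + seed
reproduces all outputs byte-for-byte.

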