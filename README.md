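# imerelax

Quantitative MRI and histology analysis of **intramyelinic edema (IME)** —
white-matter lesions in which fluid vacuoles split the myelin lamellae.
The package is aimed at preclinical relaxometry groups who want to relate
multi-exponential T2 (MET2) and quantitative magnetization-transfer (qMT)
metrics to quantitative histology, and to understand how
inter-compartmental water exchange distorts that relationship.

## What it computes

**Exchange-aware forward models.** Transverse magnetization of an n-pool
system evolves as `dM/dt = A M` with
`A_ii = −(1/T2_i + Σ_j k_ij)`, `A_ij = k_ji`, where exchange rates obey
detailed balance `f_i k_ij = f_j k_ji`. Eigen-decomposition gives the
apparent decay components. The central worked example: for intrinsic
T2 = 50/150 ms, 75/25 signal split and a 200 ms residence time of the
long-T2 pool, the observed decay is bi-exponential with **equal**
amplitudes — exchange makes the long-T2 amplitude 2× the long pool's
volume fraction. Longitudinal recovery after a selective inversion is the
coupled two-pool SIR-qMT model with five fitted parameters
(M0, PSR, k_mf, R1, S_f).

**Estimation.**

* `met2` — variable-projection fitting of 1–3 Gaussian T2-spectral
  components (non-negative amplitudes), sequential F-test model selection,
  exact 1-D k-means clustering of component T2s into short / intermediate /
  long classes, myelin water fraction (MWF, short class) and edema water
  fraction (EWF, long class), voxel-by-voxel intra-ROI standard errors.
* `qmt` — bounded nonlinear least-squares SIR fit returning PSR, k_mf,
  T1 = 1/R1 with Jacobian-based standard errors and optional
  magnitude-data polarity restoration.
* `histology` — Perona–Malik diffusion + CLAHE preprocessing, seeded
  region-growing segmentation into myelin / intra-extra-axonal / edema,
  volume fractions, water contents `W = Σ V_x ρ_x`, `W_x = V_x ρ_x / W`
  (ρ_my = 0.4, ρ_ie = 0.8, ρ_ed = 1.0), and lesion density / circular-
  equivalent diameter statistics.
* `synthetic` — generators for 40-echo decays, 25-point SIR series,
  toluidine-blue-like histology fields and whole three-group × four-tract
  studies with known ground truth.
* `pipeline` — per-ROI study tables, Welch group comparisons with
  significance stars, and MRI-vs-histology regressions (EWF–W_ed,
  MWF–W_my, PSR–V_my).

See `docs/methods.md` for model details, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from imerelax import (PoolSystem, apparent_transverse_components,
                      EchoScheme, simulate_roi_decay)
from imerelax.met2 import met2_ladder, assign_t2_classes, compute_water_fractions

# the worked two-pool exchange system
system = PoolSystem.two_pool(0.75, 0.050, 0.150, residence_long=0.2)
comps = apparent_transverse_components(system)
print("apparent T2 (ms):", np.round(comps.t2_app * 1e3, 1))
print("amplitudes:      ", np.round(comps.amplitudes, 3))

# simulate its multi-echo decay and fit it back
times = EchoScheme().times_s()
decay = simulate_roi_decay(system, times, snr=1000, seed=0, noise="gaussian")
fits, n = met2_ladder(decay, times)
fit = fits[n]
labels = assign_t2_classes(fit.t2s_s, {"intermediate": 0.045, "long": 0.092})
wf = compute_water_fractions(fit, labels)
print(f"selected {n} components; fitted EWF = {wf.ewf:.3f}")
```

Output:

```
apparent T2 (ms): [44.6 91.8]
amplitudes:       [0.5 0.5]
selected 2 components; fitted EWF = 0.468
```

Although only 25% of the water sits in the long-T2 pool, exchange shifts
the apparent components to 44.6/91.8 ms with equal amplitudes, and the
fitted edema water fraction comes out near 0.5 — twice the volume
fraction. A full synthetic study reproduces the same structure as a
pooled regression (EWF ≈ 2 × W_ed, r² > 0.9 at these noise levels):

```
imerelax simulate --seed 7 --out study_bundle
imerelax study --bundle study_bundle --out study_out
```

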