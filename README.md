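# dyncrit

Models and analyses of **dynamical criticality** in neural systems: the idea
that neural circuits gain both robustness and flexibility by poising
themselves at the onset of many simultaneous dynamical bifurcations, with
eigenvalues of their effective linear dynamics hugging the instability line
Re λ = 0.

The package is aimed at computational neuroscientists and dynamical-systems
researchers who want runnable, tested versions of this family of models and
the matching time-series analysis:

- **`dyncrit.hopf`** — the forced Hopf normal form
  `dz/dt = (μ + iω₀)z − |z|²z + F e^{iωt}`, exhibiting the four linked
  critical signatures: high amplification, sharp tuning, the compressive
  1/3-power response `R = F^{1/3}`, and spontaneous oscillation at
  amplitude `√μ` past threshold.
- **`dyncrit.antihebbian`** — the self-poising network
  `ẋ = Mx`, `Ṁ = α(I − xxᵀ)`: anti-Hebbian plasticity drives the spectrum
  of M onto the imaginary axis, where it flutters forever on the
  `α^{-1/2}` timescale.
- **`dyncrit.ccml`** — critically coupled map lattices: a local Gaussian
  map `f(x) = c·x·e^{−x²/2}` alternating with the orthogonal,
  volume-conserving exposure operator `U = e^{λM}` built from exactly
  antisymmetric couplings (1D/2D checkerboard, 2D bipartite Gaussian).
- **`dyncrit.spectra`** — spatiotemporal power spectra, spectral entropy
  and low-frequency-power summaries, and (c, λ) phase diagrams separating
  ordered, complex ("edge of chaos") and chaotic regimes.
- **`dyncrit.critical_modes`** — critical mode analysis: sliding-window
  AR(1) fits `x[t+1] = A x[t] + ε` to multichannel recordings, eigenvalues
  mapped to the continuous-time growth-rate plane by `s = f_s · log λ(A)`,
  surrogate negative controls, and permutation-tested condition contrasts
  (e.g. awake-like vs anesthetized-like stabilization). Validated on a
  bundled synthetic ECoG-like generator with prescribed eigenvalues.

A `dyncrit` console script exposes reproducible, manifest-logged runs
(`hopf sweep`, `antihebbian run`, `ccml run`, `ccml sweep`,
`modes fit|surrogate|compare`).

## Worked example

```python
import numpy as np
from dyncrit import ccml, hopf, critical_modes as cm

# volume-conserving coupling: det e^{λM} = 1 for antisymmetric M
op = ccml.exposure(ccml.checkerboard_1d(64), 4.0)
print(np.linalg.det(op.U))                      # 1.0000000000013376

# compressive response at criticality: log-log slope of R(F) = 1/3
print(hopf.response_exponent(0.0, 0.0, np.logspace(-8, -2, 25)))
#                                                 0.3333333333333336

# stabilization contrast on synthetic recordings (Re targets −2 vs −20 1/s)
awake  = cm.synth_series(8, 30.0, 250.0,
         [(-2.0, 5.0), (-2.0, 15.0), (-2.0, 40.0), (-2.0, 60.0)], seed=101)
anesth = cm.synth_series(8, 30.0, 250.0,
         [(-20.0, 5.0), (-20.0, 15.0), (-20.0, 40.0), (-20.0, 60.0)], seed=102)
fa, fb = cm.sliding_fit(awake, 500, 500), cm.sliding_fit(anesth, 500, 500)
print(cm.criticality_index(fa)["mean_abs_re"])  # 2.4100954820040643
print(cm.criticality_index(fb)["mean_abs_re"])  # 20.460152521645725
print(cm.stability_shift(fa, fb, n_perm=999, seed=0))
# {'delta_mean_re': -18.05005703964166, 'permutation_p': 0.001, ...}
```

The determinant of the exposure operator is 1 to 1e−12 — the coupling
rotates the field without contracting phase-space volume, so the lattice's
rich dynamics is entirely in the hands of the local map. The fitted
response exponent is the compressive 1/3 power law of a critical oscillator.
In the two-condition contrast, the fitted eigenvalues of the "anesthetized"
condition sit an order of magnitude further from the instability line than
the "awake" ones (mean |Re| 20.5 vs 2.4 1/s), and the window-label
permutation test certifies the stabilization at p = 0.001.

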