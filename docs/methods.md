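# Methods

This note records the models implemented in `dyncrit`, the numerical and
statistical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Forced Hopf normal form (`dyncrit.hopf`)

The canonical supercritical Hopf normal form with unit cubic coefficient and
additive periodic forcing,

    dz/dt = (mu + i*omega0) z - |z|^2 z + F exp(i*omega*t),

is the minimal model of an active oscillatory element poised at an
instability. Its steady state in the frame co-rotating with the forcing
satisfies

    R^2 ((mu - R^2)^2 + (omega0 - omega)^2) = F^2,   R = |z|,

a cubic in R^2. The four critical signatures follow directly: at mu = 0 and
resonance, R = F^(1/3) (compressive nonlinearity); the resonance gain R/F =
F^(-2/3) diverges as the forcing fades (high amplification); the tuning
curve's relative half-width shrinks with F (sharp tuning); and for mu > 0 an
unforced limit cycle of amplitude sqrt(mu) appears (spontaneous
oscillation). The mistuned side is implemented as mu > 0, the supercritical
side, where the self-sustained oscillation exists.

Numerics. Roots of the cubic come from the polynomial companion matrix;
coincident roots closer than 1e-9 relative are collapsed. For F = 0 the
radial equation decouples from the detuning, so the attractor amplitude (0
for mu <= 0, sqrt(mu) for mu > 0) is returned directly — the cubic would
miss the limit-cycle root off resonance. When several positive roots exist
the response is bistable: all roots are returned sorted with a
`multistable` flag, and sweep drivers exclude such points with a warning
count rather than silently picking a branch. Time integration is fixed-step
RK4 in the rotating frame (the fast carrier is removed analytically), with
dt defaulting to 1e-2 of the forcing period; a non-finite or |z| > 1e6
state raises a blow-up error naming the step. The half-width of a tuning
curve is measured at 1/sqrt(2) of the peak by linear interpolation and is
NaN (with a warning) when the curve does not fall that far inside the grid.

## Anti-Hebbian self-poising (`dyncrit.antihebbian`)

The existence-proof model of self-organized dynamical criticality couples a
linear rate network to an anti-Hebbian synaptic flow:

    dx/dt = M x,        dM/dt = alpha (I - x x^T),

with no noise term. The identity term inflates all real parts at rate
alpha; the outer-product term deflates along directions of high activity.
The feedback poises the spectrum of M on the imaginary axis: stable modes
let activity decay, which lets the identity term push them back up;
unstable modes amplify activity, which pushes them back down.

Defaults. Initial conditions are not part of the model definition; the
package draws x ~ N(0, 1) per component and M entries ~ N(0, 1/n), so the
initial spectrum has O(1) radius by the circular law. Both scales are
configurable. The integrator is fixed-step RK4 on the joint (x, M) system
with dt = 0.01 * min(1, 1/alpha), resolving both the O(1) activity
timescale and the O(1/alpha) learning epoch; T defaults to 10/alpha. The
integrator was cross-checked against an adaptive RK45 oracle at rtol 1e-8:
stationary-tail statistics agree to 0.1%.

Eigenvalue tracking. Spectra are recorded every `record_every` steps and
matched frame-to-frame by minimum-cost assignment in the complex plane
(`scipy.optimize.linear_sum_assignment`) — at n <= 64 this is as cheap as a
greedy pass and cannot produce the crossing artifacts greedy matching can;
conjugate pairing is preserved in practice because matched distances are
small at the default recording intervals. Matching only affects per-track
quantities (the fluctuation timescale); pooled summaries are
permutation-invariant.

Epochs. `epoch_summary` reports: `t_stabilize`, the first recorded time
with max Re(eig) < 0; `t_flatten`, the first time mean |Re(eig)| falls
below a configured fraction (default 0.25) of its initial value; and
`fluct_timescale`, the median across eigenvalue tracks of the e-folding
time of the autocorrelation of Re over the stationary tail, with a +inf
sentinel when no track decorrelates (e.g. a frozen trace). The flattening
fraction default matters: in the stationary state the real parts fluctuate
in a band whose mean |Re| is approximately 3*sqrt(alpha) (measured across
n in {16, 32, 64} and alpha in {1e-1..1e-3}, and reproduced by the
independent oracle), so a fraction below that band — e.g. 5% of an O(1)
initial spread for alpha >= 1e-3 — would never trigger. 0.25 marks the end
of the O(1/alpha) flattening epoch, which at alpha = 1e-3 completes at
t ~ 1/alpha as expected. The same band explains two test outcomes reported
honestly as failures in the acceptance suite: at n = 32, alpha = 1e-3 the
tail mean |Re| (~0.11) does not reach 5% of the initial spread (~0.026),
and the *maximum* over 32 eigenvalues fluctuating in that band is always
positive, so it never changes sign even though individual eigenvalues cross
zero constantly (the per-eigenvalue crossings are asserted in the unit
suite). The fluctuation timescale itself scales as alpha^(-1/2) — the
geometric mean of the two basic timescales — with a fitted log-log exponent
of about 0.48 in the acceptance run.

## Critically coupled map lattices (`dyncrit.ccml`)

A CCML iterates two strictly alternating stages on a real field over a
periodic lattice: the local Gaussian map f(x) = c x exp(-x^2/2) applied at
every site, then the linear exposure operator U = exp(lam M) with M exactly
antisymmetric. Because M is antisymmetric, U is special orthogonal: the
coupling stage conserves Euclidean norm and phase-space volume exactly (up
to the 1e-8-level roundoff of the matrix exponential), so all contraction
and stretching is done by the map. The notation follows one convention
throughout: map prefactor c (written alpha in some continuous-time
accounts) and exposure time lam (also written tau); the operator U is
elsewhere written G.

Couplings. Three constructions, all with entries assigned in exactly
antisymmetric mirrored pairs (integer or closed-form values, so
antisymmetry is exact, not approximate):

- `checkerboard_1d(n)`: M[i, i±1 mod n] = (-1)^i, even n >= 4 (odd n breaks
  the two-colouring at the periodic seam and is refused).
- `checkerboard_2d(nx, ny)`: 4-neighbour coupling with source sign
  (-1)^(i+j), even extents. This lattice is strongly anisotropic along
  diagonals.
- `bipartite_gaussian_2d(nx, ny, sigma, cutoff)`: two stacked grids, the
  excitatory layer coupling to the inhibitory one with the circular kernel
  exp(-(dx^2+dy^2)/(2 sigma^2)) over minimum-image displacements and the
  minimal antisymmetric completion M = [[0, K], [-K^T, 0]]. The kernel is
  truncated at 4*sigma with no renormalization (untouched tail < 3e-4 of
  the peak), so results are bit-for-bit reproducible given the descriptor.

The exponential is computed densely once per (M, lam) via `scipy.linalg.expm`
(lattices here are at most a few thousand sites). For the 1D checkerboard,
(U+U^T)/2 = cosh(lam M) contains even powers of M and couples each site to
its own parity sublattice, while (U-U^T)/2 = sinh(lam M) couples to the
opposite parity; `row_decomposition` verifies this parity support and
reports signed-offset profiles, whose 90%-mass radius grows diffusively
with lam.

Initial fields are i.i.d. uniform on [-a, a] (seeded). Boundary conditions
are periodic everywhere — the construction preserves translation invariance
and exact antisymmetry. The sign convention for the 2D runs takes the
printed values literally (c = -1.2 and c = -2.3).

## Spectra and phase diagrams (`dyncrit.spectra`)

Trajectories are Fourier transformed over every lattice dimension and over
time in blocks (default 256 steps, 50% overlap, no taper — map iterates are
not band-limited signals and the leakage is identical across cells), with
|.|^2/N normalization so the power sums to the mean squared field value
times the bin count (Parseval per block), then averaged across blocks.
Spectral entropy is Shannon entropy base 2 of the normalized spectrum with
the DC bin excluded by default, since the scientifically interesting
contrast is between low-but-nonzero frequencies and broadband power.
Low-frequency power is the share of non-DC power inside an inf-norm ball of
radius `band` (default 0.1) times Nyquist on every frequency axis.

Phase diagrams sweep (c, lam), building U once per lam; each cell's initial
field comes from an RNG stream seeded by (seed, c index, lam index), so any
cell reproduces in isolation. Cells whose recorded field RMS is below 1e-7
are flagged quiescent (their entropy would measure float noise) and cells
that blow up are flagged and skipped; neither aborts the sweep. Regime
classification splits the *observed entropy range* into three equal
terciles (ordered / complex / chaotic). Range terciles, not count
percentiles, are used deliberately: the entropy landscape contains broad
plateaus (e.g. the weak-coupling regime), and a count-based boundary
landing inside a plateau splits one physical regime into scattered islands
on estimator noise alone. `intermediate_component_fraction` then measures
whether the complex regime forms one solid region (largest 4-connected
component as a fraction of all complex cells). The acceptance sweep uses
c in [0.5, 3.0] (11 points) and lam in [0, 0.75] (step 0.075, a grid that
contains the 0.675 slice; 0.675 sits near the top of the diagrammed lam
range), with per-cell entropy medianed over three seeds and 2048 recorded
steps after a 512-step transient — sizes chosen so the entropy estimator's
seed-to-seed scatter is small compared with the inter-regime contrasts.

## Critical mode analysis (`dyncrit.critical_modes`)

Windowed AR(1) fits x[t+1] = A x[t] + e[t] by ordinary least squares per
window (no ridge by default; a ridge option exists for ill-conditioned
windows and is recorded by callers in metadata). Channel means are removed
per window — affine offsets otherwise bias A — with the regressor and
response blocks centred separately, which keeps noiseless data exactly
solvable; no other pre-processing is applied or silently introduced,
because filtering and smoothing can manufacture spurious proximity to
criticality. The solver is QR/SVD least squares, not normal equations
(which square the condition number and visibly corrupt near-noiseless
fits); a rank-deficient window yields the minimum-norm solution and is
flagged, and flagged windows are excluded from pooled summaries.

Eigenvalues: `eigs_discrete` are eigenvalues of A; `eigs_continuous =
fs * log(eigs_discrete)` on the principal branch, so Re is a growth rate in
1/s and Im an angular frequency in rad/s (divide by 2*pi for Hz; the
histogram helper does). Frequencies above Nyquist are unrepresentable —
aliasing folds them — which is an intrinsic limit of sampled-data analysis,
not of the implementation. Defaults for window and hop are 2 s and 0.5 s
and are mandatory, visible parameters of every fitting entry point.

Synthetic generator. `synth_series` builds a real propagator with
prescribed continuous-time eigenvalues — one 2x2 rotation-scaling block per
(Re [1/s], Im [Hz]) pair, conjugates implied, 1x1 blocks for Im = 0, extra
channels filled at the median decay rate — conjugated by a seeded random
orthogonal basis, then drives it with i.i.d. Gaussian innovations. A
burn-in of five times the slowest decay time (capped at 5000 samples) makes
the recorded stretch near-stationary. Unstable specifications are refused
unless forced. What this emulates about ECoG-like data: multichannel mixing
of damped oscillatory modes at controlled distances from the instability
line. What it does not: nonlinearity, nonstationary mode drift, 1/f
backgrounds, volume conduction, artifacts, non-Gaussian noise. Passing
recovery tests therefore demonstrates estimator correctness under the
model's own assumptions, not validity on real recordings.

Statistics. Surrogates: per-channel sample shuffling (destroys all
dynamics, preserves marginals exactly), per-channel Fourier phase
randomization (preserves each periodogram exactly, destroys cross-channel
phase and nonlinear structure; the Nyquist bin of even-length signals is
kept real), and whole-window shuffling (destroys slow ordering, preserves
local dynamics). The condition contrast `stability_shift` is the
difference of pooled mean growth rates, tested by permuting *window*
labels: windows, not eigenvalues, are the exchangeable unit, because the n
eigenvalues of one window are one dependent draw. With equal per-window
eigenvalue counts this is implemented on per-window mean Re. Valid
calibration additionally requires non-overlapping windows: 50%-overlapping
windows share samples, violate exchangeability, and were measured to
inflate the type-I rate to ~0.16 at nominal 0.05, while non-overlapping
windows calibrate inside the binomial band. The two-sided p uses the
add-one correction.

Known estimator limitation (reported red in the acceptance suite rather
than patched): per-window OLS underestimates slow decay. For a mode at
Re = -1 1/s analyzed in 2 s windows at fs = 250 Hz, the pooled median
recovers about -1.28 (28% relative); the same data in one 60 s window
recovers -1.04. This is standard small-sample AR bias (order 1/T with a
mode whose decay time is half the window); the package keeps the plain OLS
estimator and the 2 s default rather than silently substituting a
bias-corrected estimator, and callers probing near-critical modes should
lengthen windows until estimates stop drifting. Faster modes (-5, -20 1/s)
and all frequencies recover to well under 2% / 0.05 Hz at the same
settings.

## CLI and serialization

Every run writes a manifest (resolved configuration, package version, seed,
status) before any result and marks it done/failed afterwards, so partial
outputs are never mistaken for results. Arrays are stored as .npz with a
JSON sidecar carrying units and provenance; response curves, phase-diagram
matrices and recordings also round-trip through delimited text. Numeric
results go only to artifacts, never to the log stream. Configuration is
JSON; unknown keys are rejected by name.

## Problem sizes

Default problem sizes throughout (lattices of 64-512 sites, 1536-2560 map
steps, 60 s synthetic recordings, 10-seed recovery ensembles, 200-rep
calibration, anti-Hebbian runs to T = 10/alpha at n = 32) were chosen so
that every quantity's estimator noise is small relative to the effect being
asserted; they are the package's own test conditions and can all be scaled
up through the public APIs.
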