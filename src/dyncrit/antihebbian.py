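"""Anti-Hebbian self-poising network.

Linear activity dynamics coupled to an anti-Hebbian evolution of the synaptic
matrix:

    dx/dt = M x
    dM/dt = alpha (I - x x^T)

with activity vector ``x`` (length n) and real synaptic matrix ``M`` (n x n).
The learning rate ``alpha`` sets a slow timescale 1/alpha well separated from
the O(1) activity timescale.  Starting from random initial conditions the
spectrum of M reorganizes in distinct epochs: within a time of order 1 every
unstable eigenvalue (positive real part) relaxes to stability; over a time of
order 1/alpha the whole cloud of eigenvalues flattens against the imaginary
axis; and forever after the eigenvalues fluctuate around the critical line
Re = 0 on the intermediate timescale alpha^(-1/2) — the geometric mean of the
two basic timescales.  The network thus poises itself at the onset of many
simultaneous Hopf bifurcations without any parameter tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import BlowupError, InsufficientSpanError

__all__ = [
    "AHConfig",
    "AHState",
    "AHTrajectory",
    "EigenTrace",
    "init",
    "integrate",
    "epoch_summary",
    "tail_stats",
]


@dataclass(frozen=True)
class AHConfig:
    """Configuration of an anti-Hebbian run.

    ``dt`` defaults to ``0.01 * min(1, 1/alpha)`` so both the O(1) activity
    epoch and the O(1/alpha) flattening epoch are resolved.  ``T`` defaults
    to ``10/alpha``, long enough to include a stationary tail.
    ``init_scale_M`` defaults to ``1/sqrt(n)`` so the initial spectrum has
    O(1) radius by the circular law.
    """

    n: int
    alpha: float
    dt: float | None = None
    T: float | None = None
    seed: int = 0
    init_scale_x: float = 1.0
    init_scale_M: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be > 0")

    @property
    def dt_eff(self) -> float:
        return self.dt if self.dt is not None else 0.01 * min(1.0, 1.0 / self.alpha)

    @property
    def T_eff(self) -> float:
        return self.T if self.T is not None else 10.0 / self.alpha

    @property
    def scale_M_eff(self) -> float:
        return self.init_scale_M if self.init_scale_M is not None else 1.0 / np.sqrt(self.n)


@dataclass
class AHState:
    """Joint state: activity vector x, synaptic matrix M, time t."""

    x: np.ndarray
    M: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("M must be square")
        if self.x.shape != (self.M.shape[0],):
            raise ValueError("x length must match M's dimension")


@dataclass
class AHTrajectory:
    """Recorded samples of an anti-Hebbian run (activity and tr M only)."""

    times: np.ndarray
    x: np.ndarray          # frames x n
    trace_M: np.ndarray    # frames
    final_state: AHState


@dataclass
class EigenTrace:
    """Time-indexed eigenvalues of an evolving real matrix.

    ``eigs[k]`` holds the n complex eigenvalues at ``times[k]``, reordered so
    that row j follows a single eigenvalue continuously across frames
    (nearest-neighbour assignment in the complex plane between consecutive
    frames).  Spectra of a real matrix are closed under conjugation.
    """

    times: np.ndarray
    eigs: np.ndarray       # frames x n, complex

    def real_spread(self, frame: int = 0) -> float:
        """Standard deviation of the eigenvalue real parts at one frame."""
        return float(np.std(self.eigs[frame].real))


def init(config: AHConfig) -> AHState:
    """Draw the random initial condition prescribed by ``config``.

    x ~ N(0, init_scale_x^2) i.i.d.; M entries ~ N(0, init_scale_M^2) i.i.d.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    x = config.init_scale_x * rng.standard_normal(config.n)
    M = config.scale_M_eff * rng.standard_normal((config.n, config.n))
    return AHState(x=x, M=M, t=0.0)


def _match_eigs(prev: np.ndarray, new: np.ndarray) -> np.ndarray:
    """Reorder ``new`` to minimize total distance to ``prev`` (assignment)."""
    cost = np.abs(prev[:, None] - new[None, :])
    _, col = linear_sum_assignment(cost)
    return new[col]


def integrate(
    state: AHState,
    config: AHConfig,
    record_every: int = 10,
) -> tuple[AHTrajectory, EigenTrace]:
    """Advance the joint (x, M) system with fixed-step RK4, recording eigenvalues.

    Every ``record_every`` steps the current x, tr M and the spectrum of M
    are recorded; eigenvalues are matched across frames by minimum-cost
    assignment in the complex plane so each row of the trace follows one
    eigenvalue.  The initial state is always frame 0.

    Raises
    ------
    BlowupError
        If the state becomes non-finite, naming the time of failure.
    """
    dt = config.dt_eff
    n_steps = int(round(config.T_eff / dt))
    alpha = config.alpha
    n = config.n
    I = np.eye(n)

    x = state.x.copy()
    M = state.M.copy()
    t0 = state.t

    times = [t0]
    xs = [x.copy()]
    trs = [float(np.trace(M))]
    eig_frames = [np.sort_complex(np.linalg.eigvals(M))]

    h = dt
    for k in range(n_steps):
        # RK4 on the joint system; dM/dt depends only on x
        k1x = M @ x
        k1M = alpha * (I - np.outer(x, x))
        x2 = x + 0.5 * h * k1x
        k2x = (M + 0.5 * h * k1M) @ x2
        k2M = alpha * (I - np.outer(x2, x2))
        x3 = x + 0.5 * h * k2x
        k3x = (M + 0.5 * h * k2M) @ x3
        k3M = alpha * (I - np.outer(x3, x3))
        x4 = x + h * k3x
        k4x = (M + h * k3M) @ x4
        k4M = alpha * (I - np.outer(x4, x4))
        x += (h / 6.0) * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        M += (h / 6.0) * (k1M + 2.0 * k2M + 2.0 * k3M + k4M)

        if (k + 1) % record_every == 0:
            t = t0 + (k + 1) * h
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(M))):
                raise BlowupError(f"non-finite state at t={t:.6g}", step=k + 1, time=t)
            times.append(t)
            xs.append(x.copy())
            trs.append(float(np.trace(M)))
            eig_frames.append(_match_eigs(eig_frames[-1], np.linalg.eigvals(M)))

    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(M))):
        raise BlowupError("non-finite final state", step=n_steps, time=t0 + n_steps * h)

    traj = AHTrajectory(
        times=np.asarray(times),
        x=np.asarray(xs),
        trace_M=np.asarray(trs),
        final_state=AHState(x=x, M=M, t=t0 + n_steps * h),
    )
    trace = EigenTrace(times=np.asarray(times), eigs=np.asarray(eig_frames))
    return traj, trace


def _acf_decay_time(series: np.ndarray, dt: float, level: float = 1.0 / np.e) -> float:
    """First lag (interpolated) where the normalized autocorrelation drops
    below ``level``; +inf if it never does (e.g. a constant series)."""
    y = series - series.mean()
    var = float(np.dot(y, y))
    if var <= 1e-300 * series.size:
        return float("inf")
    n = y.size
    acf = np.correlate(y, y, mode="full")[n - 1:] / var
    below = np.nonzero(acf < level)[0]
    if below.size == 0:
        return float("inf")
    j = int(below[0])
    if j == 0:
        return 0.0
    frac = (acf[j - 1] - level) / (acf[j - 1] - acf[j])
    return (j - 1 + frac) * dt


def tail_stats(trace: EigenTrace, tail_frac: float = 0.25) -> dict:
    """Summaries of the stationary tail (last ``tail_frac`` of the trace).

    Returns ``mean_abs_re`` (tail average of mean |Re(eig)|),
    ``initial_spread`` (std of Re at frame 0), and ``max_re_sign_changes``
    (number of sign changes of max Re across the tail — nonzero when the
    leading eigenvalue keeps crossing the critical line).
    """
    n_frames = trace.times.size
    i0 = int(np.floor((1.0 - tail_frac) * n_frames))
    tail = trace.eigs[i0:]
    mean_abs_re = float(np.mean(np.abs(tail.real)))
    max_re = tail.real.max(axis=1)
    signs = np.sign(max_re)
    signs = signs[signs != 0]
    changes = int(np.count_nonzero(np.diff(signs)))
    return {
        "mean_abs_re": mean_abs_re,
        "initial_spread": trace.real_spread(0),
        "max_re_sign_changes": changes,
    }


def epoch_summary(
    trace: EigenTrace,
    alpha: float,
    flatten_frac: float = 0.25,
    tail_frac: float = 0.25,
) -> dict:
    """Characteristic times of the three epochs of the self-poising run.

    - ``t_stabilize``: first recorded time with max Re(eig) < 0 (end of the
      O(1) stabilization epoch), NaN if never reached.
    - ``t_flatten``: first time mean |Re(eig)| falls below ``flatten_frac``
      of its initial value (the O(1/alpha) flattening epoch), NaN if never.
      The default fraction 0.25 marks the end of that epoch while sitting
      above the stationary fluctuation band (~3 sqrt(alpha)) for the
      learning rates of interest.
    - ``fluct_timescale``: e-folding time of the autocorrelation of single
      eigenvalue real parts over the stationary tail; the median across the
      n matched eigenvalue tracks (a +inf sentinel if no track decorrelates,
      e.g. for a constant trace).

    Raises
    ------
    InsufficientSpanError
        If the trace spans less than 2/alpha.
    """
    span = trace.times[-1] - trace.times[0]
    if span < 2.0 / alpha:
        raise InsufficientSpanError(
            f"trace spans {span:.3g} < 2/alpha = {2.0 / alpha:.3g}; epochs unresolved"
        )
    re = trace.eigs.real
    max_re = re.max(axis=1)
    mean_abs = np.abs(re).mean(axis=1)

    stab = np.nonzero(max_re < 0)[0]
    t_stabilize = float(trace.times[stab[0]]) if stab.size else float("nan")

    flat = np.nonzero(mean_abs < flatten_frac * mean_abs[0])[0]
    t_flatten = float(trace.times[flat[0]]) if flat.size else float("nan")

    n_frames = trace.times.size
    i0 = int(np.floor((1.0 - tail_frac) * n_frames))
    dt_rec = float(np.median(np.diff(trace.times)))
    taus = [_acf_decay_time(re[i0:, j], dt_rec) for j in range(re.shape[1])]
    finite = [t for t in taus if np.isfinite(t)]
    fluct = float(np.median(finite)) if finite else float("inf")

    return {
        "t_stabilize": t_stabilize,
        "t_flatten": t_flatten,
        "fluct_timescale": fluct,
    }
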