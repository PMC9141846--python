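"""Critically coupled map lattices (CCMLs).

A CCML alternates two operations on a real scalar field over a lattice:
a local 1D map applied in parallel at every site,

    xbar_i(t) = f(x_i(t)),          f(x) = c x exp(-x^2 / 2),

followed by a linear coupling through the *exposure operator*

    x_i(t+1) = sum_j U_ij xbar_j(t),        U = exp(lam * M),

where M is an antisymmetric coupling matrix ("critical" in the sense that
its spectrum is purely imaginary: every mode sits exactly at the onset of a
Hopf-type instability).  Because M is antisymmetric, U is orthogonal with
det U = 1: the coupling stage conserves phase-space volume and Euclidean
norm, so all contraction or expansion is in the hands of the local map.  The
exposure time ``lam`` (elsewhere written tau) controls the spatial range of
U, which broadens diffusively while remaining volume-preserving.

Three coupling constructions are provided: the 1D nearest-neighbour
checkerboard ``M[i, i+-1] = (-1)^i``, its 2D analogue with source-site sign
``(-1)^(i+j)``, and a two-layer bipartite lattice with circularly symmetric
Gaussian cross-couplings (excitatory layer -> inhibitory layer and back with
opposite sign), which removes the strong diagonal anisotropy of the 2D
checkerboard.  All lattices are periodic; checkerboard extents must be even
so the two-colouring closes at the seam.

The local map prefactor is written ``c`` (alias alpha in continuous-time
notation) and the exposure time ``lam`` (alias tau); the stroboscopic
propagator U is elsewhere written G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .errors import BlowupError, GeometryError

__all__ = [
    "LatticeGeometry",
    "CouplingMatrix",
    "ExposureOperator",
    "LatticeFieldSeries",
    "checkerboard_1d",
    "checkerboard_2d",
    "bipartite_gaussian_2d",
    "exposure",
    "row_decomposition",
    "profile_width",
    "gaussian_map",
    "step",
    "simulate",
    "random_field",
]


@dataclass(frozen=True)
class LatticeGeometry:
    """Lattice kind, per-dimension extents and boundary condition.

    ``kind`` is one of ``chain_1d``, ``grid_2d``, ``bipartite_grid_2d``.
    For the bipartite kind ``shape`` is the extent of ONE layer; the site
    count doubles.  Only periodic boundaries are supported.
    """

    kind: str
    shape: tuple[int, ...]
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.kind not in ("chain_1d", "grid_2d", "bipartite_grid_2d"):
            raise GeometryError(f"unknown lattice kind {self.kind!r}")
        if self.boundary != "periodic":
            raise GeometryError("only periodic boundaries are supported")
        if self.kind in ("chain_1d", "grid_2d") and any(s % 2 for s in self.shape):
            raise GeometryError(
                "checkerboard lattices need even extents: the two-colouring "
                f"breaks at the periodic seam for shape {self.shape}"
            )

    @property
    def n_sites(self) -> int:
        n = int(np.prod(self.shape))
        return 2 * n if self.kind == "bipartite_grid_2d" else n

    @property
    def field_shape(self) -> tuple[int, ...]:
        """Shape of the field viewed as a spatial array (layer axis first
        for bipartite lattices)."""
        if self.kind == "bipartite_grid_2d":
            return (2, *self.shape)
        return self.shape


@dataclass(frozen=True)
class CouplingMatrix:
    """Antisymmetric coupling M over the flattened site index, plus geometry."""

    geometry: LatticeGeometry
    M: np.ndarray
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.shape != (self.geometry.n_sites, self.geometry.n_sites):
            raise GeometryError("coupling matrix size does not match the geometry")
        if np.max(np.abs(M + M.T)) != 0.0:
            raise GeometryError("coupling matrix must be exactly antisymmetric")


@dataclass(frozen=True)
class ExposureOperator:
    """U = exp(lam * M): the orthogonal, volume-preserving coupling propagator."""

    U: np.ndarray
    lam: float
    source: CouplingMatrix


@dataclass
class LatticeFieldSeries:
    """A recorded CCML trajectory: real field over sites x time steps."""

    geometry: LatticeGeometry
    values: np.ndarray          # n_sites x n_steps
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.geometry.n_sites:
            raise ValueError("values must be (n_sites, n_steps)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def as_spatial(self) -> np.ndarray:
        """View the series as (*spatial_shape, time)."""
        return self.values.reshape(*self.geometry.field_shape, -1)


def checkerboard_1d(n: int) -> CouplingMatrix:
    """Periodic 1D chain with nearest-neighbour checkerboard coupling.

    ``M[i, i+-1 mod n] = (-1)^i``, zero elsewhere.  Antisymmetry follows
    because the mirrored entry carries the opposite sign:
    ``M[i+1, i] = (-1)^(i+1) = -M[i, i+1]``.  Requires even n >= 4.
    """
    if n < 4 or n % 2:
        raise GeometryError(f"checkerboard chain needs even n >= 4, got {n}")
    M = np.zeros((n, n))
    for i in range(n):
        s = -1.0 if i % 2 else 1.0
        M[i, (i + 1) % n] = s
        M[i, (i - 1) % n] = s
    geom = LatticeGeometry("chain_1d", (n,))
    return CouplingMatrix(geom, M, {"construction": "checkerboard_1d", "n": n})


def checkerboard_2d(nx: int, ny: int) -> CouplingMatrix:
    """Periodic 2D grid, 4-neighbour coupling with source sign (-1)^(i+j).

    Odd sites are excitatory, even sites inhibitory, all couplings of unit
    magnitude; nearest neighbours have opposite colour so the matrix is
    antisymmetric.  Requires even extents.
    """
    if nx % 2 or ny % 2 or nx < 2 or ny < 2:
        raise GeometryError(f"checkerboard grid needs even extents, got {(nx, ny)}")
    n = nx * ny
    M = np.zeros((n, n))
    for i in range(nx):
        for j in range(ny):
            s = -1.0 if (i + j) % 2 else 1.0
            p = i * ny + j
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                q = ((i + di) % nx) * ny + (j + dj) % ny
                M[p, q] = s
    geom = LatticeGeometry("grid_2d", (nx, ny))
    return CouplingMatrix(geom, M, {"construction": "checkerboard_2d", "shape": (nx, ny)})


def bipartite_gaussian_2d(
    nx: int,
    ny: int,
    sigma: float = 1.0,
    cutoff: float | None = None,
) -> CouplingMatrix:
    """Two stacked periodic grids with Gaussian cross-layer coupling.

    The top (excitatory) layer couples only to the bottom (inhibitory) layer
    and vice versa, with circularly symmetric kernel
    ``K[p, q] = exp(-(dx^2 + dy^2) / (2 sigma^2))`` over minimum-image
    displacements, truncated beyond ``cutoff`` (default 4 sigma, untouched
    tail < 3e-4 of the peak; no renormalization).  The minimal antisymmetric
    completion is the block form ``M = [[0, K], [-K^T, 0]]``.
    """
    if cutoff is None:
        cutoff = 4.0 * sigma
    n = nx * ny
    ii = np.arange(nx)
    jj = np.arange(ny)
    dx = np.minimum(np.abs(ii[:, None] - ii[None, :]), nx - np.abs(ii[:, None] - ii[None, :]))
    dy = np.minimum(np.abs(jj[:, None] - jj[None, :]), ny - np.abs(jj[:, None] - jj[None, :]))
    d2 = (dx[:, None, :, None] ** 2 + dy[None, :, None, :] ** 2).astype(float)
    K = np.exp(-d2 / (2.0 * sigma * sigma))
    K[d2 > cutoff * cutoff] = 0.0
    K = K.reshape(n, n)
    M = np.zeros((2 * n, 2 * n))
    M[:n, n:] = K
    M[n:, :n] = -K.T
    geom = LatticeGeometry("bipartite_grid_2d", (nx, ny))
    return CouplingMatrix(
        geom, M,
        {"construction": "bipartite_gaussian_2d", "shape": (nx, ny),
         "sigma": sigma, "cutoff": cutoff},
    )


def exposure(coupling: CouplingMatrix, lam: float) -> ExposureOperator:
    """Exposure operator ``U = exp(lam * M)``.

    For antisymmetric M the result is special orthogonal (``U^T U = I``,
    ``det U = 1``): the coupling rotates the field in site space without
    contracting or dilating phase-space volume.  Row profiles of U decay
    with lattice distance and broaden diffusively as ``lam`` grows.
    """
    if not np.isfinite(lam):
        raise ValueError("lam must be finite")
    U = expm(lam * coupling.M)
    return ExposureOperator(U=U, lam=float(lam), source=coupling)


def profile_width(offsets: np.ndarray, profile: np.ndarray, mass: float = 0.9) -> int:
    """Smallest offset radius containing ``mass`` of the |profile| weight."""
    w = np.abs(profile)
    total = w.sum()
    if total == 0:
        return 0
    for r in range(int(np.max(np.abs(offsets))) + 1):
        if w[np.abs(offsets) <= r].sum() >= mass * total:
            return r
    return int(np.max(np.abs(offsets)))


def row_decomposition(op: ExposureOperator, row: int = 0) -> dict:
    """Split U into its symmetric and antisymmetric matrix parts along one row.

    For the 1D checkerboard generator, ``(U + U^T)/2 = cosh(lam M)`` contains
    the even powers of M and therefore couples each site only to its own
    sublattice (even signed offsets), while ``(U - U^T)/2 = sinh(lam M)``
    couples to the opposite sublattice (odd offsets); both profiles are even
    in |offset| in magnitude.  The parity support is verified and a
    violation raises, since it is guaranteed by the algebra.

    Returns a dict with ``offsets`` (signed lattice offsets), ``symmetric``
    and ``antisymmetric`` row profiles.
    """
    geom = op.source.geometry
    if geom.kind != "chain_1d":
        raise GeometryError("row decomposition is defined for 1D chains only")
    n = geom.shape[0]
    S = 0.5 * (op.U + op.U.T)
    A = 0.5 * (op.U - op.U.T)
    offsets = np.arange(-(n // 2), n - n // 2)
    sym = np.array([S[row, (row + d) % n] for d in offsets])
    anti = np.array([A[row, (row + d) % n] for d in offsets])
    scale = max(np.max(np.abs(sym)), np.max(np.abs(anti)), 1e-300)
    even = offsets % 2 == 0
    if np.max(np.abs(sym[~even])) > 1e-10 * scale or np.max(np.abs(anti[even])) > 1e-10 * scale:
        raise AssertionError("sublattice parity support violated; generator is not checkerboard")
    return {"offsets": offsets, "symmetric": sym, "antisymmetric": anti}


def gaussian_map(x: np.ndarray, c: float) -> np.ndarray:
    """Local map ``f(x) = c x exp(-x^2/2)``, elementwise.

    Bounded: ``|f| <= |c| e^(-1/2)`` with the extremum at x = +-1; the slope
    at the origin is c, so |c| < 1 makes the quiescent state attracting
    while growing |c| drives a period-doubling route to chaos.
    """
    x = np.asarray(x, dtype=float)
    return c * x * np.exp(-0.5 * x * x)


def step(field: np.ndarray, op: ExposureOperator, c: float) -> np.ndarray:
    """One stroboscopic CCML step: local map first, then the coupling.

    With ``lam = 0`` the coupling is the identity and the step reduces to
    the bare elementwise map (returned as such, bit for bit).
    """
    mapped = gaussian_map(field, c)
    out = mapped if op.lam == 0.0 else op.U @ mapped
    if not np.all(np.isfinite(out)):
        raise BlowupError("non-finite field after step")
    return out


def simulate(
    field0: np.ndarray,
    op: ExposureOperator,
    c: float,
    steps: int,
    transient: int = 0,
    seed: int | None = None,
) -> LatticeFieldSeries:
    """Iterate the two-step dynamics, discarding an initial transient.

    Runs ``steps`` iterations from ``field0`` and records the field after
    each of the final ``steps - transient``.  Deterministic given ``field0``.
    A blowup aborts with the failing step index.
    """
    if not steps > transient >= 0:
        raise ValueError("need steps > transient >= 0")
    field = np.asarray(field0, dtype=float).ravel().copy()
    geom = op.source.geometry
    if field.size != geom.n_sites:
        raise GeometryError("initial field size does not match the lattice")
    recorded = np.empty((geom.n_sites, steps - transient))
    for k in range(steps):
        try:
            field = step(field, op, c)
        except BlowupError as err:
            raise BlowupError(f"blowup at step {k + 1}", step=k + 1) from err
        if k >= transient:
            recorded[:, k - transient] = field
    return LatticeFieldSeries(
        geometry=geom,
        values=recorded,
        params={"c": c, "lam": op.lam, "transient": transient},
        seed=seed,
    )


def random_field(
    geometry: LatticeGeometry,
    amplitude: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """I.i.d. uniform initial field on [-amplitude, amplitude]."""
    rng = np.random.default_rng(rng)
    return rng.uniform(-amplitude, amplitude, size=geometry.n_sites)
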