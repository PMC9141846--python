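"""Spatiotemporal spectra, spectral entropy, and (c, lam) phase diagrams.

The character of a coupled-map-lattice regime is summarized by its averaged
spatiotemporal power spectrum: the trajectory is Fourier transformed over
all lattice dimensions and over time within overlapping blocks, and the
squared moduli are averaged across blocks.  Treating the normalized spectrum
as a probability distribution, its Shannon entropy measures the complexity
of the regime — near zero for frozen or synchronized states whose power
concentrates in a few bins, maximal (log2 of the bin count) for featureless
broadband chaos.  Complex "edge of chaos" regimes are distinguished by a
large fraction of power at low but nonzero spatiotemporal frequencies, which
the low-frequency-power summary captures.  Sweeping the map prefactor c and
the exposure time lam produces phase diagrams of both summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ccml import CouplingMatrix, LatticeFieldSeries, exposure, random_field, simulate
from .errors import BlowupError, UndefinedEntropyError

__all__ = [
    "STSpectrum",
    "PhaseDiagramGrid",
    "st_spectrum",
    "spectral_entropy",
    "low_frequency_power",
    "regime_thresholds",
    "intermediate_component_fraction",
    "phase_diagram",
    "CELL_OK",
    "CELL_QUIESCENT",
    "CELL_BLOWUP",
]

CELL_OK = 0
CELL_QUIESCENT = 1
CELL_BLOWUP = 2


@dataclass
class STSpectrum:
    """Averaged spatiotemporal power spectrum.

    ``power`` has one axis per spatial dimension plus a trailing temporal
    axis; ``axes`` gives the frequency value of every bin on each axis, in
    cycles per lattice spacing (spatial) or cycles per step (temporal), with
    the DC bin at index 0 on every axis.  Power is normalized so that its
    total equals the mean squared field value times the bin count (Parseval,
    per block, averaged over ``n_averages`` blocks).
    """

    power: np.ndarray
    axes: list[np.ndarray]
    n_averages: int

    def __post_init__(self) -> None:
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise ValueError("power must be nonnegative and finite")

    def dc_mask(self) -> np.ndarray:
        """Boolean mask selecting the single all-zero-frequency bin."""
        mask = np.zeros(self.power.shape, dtype=bool)
        mask[(0,) * self.power.ndim] = True
        return mask


@dataclass
class PhaseDiagramGrid:
    """Entropy and low-frequency-power summaries over a (c, lam) grid.

    ``status`` flags each cell: 0 ok, 1 quiescent (field decayed to
    numerical noise; summaries set to NaN), 2 blowup (NaN).  Flagged cells
    are excluded from any colour scaling downstream.
    """

    c_values: np.ndarray
    lam_values: np.ndarray
    entropy: np.ndarray          # len(c) x len(lam), bits
    low_freq_power: np.ndarray   # len(c) x len(lam), fraction
    status: np.ndarray           # len(c) x len(lam), int
    run_config: dict = field(default_factory=dict)


def st_spectrum(
    series: LatticeFieldSeries,
    block_len: int = 256,
    overlap: float = 0.5,
) -> STSpectrum:
    """Block-averaged space-time power spectrum of a lattice trajectory.

    Each block of ``block_len`` consecutive steps is Fourier transformed over
    every spatial axis and over time (no taper: map trajectories are not
    band-limited signals, and the leakage is identical across phase-diagram
    cells); squared moduli divided by the block's element count are averaged
    over blocks hopped by ``block_len * (1 - overlap)``.
    """
    data = series.as_spatial()
    T = data.shape[-1]
    if block_len > T:
        raise ValueError(f"block_len {block_len} exceeds series length {T}")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    hop = max(1, int(round(block_len * (1.0 - overlap))))
    starts = range(0, T - block_len + 1, hop)
    power = np.zeros((*data.shape[:-1], block_len))
    n_avg = 0
    for s in starts:
        block = data[..., s:s + block_len]
        spec = np.fft.fftn(block)
        power += (spec.real ** 2 + spec.imag ** 2) / block.size
        n_avg += 1
    power /= n_avg
    axes = [np.fft.fftfreq(n) for n in power.shape]
    return STSpectrum(power=power, axes=axes, n_averages=n_avg)


def spectral_entropy(spec: STSpectrum, exclude_dc: bool = True) -> float:
    """Shannon entropy (bits) of the spectrum viewed as a distribution.

    Power is normalized to sum to one over the included bins; the DC bin is
    excluded by default since the interesting contrast is between low-but-
    nonzero frequencies and broadband power.  Zero total power raises
    :class:`UndefinedEntropyError`.
    """
    p = spec.power.ravel().copy()
    if exclude_dc:
        p[0] = 0.0  # flat index 0 is the all-axes DC bin
    total = p.sum()
    if total <= 0:
        raise UndefinedEntropyError("zero total power: entropy undefined")
    p /= total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def low_frequency_power(spec: STSpectrum, band: float = 0.1) -> float:
    """Fraction of non-DC power at low spatiotemporal frequencies.

    A bin at frequencies (k1, ..., omega) is "low" when
    ``0 < max_axis |f_axis| / f_Nyquist <= band`` — an inf-norm ball of
    radius ``band`` times Nyquist on every axis, DC excluded.  The result is
    that band's share of total non-DC power.
    """
    if not 0 < band < 0.5 + 1e-12:
        raise ValueError("band must be in (0, 0.5]")
    grids = np.meshgrid(*[np.abs(a) / 0.5 for a in spec.axes], indexing="ij")
    nu_inf = np.maximum.reduce(grids)
    nondc = nu_inf > 0
    total = spec.power[nondc].sum()
    if total <= 0:
        return 0.0
    low = nondc & (nu_inf <= band)
    return float(spec.power[low].sum() / total)


def regime_thresholds(entropy: np.ndarray) -> tuple[float, float]:
    """Entropy levels splitting the observed range into three equal terciles.

    Cells below the lower threshold are "ordered" (strongly peaked spectra),
    above the upper "chaotic" (broadband), and between them "complex".
    Range-based terciles are used rather than count percentiles: the entropy
    landscape contains large plateaus, and a count-based boundary falling
    inside a plateau would split one regime in two on estimator noise alone.
    """
    finite = entropy[np.isfinite(entropy)]
    if finite.size == 0:
        raise ValueError("no finite entropy cells")
    lo = float(finite.min() + (finite.max() - finite.min()) / 3.0)
    hi = float(finite.min() + 2.0 * (finite.max() - finite.min()) / 3.0)
    return lo, hi


def intermediate_component_fraction(entropy: np.ndarray) -> float:
    """Largest connected fraction of intermediate-entropy ("complex") cells.

    Classifies cells by :func:`regime_thresholds` and returns the size of
    the largest 4-connected component of intermediate cells divided by their
    total count — near 1 when the complex regime forms a solid region of
    parameter space rather than scattered islands.
    """
    from scipy import ndimage

    lo, hi = regime_thresholds(entropy)
    mid = np.isfinite(entropy) & (entropy >= lo) & (entropy <= hi)
    if not mid.any():
        return 0.0
    labels, n = ndimage.label(mid)
    sizes = ndimage.sum(mid, labels, range(1, n + 1))
    return float(np.max(sizes) / mid.sum())


def phase_diagram(
    coupling: CouplingMatrix,
    c_values: np.ndarray,
    lam_values: np.ndarray,
    steps: int = 1536,
    transient: int = 512,
    block_len: int = 256,
    overlap: float = 0.5,
    init_amplitude: float = 1.0,
    band: float = 0.1,
    seed: int = 0,
    quiescent_rms: float = 1e-7,
) -> PhaseDiagramGrid:
    """Sweep (c, lam), computing spectral entropy and low-frequency power.

    The exposure operator is built once per lam.  Each cell runs from an
    independent random initial field whose RNG stream is derived from
    ``(seed, c index, lam index)``, so any cell can be reproduced in
    isolation.  A cell whose recorded field has RMS below ``quiescent_rms``
    is flagged quiescent (its entropy would only measure float noise); a
    blowup is caught, flagged, and never aborts the sweep.
    """
    c_values = np.asarray(c_values, dtype=float)
    lam_values = np.asarray(lam_values, dtype=float)
    if c_values.size == 0 or lam_values.size == 0:
        raise ValueError("c and lam grids must be nonempty")
    nc, nl = c_values.size, lam_values.size
    entropy = np.full((nc, nl), np.nan)
    lfp = np.full((nc, nl), np.nan)
    status = np.zeros((nc, nl), dtype=int)
    for li, lam in enumerate(lam_values):
        op = exposure(coupling, lam)
        for ci, c in enumerate(c_values):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, li]))
            field0 = random_field(coupling.geometry, init_amplitude, rng)
            try:
                series = simulate(field0, op, c, steps=steps, transient=transient)
            except BlowupError:
                status[ci, li] = CELL_BLOWUP
                continue
            if np.sqrt(np.mean(series.values ** 2)) < quiescent_rms:
                status[ci, li] = CELL_QUIESCENT
                continue
            spec = st_spectrum(series, block_len=block_len, overlap=overlap)
            entropy[ci, li] = spectral_entropy(spec)
            lfp[ci, li] = low_frequency_power(spec, band=band)
    return PhaseDiagramGrid(
        c_values=c_values,
        lam_values=lam_values,
        entropy=entropy,
        low_freq_power=lfp,
        status=status,
        run_config={
            "steps": steps, "transient": transient, "block_len": block_len,
            "overlap": overlap, "init_amplitude": init_amplitude,
            "band": band, "seed": seed,
            "lattice": coupling.descriptor,
        },
    )
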