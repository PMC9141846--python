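"""Forced Hopf normal form: steady states, sweeps, and time integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from dyncrit import hopf
from dyncrit.hopf import HopfParams


def brute_force_roots(mu: float, detuning: float, F: float) -> np.ndarray:
    """Independent oracle: bracketed root finding on the amplitude equation
    h(R) = R^2((mu - R^2)^2 + d^2) - F^2.

    Scans a dense log-spaced grid in R for sign changes and polishes each
    with Brent's method; avoids the polynomial-companion path used by the
    implementation.  The log grid keeps relative accuracy at tiny F.
    """
    def h(R):
        return R * R * ((mu - R * R) ** 2 + detuning ** 2) - F * F

    rmax = 2.0 * max(np.sqrt(abs(mu)), F ** (1.0 / 3.0), 1.0)
    grid = np.concatenate([[0.0], np.logspace(-12, np.log10(rmax), 8000)])
    vals = h(grid)
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(h, grid[i], grid[i + 1], xtol=1e-300, rtol=1e-14))
    return np.asarray(sorted(roots))


@pytest.mark.parametrize(
    "mu, F, omega, expected",
    [
        (0.0, 0.0, 1.0, 0.0),            # unforced at the bifurcation
        (0.0, 1e-6, 1.0, 1e-2),          # R^3 = F at resonant criticality
        (0.04, 0.0, 1.0, 0.2),           # spontaneous limit cycle sqrt(mu)
    ],
)
def test_steady_response_known_values(mu, F, omega, expected):
    resp = hopf.steady_response(HopfParams(mu=mu, omega0=1.0, F=F, omega=omega))
    assert resp.amplitude == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    mu=st.floats(-2.0, 2.0),
    detuning=st.floats(-1.0, 1.0),
    F=st.floats(1e-9, 1.0),
)
def test_steady_response_matches_bracketing_oracle(mu, detuning, F):
    """Every returned amplitude solves the steady-state cubic, and the root
    set agrees with an independent bracketed root finder."""
    resp = hopf.steady_response(HopfParams(mu=mu, omega0=1.0, F=F, omega=1.0 - detuning))
    for R in resp.amplitudes:
        residual = R * R * ((mu - R * R) ** 2 + detuning ** 2) - F * F
        scale = max(F * F, 1e-30)
        assert abs(residual) < 1e-6 * scale + 1e-12
    oracle = brute_force_roots(mu, detuning, F)
    assert resp.amplitudes[0] == pytest.approx(oracle[0], rel=1e-6, abs=1e-12)
    # only compare branch counts away from fold degeneracies, where both
    # root finders resolve the branches unambiguously
    def well_separated(roots):
        return roots.size < 2 or np.min(np.diff(roots)) > 1e-3 * roots[-1]

    if well_separated(oracle) and well_separated(resp.amplitudes):
        assert resp.multistable == (oracle.size > 1)


def test_one_third_power_identity():
    """At mu=0 and resonance, R^3 = F to 1e-10 relative over 8 decades."""
    for F in np.logspace(-9, -1, 33):
        R = hopf.steady_response(HopfParams(mu=0.0, F=F)).amplitude
        assert abs(R ** 3 - F) / F < 1e-10


def test_response_exponent_compressive_and_linear():
    slope_crit = hopf.response_exponent(0.0, 0.0, np.logspace(-8, -2, 25))
    assert 0.32 <= slope_crit <= 0.34
    # deep in the stable regime the response is linear: R ~ F/|mu|
    slope_lin = hopf.response_exponent(-1.0, 0.0, np.logspace(-8, -5, 20))
    assert slope_lin == pytest.approx(1.0, abs=1e-3)


def test_response_exponent_short_grid_warns_but_works():
    with pytest.warns(UserWarning, match="decades"):
        slope = hopf.response_exponent(0.0, 0.0, np.logspace(-4, -3, 10))
    assert slope == pytest.approx(1.0 / 3.0, abs=0.01)


def test_simulate_decay_and_limit_cycle():
    # damped linear regime: |z| collapses within 10 time units
    _, z = hopf.simulate(HopfParams(mu=-1.0), duration=10.0, dt=0.01, z0=0.1)
    assert abs(z[-1]) < 1e-4
    # resonant forcing at criticality: |z| -> F^(1/3) within 1%
    _, z = hopf.simulate(HopfParams(mu=0.0, F=1e-3), duration=400.0, dt=0.05)
    assert abs(z[-1]) == pytest.approx(0.1, rel=0.01)
    # supercritical growth from a small seed to the limit cycle sqrt(mu)
    _, z = hopf.simulate(HopfParams(mu=0.04), duration=400.0, dt=0.05, z0=1e-3)
    assert abs(z[-1]) == pytest.approx(0.2, rel=0.01)


def test_simulate_agrees_with_steady_response_random_sweep():
    rng = np.random.default_rng(7)
    for _ in range(5):
        mu = rng.uniform(-1.0, 0.0)
        F = 10 ** rng.uniform(-4, -2)
        detuning = rng.uniform(-0.05, 0.05)
        p = HopfParams(mu=mu, F=F, omega=1.0 - detuning)
        resp = hopf.steady_response(p)
        if resp.multistable:
            continue
        relax = 5.0 / max(abs(mu), F ** (2.0 / 3.0))
        _, z = hopf.simulate(p, duration=relax, dt=0.05)
        assert abs(z[-1]) == pytest.approx(resp.amplitude, rel=0.01)


def test_unforced_recovery_both_sides():
    """|z| -> 0 for mu<0 and |z| -> sqrt(mu) for mu>0 within 1% after 100/|mu|."""
    _, z = hopf.simulate(HopfParams(mu=-0.5), duration=200.0, dt=0.05, z0=0.3)
    assert abs(z[-1]) < 0.01 * 0.3
    _, z = hopf.simulate(HopfParams(mu=0.25), duration=400.0, dt=0.05, z0=1e-2)
    assert abs(z[-1]) == pytest.approx(0.5, rel=0.01)


def test_simulate_blowup_reports_step():
    from dyncrit.errors import BlowupError

    with pytest.raises(BlowupError) as err:
        with np.errstate(all="ignore"):
            hopf.simulate(HopfParams(mu=0.0), duration=100.0, dt=10.0, z0=3.0 + 0j)
    assert err.value.step is not None


def test_tuning_curve_gain_and_sharpening():
    grid = np.linspace(0.9, 1.1, 801)
    # resonance gain F^(-2/3) at criticality, diverging as F -> 0
    for F in (1e-4, 1e-5):
        curve = hopf.tuning_curve(0.0, F, grid)
        assert curve.meta["gain"] == pytest.approx(F ** (-2.0 / 3.0), rel=1e-3)
    # relative half-width shrinks as the forcing shrinks (sharp tuning for faint input)
    hw_small = hopf.tuning_curve(0.0, 1e-5, grid).meta["rel_half_width"]
    hw_large = hopf.tuning_curve(0.0, 1e-3, np.linspace(0.7, 1.3, 801)).meta["rel_half_width"]
    assert hw_small < hw_large
    # linear-response bound on the stable side: gain <= 1/|mu| (the curve is
    # too broad to fall to 1/sqrt(2) inside this grid, which warns)
    with pytest.warns(UserWarning, match="1/sqrt"):
        curve = hopf.tuning_curve(-1.0, 1e-3, grid)
    assert curve.meta["gain"] <= 1.0 / 1.0 + 1e-9


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        HopfParams(mu=0.0, F=-1.0)
    with pytest.raises(ValueError):
        HopfParams(mu=0.0, omega0=0.0)
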