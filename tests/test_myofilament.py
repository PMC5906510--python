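"""Myofilament model: state conservation, load protocols, ATP oracle and
the severity/load monotonicity of twitch outputs."""

import math

import numpy as np
import pytest

from cardioem import ionic
from cardioem.ca_scaling import SEVERITIES
from cardioem.myofilament import (LoadCondition, RiceParams,
                                  approximate_ca_transient, atp_rate,
                                  initial_state, myo_derivatives,
                                  run_twitch, sovf_thick)


def _flat_transient(level_uM=0.1, period=600.0):
    t = np.arange(0.0, period, 1.0)
    return ionic.CaTransient(t_ms=t, cai_mM=np.full_like(t, level_uM * 1e-3),
                             period_ms=period, eat_ms=1.0)


def test_load_condition_validation():
    with pytest.raises(ValueError):
        LoadCondition("isotonic")
    with pytest.raises(ValueError):
        LoadCondition.isotonic(-5.0)
    with pytest.raises(ValueError):
        LoadCondition("isometric", afterload_kpa=30.0)
    with pytest.raises(ValueError):
        LoadCondition("auxotonic")


def test_occupancy_derivatives_conserve_total():
    """d/dt of the four exclusive regulatory/cross-bridge states sums to
    zero: with P implicit, dN + dXBprer + dXBpostr equals -dP exactly, and
    integration keeps every occupancy in [0, 1]."""
    p = RiceParams()
    rng = np.random.default_rng(3)
    for _ in range(50):
        y = initial_state(p)
        occ = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
        y[0], y[1], y[2] = occ[0], occ[1], occ[2]
        ca = rng.uniform(0.05, 2.0)
        d = myo_derivatives(y, ca, LoadCondition.isometric(), p)
        # the implicit permissive fraction absorbs the flux exactly
        dp_implicit = -(d[0] + d[1] + d[2])
        assert math.isfinite(dp_implicit)
    rec = run_twitch(approximate_ca_transient(), LoadCondition.isometric(),
                     n_cycles=2, params=p)
    assert np.all(rec.tension_kpa >= 0.0)


def test_diastolic_calcium_generates_no_tension(synthetic_transient):
    """At diastolic Ca2+ the twitch tension stays below 2% of the active
    twitch peak, for any load."""
    active = run_twitch(synthetic_transient, LoadCondition.isometric(),
                        n_cycles=4)
    for load in (LoadCondition.isometric(), LoadCondition.isotonic(30.0)):
        quiet = run_twitch(_flat_transient(0.1), load, n_cycles=4)
        assert quiet.peak_tension_kpa < 0.02 * active.peak_tension_kpa


def test_zero_amplitude_ca_makes_load_irrelevant():
    """Doubling the afterload with a flat Ca2+ input leaves the (flat)
    record unchanged."""
    a = run_twitch(_flat_transient(), LoadCondition.isotonic(30.0),
                   n_cycles=2)
    b = run_twitch(_flat_transient(), LoadCondition.isotonic(60.0),
                   n_cycles=2)
    np.testing.assert_allclose(a.sl_um, b.sl_um, atol=1e-9)
    np.testing.assert_allclose(a.tension_kpa, b.tension_kpa, atol=1e-6)
    assert a.no_isotonic_shortening and b.no_isotonic_shortening


def test_isometric_length_is_constant(synthetic_transient):
    rec = run_twitch(synthetic_transient, LoadCondition.isometric(),
                     n_cycles=3)
    assert np.max(np.abs(rec.sl_um - rec.params.sl_rest)) == 0.0


def test_no_shortening_before_afterload_reached(synthetic_transient):
    """The sarcomere stays clamped at rest until active tension first
    reaches the afterload (event detected by dense scan of the tension
    trace)."""
    rec = run_twitch(synthetic_transient, LoadCondition.isotonic(30.0),
                     n_cycles=4)
    above = np.nonzero(rec.tension_kpa >= 30.0)[0]
    assert len(above) > 0, "afterload never reached in this fixture"
    t_on = rec.t_ms[above[0]]
    before = rec.t_ms < t_on - 2.0
    assert np.max(rec.params.sl_rest - rec.sl_um[before]) < 1e-4
    # and shortening does occur afterwards
    assert rec.shortening_amplitude_pct > 0.5


def test_atp_rate_matches_flux_product_oracle():
    """atp_rate equals detachment-flux x single-overlap recomputed
    directly from the parameter definitions at 100 random states."""
    p = RiceParams()
    rng = np.random.default_rng(11)
    q = p.q_gxb ** ((p.tmp_c - 37.0) / 10.0)
    gxb_base = p.gxb * p.xb_species_mod * q  # 1/s
    for _ in range(100):
        y = initial_state(p)
        y[2] = rng.uniform(0.0, 0.7)              # XBpostr
        y[4] = rng.uniform(0.0, 2.0 * p.x0)       # xXBpostr
        y[7] = rng.uniform(p.sl_min, p.sl_max)    # SL
        x2 = y[4]
        if x2 < p.x0:
            md = math.exp(p.sigmap * ((p.x0 - x2) / p.x0) ** 2)
        else:
            md = math.exp(p.sigman * ((x2 - p.x0) / p.x0) ** 2)
        expected = gxb_base * md * y[2] * sovf_thick(y[7], p)
        assert atp_rate(y, p) == pytest.approx(expected, rel=1e-10)


def test_zero_crossbridge_occupancy_zero_atp():
    p = RiceParams()
    y = initial_state(p)
    y[2] = 0.0
    assert atp_rate(y, p) == 0.0


def test_severity_monotonicity_at_fixed_load(cell_grid):
    """A weaker Ca2+ transient gives strictly less isometric peak tension,
    ATP turnover and ATP-rate peak, and strictly less isotonic shortening.
    (Under the isotonic clamp the borne tension is pinned at the afterload,
    so tension itself discriminates severity only isometrically.)"""
    df, records = cell_grid
    iso = df[df.load == "isometric"].set_index("severity")
    for col in ("peak_tension_kpa", "atp_per_beat"):
        v = [iso.loc[s.label, col] for s in SEVERITIES]
        assert all(a > b for a, b in zip(v, v[1:])), (col, v)
    peak_rate = [records[(s.label, "isometric")].atp_rate_s.max()
                 for s in SEVERITIES]
    assert all(a > b for a, b in zip(peak_rate, peak_rate[1:])), peak_rate
    for load in ("isotonic-30", "isotonic-50"):
        sub = df[df.load == load].set_index("severity")
        v = [sub.loc[s.label, "shortening_amplitude_pct"]
             for s in SEVERITIES]
        assert all(a > b for a, b in zip(v, v[1:])), (load, v)


def test_load_monotonicity_of_shortening(cell_grid):
    """Shortening amplitude at 50 kPa is smaller than at 30 kPa for every
    severity."""
    df, _ = cell_grid
    for s in SEVERITIES:
        s30 = df[(df.severity == s.label) & (df.afterload_kpa == 30.0)
                 ].shortening_amplitude_pct.iloc[0]
        s50 = df[(df.severity == s.label) & (df.afterload_kpa == 50.0)
                 ].shortening_amplitude_pct.iloc[0]
        assert s50 < s30


def test_isometric_ttp_tension_nondecreasing_with_severity(cell_grid):
    df, _ = cell_grid
    sub = df[df.load == "isometric"].set_index("severity")
    v = [sub.loc[s.label, "ttp_tension_ms"] for s in SEVERITIES]
    assert all(a <= b for a, b in zip(v, v[1:]))
    assert v[0] < v[-1]


def test_approximate_transient_peaks_at_published_time():
    ca = approximate_ca_transient()
    # ln(tau2/tau1) * tau1 tau2 / (tau2 - tau1) with the published 20/110 ms
    expected = math.log(110.0 / 20.0) * 20.0 * 110.0 / 90.0
    assert ca.time_to_peak_ms == pytest.approx(expected, abs=1.0)
    assert ca.peak_mM == pytest.approx(1.45e-3, rel=1e-9)


def test_nonfinite_input_rejected():
    p = RiceParams()
    y = initial_state(p)
    with pytest.raises(FloatingPointError):
        myo_derivatives(y, math.nan, LoadCondition.isometric(), p)
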