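"""Lumped circulation: valve/chamber operations, conservation, suction
guard, and the LVAD hemodynamic/EMD orderings of the 8-scenario sweep."""

import numpy as np
import pytest

from cardioem import circulation as circ
from cardioem.circulation import (ChamberModel, CircParams, LVADConfig,
                                  chamber_pressure, initial_state,
                                  simulate_circulation, step_circulation,
                                  valve_flow)

SEV = ("HF1", "HF2", "HF3", "HF4")


def _gaussian_tension(peak_kpa=80.0, period=600.0):
    t = np.arange(0.0, period, 1.0)
    return peak_kpa * np.exp(-((t - 120.0) ** 2) / (2 * 60.0 ** 2))


# ---- valve and chamber operations -----------------------------------------

def test_valve_flow_diode_and_ohmic():
    assert valve_flow(100.0, 100.0, 0.1) == 0.0
    assert valve_flow(100.0, 80.0, 0.1) == pytest.approx(200.0)
    assert valve_flow(80.0, 100.0, 0.1) == 0.0  # no regurgitation
    with pytest.raises(ValueError):
        valve_flow(1.0, 0.0, 0.0)


def test_chamber_pressure_passive_at_zero_tension():
    ch = ChamberModel()
    p = chamber_pressure(ch.v0_pas, 0.0, ch, hf=False)
    assert p == pytest.approx(0.0, abs=1e-12)


def test_chamber_pressure_monotone_in_volume():
    ch = ChamberModel()
    v = np.linspace(ch.v0_pas, 2 * ch.v0_pas + 80.0, 200)
    for tension in (0.0, 40.0, 90.0):
        p = np.array([chamber_pressure(x, tension, ch) for x in v])
        assert np.all(np.diff(p) >= 0.0)


def test_hf_passive_stiffness_is_fivefold():
    ch = ChamberModel()
    for v in (30.0, 60.0, 90.0):
        assert chamber_pressure(v, 0.0, ch, hf=True) \
            == pytest.approx(5.0 * chamber_pressure(v, 0.0, ch, hf=False))
    with pytest.raises(ValueError):
        chamber_pressure(-1.0, 0.0, ch)


def test_step_rejects_large_dt():
    st = initial_state(CircParams())
    with pytest.raises(ValueError):
        step_circulation(st, 0.0, 0.0, CircParams(), dt_s=0.002)


# ---- conservation and suction ---------------------------------------------

@pytest.mark.parametrize("lvad_on", [False, True])
def test_blood_volume_conserved_over_10s(lvad_on):
    params = CircParams()
    tension = _gaussian_tension()
    _, rec, _ = simulate_circulation(tension, 600.0, params,
                                     LVADConfig(enabled=lvad_on),
                                     duration_s=10.0)
    drift = abs(rec["v_total"][-1] - rec["v_total"][0])
    assert drift < 0.1


def test_suction_guard_engages_for_excessive_pump_flow():
    """A pump demanding far more than venous return trips the guard and
    the LV volume never goes below the floor; volume stays conserved."""
    params = CircParams()
    tension = _gaussian_tension(peak_kpa=20.0)
    _, rec, suction = simulate_circulation(
        tension, 600.0, params, LVADConfig(enabled=True, flow_mls=400.0),
        duration_s=5.0)
    assert suction > 0
    assert rec["v_lv"].min() >= params.lv_floor - 0.5
    assert abs(rec["v_total"][-1] - rec["v_total"][0]) < 0.1


def test_lvad_config_validation():
    with pytest.raises(ValueError):
        LVADConfig(flow_mls=-1.0)


# ---- sweep-level properties (paper regime) --------------------------------

def test_conservation_in_all_scenarios(sweep):
    for r in sweep.values():
        assert r.volume_drift_ml < 0.1


def test_ef_strictly_decreasing_with_severity_in_control(sweep):
    ef = [sweep[(s, False)].ef_pct for s in SEV]
    assert all(a > b for a, b in zip(ef, ef[1:]))


def test_pv_loops_shift_right_with_severity_left_with_lvad(sweep):
    edv = [sweep[(s, False)].edv_ml for s in SEV]
    assert all(a < b for a, b in zip(edv, edv[1:]))
    for s in SEV:
        assert sweep[(s, True)].edv_ml < sweep[(s, False)].edv_ml


def test_full_assist_split_between_hf2_and_hf3(sweep):
    """With the 50 mL/s pump the aortic valve stays shut for the whole
    cycle in HF3/HF4 (full assist) but opens in HF1/HF2."""
    for s in ("HF1", "HF2"):
        r = sweep[(s, True)]
        assert r.aortic_valve_open and not r.fully_assisted
    for s in ("HF3", "HF4"):
        r = sweep[(s, True)]
        assert not r.aortic_valve_open and r.fully_assisted
        assert np.max(r.q_ao) == 0.0
    # control scenarios always eject
    for s in SEV:
        assert sweep[(s, False)].aortic_valve_open


def test_stroke_work_lower_with_lvad_everywhere(sweep):
    for s in SEV:
        assert sweep[(s, True)].stroke_work_mmhg_ml \
            < sweep[(s, False)].stroke_work_mmhg_ml


def test_atp_lower_with_lvad_and_largest_reduction_at_hf4(sweep):
    red = []
    for s in SEV:
        c = sweep[(s, False)].atp_per_beat
        o = sweep[(s, True)].atp_per_beat
        assert o < c
        red.append((c - o) / c)
    assert red[3] == max(red)


def test_lvad_reduces_lv_peak_pressure_in_severe_hf(sweep):
    for s in ("HF3", "HF4"):
        assert sweep[(s, True)].lv_peak_pressure_mmhg \
            < sweep[(s, False)].lv_peak_pressure_mmhg


def test_emd_orderings(sweep):
    """EMD rises with severity in control, falls under LVAD at every
    severity, and the relative reduction is largest at HF4."""
    emd_c = [sweep[(s, False)].emd.emd_ms for s in SEV]
    assert all(a < b for a, b in zip(emd_c, emd_c[1:]))
    red = []
    for s in SEV:
        c = sweep[(s, False)].emd.emd_ms
        o = sweep[(s, True)].emd.emd_ms
        assert o <= c
        red.append((c - o) / c)
    assert red[3] == max(red)


def test_scenarios_settle_to_periodic_state(sweep):
    for r in sweep.values():
        assert r.convergence_ml < 0.5
        assert r.suction_events == 0
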