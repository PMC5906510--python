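"""Closed-loop lumped circulation with tension-driven ventricles and a
constant-flow LVAD.

Eight stressed-volume compartments are connected in a loop:

    LV -> (aortic valve / LVAD) -> systemic arteries -> systemic veins ->
    RA -> (tricuspid) -> RV -> (pulmonary valve) -> pulmonary arteries ->
    pulmonary veins -> LA -> (mitral) -> LV

Valves are ideal diodes in series with a linear resistance; atria and the
vascular beds are passive compliances.  Each ventricle is a reduced-order
chamber driven by the myofilament twitch-tension waveform: its pressure is
an active part proportional to the instantaneous tension times a linear
volume factor (a time-varying-elastance surrogate for the finite-element
ventricle) plus an exponential end-diastolic (passive) pressure-volume
relation whose stiffness constant is scaled fivefold for the failing
myocardium.  The LVAD is a flow generator drawing a constant flow from the
LV into the systemic-artery compartment, bypassing the aortic valve; a
suction guard limits the pump to the available LV volume.

For reporting cell-level afterload, LV wall stress is read out with a
thick-sphere Laplace relation sigma = P * (1/3 + V/V_wall).

The update is explicitly conservative: every flow leaves one compartment
and enters another, so total blood volume is constant to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .ca_scaling import HFSeverity, scale_transient
from .ionic import CaTransient
from .metrics import EMDRecord, emd_for_twitch
from .myofilament import LoadCondition, RiceParams, run_twitch

__all__ = [
    "CircParams",
    "ChamberModel",
    "LVADConfig",
    "CircState",
    "ScenarioResult",
    "valve_flow",
    "chamber_pressure",
    "step_circulation",
    "simulate_circulation",
    "run_scenario",
    "MMHG_PER_KPA",
]

MMHG_PER_KPA = 7.50062


@dataclass(frozen=True)
class LVADConfig:
    """Constant-flow LVAD from the LV apex to the aorta.

    The default 50 mL/s (3 L/min) fully assists the two most severe HF
    conditions in this model, matching the small (child-sized) failing
    ventricle it supports.
    """

    enabled: bool = False
    flow_mls: float = 50.0

    def __post_init__(self) -> None:
        if self.flow_mls < 0:
            raise ValueError("LVAD flow must be >= 0")


@dataclass(frozen=True)
class ChamberModel:
    """Reduced-order ventricular chamber driven by myofilament tension.

    P(V, T) = k_act * T * max(V - v0_act, 0) + s * b_pas * (e^{a(V-v0)} - 1)

    with T the instantaneous active tension (kPa) and s the heart-failure
    passive-stiffness multiplier (5 when the HF flag is set).
    """

    k_act: float = 0.05         # mmHg / (kPa mL)
    v0_act: float = 25.0        # mL
    b_pas: float = 0.12         # mmHg
    a_pas: float = 0.04         # 1/mL
    v0_pas: float = 10.0        # mL
    v_wall: float = 50.0        # mL, wall volume for the Laplace readout
    v_sl_ref: float = 75.0      # mL, cavity volume mapped to the rest SL

    def passive(self, volume: float, hf: bool = True,
                stiffness_multiplier: float = 5.0) -> float:
        s = stiffness_multiplier if hf else 1.0
        return s * self.b_pas * math.expm1(self.a_pas * (volume - self.v0_pas))

    def wall_stress_kpa(self, pressure_mmhg: float, volume_ml: float) -> float:
        """Thick-sphere Laplace wall stress for a cavity P and volume."""
        return pressure_mmhg / MMHG_PER_KPA * (1.0 / 3.0
                                               + volume_ml / self.v_wall)


def chamber_pressure(volume_ml: float, tension_kpa: float,
                     chamber: ChamberModel, hf: bool = True,
                     stiffness_multiplier: float = 5.0) -> float:
    """Chamber pressure (mmHg) from volume and instantaneous tension."""
    if volume_ml < 0:
        raise ValueError("volume must be >= 0")
    act = chamber.k_act * max(tension_kpa, 0.0) \
        * max(volume_ml - chamber.v0_act, 0.0)
    return act + chamber.passive(volume_ml, hf, stiffness_multiplier)


def valve_flow(p_upstream: float, p_downstream: float,
               resistance: float) -> float:
    """Ideal diode + linear resistance: max(0, dP/R) (mL/s)."""
    if resistance <= 0:
        raise ValueError("resistance must be > 0")
    return max(0.0, (p_upstream - p_downstream) / resistance)


@dataclass(frozen=True)
class CircParams:
    """Lumped-parameter constants (mmHg, s, mL) and HF modifiers.

    Baselines follow the cited lumped-circulation literature scaled to the
    small dilated ventricle; the paper states only the HF adjustments (a
    raised resistance, a 10% compliance decrease and the fivefold passive
    stiffness), so the baselines are this package's own documented choice
    and are exposed for override.
    """

    # valve and vascular resistances (mmHg s / mL)
    r_mi: float = 0.008
    r_ao: float = 0.008
    r_tr: float = 0.008
    r_pu: float = 0.008
    r_sa: float = 1.9
    r_sv: float = 0.05
    r_pa: float = 0.15
    r_pv: float = 0.03
    # compliances (mL / mmHg)
    c_sa: float = 1.3
    c_sv: float = 60.0
    c_pa: float = 4.5
    c_pv: float = 8.0
    c_la: float = 10.0
    c_ra: float = 12.0
    # total stressed blood volume (mL)
    total_volume: float = 800.0
    # HF modifiers
    hf: bool = True
    resistance_multiplier: float = 1.2
    compliance_multiplier: float = 0.9
    stiffness_multiplier: float = 5.0
    # suction guard floor for the LV under LVAD (mL)
    lv_floor: float = 5.0

    def effective(self) -> dict[str, float]:
        """Apply the HF modifiers to the vascular beds."""
        rm = self.resistance_multiplier if self.hf else 1.0
        cm = self.compliance_multiplier if self.hf else 1.0
        return {
            "r_mi": self.r_mi, "r_ao": self.r_ao,
            "r_tr": self.r_tr, "r_pu": self.r_pu,
            "r_sa": self.r_sa * rm, "r_sv": self.r_sv,
            "r_pa": self.r_pa * rm, "r_pv": self.r_pv,
            "c_sa": self.c_sa * cm, "c_sv": self.c_sv * cm,
            "c_pa": self.c_pa * cm, "c_pv": self.c_pv * cm,
            "c_la": self.c_la * cm, "c_ra": self.c_ra * cm,
        }


# compartment order used throughout
COMPARTMENTS = ("LV", "SA", "SV", "RA", "RV", "PA", "PV", "LA")


@dataclass
class CircState:
    """Compartment volumes (mL) and the instantaneous flows (mL/s)."""

    volumes: np.ndarray                       # order: COMPARTMENTS
    flows: dict[str, float] = field(default_factory=dict)

    @property
    def total_volume(self) -> float:
        return float(np.sum(self.volumes))

    def volume(self, name: str) -> float:
        return float(self.volumes[COMPARTMENTS.index(name)])


def initial_state(params: CircParams) -> CircState:
    """Distribute the total stressed volume over the compartments."""
    frac = np.array([0.11, 0.19, 0.33, 0.09, 0.11, 0.06, 0.06, 0.05])
    return CircState(volumes=params.total_volume * frac / frac.sum())


@njit(cache=True)
def _step_kernel(vols, t_lv, t_rv, dt,
                 r_mi, r_ao, r_tr, r_pu, r_sa, r_sv, r_pa, r_pv,
                 c_sa, c_sv, c_pa, c_pv, c_la, c_ra,
                 k_lv, v0a_lv, b_lv, a_lv, v0p_lv,
                 k_rv, v0a_rv, b_rv, a_rv, v0p_rv,
                 stiff, q_lvad, lv_floor):
    """One conservative step stage: returns (dV/dt, flows) at the state."""
    v_lv, v_sa, v_sv, v_ra, v_rv, v_pa, v_pv, v_la = vols

    p_lv = k_lv * t_lv * max(v_lv - v0a_lv, 0.0) \
        + stiff * b_lv * (math.exp(a_lv * (v_lv - v0p_lv)) - 1.0)
    p_rv = k_rv * t_rv * max(v_rv - v0a_rv, 0.0) \
        + stiff * b_rv * (math.exp(a_rv * (v_rv - v0p_rv)) - 1.0)
    p_sa = v_sa / c_sa
    p_sv = v_sv / c_sv
    p_ra = v_ra / c_ra
    p_pa = v_pa / c_pa
    p_pv = v_pv / c_pv
    p_la = v_la / c_la

    q_mi = max(0.0, (p_la - p_lv) / r_mi)
    q_ao = max(0.0, (p_lv - p_sa) / r_ao)
    q_sa = (p_sa - p_sv) / r_sa
    q_sv = (p_sv - p_ra) / r_sv
    q_tr = max(0.0, (p_ra - p_rv) / r_tr)
    q_pu = max(0.0, (p_rv - p_pa) / r_pu)
    q_pa = (p_pa - p_pv) / r_pa
    q_pv = (p_pv - p_la) / r_pv

    # suction guard: the pump cannot take more than the LV holds above floor
    q_pump = q_lvad
    avail = (v_lv - lv_floor) / dt + q_mi - q_ao
    suction = False
    if q_pump > avail:
        q_pump = max(0.0, avail)
        suction = True

    dv = np.empty(8)
    dv[0] = q_mi - q_ao - q_pump          # LV
    dv[1] = q_ao + q_pump - q_sa          # SA
    dv[2] = q_sa - q_sv                   # SV
    dv[3] = q_sv - q_tr                   # RA
    dv[4] = q_tr - q_pu                   # RV
    dv[5] = q_pu - q_pa                   # PA
    dv[6] = q_pa - q_pv                   # PV
    dv[7] = q_pv - q_mi                   # LA
    return dv, p_lv, p_sa, p_rv, q_ao, q_mi, q_pump, suction


@njit(cache=True)
def _simulate_kernel(vols0, tension_lv, tension_rv, dt, n_steps, rec_stride,
                     r_mi, r_ao, r_tr, r_pu, r_sa, r_sv, r_pa, r_pv,
                     c_sa, c_sv, c_pa, c_pv, c_la, c_ra,
                     k_lv, v0a_lv, b_lv, a_lv, v0p_lv,
                     k_rv, v0a_rv, b_rv, a_rv, v0p_rv,
                     stiff, q_lvad, lv_floor):
    vols = vols0.copy()
    n_rec = n_steps // rec_stride
    out = np.empty((8, n_rec))    # t, P_lv, P_sa, V_lv, Q_ao, Q_mi, Q_lvad, Vtot
    suction_events = 0
    irec = 0
    for i in range(n_steps):
        t_lv = tension_lv[i]
        t_rv = tension_rv[i]
        dv1, p_lv, p_sa, p_rv, q_ao, q_mi, q_pump, suc = _step_kernel(
            vols, t_lv, t_rv, dt,
            r_mi, r_ao, r_tr, r_pu, r_sa, r_sv, r_pa, r_pv,
            c_sa, c_sv, c_pa, c_pv, c_la, c_ra,
            k_lv, v0a_lv, b_lv, a_lv, v0p_lv,
            k_rv, v0a_rv, b_rv, a_rv, v0p_rv,
            stiff, q_lvad, lv_floor)
        if i % rec_stride == 0 and irec < n_rec:
            out[0, irec] = i * dt
            out[1, irec] = p_lv
            out[2, irec] = p_sa
            out[3, irec] = vols[0]
            out[4, irec] = q_ao
            out[5, irec] = q_pump
            out[6, irec] = q_mi
            out[7, irec] = np.sum(vols)
            irec += 1
        # midpoint (RK2) stage
        mid = vols + 0.5 * dt * dv1
        dv2, _, _, _, _, _, _, suc2 = _step_kernel(
            mid, t_lv, t_rv, dt,
            r_mi, r_ao, r_tr, r_pu, r_sa, r_sv, r_pa, r_pv,
            c_sa, c_sv, c_pa, c_pv, c_la, c_ra,
            k_lv, v0a_lv, b_lv, a_lv, v0p_lv,
            k_rv, v0a_rv, b_rv, a_rv, v0p_rv,
            stiff, q_lvad, lv_floor)
        vols = vols + dt * dv2
        if suc or suc2:
            suction_events += 1
    return vols, out, suction_events


def _kernel_params(params: CircParams, lv: ChamberModel, rv: ChamberModel,
                   lvad: LVADConfig) -> tuple:
    e = params.effective()
    stiff = params.stiffness_multiplier if params.hf else 1.0
    q = lvad.flow_mls if lvad.enabled else 0.0
    return (e["r_mi"], e["r_ao"], e["r_tr"], e["r_pu"],
            e["r_sa"], e["r_sv"], e["r_pa"], e["r_pv"],
            e["c_sa"], e["c_sv"], e["c_pa"], e["c_pv"],
            e["c_la"], e["c_ra"],
            lv.k_act, lv.v0_act, lv.b_pas, lv.a_pas, lv.v0_pas,
            rv.k_act, rv.v0_act, rv.b_pas, rv.a_pas, rv.v0_pas,
            stiff, q, params.lv_floor)


DEFAULT_RV = ChamberModel(k_act=0.007, v0_act=10.0, b_pas=0.06,
                          a_pas=0.04, v0_pas=10.0, v_wall=25.0)


def step_circulation(state: CircState, tension_lv_kpa: float,
                     tension_rv_kpa: float, params: CircParams,
                     lvad: LVADConfig = LVADConfig(),
                     dt_s: float = 0.00025,
                     lv_chamber: ChamberModel = ChamberModel(),
                     rv_chamber: ChamberModel = DEFAULT_RV) -> CircState:
    """Advance the circulation by one conservative explicit step.

    ``dt_s`` must not exceed 1 ms.  The returned state carries the
    instantaneous flows (mL/s) evaluated at the incoming state.
    """
    if dt_s > 0.001:
        raise ValueError("dt must be <= 1 ms")
    kp = _kernel_params(params, lv_chamber, rv_chamber, lvad)
    dv, p_lv, p_sa, p_rv, q_ao, q_mi, q_pump, suc = _step_kernel(
        state.volumes, tension_lv_kpa, tension_rv_kpa, dt_s, *kp)
    mid = state.volumes + 0.5 * dt_s * dv
    dv2 = _step_kernel(mid, tension_lv_kpa, tension_rv_kpa, dt_s, *kp)[0]
    new = state.volumes + dt_s * dv2
    return CircState(volumes=new,
                     flows={"Q_AO": q_ao, "Q_MI": q_mi, "Q_LVAD": q_pump,
                            "P_LV": p_lv, "P_SA": p_sa, "P_RV": p_rv,
                            "suction": float(suc)})


@dataclass
class ScenarioResult:
    """Per-condition hemodynamic summary of a 42-s scenario run."""

    severity: str
    lvad: LVADConfig
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    stroke_work_mmhg_ml: float
    lv_peak_pressure_mmhg: float
    lv_min_pressure_mmhg: float
    ao_peak_pressure_mmhg: float
    ao_min_pressure_mmhg: float
    aortic_valve_open: bool
    fully_assisted: bool
    afterload_kpa: float
    atp_per_beat: float
    emd: EMDRecord | None
    suction_events: int
    volume_drift_ml: float
    convergence_ml: float
    # last-beat traces (1 ms sampling)
    t_ms: np.ndarray
    p_lv: np.ndarray
    p_ao: np.ndarray
    v_lv: np.ndarray
    q_ao: np.ndarray
    q_lvad: np.ndarray

    def summary(self) -> dict:
        return {
            "severity": self.severity,
            "lvad": self.lvad.enabled,
            "EDV_ml": self.edv_ml, "ESV_ml": self.esv_ml,
            "SV_ml": self.sv_ml, "EF_pct": self.ef_pct,
            "stroke_work_mmHg_ml": self.stroke_work_mmhg_ml,
            "LV_peak_mmHg": self.lv_peak_pressure_mmhg,
            "AO_range_mmHg": [self.ao_min_pressure_mmhg,
                              self.ao_peak_pressure_mmhg],
            "fully_assisted": self.fully_assisted,
            "afterload_kPa": self.afterload_kpa,
            "ATP_per_beat": self.atp_per_beat,
            "EMD_ms": None if self.emd is None else self.emd.emd_ms,
            "MAT_ms": None if self.emd is None else self.emd.mat_ms,
            "suction_events": self.suction_events,
            "volume_drift_ml": self.volume_drift_ml,
        }


def simulate_circulation(tension_waveform_kpa: np.ndarray,
                         period_ms: float,
                         params: CircParams,
                         lvad: LVADConfig = LVADConfig(),
                         duration_s: float = 42.0,
                         dt_s: float = 0.00025,
                         rv_tension_fraction: float = 1.0,
                         lv_chamber: ChamberModel = ChamberModel(),
                         rv_chamber: ChamberModel = DEFAULT_RV,
                         state0: CircState | None = None):
    """Run the closed loop for ``duration_s`` driven by a periodic LV
    tension waveform (kPa, sampled at 1 ms over one period).

    Returns (final CircState, record dict sampled at 1 ms, suction count).
    """
    n_steps = int(round(duration_s / dt_s))
    rec_stride = max(1, int(round(0.001 / dt_s)))
    tper = np.asarray(tension_waveform_kpa, dtype=float)
    tgrid = np.arange(len(tper))  # ms
    t_of_step = (np.arange(n_steps) * dt_s * 1e3) % period_ms
    t_lv = np.interp(t_of_step, tgrid, tper, period=period_ms)
    t_rv = rv_tension_fraction * t_lv
    s0 = state0 or initial_state(params)
    kp = _kernel_params(params, lv_chamber, rv_chamber, lvad)
    vols, out, suction = _simulate_kernel(
        s0.volumes.astype(float), t_lv, t_rv, dt_s, n_steps, rec_stride, *kp)
    record = {
        "t_ms": out[0] * 1e3, "p_lv": out[1], "p_ao": out[2],
        "v_lv": out[3], "q_ao": out[4], "q_lvad": out[5], "q_mi": out[6],
        "v_total": out[7],
    }
    return CircState(volumes=vols), record, suction


def run_scenario(severity: HFSeverity,
                 lvad: LVADConfig,
                 ca_baseline: CaTransient,
                 circ_params: CircParams | None = None,
                 rice_params: RiceParams | None = None,
                 lv_chamber: ChamberModel = ChamberModel(),
                 rv_chamber: ChamberModel = DEFAULT_RV,
                 duration_s: float = 42.0,
                 n_twitch_cycles: int = 20,
                 dt_s: float = 0.00025) -> ScenarioResult:
    """One condition of the 8-scenario sweep (severity x control/LVAD).

    The severity's scaled Ca2+ transient drives an isometric twitch whose
    steady-state tension waveform drives the ventricles for ``duration_s``
    (one-way coupling).  The cell-level afterload reported back to the
    myofilament surrogate is the LV wall stress at peak systole, and the
    scenario's EMD and contractile ATP come from an afterloaded isotonic
    twitch at that load.
    """
    cp = circ_params or CircParams()
    rp = rice_params or RiceParams()
    ca = scale_transient(ca_baseline, severity)
    iso = run_twitch(ca, LoadCondition.isometric(),
                     n_cycles=n_twitch_cycles, params=rp)

    state, rec, suction = simulate_circulation(
        iso.tension_kpa, ca.period_ms, cp, lvad, duration_s=duration_s,
        dt_s=dt_s, lv_chamber=lv_chamber, rv_chamber=rv_chamber)

    # last full beat
    period = ca.period_ms
    n_per_beat = int(round(period))
    t = rec["t_ms"]
    last = slice(len(t) - n_per_beat, len(t))
    p_lv = rec["p_lv"][last]
    p_ao = rec["p_ao"][last]
    v_lv = rec["v_lv"][last]
    q_ao = rec["q_ao"][last]
    q_lvad = rec["q_lvad"][last]
    t_beat = t[last] - t[last][0]

    edv = float(v_lv.max())
    esv = float(v_lv.min())
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else math.nan
    # stroke work: enclosed PV-loop area over the beat
    sw = abs(float(np.trapezoid(p_lv, v_lv)))
    # periodicity check: LV volume one period apart
    prev = slice(len(t) - 2 * n_per_beat, len(t) - n_per_beat)
    conv = float(np.max(np.abs(rec["v_lv"][prev] - v_lv))) \
        if len(t) >= 2 * n_per_beat else math.nan
    drift = float(abs(rec["v_total"][-1] - rec["v_total"][0]))

    # cell-level afterload: peak systolic wall stress over the beat
    sigma = np.array([lv_chamber.wall_stress_kpa(p, v)
                      for p, v in zip(p_lv, v_lv)])
    afterload = float(sigma.max())

    # EMD from the afterloaded twitch at the scenario's wall-stress load
    emd_rec = None
    tw = run_twitch(ca, LoadCondition.isotonic(afterload),
                    n_cycles=n_twitch_cycles, params=rp)
    if not tw.no_isotonic_shortening:
        emd_rec = emd_for_twitch(tw)

    # scenario ATP from the volume-coupled fiber-strain twitch: sarcomere
    # length follows the cube root of cavity volume, so LVAD volume
    # unloading shortens the fibers and lowers the overlap-weighted
    # detachment flux
    sl_wave = rp.sl_rest * np.cbrt(v_lv / lv_chamber.v_sl_ref)
    sl_wave = np.clip(sl_wave, rp.sl_min + 0.01, rp.sl_max)
    aux = run_twitch(ca, LoadCondition.isometric(),
                     n_cycles=n_twitch_cycles, params=rp,
                     sl_waveform_um=sl_wave)
    atp = aux.atp_per_beat

    valve_open = bool(np.max(q_ao) > 1e-9)
    return ScenarioResult(
        severity=severity.label, lvad=lvad,
        edv_ml=edv, esv_ml=esv, sv_ml=sv, ef_pct=ef,
        stroke_work_mmhg_ml=sw,
        lv_peak_pressure_mmhg=float(p_lv.max()),
        lv_min_pressure_mmhg=float(p_lv.min()),
        ao_peak_pressure_mmhg=float(p_ao.max()),
        ao_min_pressure_mmhg=float(p_ao.min()),
        aortic_valve_open=valve_open,
        fully_assisted=lvad.enabled and not valve_open,
        afterload_kpa=afterload,
        atp_per_beat=atp,
        emd=emd_rec,
        suction_events=suction,
        volume_drift_ml=drift,
        convergence_ml=conv,
        t_ms=t_beat, p_lv=p_lv, p_ao=p_ao, v_lv=v_lv,
        q_ao=q_ao, q_lvad=q_lvad,
    )
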