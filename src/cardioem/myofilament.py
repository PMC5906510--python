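"""Cross-bridge myofilament model: Ca2+ transient -> tension, shortening, ATP.

Implements the approximate cooperative-activation / cross-bridge-cycling
myofilament model of cardiac muscle (Rice-type formulation): Ca2+ binds
low- and high-affinity troponin regulatory sites, thin-filament
permissiveness follows a steeply cooperative (Hill-like) function of the
overlap-weighted bound-troponin fraction, and attached cross-bridges cycle
through pre- and post-power-stroke states with strain-dependent rates.
Mean cross-bridge distortions carry the force-velocity behaviour; the
single-overlap fractions of the thick and thin filaments carry the
force-length behaviour.

The Ca2+ transient is a prescribed input (one-way excitation-contraction
coupling); there is no feedback from length or force onto Ca2+.

Mechanical load protocols
-------------------------
isometric  : sarcomere length fixed ("infinite load").
isotonic   : afterloaded twitch; length is clamped at rest until active
             tension first reaches the afterload, then shortens/relengthens
             tracking constant borne tension, and is clamped again once it
             returns to the rest length.

Normalized active force is mapped to kPa by a single calibration constant
(``tension_scale_kpa``); contractile ATP consumption rate is the product of
the post-power-stroke detachment flux and the thick-filament single-overlap
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .ionic import CaTransient

__all__ = [
    "RiceParams",
    "LoadCondition",
    "TwitchRecord",
    "myo_derivatives",
    "run_twitch",
    "atp_rate",
    "active_force",
    "sovf_thick",
    "sovf_thin",
]

# state layout: 0 N, 1 XBprer, 2 XBpostr, 3 xXBprer, 4 xXBpostr,
#               5 TRPNCaL, 6 TRPNCaH, 7 SL


@dataclass(frozen=True)
class RiceParams:
    """Published myofilament constants (rates in 1/s at 37 C) plus the
    calibration and protocol constants of this package.

    ``xb_species_mod`` scales all cross-bridge cycling rates; 1.0 is the
    small-rodent setting of the source model, 0.2 the large-mammal setting
    used here for human simulations.  ``tmp_c`` applies the published Q10s
    relative to 37 C.
    """

    # Ca binding to troponin (1/uM/s, 1/s)
    kon: float = 50.0
    koff_l: float = 250.0
    koff_h: float = 25.0
    # tropomyosin permissiveness
    perm50: float = 0.5
    nperm: float = 15.0
    kn_p: float = 500.0
    kp_n: float = 50.0
    # cross-bridge cycling (1/s)
    fapp: float = 500.0
    gapp: float = 70.0
    gslmod: float = 6.0
    hf: float = 2000.0
    hfmdc: float = 5.0
    hb: float = 400.0
    gxb: float = 70.0
    sigmap: float = 8.0
    sigman: float = 1.0
    # mean-strain dynamics
    x0: float = 0.007          # power-stroke distortion (um)
    xpsi: float = 2.0
    # sarcomere geometry (um)
    len_thin: float = 1.2
    len_thick: float = 1.65
    len_hbare: float = 0.1
    sl_min: float = 1.4
    sl_max: float = 2.4
    sl_rest: float = 2.2       # protocol rest length
    # temperature / species
    tmp_c: float = 37.0
    xb_species_mod: float = 0.2
    q_kon: float = 1.5
    q_koff: float = 1.3
    q_kn_p: float = 1.6
    q_kp_n: float = 1.6
    q_fapp: float = 6.25
    q_gapp: float = 2.5
    q_hf: float = 6.25
    q_hb: float = 6.25
    q_gxb: float = 6.25
    # calibration: normalized force -> kPa
    tension_scale_kpa: float = 100.0
    # constraint-stabilization rate (1/s) of the isotonic borne-tension
    # constraint dF/dt = -rate*(F - afterload); sets how fast transient
    # violations decay, not the shortening velocity (which the
    # cross-bridge kinetics determine)
    track_gain: float = 2000.0

    def _q(self, q: float) -> float:
        return q ** ((self.tmp_c - 37.0) / 10.0)

    def rates_ms(self) -> dict[str, float]:
        """Temperature/species-adjusted rates in 1/ms (kon in 1/uM/ms)."""
        xb = self.xb_species_mod
        return {
            "kon": self.kon * self._q(self.q_kon) * 1e-3,
            "koff_l": self.koff_l * self._q(self.q_koff) * 1e-3,
            "koff_h": self.koff_h * self._q(self.q_koff) * 1e-3,
            "kn_p": self.kn_p * self._q(self.q_kn_p) * 1e-3,
            "kp_n": self.kp_n * self._q(self.q_kp_n) * 1e-3,
            "fapp": self.fapp * xb * self._q(self.q_fapp) * 1e-3,
            "gapp": self.gapp * xb * self._q(self.q_gapp) * 1e-3,
            "hf": self.hf * xb * self._q(self.q_hf) * 1e-3,
            "hb": self.hb * xb * self._q(self.q_hb) * 1e-3,
            "gxb": self.gxb * xb * self._q(self.q_gxb) * 1e-3,
        }

    def duty_fractions(self) -> tuple[float, float]:
        """Steady-state pre/post-stroke duty fractions of the base cycle
        (strain-independent rates; species/temperature factors cancel)."""
        f, g, hf_, hb_, gx = self.fapp, self.gapp, self.hf, self.hb, self.gxb
        den = g * hb_ + g * gx + hf_ * gx + f * hb_ + f * gx + f * hf_
        return f * (hb_ + gx) / den, f * hf_ / den


def sovf_thick(sl: float, p: RiceParams) -> float:
    """Single-overlap fraction of the thick filament at sarcomere length sl."""
    ze = min(p.len_thick / 2.0, sl / 2.0)
    cle = max(sl / 2.0 - (sl - p.len_thin), p.len_hbare / 2.0)
    return 2.0 * max(ze - cle, 0.0) / (p.len_thick - p.len_hbare)


def sovf_thin(sl: float, p: RiceParams) -> float:
    """Single-overlap fraction of the thin filament at sarcomere length sl."""
    ze = min(p.len_thick / 2.0, sl / 2.0)
    cle = max(sl / 2.0 - (sl - p.len_thin), p.len_hbare / 2.0)
    return max(ze - cle, 0.0) / p.len_thin


@dataclass(frozen=True)
class LoadCondition:
    """Mechanical boundary condition of the twitch.

    ``isometric`` fixes the sarcomere length ("infinite load");
    ``isotonic`` requires a positive afterload in kPa.
    """

    kind: str = "isometric"
    afterload_kpa: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("isometric", "isotonic"):
            raise ValueError(f"unknown load kind {self.kind!r}")
        if self.kind == "isotonic":
            if self.afterload_kpa is None or self.afterload_kpa <= 0:
                raise ValueError("isotonic load requires afterload_kpa > 0")
        elif self.afterload_kpa is not None:
            raise ValueError("isometric load takes no afterload")

    @classmethod
    def isometric(cls) -> "LoadCondition":
        return cls("isometric")

    @classmethod
    def isotonic(cls, afterload_kpa: float) -> "LoadCondition":
        return cls("isotonic", afterload_kpa)


@njit(cache=True)
def _rhs_myo(t, y, ca_grid, sl_grid, ca_dt, period,
             kon, koffl, koffh, perm50, nperm, knp0, kpn0,
             fapp, gapp0, gslmod, hf0, hfmdc, hb, gxb0,
             sigmap, sigman, x0, xpsi,
             len_thin, len_thick, len_hbare,
             prer_ss, postr_ss,
             mode, f_aft, track_gain, sl_rest, sl_min):
    n_ = y[0]
    xbprer = y[1]
    xbpostr = y[2]
    x1 = y[3]
    x2 = y[4]
    trpl = y[5]
    trph = y[6]
    sl = y[7]

    # prescribed periodic Ca2+ (uM), linear interpolation on a uniform grid
    tm = t % period
    fi = tm / ca_dt
    i0 = int(fi)
    frac = fi - i0
    i1 = i0 + 1
    if i1 >= ca_grid.shape[0]:
        i1 = 0
    ca = ca_grid[i0] * (1.0 - frac) + ca_grid[i1] * frac

    # filament overlap
    ze = min(len_thick / 2.0, sl / 2.0)
    cle = max(sl / 2.0 - (sl - len_thin), len_hbare / 2.0)
    len_sovr = max(ze - cle, 0.0)
    sovft = 2.0 * len_sovr / (len_thick - len_hbare)
    sovfn = len_sovr / len_thin

    # troponin binding
    dtrpl = kon * ca * (1.0 - trpl) - koffl * trpl
    dtrph = kon * ca * (1.0 - trph) - koffh * trph

    # cooperative permissiveness
    tropreg = (1.0 - sovfn) * trpl + sovfn * trph
    if tropreg < 1e-12:
        tropreg = 1e-12
    permtot = math.sqrt(1.0 / (1.0 + (perm50 / tropreg) ** nperm))
    inprmt = 1.0 / permtot
    if inprmt > 100.0:
        inprmt = 100.0
    knp = knp0 * permtot
    kpn = kpn0 * inprmt

    # strain-dependent cycling rates
    # exponents are capped at +-8: the published strain dependences
    # overflow for the large transient distortions a fast length change
    # can produce, and the rates saturate physically anyway
    sgn = 1.0 if x1 >= 0.0 else -1.0
    e1 = -sgn * hfmdc * (x1 / x0) ** 2
    hfmd = math.exp(min(max(e1, -8.0), 8.0))
    if x2 < x0:
        e2 = sigmap * ((x0 - x2) / x0) ** 2
    else:
        e2 = sigman * ((x2 - x0) / x0) ** 2
    gxbmd = math.exp(min(e2, 8.0))
    hf_ = hf0 * hfmd
    gxb = gxb0 * gxbmd
    gapp = gapp0 * (1.0 + (1.0 - sovft) * gslmod)

    p_ = 1.0 - n_ - xbprer - xbpostr
    dn = -knp * n_ + kpn * p_
    dprer = fapp * p_ - gapp * xbprer - hf_ * xbprer + hb * xbpostr
    dpostr = hf_ * xbprer - hb * xbpostr - gxb * xbpostr

    # normalized active force and the length boundary condition
    fnorm = sovft * (xbpostr * x2 + xbprer * x1) / (x0 * postr_ss)
    if mode == 1.0:
        # afterloaded isotonic: while borne tension is at the afterload,
        # the length obeys the index-1 constraint dF/dt = -beta*(F - F_aft)
        # solved for dSL/dt (velocity then set by cross-bridge kinetics),
        # clamped at the rest length above and the geometric floor below
        excess = fnorm - f_aft
        dsl = 0.0
        latched = sl < sl_rest - 1e-4
        if latched or excess > 0.0:
            g1 = (xpsi / prer_ss) * (-fapp * x1 + hb * (x2 - x0 - x1))
            g2 = (xpsi / postr_ss) * (hf_ * (x1 + x0 - x2))
            fpre = sovft / (x0 * postr_ss)
            # d(sovft)/dSL on the piecewise-linear overlap function
            dze = 0.5 if sl < len_thick else 0.0
            dcle = -0.5 if (len_thin - sl / 2.0) > len_hbare / 2.0 else 0.0
            dsovft = 2.0 * (dze - dcle) / (len_thick - len_hbare)
            f_sl = dsovft * (xbpostr * x2 + xbprer * x1) / (x0 * postr_ss)
            denom = f_sl + 0.5 * fpre * (xbprer + xbpostr)
            couple = (fpre * xbprer * g1 + fpre * xbpostr * g2
                      + fpre * x1 * dprer + fpre * x2 * dpostr)
            if denom > 1e-8:
                dsl = (-couple - track_gain * excess) / denom
            else:
                dsl = -1e3 * excess
            # physical velocity cap: bounds the quasi-static snap-back
            # when activation collapses under the still-attached load
            # velocity bound ~ the model's maximal (unloaded-type)
            # shortening velocity; while it binds, borne tension may
            # transiently exceed the afterload (massless-load limit)
            if dsl > 0.02:
                dsl = 0.02
            elif dsl < -0.02:
                dsl = -0.02
            if latched:
                # taper relengthening to zero exactly at the latch
                # boundary, so the RHS is continuous where the state
                # parks between beats
                if dsl > 0.0:
                    w = (sl_rest - 1e-4 - sl) / 2e-4
                    if w < 0.0:
                        w = 0.0
                    if w > 1.0:
                        w = 1.0
                    dsl *= w
            else:
                # at/near rest: shortening only, switched on smoothly in
                # the force excess so the clamp boundary is chatter-free
                if dsl < 0.0:
                    s_on = excess / 1e-3
                    if s_on > 1.0:
                        s_on = 1.0
                    dsl *= s_on
                else:
                    dsl = 0.0
            if dsl < 0.0:
                # taper shortening into the geometric floor
                w = (sl - sl_min) / 2e-4
                if w < 0.0:
                    w = 0.0
                if w > 1.0:
                    w = 1.0
                dsl *= w
    elif mode == 2.0:
        # prescribed periodic length waveform (volume-coupled fiber strain)
        tgt = sl_grid[i0] * (1.0 - frac) + sl_grid[i1] * frac
        i2 = i1 + 1
        if i2 >= sl_grid.shape[0]:
            i2 = 0
        dtgt = (sl_grid[i2] - sl_grid[i0]) / (2.0 * ca_dt) if i0 > 0 \
            else (sl_grid[i1] - sl_grid[i0]) / ca_dt
        dsl = dtgt + 1.0 * (tgt - sl)
    else:
        dsl = 0.0

    # mean-strain dynamics (steady-state duty fractions in the denominators)
    dx1 = 0.5 * dsl + (xpsi / prer_ss) * (-fapp * x1 + hb * (x2 - x0 - x1))
    dx2 = 0.5 * dsl + (xpsi / postr_ss) * (hf_ * (x1 + x0 - x2))

    dy = np.empty(8)
    dy[0] = dn
    dy[1] = dprer
    dy[2] = dpostr
    dy[3] = dx1
    dy[4] = dx2
    dy[5] = dtrpl
    dy[6] = dtrph
    dy[7] = dsl
    return dy


def _rhs_args(p: RiceParams, ca_grid: np.ndarray, ca_dt: float,
              period: float, load: LoadCondition,
              sl_grid: np.ndarray | None = None) -> tuple:
    r = p.rates_ms()
    prer_ss, postr_ss = p.duty_fractions()
    if sl_grid is not None:
        isotonic = 2.0
    elif load.kind == "isotonic":
        isotonic = 1.0
    else:
        isotonic = 0.0
    f_aft = 0.0
    if load.kind == "isotonic":
        f_aft = load.afterload_kpa / p.tension_scale_kpa
    if sl_grid is None:
        sl_grid = np.full(ca_grid.shape, p.sl_rest)
    return (ca_grid, sl_grid, ca_dt, period,
            r["kon"], r["koff_l"], r["koff_h"], p.perm50, p.nperm,
            r["kn_p"], r["kp_n"],
            r["fapp"], r["gapp"], p.gslmod, r["hf"], p.hfmdc,
            r["hb"], r["gxb"], p.sigmap, p.sigman, p.x0, p.xpsi,
            p.len_thin, p.len_thick, p.len_hbare,
            prer_ss, postr_ss,
            isotonic, f_aft, p.track_gain * 1e-3, p.sl_rest, p.sl_min)


def initial_state(p: RiceParams, ca_diastolic_uM: float = 0.1) -> np.ndarray:
    """Diastolic myofilament state at the rest length."""
    kdl = p.koff_l / p.kon
    kdh = p.koff_h / p.kon
    return np.array([
        0.999, 1e-6, 1e-6, 0.0, p.x0,
        ca_diastolic_uM / (ca_diastolic_uM + kdl),
        ca_diastolic_uM / (ca_diastolic_uM + kdh),
        p.sl_rest,
    ])


def myo_derivatives(y: np.ndarray, ca_uM: float, load: LoadCondition,
                    params: RiceParams | None = None) -> np.ndarray:
    """Time derivative (1/ms) of the myofilament state at a fixed Ca2+."""
    p = params or RiceParams()
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(y)) and np.isfinite(ca_uM)):
        raise FloatingPointError("non-finite myofilament input")
    ca_grid = np.array([ca_uM, ca_uM])
    return _rhs_myo(0.0, y, *_rhs_args(p, ca_grid, 1.0, 1.0, load))


def active_force(y: np.ndarray, params: RiceParams | None = None) -> float:
    """Normalized active force at a state (1 = maximal steady isometric
    force at full activation and full single overlap)."""
    p = params or RiceParams()
    _, postr_ss = p.duty_fractions()
    sovft = sovf_thick(float(y[7]), p)
    return sovft * (y[2] * y[4] + y[1] * y[3]) / (p.x0 * postr_ss)


def atp_rate(y: np.ndarray, params: RiceParams | None = None) -> float:
    """Contractile ATP consumption rate (1/s, normalized): the product of
    the post-power-stroke detachment flux and the thick-filament
    single-overlap fraction."""
    p = params or RiceParams()
    r = p.rates_ms()
    x2 = float(y[4])
    if x2 < p.x0:
        e2 = p.sigmap * ((p.x0 - x2) / p.x0) ** 2
    else:
        e2 = p.sigman * ((x2 - p.x0) / p.x0) ** 2
    gxb_ms = r["gxb"] * math.exp(min(e2, 8.0))
    return 1e3 * gxb_ms * float(y[2]) * sovf_thick(float(y[7]), p)


def approximate_ca_transient(period_ms: float = 600.0,
                             diastolic_uM: float = 0.09,
                             amplitude_uM: float = 1.45,
                             tau1_ms: float = 20.0,
                             tau2_ms: float = 110.0,
                             eat_ms: float = 1.0,
                             sample_ms: float = 1.0) -> CaTransient:
    """The myofilament model's published biexponential approximate Ca2+
    transient (peak-normalized difference of two exponentials).

    With the published time constants (20 and 110 ms) the waveform peaks at
    ln(tau2/tau1) * tau1*tau2/(tau2-tau1) ~ 41.6 ms after onset.  Useful as
    a self-contained driver when no ionic-model trace is wanted.
    """
    t = np.arange(0.0, period_ms, sample_ms)
    shape = np.exp(-t / tau2_ms) - np.exp(-t / tau1_ms)
    shape /= shape.max()
    cai = (diastolic_uM + (amplitude_uM - diastolic_uM) * shape) * 1e-3
    return CaTransient(t_ms=t, cai_mM=cai, period_ms=period_ms, eat_ms=eat_ms)


@dataclass
class TwitchRecord:
    """Last-cycle time series of one twitch plus derived metrics.

    Times are relative to the cycle's stimulus; lengths are reported both
    as sarcomere length (um) and as equivalent cell length (% of rest).
    """

    t_ms: np.ndarray
    cai_uM: np.ndarray
    tension_kpa: np.ndarray
    sl_um: np.ndarray
    atp_rate_s: np.ndarray
    load: LoadCondition
    severity: str | None
    n_cycles: int
    eat_ms: float
    params: RiceParams
    prev_peak_tension_kpa: float | None = None
    no_isotonic_shortening: bool = False

    @property
    def length_pct(self) -> np.ndarray:
        return 100.0 * self.sl_um / self.params.sl_rest

    @property
    def peak_tension_kpa(self) -> float:
        return float(np.max(self.tension_kpa))

    @property
    def ttp_ca_ms(self) -> float:
        return float(self.t_ms[int(np.argmax(self.cai_uM))])

    @property
    def ttp_tension_ms(self) -> float:
        return float(self.t_ms[int(np.argmax(self.tension_kpa))])

    @property
    def ttp_shortening_ms(self) -> float:
        """Time of peak shortening (minimum length); NaN without shortening."""
        if self.no_isotonic_shortening or self.load.kind == "isometric":
            return math.nan
        return float(self.t_ms[int(np.argmin(self.sl_um))])

    @property
    def ttp_atp_ms(self) -> float:
        return float(self.t_ms[int(np.argmax(self.atp_rate_s))])

    @property
    def shortening_amplitude_pct(self) -> float:
        """Peak shortening as % of the rest length."""
        return 100.0 * (self.params.sl_rest - float(np.min(self.sl_um))) \
            / self.params.sl_rest

    @property
    def shortening(self) -> np.ndarray:
        """Shortening trace rest_length - L(t) (um)."""
        return self.params.sl_rest - self.sl_um

    @property
    def atp_per_beat(self) -> float:
        """Cycle integral of the ATP rate (dimensionless turnovers)."""
        return float(np.trapezoid(self.atp_rate_s, self.t_ms) / 1e3)

    @property
    def steady_state(self) -> bool:
        if self.prev_peak_tension_kpa is None:
            return False
        return abs(self.peak_tension_kpa - self.prev_peak_tension_kpa) \
            < 0.01 * self.peak_tension_kpa

    def metrics(self) -> dict[str, float]:
        return {
            "peak_tension_kpa": self.peak_tension_kpa,
            "ttp_ca_ms": self.ttp_ca_ms,
            "ttp_tension_ms": self.ttp_tension_ms,
            "ttp_shortening_ms": self.ttp_shortening_ms,
            "ttp_atp_ms": self.ttp_atp_ms,
            "shortening_amplitude_pct": self.shortening_amplitude_pct,
            "atp_per_beat": self.atp_per_beat,
        }


def run_twitch(ca: CaTransient, load: LoadCondition,
               n_cycles: int = 20,
               params: RiceParams | None = None,
               sample_ms: float = 1.0,
               sl_waveform_um: np.ndarray | None = None) -> TwitchRecord:
    """Drive the myofilament model with a periodic Ca2+ transient for
    ``n_cycles`` cycles and return the last (steady-state) cycle.

    The Ca2+ transient is in mM (ionic-model convention) and is converted
    to uM internally.  Metrics are computed on the final cycle, times
    relative to that cycle's stimulus.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    p = params or RiceParams()
    period = ca.period_ms
    # resample the transient onto a uniform grid for the compiled kernel
    ngrid = int(round(period / sample_ms))
    tg = np.arange(ngrid) * sample_ms
    ca_grid = np.interp(tg, ca.t_ms, ca.cai_mM) * 1e3  # -> uM
    sl_grid = None
    if sl_waveform_um is not None:
        sl_grid = np.asarray(sl_waveform_um, dtype=float)
        if len(sl_grid) != ngrid:
            sl_grid = np.interp(tg, np.linspace(0.0, period, len(sl_grid)),
                                sl_grid)
    args = _rhs_args(p, ca_grid, sample_ms, period, load, sl_grid)

    y0 = initial_state(p, ca_diastolic_uM=float(ca_grid[0]))
    if sl_grid is not None:
        y0[7] = float(sl_grid[0])
    t_end = n_cycles * period
    t_prev = (n_cycles - 1) * period
    # sample the final two cycles densely; one point per earlier cycle
    t_dense = max(t_prev - period, 0.0)
    t_eval = np.concatenate([
        np.arange(0.0, t_dense, period),
        np.arange(t_dense, t_end, sample_ms), [t_end],
    ])
    t_eval = np.unique(t_eval)
    sol = solve_ivp(_rhs_myo, (0.0, t_end), y0, method="LSODA", args=args,
                    t_eval=t_eval, rtol=1e-7,
                    atol=np.array([1e-8, 1e-10, 1e-10, 1e-12, 1e-12,
                                   1e-9, 1e-9, 1e-8]))
    if not sol.success:
        raise RuntimeError(f"myofilament integration failed: {sol.message}")

    mask = sol.t >= t_prev - 1e-9
    t_last = sol.t[mask][:ngrid] - t_prev
    y_last = sol.y[:, mask][:, :ngrid]

    _, postr_ss = p.duty_fractions()

    def _tension(ys: np.ndarray) -> np.ndarray:
        sovft = np.array([sovf_thick(s, p) for s in ys[7]])
        fn = sovft * (ys[2] * ys[4] + ys[1] * ys[3]) / (p.x0 * postr_ss)
        return p.tension_scale_kpa * np.maximum(fn, 0.0), sovft

    tension, sovft = _tension(y_last)

    r = p.rates_ms()
    x2 = y_last[4]
    gxbmd = np.exp(np.minimum(
        np.where(x2 < p.x0,
                 p.sigmap * ((p.x0 - x2) / p.x0) ** 2,
                 p.sigman * ((x2 - p.x0) / p.x0) ** 2), 8.0))
    atp = 1e3 * r["gxb"] * gxbmd * y_last[2] * sovft

    # previous-cycle peak tension for the steady-state flag
    prev_peak = None
    if n_cycles >= 2:
        maskp = (sol.t >= t_dense - 1e-9) & (sol.t < t_prev)
        prev_t, _ = _tension(sol.y[:, maskp])
        prev_peak = float(np.max(prev_t))
    no_short = False
    if load.kind == "isotonic":
        no_short = float(np.min(y_last[7])) > p.sl_rest - 1e-4

    cai_last = np.interp(t_last, tg, ca_grid)
    rec = TwitchRecord(
        t_ms=t_last, cai_uM=cai_last, tension_kpa=tension,
        sl_um=y_last[7].copy(), atp_rate_s=atp, load=load,
        severity=ca.severity, n_cycles=n_cycles, eat_ms=ca.eat_ms,
        params=p, prev_peak_tension_kpa=prev_peak,
        no_isotonic_shortening=no_short,
    )
    return rec
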