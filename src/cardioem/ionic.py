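"""Human ventricular myocyte ionic models and pacing protocols.

The transmembrane potential and intracellular Ca2+ transient are produced by
one of two published human ventricular ionic ODE formulations (the 2004 and
the revised 2006 ten Tusscher family models), selectable via the ``variant``
string.  Both describe the sarcolemmal currents (I_Na, I_CaL, I_Kr, I_Ks,
I_K1, I_to, I_NaCa, I_NaK, I_pCa, I_pK, background Na/Ca currents) together
with sarcoplasmic-reticulum Ca2+ cycling (release, leak, uptake).  The Ca2+
transient of the paced steady-state beat is the one-way coupling signal fed
to the myofilament model.

Units follow the source models: mV, ms, mM, and current densities in pA/pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "PacingProtocol",
    "PacedTrace",
    "CaTransient",
    "IonicState",
    "VARIANTS",
    "init_resting_state",
    "derivatives",
    "ionic_currents",
    "run_paced",
    "extract_ca_transient",
    "find_diastolic_threshold",
]

# physical constants shared by both model generations
_R = 8314.472      # J/(kmol K)
_F = 96485.3415    # C/mol
_T = 310.0         # K
_CAPACITANCE = 0.185

_KO, _CAO, _NAO = 5.4, 2.0, 140.0


@dataclass(frozen=True)
class PacingProtocol:
    """Rectangular-pulse pacing at a fixed basic cycle length.

    ``stim_amplitude`` is a current density in pA/pF; depolarizing stimuli
    are negative (they enter dVm/dt with a minus sign).  ``None`` requests
    twice the diastolic threshold, found once by bisection per variant.
    """

    bcl_ms: float = 600.0
    n_beats: int = 20
    stim_amplitude: float | None = -52.0
    stim_duration_ms: float = 1.0
    sample_ms: float = 1.0

    def __post_init__(self) -> None:
        if not self.bcl_ms > self.stim_duration_ms > 0:
            raise ValueError("require bcl > stim_duration > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.stim_amplitude is not None and self.stim_amplitude > 0:
            raise ValueError("depolarizing stimulus must be <= 0 (pA/pF)")


@dataclass
class IonicState:
    """Joined snapshot of the ionic state vector, with named access."""

    variant: str
    y: np.ndarray

    @property
    def vm(self) -> float:
        return float(self.y[0])

    def __getitem__(self, name: str) -> float:
        return float(self.y[VARIANTS[self.variant]["names"].index(name)])

    def gates(self) -> np.ndarray:
        idx = VARIANTS[self.variant]["gate_idx"]
        return self.y[idx]

    def concentrations(self) -> np.ndarray:
        idx = VARIANTS[self.variant]["conc_idx"]
        return self.y[idx]


@dataclass
class PacedTrace:
    """Uniformly sampled (Vm, Cai) trace from a paced run."""

    t_ms: np.ndarray
    vm_mV: np.ndarray
    cai_mM: np.ndarray
    protocol: PacingProtocol
    variant: str
    stim_amplitude: float
    beat_peak_cai: np.ndarray = field(default_factory=lambda: np.empty(0))
    final_state: np.ndarray | None = None

    @property
    def steady_state(self) -> bool:
        """Beat-to-beat peak-Cai change of the last two beats below 1%."""
        if len(self.beat_peak_cai) < 2:
            return False
        a, b = self.beat_peak_cai[-2:]
        return abs(b - a) / abs(b) < 0.01


@dataclass
class CaTransient:
    """One-period Ca2+ waveform, t = 0 at the stimulus of its beat."""

    t_ms: np.ndarray
    cai_mM: np.ndarray
    period_ms: float
    eat_ms: float
    severity: str | None = None

    @property
    def diastolic_mM(self) -> float:
        return float(self.cai_mM[0])

    @property
    def peak_mM(self) -> float:
        return float(np.max(self.cai_mM))

    @property
    def time_to_peak_ms(self) -> float:
        return float(self.t_ms[int(np.argmax(self.cai_mM))])

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Periodic linear interpolation of the waveform."""
        return np.interp(np.mod(t, self.period_ms), self.t_ms, self.cai_mM)


# ---------------------------------------------------------------------------
# 2006 formulation (19 states).  State layout:
# 0 V, 1 m, 2 h, 3 j, 4 d, 5 f, 6 f2, 7 fCass, 8 r, 9 s, 10 xr1, 11 xr2,
# 12 xs, 13 Rq (RyR adaptation), 14 Cai, 15 Cass, 16 Casr, 17 Nai, 18 Ki
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_tt06(t, y, stim, gto, gks, endo):
    V = y[0]
    m, h, j = y[1], y[2], y[3]
    d, f, f2, fcass = y[4], y[5], y[6], y[7]
    r, s = y[8], y[9]
    xr1, xr2, xs = y[10], y[11], y[12]
    rq = y[13]
    cai, cass, casr = y[14], y[15], y[16]
    nai, ki = y[17], y[18]

    rtf = _R * _T / _F
    ek = rtf * math.log(_KO / ki)
    ena = rtf * math.log(_NAO / nai)
    eks = rtf * math.log((_KO + 0.03 * _NAO) / (ki + 0.03 * nai))
    eca = 0.5 * rtf * math.log(_CAO / cai)

    ina = 14.838 * m ** 3 * h * j * (V - ena)
    ibna = 0.00029 * (V - ena)

    z = 2.0 * (V - 15.0) * _F / (_R * _T)
    if abs(z) < 1e-7:
        zfac = 1.0
    else:
        zfac = z / (math.exp(z) - 1.0)
    ical = (3.98e-5 * d * f * f2 * fcass * 2.0 * _F * zfac
            * (0.25 * cass * math.exp(z) - _CAO))

    ibca = 0.000592 * (V - eca)
    ito = gto * r * s * (V - ek)
    ikr = 0.153 * math.sqrt(_KO / 5.4) * xr1 * xr2 * (V - ek)
    iks = gks * xs * xs * (V - eks)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - ek - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (V - ek + 100.0))
            + math.exp(0.1 * (V - ek - 10.0)))
           / (1.0 + math.exp(-0.5 * (V - ek))))
    ik1 = 5.405 * math.sqrt(_KO / 5.4) * ak1 / (ak1 + bk1) * (V - ek)

    vf_rt = V * _F / (_R * _T)
    inaca = (1000.0 * (math.exp(0.35 * vf_rt) * nai ** 3 * _CAO
                       - math.exp(-0.65 * vf_rt) * _NAO ** 3 * cai * 2.5)
             / ((87.5 ** 3 + _NAO ** 3) * (1.38 + _CAO)
                * (1.0 + 0.1 * math.exp(-0.65 * vf_rt))))
    inak = (2.724 * _KO * nai
            / ((_KO + 1.0) * (nai + 40.0)
               * (1.0 + 0.1245 * math.exp(-0.1 * vf_rt)
                  + 0.0353 * math.exp(-vf_rt))))
    ipca = 0.1238 * cai / (0.0005 + cai)
    ipk = 0.0146 * (V - ek) / (1.0 + math.exp((25.0 - V) / 5.98))

    itot = (ikr + iks + ik1 + ito + ina + ibna + ical + ibca
            + inak + inaca + ipca + ipk + stim)

    # gate kinetics
    minf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = (0.1 / (1.0 + math.exp((V + 35.0) / 5.0))
          + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0)))
    taum = am * bm

    hinf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tauh = 1.0 / (ah + bh)

    jinf = hinf
    if V >= -40.0:
        aj = 0.0
        bj = (0.6 * math.exp(0.057 * V)
              / (1.0 + math.exp(-0.1 * (V + 32.0))))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V)
               - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = (0.02424 * math.exp(-0.01052 * V)
              / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    tauj = 1.0 / (aj + bj)

    dinf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    taud = ad * bd + gd

    finf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tauf = (1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
            + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
            + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0)

    f2inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tauf2 = (562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
             + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
             + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0)))

    fcassinf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    rinf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    taur = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    if endo > 0.5:
        sinf = 1.0 / (1.0 + math.exp((V + 28.0) / 5.0))
        taus = 1000.0 * math.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        sinf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        taus = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
                + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    xr1inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tauxr1 = axr1 * bxr1

    xr2inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tauxr2 = axr2 * bxr2

    xsinf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tauxs = axs * bxs + 80.0

    # SR calcium cycling
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    drq = -k2 * cass * rq + 0.005 * (1.0 - rq)
    o_rel = k1 * cass * cass * rq / (0.06 + k1 * cass * cass)
    irel = 0.102 * o_rel * (casr - cass)
    ileak = 0.00036 * (casr - cai)
    iup = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
    ixfer = 0.0038 * (cass - cai)

    vc, vsr, vss = 0.016404, 0.001094, 5.468e-5
    bufc = 1.0 / (1.0 + 0.2 * 0.001 / (cai + 0.001) ** 2)
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / (casr + 0.3) ** 2)
    bufss = 1.0 / (1.0 + 0.4 * 0.00025 / (cass + 0.00025) ** 2)

    dcai = bufc * ((ileak - iup) * vsr / vc + ixfer
                   - (ibca + ipca - 2.0 * inaca)
                   * _CAPACITANCE / (2.0 * vc * _F))
    dcasr = bufsr * (iup - irel - ileak)
    dcass = bufss * (-ical * _CAPACITANCE / (2.0 * vss * _F)
                     + irel * vsr / vss - ixfer * vc / vss)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * _CAPACITANCE / (vc * _F)
    dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk + stim) \
        * _CAPACITANCE / (vc * _F)

    dy = np.empty(19)
    dy[0] = -itot
    dy[1] = (minf - m) / taum
    dy[2] = (hinf - h) / tauh
    dy[3] = (jinf - j) / tauj
    dy[4] = (dinf - d) / taud
    dy[5] = (finf - f) / tauf
    dy[6] = (f2inf - f2) / tauf2
    dy[7] = (fcassinf - fcass) / taufcass
    dy[8] = (rinf - r) / taur
    dy[9] = (sinf - s) / taus
    dy[10] = (xr1inf - xr1) / tauxr1
    dy[11] = (xr2inf - xr2) / tauxr2
    dy[12] = (xsinf - xs) / tauxs
    dy[13] = drq
    dy[14] = dcai
    dy[15] = dcass
    dy[16] = dcasr
    dy[17] = dnai
    dy[18] = dki
    return dy


# ---------------------------------------------------------------------------
# 2004 formulation (17 states).  State layout:
# 0 V, 1 m, 2 h, 3 j, 4 d, 5 f, 6 fCa, 7 r, 8 s, 9 xr1, 10 xr2, 11 xs,
# 12 g (SR release inactivation), 13 Cai, 14 Casr, 15 Nai, 16 Ki
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_tt04(t, y, stim, gto, gks, endo):
    V = y[0]
    m, h, j = y[1], y[2], y[3]
    d, f, fca = y[4], y[5], y[6]
    r, s = y[7], y[8]
    xr1, xr2, xs = y[9], y[10], y[11]
    g = y[12]
    cai, casr = y[13], y[14]
    nai, ki = y[15], y[16]

    rtf = _R * _T / _F
    ek = rtf * math.log(_KO / ki)
    ena = rtf * math.log(_NAO / nai)
    eks = rtf * math.log((_KO + 0.03 * _NAO) / (ki + 0.03 * nai))
    eca = 0.5 * rtf * math.log(_CAO / cai)

    ina = 14.838 * m ** 3 * h * j * (V - ena)
    ibna = 0.00029 * (V - ena)

    z = 2.0 * V * _F / (_R * _T)
    if abs(z) < 1e-7:
        zfac = 1.0
    else:
        zfac = z / (math.exp(z) - 1.0)
    ical = (0.000175 * d * f * fca * 2.0 * _F * zfac
            * (cai * math.exp(z) - 0.341 * _CAO))

    ibca = 0.000592 * (V - eca)
    ito = gto * r * s * (V - ek)
    ikr = 0.096 * math.sqrt(_KO / 5.4) * xr1 * xr2 * (V - ek)
    iks = gks * xs * xs * (V - eks)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - ek - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (V - ek + 100.0))
            + math.exp(0.1 * (V - ek - 10.0)))
           / (1.0 + math.exp(-0.5 * (V - ek))))
    ik1 = 5.405 * math.sqrt(_KO / 5.4) * ak1 / (ak1 + bk1) * (V - ek)

    vf_rt = V * _F / (_R * _T)
    inaca = (1000.0 * (math.exp(0.35 * vf_rt) * nai ** 3 * _CAO
                       - math.exp(-0.65 * vf_rt) * _NAO ** 3 * cai * 2.5)
             / ((87.5 ** 3 + _NAO ** 3) * (1.38 + _CAO)
                * (1.0 + 0.1 * math.exp(-0.65 * vf_rt))))
    inak = (1.362 * _KO * nai
            / ((_KO + 1.0) * (nai + 40.0)
               * (1.0 + 0.1245 * math.exp(-0.1 * vf_rt)
                  + 0.0353 * math.exp(-vf_rt))))
    ipca = 0.825 * cai / (0.0005 + cai)
    ipk = 0.0146 * (V - ek) / (1.0 + math.exp((25.0 - V) / 5.98))

    itot = (ikr + iks + ik1 + ito + ina + ibna + ical + ibca
            + inak + inaca + ipca + ipk + stim)

    minf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = (0.1 / (1.0 + math.exp((V + 35.0) / 5.0))
          + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0)))
    taum = am * bm

    hinf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tauh = 1.0 / (ah + bh)

    jinf = hinf
    if V >= -40.0:
        aj = 0.0
        bj = (0.6 * math.exp(0.057 * V)
              / (1.0 + math.exp(-0.1 * (V + 32.0))))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V)
               - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = (0.02424 * math.exp(-0.01052 * V)
              / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    tauj = 1.0 / (aj + bj)

    dinf = 1.0 / (1.0 + math.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    taud = ad * bd + gd

    finf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tauf = (1125.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
            + 80.0 + 165.0 / (1.0 + math.exp((25.0 - V) / 10.0)))

    # Ca-dependent inactivation gate; it may only close while depolarized
    afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + math.exp((cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    fcainf = (afca + bfca + gfca + 0.23) / 1.46
    dfca = (fcainf - fca) / 2.0
    if fcainf > fca and V > -60.0:
        dfca = 0.0

    rinf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    taur = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    if endo > 0.5:
        sinf = 1.0 / (1.0 + math.exp((V + 28.0) / 5.0))
        taus = 1000.0 * math.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        sinf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        taus = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
                + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    xr1inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tauxr1 = axr1 * bxr1

    xr2inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tauxr2 = axr2 * bxr2

    xsinf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 60.0) / 20.0))
    tauxs = axs * bxs

    # SR release with inactivation gate g
    if cai < 0.00035:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    dg = (ginf - g) / 2.0
    if ginf > g and V > -60.0:
        dg = 0.0

    irel = (0.016464 * casr * casr / (0.0625 + casr * casr)
            + 0.008232) * d * g
    ileak = 0.00008 * (casr - cai)
    iup = 0.000425 / (1.0 + (0.00025 / cai) ** 2)

    vc, vsr = 0.016404, 0.001094
    bufc = 1.0 / (1.0 + 0.15 * 0.001 / (cai + 0.001) ** 2)
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / (casr + 0.3) ** 2)

    dcai = bufc * (-(ical + ibca + ipca - 2.0 * inaca)
                   * _CAPACITANCE / (2.0 * vc * _F)
                   + ileak - iup + irel)
    dcasr = bufsr * (vc / vsr) * (iup - irel - ileak)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * _CAPACITANCE / (vc * _F)
    dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk + stim) \
        * _CAPACITANCE / (vc * _F)

    dy = np.empty(17)
    dy[0] = -itot
    dy[1] = (minf - m) / taum
    dy[2] = (hinf - h) / tauh
    dy[3] = (jinf - j) / tauj
    dy[4] = (dinf - d) / taud
    dy[5] = (finf - f) / tauf
    dy[6] = dfca
    dy[7] = (rinf - r) / taur
    dy[8] = (sinf - s) / taus
    dy[9] = (xr1inf - xr1) / tauxr1
    dy[10] = (xr2inf - xr2) / tauxr2
    dy[11] = (xsinf - xs) / tauxs
    dy[12] = dg
    dy[13] = dcai
    dy[14] = dcasr
    dy[15] = dnai
    dy[16] = dki
    return dy


_NAMES06 = ("V", "m", "h", "j", "d", "f", "f2", "fCass", "r", "s",
            "Xr1", "Xr2", "Xs", "Rq", "Cai", "Cass", "Casr", "Nai", "Ki")
_NAMES04 = ("V", "m", "h", "j", "d", "f", "fCa", "r", "s",
            "Xr1", "Xr2", "Xs", "g", "Cai", "Casr", "Nai", "Ki")

# published 1-Hz steady-state initial values of the 2006 model (epicardial)
_INIT06 = np.array([
    -85.23, 0.00172, 0.7444, 0.7045, 3.373e-5, 0.7888, 0.9755, 0.9953,
    2.42e-8, 0.999998, 0.00621, 0.4712, 0.0095, 0.9073,
    0.000126, 0.00036, 3.64, 8.604, 136.89,
])

# resting state of the 2004 model: the published initial values relaxed
# for 20 s without stimulation (frozen here so rest is a fixed point)
_INIT04 = np.array([
    -86.49561984227874, 0.0013102321927729271, 0.7779263730832106,
    0.7779208855316347, 1.9094665477160906e-05, 0.9999251038751141,
    1.0073678771521166, 1.9570004592658664e-08, 0.9999983240320258,
    0.0001764652304432829, 0.4843344761460268, 0.002955536349536219,
    0.9999981617612382, 3.873739198791493e-05, 0.1493006674775108,
    11.30458647335185, 138.7315813475187,
])

VARIANTS: dict[str, dict] = {
    "tt2006-epi": {"rhs": _rhs_tt06, "gto": 0.294, "gks": 0.392, "endo": 0.0,
                   "names": _NAMES06, "init": _INIT06,
                   "gate_idx": list(range(1, 14)), "conc_idx": [14, 15, 16, 17, 18]},
    "tt2006-endo": {"rhs": _rhs_tt06, "gto": 0.073, "gks": 0.392, "endo": 1.0,
                    "names": _NAMES06, "init": _INIT06,
                    "gate_idx": list(range(1, 14)), "conc_idx": [14, 15, 16, 17, 18]},
    "tt2006-m": {"rhs": _rhs_tt06, "gto": 0.294, "gks": 0.098, "endo": 0.0,
                 "names": _NAMES06, "init": _INIT06,
                 "gate_idx": list(range(1, 14)), "conc_idx": [14, 15, 16, 17, 18]},
    # fCa (index 6) is excluded from the strict [0,1] gate list: the
    # published 2004 Ca-inactivation factor can slightly exceed unity
    "tt2004-epi": {"rhs": _rhs_tt04, "gto": 0.294, "gks": 0.245, "endo": 0.0,
                   "names": _NAMES04, "init": _INIT04,
                   "gate_idx": [1, 2, 3, 4, 5, 7, 8, 9, 10, 11, 12],
                   "conc_idx": [13, 14, 15, 16]},
}

DEFAULT_VARIANT = "tt2006-epi"


def _atol(variant: str) -> np.ndarray:
    names = VARIANTS[variant]["names"]
    atol = np.full(len(names), 1e-8)
    scale = {"V": 1e-5, "Cai": 1e-11, "Cass": 1e-11, "Casr": 1e-8,
             "Nai": 1e-7, "Ki": 1e-7}
    for i, n in enumerate(names):
        atol[i] = scale.get(n, 1e-8)
    return atol


def init_resting_state(variant: str = DEFAULT_VARIANT) -> IonicState:
    """Return the published model's resting/steady-paced initial state."""
    v = VARIANTS[variant]
    return IonicState(variant, v["init"].copy())


def derivatives(state: IonicState | np.ndarray, t: float = 0.0,
                stim: float = 0.0, variant: str = DEFAULT_VARIANT) -> np.ndarray:
    """Time derivative of the full ionic state vector.

    ``stim`` is the stimulus current density in pA/pF (negative =
    depolarizing); it enters dVm/dt as -(sum of currents + stim).
    """
    if isinstance(state, IonicState):
        variant, y = state.variant, state.y
    else:
        y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite ionic state (solver blow-up?)")
    v = VARIANTS[variant]
    return v["rhs"](t, y, stim, v["gto"], v["gks"], v["endo"])


def ionic_currents(state: IonicState | np.ndarray,
                   variant: str = DEFAULT_VARIANT) -> dict[str, float]:
    """All 15 membrane/SR current terms at a state, computed independently
    of the compiled right-hand side (plain-Python path).

    Membrane currents are in pA/pF; SR fluxes (I_rel, I_leak, I_up) in mM/ms.
    The sum of the 12 membrane terms equals -dVm/dt when no stimulus flows.
    """
    if isinstance(state, IonicState):
        variant, y = state.variant, state.y
    else:
        y = np.asarray(state, dtype=float)
    v = VARIANTS[variant]
    names = v["names"]
    s = {n: float(y[i]) for i, n in enumerate(names)}
    V, cai, nai, ki = s["V"], s["Cai"], s["Nai"], s["Ki"]
    rtf = _R * _T / _F
    ek = rtf * math.log(_KO / ki)
    ena = rtf * math.log(_NAO / nai)
    eks = rtf * math.log((_KO + 0.03 * _NAO) / (ki + 0.03 * nai))
    eca = 0.5 * rtf * math.log(_CAO / cai)
    vf_rt = V * _F / (_R * _T)

    out: dict[str, float] = {}
    out["I_Na"] = 14.838 * s["m"] ** 3 * s["h"] * s["j"] * (V - ena)
    out["I_Na_b"] = 0.00029 * (V - ena)
    out["I_Ca_b"] = 0.000592 * (V - eca)
    out["I_to"] = v["gto"] * s["r"] * s["s"] * (V - ek)
    out["I_Ks"] = v["gks"] * s["Xs"] ** 2 * (V - eks)
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - ek - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (V - ek + 100.0))
            + math.exp(0.1 * (V - ek - 10.0)))
           / (1.0 + math.exp(-0.5 * (V - ek))))
    out["I_K1"] = 5.405 * math.sqrt(_KO / 5.4) * ak1 / (ak1 + bk1) * (V - ek)
    out["I_NaCa"] = (1000.0 * (math.exp(0.35 * vf_rt) * nai ** 3 * _CAO
                               - math.exp(-0.65 * vf_rt) * _NAO ** 3 * cai * 2.5)
                     / ((87.5 ** 3 + _NAO ** 3) * (1.38 + _CAO)
                        * (1.0 + 0.1 * math.exp(-0.65 * vf_rt))))
    out["I_pCa"] = (0.1238 if names is _NAMES06 else 0.825) \
        * cai / (0.0005 + cai)
    out["I_pK"] = 0.0146 * (V - ek) / (1.0 + math.exp((25.0 - V) / 5.98))

    if names is _NAMES06:
        casr, cass = s["Casr"], s["Cass"]
        z = 2.0 * (V - 15.0) * _F / (_R * _T)
        zfac = 1.0 if abs(z) < 1e-7 else z / (math.exp(z) - 1.0)
        out["I_Ca_L"] = (3.98e-5 * s["d"] * s["f"] * s["f2"] * s["fCass"]
                         * 2.0 * _F * zfac
                         * (0.25 * cass * math.exp(z) - _CAO))
        out["I_Kr"] = 0.153 * math.sqrt(_KO / 5.4) * s["Xr1"] * s["Xr2"] * (V - ek)
        out["I_NaK"] = (2.724 * _KO * nai
                        / ((_KO + 1.0) * (nai + 40.0)
                           * (1.0 + 0.1245 * math.exp(-0.1 * vf_rt)
                              + 0.0353 * math.exp(-vf_rt))))
        kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
        k1 = 0.15 / kcasr
        o_rel = k1 * cass ** 2 * s["Rq"] / (0.06 + k1 * cass ** 2)
        out["I_rel"] = 0.102 * o_rel * (casr - cass)
        out["I_leak"] = 0.00036 * (casr - cai)
        out["I_up"] = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
    else:
        casr = s["Casr"]
        z = 2.0 * V * _F / (_R * _T)
        zfac = 1.0 if abs(z) < 1e-7 else z / (math.exp(z) - 1.0)
        out["I_Ca_L"] = (0.000175 * s["d"] * s["f"] * s["fCa"]
                         * 2.0 * _F * zfac
                         * (cai * math.exp(z) - 0.341 * _CAO))
        out["I_Kr"] = 0.096 * math.sqrt(_KO / 5.4) * s["Xr1"] * s["Xr2"] * (V - ek)
        out["I_NaK"] = (1.362 * _KO * nai
                        / ((_KO + 1.0) * (nai + 40.0)
                           * (1.0 + 0.1245 * math.exp(-0.1 * vf_rt)
                              + 0.0353 * math.exp(-vf_rt))))
        out["I_rel"] = (0.016464 * casr ** 2 / (0.0625 + casr ** 2)
                        + 0.008232) * s["d"] * s["g"]
        out["I_leak"] = 0.00008 * (casr - cai)
        out["I_up"] = 0.000425 / (1.0 + (0.00025 / cai) ** 2)
    return out


MEMBRANE_CURRENTS = ("I_Na", "I_Na_b", "I_Ca_L", "I_Ca_b", "I_Kr", "I_Ks",
                     "I_K1", "I_NaCa", "I_pCa", "I_NaK", "I_to", "I_pK")


def _integrate(variant: str, y0: np.ndarray, t0: float, t1: float,
               stim: float, t_eval=None, max_step=np.inf):
    v = VARIANTS[variant]
    sol = solve_ivp(v["rhs"], (t0, t1), y0, method="LSODA",
                    args=(stim, v["gto"], v["gks"], v["endo"]),
                    rtol=1e-6, atol=_atol(variant),
                    t_eval=t_eval, max_step=max_step)
    if not sol.success:
        raise RuntimeError(
            f"ionic integration failed near t={sol.t[-1]:.3f} ms: {sol.message}")
    return sol


def find_diastolic_threshold(variant: str = DEFAULT_VARIANT,
                             stim_duration_ms: float = 1.0,
                             window_ms: float = 30.0,
                             resolution: float = 0.5) -> float:
    """Diastolic stimulus threshold (pA/pF, negative) by bisection.

    A trial succeeds if Vm exceeds 0 mV within ``window_ms`` of pulse onset.
    """
    y0 = VARIANTS[variant]["init"].copy()

    def fires(amp: float) -> bool:
        sol = _integrate(variant, y0, 0.0, stim_duration_ms, amp, max_step=0.1)
        sol2 = _integrate(variant, sol.y[:, -1], stim_duration_ms, window_ms, 0.0)
        return max(sol.y[0].max(), sol2.y[0].max()) > 0.0

    lo, hi = -80.0, 0.0   # lo fires, hi does not
    if not fires(lo):
        raise RuntimeError("no action potential even at -80 pA/pF")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            lo = mid
        else:
            hi = mid
    return lo


_THRESHOLD_CACHE: dict[tuple, float] = {}


def default_stim_amplitude(variant: str = DEFAULT_VARIANT,
                           stim_duration_ms: float = 1.0) -> float:
    """Twice the diastolic threshold for this variant (cached)."""
    key = (variant, stim_duration_ms)
    if key not in _THRESHOLD_CACHE:
        _THRESHOLD_CACHE[key] = 2.0 * find_diastolic_threshold(
            variant, stim_duration_ms)
    return _THRESHOLD_CACHE[key]


def run_paced(protocol: PacingProtocol,
              variant: str = DEFAULT_VARIANT,
              y0: np.ndarray | None = None) -> PacedTrace:
    """Pace the cell for ``protocol.n_beats`` beats and sample (Vm, Cai).

    Output is uniformly sampled at ``protocol.sample_ms``; beat k spans
    [k*bcl, (k+1)*bcl) with the stimulus at the start of each beat.
    """
    v = VARIANTS[variant]
    amp = protocol.stim_amplitude
    if amp is None:
        amp = default_stim_amplitude(variant, protocol.stim_duration_ms)
    y = (v["init"] if y0 is None else np.asarray(y0, dtype=float)).copy()
    bcl, dur = protocol.bcl_ms, protocol.stim_duration_ms
    dt = protocol.sample_ms
    n_per_beat = int(round(bcl / dt))
    icai = v["names"].index("Cai")

    t_all, vm_all, cai_all, peaks = [], [], [], []
    for beat in range(protocol.n_beats):
        t0 = beat * bcl
        # stimulus segment (fine-stepped), then the rest of the cycle;
        # each segment's end point is appended to t_eval to carry the state
        te1 = t0 + np.arange(0.0, dur, dt)
        sol1 = _integrate(variant, y, t0, t0 + dur, amp,
                          t_eval=np.append(te1, t0 + dur), max_step=0.1)
        y = sol1.y[:, -1].copy()
        te2 = t0 + np.arange(math.ceil(dur / dt) * dt, bcl, dt)
        sol2 = _integrate(variant, y, t0 + dur, t0 + bcl, 0.0,
                          t_eval=np.append(te2, t0 + bcl))
        y = sol2.y[:, -1].copy()

        tb = np.concatenate([sol1.t[: len(te1)], sol2.t[: len(te2)]])
        yb = np.concatenate([sol1.y[:, : len(te1)], sol2.y[:, : len(te2)]],
                            axis=1)
        t_all.append(tb[:n_per_beat])
        vm_all.append(yb[0, :n_per_beat])
        cai_all.append(yb[icai, :n_per_beat])
        peaks.append(yb[icai].max())

    return PacedTrace(
        t_ms=np.concatenate(t_all),
        vm_mV=np.concatenate(vm_all),
        cai_mM=np.concatenate(cai_all),
        protocol=protocol, variant=variant, stim_amplitude=amp,
        beat_peak_cai=np.asarray(peaks), final_state=y,
    )


def _upward_crossing(t: np.ndarray, x: np.ndarray, level: float) -> float:
    """First upward crossing of ``level``, linearly interpolated."""
    above = x >= level
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    if above[0]:
        return float(t[0])
    if len(idx) == 0:
        raise ValueError("no upward crossing of level")
    i = idx[0]
    frac = (level - x[i]) / (x[i + 1] - x[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def extract_ca_transient(trace: PacedTrace, beat_index: int = -1,
                         severity: str | None = None) -> CaTransient:
    """One-period Ca2+ waveform of a beat, t = 0 at that beat's stimulus.

    Also records the electrical activation time (EAT): the first upward
    crossing of 0 mV after the stimulus, linearly interpolated.
    """
    bcl = trace.protocol.bcl_ms
    n_per_beat = int(round(bcl / trace.protocol.sample_ms))
    n_beats = len(trace.t_ms) // n_per_beat
    if beat_index < 0:
        beat_index += n_beats
    if not 0 <= beat_index < n_beats:
        raise ValueError(f"beat {beat_index} not contained in trace")
    sl = slice(beat_index * n_per_beat, (beat_index + 1) * n_per_beat)
    t = trace.t_ms[sl] - trace.t_ms[sl][0]
    vm = trace.vm_mV[sl]
    cai = trace.cai_mM[sl]
    try:
        eat = _upward_crossing(t, vm, 0.0)
    except ValueError as exc:
        raise ValueError("no electrical activation (Vm never exceeds 0 mV)"
                         ) from exc
    return CaTransient(t_ms=t, cai_mM=cai.copy(), period_ms=bcl,
                       eat_ms=eat, severity=severity)
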