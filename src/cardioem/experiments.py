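"""Experiment orchestration: the single-cell grid, the 8-condition
hemodynamic sweep, synthetic waveform fixtures and result serialization.

Two experiment families mirror the study design:

* ``reproduce_cell_tables`` — the severity x {isometric, isotonic-30,
  isotonic-50} single-cell grid, tabulating integer-ms times-to-peak of
  Ca2+, tension, equivalent cell length and ATP consumption rate.
* ``reproduce_condition_sweep`` — HF1..HF4 x {control, LVAD} closed-loop
  scenarios with paired percent changes in stroke work, contractile ATP
  and electromechanical delay.

Everything is deterministic; the manifest records the configuration (and
an unused seed slot, reserved) so each output is traceable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from .ca_scaling import SEVERITIES
from .circulation import (ChamberModel, CircParams, DEFAULT_RV, LVADConfig,
                          ScenarioResult, run_scenario)
from .ionic import (CaTransient, PacingProtocol, extract_ca_transient,
                    run_paced)
from .metrics import run_cell_grid
from .myofilament import RiceParams

__all__ = [
    "RunManifest",
    "baseline_transient",
    "reproduce_cell_tables",
    "reproduce_condition_sweep",
    "synthetic_waveform_fixtures",
    "save_sweep",
]


@dataclass
class RunManifest:
    """Provenance stamp for one experiment run."""

    experiment: str
    variant: str = "tt2006-epi"
    bcl_ms: float = 600.0
    n_beats: int = 20
    seed: int | None = None     # reserved; the core is deterministic
    version: str = __version__
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def baseline_transient(variant: str = "tt2006-epi",
                       protocol: PacingProtocol | None = None) -> CaTransient:
    """Steady-state Ca2+ transient of the paced ionic model (beat 20 of a
    20-beat run at BCL 600 ms by default)."""
    prot = protocol or PacingProtocol()
    trace = run_paced(prot, variant=variant)
    return extract_ca_transient(trace, -1)


def reproduce_cell_tables(ca: CaTransient | None = None,
                          params: RiceParams | None = None,
                          n_cycles: int = 20,
                          variant: str = "tt2006-epi"):
    """Peak-time tables of the single-cell grid (integer milliseconds).

    Returns (wide_table, tidy_frame): the wide table has one row per HF
    severity and the 8 metric columns of the published layout — Ca2+,
    tension, equivalent cell length and ATP rate, each under the isometric
    and the isotonic condition (isotonic values at load 30; the companion
    load-50 table is obtained by filtering the tidy frame).
    """
    ca = ca or baseline_transient(variant)
    tidy = run_cell_grid(ca, params=params, n_cycles=n_cycles)
    tables = {}
    for load_kpa in (30.0, 50.0):
        rows = []
        for sev in SEVERITIES:
            iso = tidy[(tidy.severity == sev.label)
                       & (tidy.load == "isometric")].iloc[0]
            ist = tidy[(tidy.severity == sev.label)
                       & (tidy.afterload_kpa == load_kpa)].iloc[0]

            def r(x):
                return int(round(x)) if math.isfinite(x) else None

            rows.append({
                "severity": sev.label,
                "ca_isometric_ms": r(iso.ttp_ca_ms),
                "ca_isotonic_ms": r(ist.ttp_ca_ms),
                "tension_isometric_ms": r(iso.ttp_tension_ms),
                "tension_isotonic_ms": r(ist.ttp_tension_ms),
                # no shortening occurs under the isometric clamp
                "length_isometric_ms": None,
                "length_isotonic_ms": r(ist.ttp_shortening_ms),
                "atp_isometric_ms": r(iso.ttp_atp_ms),
                "atp_isotonic_ms": r(ist.ttp_atp_ms),
            })
        tables[load_kpa] = pd.DataFrame(rows).set_index("severity")
    return tables, tidy


def reproduce_condition_sweep(ca: CaTransient | None = None,
                              circ_params: CircParams | None = None,
                              rice_params: RiceParams | None = None,
                              lv_chamber: ChamberModel = ChamberModel(),
                              rv_chamber: ChamberModel = DEFAULT_RV,
                              duration_s: float = 42.0,
                              lvad_flow_mls: float = 50.0,
                              variant: str = "tt2006-epi",
                              progress: Callable[[str], None] | None = None,
                              ):
    """Run the 8-condition sweep (HF1..HF4 x control/LVAD).

    Returns (results, comparison): ``results`` maps (severity, lvad_on) to
    the ScenarioResult; ``comparison`` is a frame with one row per
    severity carrying the control and LVAD values and the paired percent
    changes of stroke work, contractile ATP and EMD.
    """
    ca = ca or baseline_transient(variant)
    results: dict[tuple[str, bool], ScenarioResult] = {}
    for enabled in (False, True):
        for sev in SEVERITIES:
            if progress:
                progress(f"{sev.label} lvad={'on' if enabled else 'off'}")
            results[(sev.label, enabled)] = run_scenario(
                sev, LVADConfig(enabled=enabled, flow_mls=lvad_flow_mls),
                ca, circ_params=circ_params, rice_params=rice_params,
                lv_chamber=lv_chamber, rv_chamber=rv_chamber,
                duration_s=duration_s)

    def pct_drop(c: float, o: float) -> float:
        return (c - o) / c * 100.0 if c else math.nan

    rows = []
    for sev in SEVERITIES:
        c = results[(sev.label, False)]
        o = results[(sev.label, True)]
        rows.append({
            "severity": sev.label,
            "EDV_control_ml": c.edv_ml, "EDV_lvad_ml": o.edv_ml,
            "ESV_control_ml": c.esv_ml, "ESV_lvad_ml": o.esv_ml,
            "EF_control_pct": c.ef_pct, "EF_lvad_pct": o.ef_pct,
            "fully_assisted": o.fully_assisted,
            "stroke_work_control": c.stroke_work_mmhg_ml,
            "stroke_work_lvad": o.stroke_work_mmhg_ml,
            "stroke_work_reduction_pct": pct_drop(c.stroke_work_mmhg_ml,
                                                  o.stroke_work_mmhg_ml),
            "atp_control": c.atp_per_beat, "atp_lvad": o.atp_per_beat,
            "atp_reduction_pct": pct_drop(c.atp_per_beat, o.atp_per_beat),
            "emd_control_ms": c.emd.emd_ms if c.emd else math.nan,
            "emd_lvad_ms": o.emd.emd_ms if o.emd else math.nan,
            "emd_reduction_pct": pct_drop(
                c.emd.emd_ms if c.emd else math.nan,
                o.emd.emd_ms if o.emd else math.nan),
        })
    return results, pd.DataFrame(rows).set_index("severity")


def synthetic_waveform_fixtures(kind: str, **params) -> dict[str, np.ndarray]:
    """Analytic traces with closed-form EAT/MAT/time-to-peak for testing
    the metric extractors independently of the ODE models.

    kinds
    -----
    ramp          : Vm = v0 + slope*t; crosses ``level`` (default 0 mV) at
                    (level - v0)/slope.
    gaussian-twitch : x(t) = base - amp*exp(-(t-center)^2/(2*width^2));
                    extremum exactly at ``center``.
    biphasic      : piecewise-linear shortening 0 -> amp over [t0, t1]
                    then back to 0 at t2; the 10% crossing is
                    t0 + 0.1*(t1 - t0).
    """
    duration = float(params.pop("duration_ms", 600.0))
    dt = float(params.pop("sample_ms", 1.0))
    t = np.arange(0.0, duration, dt)
    if kind == "ramp":
        v0 = float(params.pop("v0", -80.0))
        slope = float(params.pop("slope", 1.0))
        return {"t_ms": t, "signal": v0 + slope * t,
                "crossing_ms": -v0 / slope}
    if kind == "gaussian-twitch":
        center = float(params.pop("center_ms", 120.0))
        width = float(params.pop("width_ms", 40.0))
        amp = float(params.pop("amplitude", 0.2))
        base = float(params.pop("baseline", 2.2))
        sig = base - amp * np.exp(-((t - center) ** 2) / (2.0 * width ** 2))
        return {"t_ms": t, "signal": sig, "peak_ms": center}
    if kind == "biphasic":
        t0 = float(params.pop("t0_ms", 50.0))
        t1 = float(params.pop("t1_ms", 200.0))
        t2 = float(params.pop("t2_ms", 400.0))
        amp = float(params.pop("amplitude", 0.3))
        base = float(params.pop("baseline", 2.2))
        short = np.where(t < t0, 0.0,
                         np.where(t < t1, amp * (t - t0) / (t1 - t0),
                                  np.where(t < t2,
                                           amp * (t2 - t) / (t2 - t1), 0.0)))
        return {"t_ms": t, "signal": base - short,
                "mat_ms": t0 + 0.1 * (t1 - t0), "peak_ms": t1}
    raise ValueError(f"unknown fixture kind {kind!r}")


def save_sweep(results: dict, comparison: pd.DataFrame, outdir: str | Path,
               manifest: RunManifest | None = None) -> Path:
    """Write the sweep outputs (per-scenario traces, summaries, comparison
    table, manifest) under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    comparison.to_csv(out / "comparison.csv")
    summaries = {}
    for (sev, on), r in results.items():
        tag = f"{sev}_{'lvad' if on else 'control'}"
        pd.DataFrame({
            "time_ms": r.t_ms, "P_LV_mmHg": r.p_lv, "P_AO_mmHg": r.p_ao,
            "V_LV_ml": r.v_lv, "Q_AO_mls": r.q_ao, "Q_LVAD_mls": r.q_lvad,
        }).to_csv(out / f"beat_{tag}.csv", index=False)
        summaries[tag] = r.summary()
    (out / "scenarios.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True, default=float))
    if manifest is not None:
        (out / "manifest.json").write_text(manifest.to_json())
    return out
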