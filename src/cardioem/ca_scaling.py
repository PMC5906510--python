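"""Heart-failure severity grading via Ca2+-transient magnitude scaling.

Systolic dysfunction is represented phenomenologically: the steady-state
Ca2+ transient of the ionic model is scaled in magnitude by a factor of
1.0, 0.9, 0.8 or 0.7 for severities HF1..HF4 (HF1 mildest).  Scaling is
applied about the diastolic baseline by default, so resting Ca2+ (and
hence diastolic tension) is unchanged; absolute scaling is available as an
alternative mode.  Timing is untouched: the scaled transient peaks at the
same instant for every severity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ionic import CaTransient

__all__ = ["HFSeverity", "SEVERITIES", "scale_transient"]

_SCALES = {"HF1": 1.0, "HF2": 0.9, "HF3": 0.8, "HF4": 0.7}


@dataclass(frozen=True)
class HFSeverity:
    """One of the four graded heart-failure conditions.

    The label <-> scale mapping is the fixed bijection
    HF1=1.0, HF2=0.9, HF3=0.8, HF4=0.7.
    """

    label: str

    def __post_init__(self) -> None:
        if self.label not in _SCALES:
            raise ValueError(f"unknown severity {self.label!r}; "
                             f"expected one of {sorted(_SCALES)}")

    @property
    def scale(self) -> float:
        return _SCALES[self.label]

    @classmethod
    def from_scale(cls, scale: float) -> "HFSeverity":
        for label, s in _SCALES.items():
            if abs(s - scale) < 1e-12:
                return cls(label)
        raise ValueError(f"no severity with scale {scale}")


SEVERITIES = tuple(HFSeverity(lbl) for lbl in ("HF1", "HF2", "HF3", "HF4"))


def scale_transient(ca: CaTransient, severity: HFSeverity | float,
                    mode: str = "about_diastole") -> CaTransient:
    """Scale a one-period Ca2+ transient for a given HF severity.

    ``mode='about_diastole'`` (default) keeps the diastolic baseline fixed:
    out(t) = dia + scale * (ca(t) - dia), so the peak-above-baseline
    amplitude is multiplied by exactly ``scale``.  ``mode='absolute'``
    multiplies the whole waveform.  Timing (period, argmax) is unchanged.
    """
    scale = severity.scale if isinstance(severity, HFSeverity) else float(severity)
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    if mode == "about_diastole":
        if scale == 1.0:
            cai = ca.cai_mM.copy()
        else:
            dia = ca.diastolic_mM
            cai = dia + scale * (ca.cai_mM - dia)
    elif mode == "absolute":
        cai = scale * ca.cai_mM
    else:
        raise ValueError(f"unknown scale_mode {mode!r}")
    label = severity.label if isinstance(severity, HFSeverity) else None
    return CaTransient(t_ms=ca.t_ms.copy(), cai_mM=cai,
                       period_ms=ca.period_ms, eat_ms=ca.eat_ms,
                       severity=label)
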