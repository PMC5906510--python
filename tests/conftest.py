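"""Shared session fixtures: the heavy simulations are run once and reused
across the unit, property and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from cardioem import ca_scaling, circulation as circ, ionic, metrics


@pytest.fixture(scope="session")
def baseline_trace() -> ionic.PacedTrace:
    """20 beats at BCL 600 ms of the default (epicardial 2006) variant."""
    return ionic.run_paced(ionic.PacingProtocol(), variant="tt2006-epi")


@pytest.fixture(scope="session")
def baseline_ca(baseline_trace) -> ionic.CaTransient:
    """Steady-state Ca2+ transient (beat 20)."""
    return ionic.extract_ca_transient(baseline_trace, -1)


@pytest.fixture(scope="session")
def cell_grid(baseline_ca):
    """Full severity x load grid at 20 cycles: (tidy frame, twitch records)."""
    return metrics.run_cell_grid(baseline_ca, n_cycles=20, keep_records=True)


@pytest.fixture(scope="session")
def sweep(baseline_ca):
    """All 8 scenarios (HF1..HF4 x control/LVAD) at 42 s."""
    results = {}
    for enabled in (False, True):
        for sev in ca_scaling.SEVERITIES:
            results[(sev.label, enabled)] = circ.run_scenario(
                sev, circ.LVADConfig(enabled=enabled), baseline_ca)
    return results


@pytest.fixture()
def synthetic_transient() -> ionic.CaTransient:
    """Analytic Ca2+ transient (biexponential-like) for cheap cell tests."""
    t = np.arange(0.0, 600.0, 1.0)
    shape = np.exp(-t / 110.0) - np.exp(-t / 20.0)
    shape /= shape.max()
    cai = (0.1 + 1.0 * shape) * 1e-3
    return ionic.CaTransient(t_ms=t, cai_mM=cai, period_ms=600.0, eat_ms=1.0)
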