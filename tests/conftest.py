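"""Shared fixtures: small hand-built series and one full-scale demo run."""

from __future__ import annotations

import time

import numpy as np
import pytest

from pshkit import SignalKind, SimConfig, VitalSignSeries, simulate_patient


def make_series(
    values,
    start_s: float = 0.0,
    period_s: float = 2.0,
    kind: SignalKind = SignalKind.HR,
    patient_id: str = "p1",
) -> VitalSignSeries:
    """A series on a uniform grid from a plain list of values."""
    values = np.asarray(values, dtype=float)
    t = start_s + period_s * np.arange(values.size)
    return VitalSignSeries(
        patient_id=patient_id,
        signal_kind=kind,
        timestamps=t,
        values=values,
        nominal_rate_hz=1.0 / period_s,
    )


@pytest.fixture(scope="session")
def small_case_patient():
    """A 2-day simulated PSH case used by several unit tests."""
    return simulate_patient(SimConfig(duration_days=2.0), seed=7, patient_id="case")


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full-scale demo run (2 cases + 2 controls, 14 days) with its wall time."""
    from pshkit.cli import run_demo

    out = tmp_path_factory.mktemp("demo")
    t0 = time.monotonic()
    report = run_demo(out, seed=17)
    elapsed = time.monotonic() - t0
    return {"report": report, "elapsed_s": elapsed, "out_dir": out}
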