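import dataclasses

import numpy as np
import pytest

from relaxdisp import spin_physics as sp
from relaxdisp import synthetic_data as sd


@pytest.fixture(scope="session")
def c13_acq_sq():
    return sp.AcquisitionCPMG(
        "13C", 800.0, 313.0, 0.024, sd.CPMG_GRID_13C, "SQ"
    )


@pytest.fixture(scope="session")
def c13_acq_mq():
    return sp.AcquisitionCPMG(
        "13C", 800.0, 313.0, 0.024, sd.CPMG_GRID_13C, "MQ"
    )


@pytest.fixture(scope="session")
def f19_acq_cpmg():
    return sp.AcquisitionCPMG(
        "19F", 500.0, 313.0, 0.016, sd.CPMG_GRID_19F_500, "SQ"
    )


@pytest.fixture(scope="session")
def r1rho_acq():
    return sp.AcquisitionR1rho(
        500.0, 313.0, sd.T_SL_GRID, sd.SL_GRID_500, "19F"
    )


@pytest.fixture(scope="session")
def f19_small_fixture():
    """Single-temperature, 500-MHz-only 19F fixture for fast fit tests."""
    full = sd.f19_313K()
    return dataclasses.replace(
        full,
        name="f19_313K_500",
        acquisitions=tuple(a for a in full.acquisitions if a.field_MHz == 500.0),
    )


@pytest.fixture(scope="session")
def f19_small_profiles(f19_small_fixture):
    return sd.fixture_profiles(f19_small_fixture, seed=42)


def truth_start(fixture):
    """Initial-value dict at the generating parameters of a fixture."""
    start = {}
    temps = sorted(fixture.exchange)
    multi = len(temps) > 1
    for t in temps:
        m = fixture.exchange[t]
        suffix = f"@{t:g}K" if multi else ""
        start[f"p_GS{suffix}"] = m.p_GS
        start[f"k_ex{suffix}"] = m.k_ex
    for probe in fixture.probes:
        start[f"dw[{probe.probe_id}]"] = probe.delta_omega_X
        if probe.delta_omega_H:
            start[f"dwH[{probe.probe_id}]"] = probe.delta_omega_H
        for acq in fixture.acquisitions:
            kind = ("R1rho" if isinstance(acq, sp.AcquisitionR1rho)
                    else acq.experiment)
            if (acq.field_MHz, kind) not in probe.R2_0:
                continue
            key = (f"{probe.probe_id}|{acq.field_MHz:g}|{kind}"
                   f"|{acq.temperature_K:g}K")
            start[f"R2_0[{key}]"] = probe.R2_0[(acq.field_MHz, kind)]
    return start


@pytest.fixture(scope="session")
def default_exchange():
    return sp.TwoStateExchange(p_GS=0.819, k_ex=710.0)
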