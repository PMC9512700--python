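"""Synthetic dispersion, titration and turnover data generators.

Each generator draws intensity-level Gaussian noise on top of the package's
own forward models, so a simulate -> extract -> fit round trip exercises the
full analysis chain.  The named fixtures encode the acquisition grids of the
emulated experiments (constant-time CPMG on three or two static fields,
on-resonance spin locks over five durations) together with published best-fit
exchange parameters as ground truth; per-probe shift differences and
intrinsic rates are *not* published and are drawn once from seeded,
physically plausible ranges (they are stand-ins, recorded in the fixture).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import spin_physics as sp
from .dispersion_fit import DispersionProfile
from .errors import ConfigurationError

__all__ = [
    "Fixture",
    "CPMG_GRID_13C",
    "CPMG_GRID_19F_500",
    "CPMG_GRID_19F_600",
    "SL_GRID_500",
    "SL_GRID_600",
    "T_SL_GRID",
    "c13_313K",
    "f19_multiT",
    "f19_313K",
    "get_fixture",
    "simulate_cpmg",
    "simulate_r1rho",
    "simulate_titration",
    "simulate_turnover",
    "fixture_profiles",
    "noiseless_profiles",
    "anisotropy_model",
]

# acquisition grids (Hz) of the emulated experiments
CPMG_GRID_13C = (83.3, 166.7, 250.0, 333.3, 416.7, 500.0, 666.7, 833.3,
                 1000.0, 1166.7, 1333.3, 1666.7, 2000.0)
CPMG_GRID_19F_500 = (62.6, 125.0, 187.5, 250.0, 312.5, 375.0, 437.5, 500.0,
                     562.5, 1000.0, 1500.0, 2500.0, 5000.0)
CPMG_GRID_19F_600 = (62.5, 125.0, 187.5, 250.0, 312.5, 375.0, 437.5, 500.0,
                     625.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 3500.0,
                     4000.0, 4500.0, 5000.0)
SL_GRID_500 = (50.0, 75.0, 100.0, 125.0, 150.0, 200.0, 250.0, 300.0, 400.0,
               500.0, 600.0, 700.0, 800.0, 1000.0, 2500.0, 3000.0, 5000.0,
               8000.0)
SL_GRID_600 = (50.0, 75.0, 100.0, 125.0, 150.0, 200.0, 250.0, 300.0, 400.0,
               500.0, 600.0, 800.0, 1000.0, 1500.0, 2000.0, 3000.0, 5000.0,
               8000.0)
T_SL_GRID = (0.0, 0.004, 0.008, 0.016, 0.032)


@dataclass(frozen=True)
class Fixture:
    """A fully specified synthetic study: truth, acquisitions and noise model.

    ``exchange`` maps temperature (K) to the generating two-state model;
    ``probes`` carry per-probe truth; ``acquisitions`` the measurement grids.
    ``noise`` is the absolute intensity-level Gaussian sigma relative to the
    reference intensity I0 = 1.  Regeneration with the same name and seed is
    bit-identical.
    """

    name: str
    exchange: dict  # temperature_K -> TwoStateExchange
    probes: tuple  # ProbeParams
    acquisitions: tuple  # AcquisitionCPMG / AcquisitionR1rho
    noise: float
    replicates: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "exchange": {
                f"{t:g}": {"p_GS": m.p_GS, "k_ex": m.k_ex}
                for t, m in self.exchange.items()
            },
            "probes": [
                {**dataclasses.asdict(p),
                 "R2_0": {f"{f:g}|{e}": v for (f, e), v in p.R2_0.items()}}
                for p in self.probes
            ],
            "acquisitions": [dataclasses.asdict(a) for a in self.acquisitions],
            "noise": self.noise,
            "replicates": self.replicates,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------


def c13_313K(seed: int = 1313) -> Fixture:
    """Methyl 13C SQ+MQ CPMG study: five probes, three fields, 313 K.

    Truth: p_ES = 0.181, k_ex = 710 s^-1.  Per-probe carbon shift differences
    are drawn from 1-3 p.p.m., proton partners from 0-0.2 p.p.m., and
    intrinsic rates per field and coherence type from 15-40 s^-1 (seeded
    stand-ins; these per-probe values are not published).
    """
    rng = np.random.default_rng(seed)
    fields = (500.0, 600.0, 800.0)
    probe_ids = ("I59", "I89", "I235", "I850", "I853")
    probes = []
    for pid in probe_ids:
        r2 = {}
        for f in fields:
            for exp in ("SQ", "MQ"):
                r2[(f, exp)] = float(rng.uniform(15.0, 40.0))
        probes.append(
            sp.ProbeParams(
                probe_id=pid,
                delta_omega_X=float(rng.uniform(1.0, 3.0)),
                delta_omega_H=float(rng.uniform(0.0, 0.2)),
                R2_0=r2,
            )
        )
    acqs = tuple(
        sp.AcquisitionCPMG("13C", f, 313.0, 0.024, CPMG_GRID_13C, exp)
        for exp in ("SQ", "MQ")
        for f in fields
    )
    return Fixture(
        name="c13_313K",
        exchange={313.0: sp.TwoStateExchange(p_GS=0.819, k_ex=710.0)},
        probes=tuple(probes),
        acquisitions=acqs,
        noise=0.003,
        replicates=2,
        seed=seed,
    )


def _f19_r2_0(dw_ppm: float, model: sp.TwoStateExchange, field_MHz: float,
              target_fwhm_hz: float = 55.0) -> float:
    """Intrinsic 19F rate such that the exchange-broadened line is ~55 Hz."""
    dw = sp.ppm_to_rad_s(dw_ppm, field_MHz, sp.GAMMA_RATIO["19F"])

    def width(r2):
        obs = sp.free_precession_eigen(model, dw, r2, r2)
        return obs.fwhm[0] - target_fwhm_hz

    return float(brentq(width, 1.0, np.pi * target_fwhm_hz))


def _f19_probe(model_313, seed: int) -> sp.ProbeParams:
    dw_ppm = 0.15
    r2_base = _f19_r2_0(dw_ppm, model_313, 500.0)
    r2 = {}
    for f in (500.0, 600.0):
        for exp in ("SQ", "R1rho"):
            r2[(f, exp)] = r2_base
    return sp.ProbeParams(
        probe_id="N12C-BTFA", delta_omega_X=dw_ppm, R2_0=r2, R1=2.0
    )


def _f19_acqs(temps) -> tuple:
    acqs = []
    for t in temps:
        acqs.append(sp.AcquisitionCPMG("19F", 500.0, t, 0.016, CPMG_GRID_19F_500, "SQ"))
        acqs.append(sp.AcquisitionCPMG("19F", 600.0, t, 0.016, CPMG_GRID_19F_600, "SQ"))
        acqs.append(sp.AcquisitionR1rho(500.0, t, T_SL_GRID, SL_GRID_500, "19F"))
        acqs.append(sp.AcquisitionR1rho(600.0, t, T_SL_GRID, SL_GRID_600, "19F"))
    return tuple(acqs)


def f19_multiT(seed: int = 1919) -> Fixture:
    """19F CPMG + on-resonance R1rho study at two fields, five temperatures.

    Truth: |dw| = 0.15 p.p.m. at all temperatures, p_GS = 0.50, k_ex linear
    in temperature from 445 s^-1 (303 K) to 913 s^-1 (313 K).  The intrinsic
    rate is chosen so the exchange-broadened line width is ~55 Hz; R1 = 2
    s^-1.
    """
    temps = (303.0, 305.5, 308.0, 310.5, 313.0)
    exchange = {
        t: sp.TwoStateExchange(0.50, float(np.interp(t, [303.0, 313.0], [445.0, 913.0])))
        for t in temps
    }
    probe = _f19_probe(exchange[313.0], seed)
    return Fixture(
        name="f19_multiT",
        exchange=exchange,
        probes=(probe,),
        acquisitions=_f19_acqs(temps),
        noise=0.003,
        replicates=3,
        seed=seed,
    )


def f19_313K(seed: int = 1919) -> Fixture:
    """Single-temperature (313 K) slice of :func:`f19_multiT`."""
    full = f19_multiT(seed)
    return Fixture(
        name="f19_313K",
        exchange={313.0: full.exchange[313.0]},
        probes=full.probes,
        acquisitions=tuple(
            a for a in full.acquisitions if a.temperature_K == 313.0
        ),
        noise=full.noise,
        replicates=full.replicates,
        seed=seed,
    )


_FIXTURES = {"c13_313K": c13_313K, "f19_multiT": f19_multiT, "f19_313K": f19_313K}


def get_fixture(name: str, seed: int | None = None) -> Fixture:
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return factory() if seed is None else factory(seed)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def _truth_rates(fixture: Fixture, probe: sp.ProbeParams, acq) -> np.ndarray:
    model = fixture.exchange[acq.temperature_K]
    dw = acq.dw_rad(probe.delta_omega_X)
    if isinstance(acq, sp.AcquisitionR1rho):
        r2_0 = probe.R2_0[(acq.field_MHz, "R1rho")]
        return np.atleast_1d(sp.r1rho_onres(model, dw, r2_0, probe.R1, acq))
    r2_0 = probe.R2_0[(acq.field_MHz, acq.experiment)]
    if acq.experiment == "SQ":
        return np.atleast_1d(sp.sq_cpmg_r2eff(model, dw, r2_0, acq))
    dwh = sp.ppm_to_rad_s(probe.delta_omega_H, acq.field_MHz, 1.0)
    return np.atleast_1d(sp.mq_cpmg_r2eff(model, dwh, dw, r2_0, acq))


def _check_noise(fixture: Fixture):
    if fixture.noise < 0:
        raise ConfigurationError("noise must be >= 0")
    if 3.0 * fixture.noise >= 1.0:
        raise ConfigurationError(
            "intensity noise so large that simulated reference intensities "
            "would routinely be negative"
        )


def simulate_cpmg(fixture: Fixture, seed: int | None = None) -> pd.DataFrame:
    """Simulate intensity tables for every CPMG acquisition of a fixture.

    Intensities follow I(nu) = I0 exp(-R2eff(nu) T_CPMG) with I0 = 1 and
    absolute Gaussian noise of sigma ``fixture.noise`` drawn independently
    per replicate; a reference row (nu_Hz = 0, no CPMG element) is emitted
    for every replicate.  Returns a long-form table with one row per
    (probe, field, temperature, experiment, frequency, replicate).
    """
    _check_noise(fixture)
    rng = np.random.default_rng(fixture.seed if seed is None else seed)
    rows = []
    for acq in fixture.acquisitions:
        if not isinstance(acq, sp.AcquisitionCPMG):
            continue
        for probe in fixture.probes:
            if acq.nucleus == "13C" and not probe.probe_id.startswith("I"):
                continue
            rates = _truth_rates(fixture, probe, acq)
            clean = sp.intensity_from_r2eff(rates, 1.0, acq.T_CPMG)
            for rep in range(1, fixture.replicates + 1):
                i0 = 1.0 + rng.normal(0.0, fixture.noise)
                noisy = clean + rng.normal(0.0, fixture.noise, clean.shape)
                rows.append(
                    dict(probe_id=probe.probe_id, nucleus=acq.nucleus,
                         field_MHz=acq.field_MHz, temperature_K=acq.temperature_K,
                         experiment=acq.experiment, nu_Hz=0.0, T_SL_s=np.nan,
                         T_relax_s=acq.T_CPMG, replicate=rep, intensity=i0,
                         value=np.nan, sigma=np.nan)
                )
                for nu, inten in zip(acq.nu_cpmg, noisy):
                    rows.append(
                        dict(probe_id=probe.probe_id, nucleus=acq.nucleus,
                             field_MHz=acq.field_MHz,
                             temperature_K=acq.temperature_K,
                             experiment=acq.experiment, nu_Hz=nu, T_SL_s=np.nan,
                             T_relax_s=acq.T_CPMG, replicate=rep,
                             intensity=inten, value=np.nan, sigma=np.nan)
                    )
    return pd.DataFrame(rows)


def simulate_r1rho(fixture: Fixture, seed: int | None = None) -> pd.DataFrame:
    """Simulate spin-lock intensity tables over (nu_SL, T_SL) grids.

    Decay over T_SL at the model R1rho(nu_SL) with absolute intensity noise,
    independently per replicate.
    """
    _check_noise(fixture)
    rng = np.random.default_rng(fixture.seed + 1 if seed is None else seed)
    rows = []
    for acq in fixture.acquisitions:
        if not isinstance(acq, sp.AcquisitionR1rho):
            continue
        for probe in fixture.probes:
            rates = _truth_rates(fixture, probe, acq)
            tsl = np.asarray(acq.T_SL)
            for nu, rate in zip(acq.nu_SL, rates):
                clean = np.exp(-rate * tsl)
                for rep in range(1, fixture.replicates + 1):
                    noisy = clean + rng.normal(0.0, fixture.noise, clean.shape)
                    for t, inten in zip(tsl, noisy):
                        rows.append(
                            dict(probe_id=probe.probe_id, nucleus=acq.nucleus,
                                 field_MHz=acq.field_MHz,
                                 temperature_K=acq.temperature_K,
                                 experiment="R1rho", nu_Hz=nu, T_SL_s=t,
                                 T_relax_s=np.nan, replicate=rep,
                                 intensity=inten, value=np.nan, sigma=np.nan)
                        )
    return pd.DataFrame(rows)


def noiseless_profiles(fixture: Fixture, sigma: float = 1.0) -> list:
    """Exact forward-model profiles (no noise), with unit sigma by default.

    Useful for self-consistency fits: parameters recovered from these
    profiles must equal the fixture truth to optimizer tolerance.
    """
    profiles = []
    for acq in fixture.acquisitions:
        freqs = (np.asarray(acq.nu_SL)
                 if isinstance(acq, sp.AcquisitionR1rho)
                 else np.asarray(acq.nu_cpmg))
        for probe in fixture.probes:
            rates = _truth_rates(fixture, probe, acq)
            profiles.append(DispersionProfile(
                probe_id=probe.probe_id, acquisition=acq, freq=freqs,
                value=rates, sigma=np.full(freqs.shape, sigma),
            ))
    return profiles


def fixture_profiles(
    fixture: Fixture, seed: int | None = None, floors: bool = True
) -> list:
    """Simulate a fixture end-to-end and return aggregated dispersion profiles.

    Runs :func:`simulate_cpmg` and :func:`simulate_r1rho`, extracts effective
    rates (intensity ratio for CPMG, per-replicate exponential fits over T_SL
    for R1rho), averages replicates and, when ``floors`` is set, applies the
    per-nucleus sigma floors.
    """
    from .cli_io import profiles_from_table

    frames = [simulate_cpmg(fixture, seed), simulate_r1rho(
        fixture, None if seed is None else seed + 1)]
    table = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    return profiles_from_table(table, fixture.acquisitions, floors=floors)


# ---------------------------------------------------------------------------
# titration and turnover
# ---------------------------------------------------------------------------


def anisotropy_model(P, K_D, r_min, s, RNA):
    """Single-site anisotropy: r_min + s * [complex] from the exact quadratic."""
    P = np.asarray(P, dtype=float)
    half = (RNA + P + K_D) / 2.0
    complex_conc = half - np.sqrt(half**2 - RNA * P)
    return r_min + s * complex_conc


def simulate_titration(
    K_D: float,
    RNA_conc: float = 1.0,
    P_grid=(0.0, 2.0, 5.0, 10.0, 30.0, 80.0, 200.0),
    noise: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
    r_min: float = 0.05,
    s: float = 0.15,
):
    """Simulate a fluorescence-anisotropy titration (concentrations in nM).

    ``noise`` is the Gaussian sigma on r_obs relative to the saturation
    amplitude ``s * RNA_conc``.  Returns a :class:`BindingCurve`.
    """
    from .binding_kinetics import BindingCurve

    rng = np.random.default_rng(seed)
    P = np.asarray(P_grid, dtype=float)
    clean = anisotropy_model(P, K_D, r_min, s, RNA_conc)
    amp = s * RNA_conc
    P_all, r_all, rep_all = [], [], []
    for rep in range(1, replicates + 1):
        P_all.append(P)
        r_all.append(clean + rng.normal(0.0, noise * amp, P.shape))
        rep_all.append(np.full(P.shape, rep, dtype=int))
    return BindingCurve(
        RNA_conc=RNA_conc,
        P_conc=np.concatenate(P_all),
        r_obs=np.concatenate(r_all),
        replicate=np.concatenate(rep_all),
    )


def simulate_turnover(
    rate: float = 0.05,
    E0: float = 50.0,
    S0: float = 500.0,
    timepoints=None,
    noise: float = 0.02,
    seed: int = 0,
):
    """Simulate substrate/product signal time series at constant turnover.

    Product accumulates linearly at ``rate * E0`` (uM/min) within the
    initial-rate window; signals are in arbitrary units proportional to
    concentration with absolute Gaussian noise of sigma ``noise * S0``.
    Default timepoints cover 30% conversion in 10 steps.
    """
    from .binding_kinetics import TurnoverSeries

    rng = np.random.default_rng(seed)
    if timepoints is None:
        t_max = 0.3 * S0 / max(rate * E0, 1e-12) if rate > 0 else 60.0
        timepoints = np.linspace(0.0, t_max, 10)
    t = np.asarray(timepoints, dtype=float)
    product = np.minimum(rate * E0 * t, S0)
    substrate = S0 - product
    return TurnoverSeries(
        time=t,
        substrate_signal=substrate + rng.normal(0.0, noise * S0, t.shape),
        product_signal=product + rng.normal(0.0, noise * S0, t.shape),
        E0=E0,
        S0=S0,
    )
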