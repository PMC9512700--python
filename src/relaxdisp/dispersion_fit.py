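"""Global weighted least-squares fitting of relaxation-dispersion datasets.

A collection of :class:`DispersionProfile` objects (SQ/MQ CPMG or on-resonance
R1rho) is fitted to the two-state exchange forward models of
:mod:`relaxdisp.spin_physics` with a declarative parameter-sharing map
(:class:`FitSchema`).  Uncertainties come from Monte-Carlo resampling of the
measured rates, and identifiability is probed with reduced-chi-square
surfaces obtained from constrained fits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import spin_physics as sp
from .errors import ConfigurationError, FitFailureError, NumericalFitError

__all__ = [
    "SIGMA_FLOORS",
    "DispersionProfile",
    "FitSchema",
    "FitResult",
    "ChiSquareSurface",
    "MonteCarloResult",
    "apply_sigma_floor",
    "fit_global",
    "fit_temperature_series",
    "fit_joint_nuclei",
    "monte_carlo_errors",
    "chi2_surface",
]

#: minimum standard deviation (s^-1) applied per detected nucleus to avoid
#: excessive weighting of points with accidentally low replicate scatter
SIGMA_FLOORS = {"13C": 0.2, "19F": 2.0}


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class DispersionProfile:
    """One dispersion curve: rate vs pulsing/locking frequency for one probe.

    ``freq`` holds nu_CPMG (CPMG) or nu_SL (R1rho) in Hz; ``value`` the
    effective rate in s^-1 and ``sigma`` its standard deviation.  Points are
    kept sorted by frequency.
    """

    probe_id: str
    acquisition: object  # AcquisitionCPMG or AcquisitionR1rho
    freq: np.ndarray
    value: np.ndarray
    sigma: np.ndarray
    n_replicates: np.ndarray | None = None

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.freq.shape == self.value.shape == self.sigma.shape):
            raise ValueError("freq, value and sigma must have matching shapes")
        if self.n_replicates is None:
            self.n_replicates = np.ones_like(self.freq, dtype=int)
        else:
            self.n_replicates = np.asarray(self.n_replicates, dtype=int)
        order = np.argsort(self.freq)
        for name in ("freq", "value", "sigma", "n_replicates"):
            setattr(self, name, getattr(self, name)[order])
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")

    @property
    def experiment(self) -> str:
        return getattr(self.acquisition, "experiment", "R1rho")

    @property
    def nucleus(self) -> str:
        return self.acquisition.nucleus

    @property
    def field_MHz(self) -> float:
        return self.acquisition.field_MHz

    @property
    def temperature_K(self) -> float:
        return self.acquisition.temperature_K

    def __len__(self) -> int:
        return self.freq.size


def apply_sigma_floor(profile: DispersionProfile, floor: float | None = None):
    """Return a copy of ``profile`` with ``sigma = max(sigma, floor)``.

    With ``floor=None`` the per-nucleus default is used (0.2 s^-1 for 13C,
    2 s^-1 for 19F data, CPMG and R1rho alike).
    """
    if floor is None:
        floor = SIGMA_FLOORS.get(profile.nucleus, 0.0)
    if floor < 0:
        raise ValueError("sigma floor must be >= 0")
    return dataclasses.replace(profile, sigma=np.maximum(profile.sigma, floor))


# ---------------------------------------------------------------------------
# parameter schema
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = {
    "p_GS": (0.5, 1.0 - 1e-6),
    "k_ex": (10.0, 1e5),
    "dw": (0.0, 10.0),
    "dwH": (0.0, 2.0),
    "R2_0": (0.1, 500.0),
    "R1": (0.01, 50.0),
}

_DEFAULT_START_GRID = {"k_ex": (1e2, 1e3, 1e4), "p_GS": (0.6, 0.9)}


@dataclass
class FitSchema:
    """Parameter-sharing map for a global dispersion fit.

    Scopes
    ------
    ``p_GS_scope`` / ``k_ex_scope``: ``"global"``, ``"per_temperature"`` or
    (p_GS only) ``"per_nucleus"``.  Shift differences are always per probe
    and shared across fields and temperatures (they are stored in p.p.m.);
    intrinsic rates are per probe x field x experiment and, when
    ``r20_per_temperature`` is set (default), also per temperature.

    ``fixed`` maps parameter names (or the bare prefixes ``"R1"``, ``"dw"``,
    ...) to fixed values; R1 is fixed by default at ``R1_default`` because an
    on-resonance spin lock carries almost no longitudinal information.

    ``starts`` optionally lists explicit initial-value dictionaries (partial
    dictionaries are completed with defaults); when omitted a multi-start
    grid over k_ex and p_GS is used.
    """

    p_GS_scope: str = "global"
    k_ex_scope: str = "global"
    r20_per_temperature: bool = True
    fit_R1: bool = False
    R1_default: float = 2.0
    dw_start: dict = field(default_factory=lambda: {"13C": 1.0, "19F": 0.2})
    dwH_start: float = 0.05
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    starts: list | None = None
    max_nfev: int | None = None

    def bound(self, name: str):
        base = name.split("[")[0].split("@")[0]
        return self.bounds.get(name, self.bounds.get(base, _DEFAULT_BOUNDS[base]))

    def fixed_value(self, name: str):
        if name in self.fixed:
            return self.fixed[name]
        base = name.split("[")[0].split("@")[0]
        if base in self.fixed:
            return self.fixed[base]
        return None


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------


def _pname_pk(base: str, scope: str, profile: DispersionProfile) -> str:
    if scope == "global":
        return base
    if scope == "per_temperature":
        return f"{base}@{profile.temperature_K:g}K"
    if scope == "per_nucleus":
        return f"{base}@{profile.nucleus}"
    raise ConfigurationError(f"unknown scope {scope!r} for {base}")


def _profile_param_names(profile: DispersionProfile, schema: FitSchema) -> dict:
    """Map model-input roles to parameter names for one profile."""
    names = {
        "p_GS": _pname_pk("p_GS", schema.p_GS_scope, profile),
        "k_ex": _pname_pk("k_ex", schema.k_ex_scope, profile),
        "dw": f"dw[{profile.probe_id}]",
    }
    r2_key = f"{profile.probe_id}|{profile.field_MHz:g}|{profile.experiment}"
    if schema.r20_per_temperature:
        r2_key += f"|{profile.temperature_K:g}K"
    names["R2_0"] = f"R2_0[{r2_key}]"
    if profile.experiment == "MQ":
        names["dwH"] = f"dwH[{profile.probe_id}]"
    if profile.experiment == "R1rho":
        r1_key = f"{profile.probe_id}|{profile.field_MHz:g}"
        if schema.r20_per_temperature:
            r1_key += f"|{profile.temperature_K:g}K"
        names["R1"] = f"R1[{r1_key}]"
    return names


def _collect_parameters(profiles: Sequence[DispersionProfile], schema: FitSchema):
    """Return (free parameter names, fixed name->value, per-profile role maps)."""
    role_maps = [_profile_param_names(p, schema) for p in profiles]
    names: list[str] = []
    for rm in role_maps:
        for name in rm.values():
            if name not in names:
                names.append(name)
    fixed = {}
    free = []
    for name in names:
        fv = schema.fixed_value(name)
        base = name.split("[")[0].split("@")[0]
        if base == "R1" and not schema.fit_R1 and fv is None:
            fv = schema.R1_default
        if fv is not None:
            fixed[name] = float(fv)
        else:
            free.append(name)
    return free, fixed, role_maps


def _default_start(name: str, profiles, role_maps, schema: FitSchema) -> float:
    base = name.split("[")[0].split("@")[0]
    if base == "p_GS":
        return 0.9
    if base == "k_ex":
        return 1e3
    if base == "dwH":
        return schema.dwH_start
    if base == "dw":
        for p, rm in zip(profiles, role_maps):
            if rm["dw"] == name:
                return schema.dw_start.get(p.nucleus, 1.0)
        return 1.0
    if base == "R2_0":
        lo, hi = schema.bound(name)
        for p, rm in zip(profiles, role_maps):
            if rm["R2_0"] == name:
                return float(np.clip(p.value.min(), lo + 1e-9, hi))
        return 20.0
    if base == "R1":
        return schema.R1_default
    raise ConfigurationError(f"no default start for {name}")


def _build_starts(free, profiles, role_maps, schema: FitSchema):
    defaults = {n: _default_start(n, profiles, role_maps, schema) for n in free}
    if schema.starts is not None:
        return [{**defaults, **s} for s in schema.starts]
    starts = []
    kex_names = sorted({n for n in free if n.startswith("k_ex")})
    p_names = sorted({n for n in free if n.startswith("p_GS")})
    for kex0 in _DEFAULT_START_GRID["k_ex"]:
        for p0 in _DEFAULT_START_GRID["p_GS"]:
            s = dict(defaults)
            s.update({n: kex0 for n in kex_names})
            s.update({n: p0 for n in p_names})
            starts.append(s)
    return starts


# ---------------------------------------------------------------------------
# model evaluation and residuals
# ---------------------------------------------------------------------------


def _profile_model(profile: DispersionProfile, values: dict, roles: dict):
    model = sp.TwoStateExchange(values[roles["p_GS"]], values[roles["k_ex"]])
    acq = profile.acquisition
    dw_rad = acq.dw_rad(values[roles["dw"]])
    r2_0 = values[roles["R2_0"]]
    if profile.experiment == "SQ":
        return sp.sq_cpmg_r2eff(model, dw_rad, r2_0, acq, profile.freq)
    if profile.experiment == "MQ":
        dwh_rad = sp.ppm_to_rad_s(values[roles["dwH"]], acq.field_MHz, 1.0)
        return sp.mq_cpmg_r2eff(model, dwh_rad, dw_rad, r2_0, acq, profile.freq)
    if profile.experiment == "R1rho":
        return sp.r1rho_onres(
            model, dw_rad, r2_0, values[roles["R1"]], acq, profile.freq
        )
    raise ConfigurationError(f"unknown experiment {profile.experiment!r}")


class _Objective:
    def __init__(self, profiles, schema):
        self.profiles = list(profiles)
        self.schema = schema
        self.free, self.fixed, self.role_maps = _collect_parameters(
            self.profiles, schema
        )
        self.ndata = sum(len(p) for p in self.profiles)
        # zero sigmas (noiseless synthetic data) are treated as unit weights
        self._weights = [
            np.where(p.sigma > 0, p.sigma, 1.0) for p in self.profiles
        ]

    def values(self, x) -> dict:
        vals = dict(self.fixed)
        vals.update(zip(self.free, x))
        return vals

    def residuals(self, x):
        vals = self.values(x)
        res = [
            (_profile_model(p, vals, rm) - p.value) / w
            for p, rm, w in zip(self.profiles, self.role_maps, self._weights)
        ]
        return np.concatenate(res)

    def chi2(self, x) -> float:
        return float(np.sum(self.residuals(x) ** 2))


def _x_scale(free):
    scale = {"p_GS": 0.1, "k_ex": 100.0, "dw": 0.2, "dwH": 0.05, "R2_0": 5.0, "R1": 1.0}
    return np.array([scale[n.split("[")[0].split("@")[0]] for n in free])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Best-fit parameter values, goodness of fit and provenance of a fit."""

    params: dict
    fixed: dict
    chi2: float
    chi2_nu: float
    ndata: int
    nfree: int
    success: bool
    message: str
    warnings: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    seed: int | None = None
    start_diagnostics: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def __getitem__(self, name: str) -> float:
        if name in self.params:
            return self.params[name]
        return self.fixed[name]


@dataclass
class ChiSquareSurface:
    """Reduced chi-square versus one systematically fixed parameter."""

    param_name: str
    grid: np.ndarray
    chi2_nu: np.ndarray
    failed: np.ndarray
    unconstrained_chi2_nu: float

    def to_dict(self) -> dict:
        return {
            "param_name": self.param_name,
            "grid": list(map(float, self.grid)),
            "chi2_nu": list(map(float, self.chi2_nu)),
            "failed": list(map(bool, self.failed)),
            "unconstrained_chi2_nu": float(self.unconstrained_chi2_nu),
        }


@dataclass
class MonteCarloResult:
    """Per-parameter standard deviations over Monte-Carlo refit cycles."""

    errors: dict
    n_cycles: int
    n_failed: int
    seed: int
    samples: dict | None = None


# ---------------------------------------------------------------------------
# fitting entry points
# ---------------------------------------------------------------------------


def _run_single(obj: _Objective, x0, bounds_lo, bounds_hi, max_nfev=None):
    return least_squares(
        obj.residuals,
        np.clip(x0, bounds_lo, bounds_hi),
        bounds=(bounds_lo, bounds_hi),
        method="trf",
        x_scale=_x_scale(obj.free),
        ftol=1e-10,
        xtol=1e-10,
        gtol=1e-10,
        max_nfev=max_nfev,
    )


def fit_global(
    profiles: Iterable[DispersionProfile],
    schema: FitSchema | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit all profiles simultaneously under the schema's sharing map.

    Minimizes ``sum(((data - model) / sigma)**2)`` with a trust-region
    least-squares solver, multi-starting from the schema's initial-value
    policy and keeping the lowest-chi-square solution.  Boundary-touching
    parameters and unidentifiable configurations (flat profiles) are flagged
    in ``FitResult.warnings``.
    """
    profiles = list(profiles)
    if not profiles:
        raise ConfigurationError("no profiles to fit")
    for p in profiles:
        if len(p) < 4:
            raise ConfigurationError(
                f"profile {p.probe_id!r} has {len(p)} points; >= 4 required"
            )
    schema = schema or FitSchema()
    obj = _Objective(profiles, schema)
    lo = np.array([schema.bound(n)[0] for n in obj.free])
    hi = np.array([schema.bound(n)[1] for n in obj.free])
    starts = _build_starts(obj.free, profiles, obj.role_maps, schema)

    best = None
    diagnostics = []
    for s in starts:
        x0 = np.array([s[n] for n in obj.free])
        try:
            res = _run_single(obj, x0, lo, hi, schema.max_nfev)
        except (NumericalFitError, np.linalg.LinAlgError) as exc:
            diagnostics.append({"start": s, "success": False, "message": str(exc)})
            continue
        diagnostics.append(
            {"start": s, "success": bool(res.success), "cost": float(res.cost),
             "message": res.message}
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError(
            "no start converged in global dispersion fit", diagnostics
        )

    params = dict(zip(obj.free, map(float, best.x)))
    chi2 = float(2.0 * best.cost)
    nfree = len(obj.free)
    dof = max(obj.ndata - nfree, 1)
    warnings = []
    span = hi - lo
    for n, v, l, h, s in zip(obj.free, best.x, lo, hi, span):
        if v - l < 1e-6 * s or h - v < 1e-6 * s:
            warnings.append(f"parameter {n} at bound ({v:g})")
    for n, v in params.items():
        if n.startswith("dw[") and v < 1e-3:
            warnings.append(
                f"{n} ~ 0: exchange parameters unidentifiable from flat profile"
            )
    # identifiability: if no profile linked to a k_ex parameter shows model
    # dispersion beyond the noise level, the exchange parameters are free-floating
    vals = obj.values(best.x)
    kex_amplitude: dict = {}
    for p, rm in zip(profiles, obj.role_maps):
        amp = float(np.ptp(_profile_model(p, vals, rm)))
        name = rm["k_ex"]
        kex_amplitude[name] = max(kex_amplitude.get(name, 0.0), amp)
    noise_scale = float(np.median(np.concatenate([p.sigma for p in profiles])))
    for name, amp in kex_amplitude.items():
        if amp < 2.0 * max(noise_scale, 1e-12):
            warnings.append(
                f"{name}: model dispersion amplitude {amp:.3g} s^-1 below the "
                "noise level; exchange parameters unidentifiable"
            )
    return FitResult(
        params=params,
        fixed=dict(obj.fixed),
        chi2=chi2,
        chi2_nu=chi2 / dof,
        ndata=obj.ndata,
        nfree=nfree,
        success=True,
        message=best.message,
        warnings=warnings,
        seed=seed,
        start_diagnostics=diagnostics,
    )


def fit_temperature_series(
    profiles: Iterable[DispersionProfile],
    schema: FitSchema | None = None,
    seed: int | None = None,
) -> FitResult:
    """Multi-temperature fit: one global |dw|, per-temperature (p_GS, k_ex).

    With a single temperature present this reduces exactly to
    :func:`fit_global` with global scopes.
    """
    profiles = list(profiles)
    temps = {p.temperature_K for p in profiles}
    schema = schema or FitSchema()
    scope = "per_temperature" if len(temps) > 1 else "global"
    schema = dataclasses.replace(schema, p_GS_scope=scope, k_ex_scope=scope)
    return fit_global(profiles, schema, seed=seed)


def fit_joint_nuclei(
    c13_profiles: Iterable[DispersionProfile],
    f19_profiles: Iterable[DispersionProfile],
    schema: FitSchema | None = None,
    share_p_GS: bool = True,
    seed: int | None = None,
) -> FitResult:
    """Joint one-temperature fit of 13C and 19F data with a shared k_ex.

    Per-probe shift differences and intrinsic rates stay nucleus-specific;
    ``share_p_GS=False`` lets each nucleus keep its own ground-state
    population.  An empty profile list on either side reduces to
    :func:`fit_global` on the other.
    """
    profiles = list(c13_profiles) + list(f19_profiles)
    temps = {p.temperature_K for p in profiles}
    if len(temps) > 1:
        raise ConfigurationError(
            f"joint-nucleus fit expects one temperature, got {sorted(temps)}"
        )
    schema = schema or FitSchema()
    if not share_p_GS:
        schema = dataclasses.replace(schema, p_GS_scope="per_nucleus")
    return fit_global(profiles, schema, seed=seed)


# ---------------------------------------------------------------------------
# Monte-Carlo errors and chi-square surfaces
# ---------------------------------------------------------------------------


def monte_carlo_errors(
    result: FitResult,
    profiles: Iterable[DispersionProfile],
    schema: FitSchema | None = None,
    n_cycles: int = 500,
    seed: int = 0,
    keep_samples: bool = False,
) -> MonteCarloResult:
    """Parameter standard deviations from Monte-Carlo resampling.

    Each cycle perturbs every measured rate by a centered Gaussian of its
    standard deviation and re-runs the fit from the best-fit solution; the
    spread of each parameter over cycles is its reported error.
    Deterministic for a given ``seed``.
    """
    if n_cycles < 2:
        raise ConfigurationError("n_cycles must be >= 2")
    profiles = list(profiles)
    schema = schema or FitSchema()
    rng = np.random.default_rng(seed)
    base = _Objective(profiles, schema)
    if set(base.free) != set(result.params):
        raise ConfigurationError(
            "schema/profiles do not reproduce the fitted parameter set"
        )
    lo = np.array([schema.bound(n)[0] for n in base.free])
    hi = np.array([schema.bound(n)[1] for n in base.free])
    x_best = np.array([result.params[n] for n in base.free])

    samples = []
    failures = []
    for cycle in range(n_cycles):
        perturbed = [
            dataclasses.replace(p, value=p.value + rng.normal(0.0, p.sigma))
            for p in profiles
        ]
        obj = _Objective(perturbed, schema)
        try:
            res = _run_single(obj, x_best, lo, hi, max_nfev=100 * len(base.free))
            if not res.success:
                raise NumericalFitError(res.message)
            samples.append(res.x)
        except Exception as exc:  # noqa: BLE001 - cycle failures are collected
            failures.append({"cycle": cycle, "message": str(exc)})
    n_failed = len(failures)
    if n_failed > 0.1 * n_cycles:
        raise NumericalFitError(
            f"{n_failed}/{n_cycles} Monte-Carlo cycles failed: {failures[:5]}"
        )
    arr = np.array(samples)
    errors = {n: float(np.std(arr[:, i], ddof=1)) for i, n in enumerate(base.free)}
    return MonteCarloResult(
        errors=errors,
        n_cycles=n_cycles,
        n_failed=n_failed,
        seed=seed,
        samples={n: arr[:, i].tolist() for i, n in enumerate(base.free)}
        if keep_samples
        else None,
    )


def chi2_surface(
    result: FitResult,
    profiles: Iterable[DispersionProfile],
    param_name: str,
    grid,
    schema: FitSchema | None = None,
) -> ChiSquareSurface:
    """Reduced chi-square surface for one parameter by constrained refits.

    The probed parameter is fixed at each grid value while all other free
    parameters are re-optimized from the best-fit solution.  Values are
    normalized by the unconstrained fit's degrees of freedom so the surface
    at the optimum matches the unconstrained reduced chi-square.
    """
    profiles = list(profiles)
    schema = schema or FitSchema()
    if param_name not in result.params:
        raise ConfigurationError(f"{param_name!r} is not a free parameter of the fit")
    grid = np.asarray(grid, dtype=float)
    dof = max(result.ndata - result.nfree, 1)

    out = np.empty_like(grid)
    failed = np.zeros(grid.shape, dtype=bool)
    for i, gval in enumerate(grid):
        con = dataclasses.replace(
            schema, fixed={**schema.fixed, param_name: float(gval)}
        )
        obj = _Objective(profiles, con)
        lo = np.array([con.bound(n)[0] for n in obj.free])
        hi = np.array([con.bound(n)[1] for n in obj.free])
        x0 = np.array([result.params[n] for n in obj.free])
        try:
            res = _run_single(obj, x0, lo, hi, max_nfev=200 * max(len(obj.free), 1))
            out[i] = 2.0 * res.cost / dof
        except Exception as exc:  # noqa: BLE001 - flagged, surface still returned
            out[i] = np.nan
            failed[i] = True
    return ChiSquareSurface(
        param_name=param_name,
        grid=grid,
        chi2_nu=out,
        failed=failed,
        unconstrained_chi2_nu=result.chi2_nu,
    )
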