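"""Derived quantities and consistency checks on fitted exchange parameters.

Decomposition of the exchange rate into forward/backward rates, the
population-weighted shift expected when ligand binding locks the excited
conformation, binding free-energy differences from affinity fold changes,
chemical-shift perturbations and simple linear trend fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import NumericalFitError

__all__ = [
    "GAS_CONSTANT",
    "DerivedRates",
    "ShiftRecord",
    "TrendResult",
    "forward_backward_rates",
    "population_weighted_shift",
    "ddG_from_kd_ratio",
    "csp",
    "linear_trend",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class DerivedRates:
    """Forward/backward rates of the two-state equilibrium (s^-1)."""

    k_GS_ES: float
    k_ES_GS: float
    p_GS: float
    k_ex: float

    def rounded(self) -> "DerivedRates":
        """Integer-rounded copy (rates are conventionally printed as integers)."""
        return DerivedRates(
            round(self.k_GS_ES), round(self.k_ES_GS), self.p_GS, self.k_ex
        )


@dataclass(frozen=True)
class ShiftRecord:
    """Chemical shifts (p.p.m.) per probe and nucleus under one condition."""

    condition: str
    shifts: dict  # probe_id -> {nucleus: shift}

    def probes(self):
        return set(self.shifts)


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    r: float
    slope_err: float
    degenerate_y: bool = False


def forward_backward_rates(p_GS: float, k_ex: float) -> DerivedRates:
    """Split k_ex into k_GS_ES = (1 - p_GS) k_ex and k_ES_GS = p_GS k_ex."""
    if not 0.0 <= p_GS <= 1.0:
        raise ValueError(f"p_GS must lie in [0, 1], got {p_GS}")
    if k_ex < 0:
        raise ValueError("k_ex must be >= 0")
    return DerivedRates(
        k_GS_ES=(1.0 - p_GS) * k_ex,
        k_ES_GS=p_GS * k_ex,
        p_GS=p_GS,
        k_ex=k_ex,
    )


def population_weighted_shift(p_GS: float, abs_dw: float) -> float:
    """Expected apo->bound observed-shift change p_GS * |dw| (p.p.m.).

    When binding locks the exchanging site in the excited conformation, the
    averaged apo peak (offset p_ES |dw| from the ground state) moves the
    remaining p_GS |dw| to the pure excited-state position.
    """
    if not 0.0 <= p_GS <= 1.0:
        raise ValueError(f"p_GS must lie in [0, 1], got {p_GS}")
    return p_GS * abs(abs_dw)


def ddG_from_kd_ratio(fold_change: float, T: float = 298.0) -> float:
    """Binding free-energy penalty R T ln(fold_change) in kJ/mol.

    ``fold_change`` is the factor by which the dissociation constant
    increases; T defaults to room temperature (298 K).
    """
    if fold_change < 1.0:
        raise ValueError("fold_change must be >= 1 (a K_D increase)")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT * T * np.log(fold_change) / 1000.0


def csp(shift_a: ShiftRecord, shift_b: ShiftRecord, nucleus: str,
        combined: bool = False, combine_weights: dict | None = None):
    """Per-probe chemical-shift perturbations |delta_b - delta_a| (p.p.m.).

    Returns ``(csps, skipped)`` where ``csps`` maps probe_id to |CSP| and
    ``skipped`` lists probes missing from either record or lacking the
    nucleus.  With ``combined=True`` a weighted root-sum-square over all
    common nuclei is computed instead (weights default to 1 for 1H and 0.25
    for 13C); the plain single-nucleus difference is the default.
    """
    weights = {"1H": 1.0, "13C": 0.25}
    if combine_weights:
        weights.update(combine_weights)
    csps = {}
    skipped = []
    for probe in sorted(shift_a.probes() | shift_b.probes()):
        a = shift_a.shifts.get(probe)
        b = shift_b.shifts.get(probe)
        if a is None or b is None:
            skipped.append(probe)
            continue
        if combined:
            common = set(a) & set(b)
            if not common:
                skipped.append(probe)
                continue
            csps[probe] = float(np.sqrt(sum(
                (weights.get(n, 1.0) * (b[n] - a[n])) ** 2 for n in common
            )))
        else:
            if nucleus not in a or nucleus not in b:
                skipped.append(probe)
                continue
            csps[probe] = abs(b[nucleus] - a[nucleus])
    return csps, skipped


def linear_trend(x, y, sigma_y=None) -> TrendResult:
    """Weighted (or plain) least-squares line with Pearson correlation.

    Degenerate x (zero variance) raises; constant y returns slope 0 with the
    correlation flagged as undefined (``r = nan``, ``degenerate_y = True``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend fit")
    if np.ptp(x) == 0:
        raise NumericalFitError("x has zero variance; slope undefined")
    if np.ptp(y) == 0:
        return TrendResult(0.0, float(y[0]), float("nan"), 0.0, degenerate_y=True)
    if sigma_y is None:
        res = stats.linregress(x, y)
        return TrendResult(
            float(res.slope), float(res.intercept), float(res.rvalue),
            float(res.stderr),
        )
    sigma_y = np.asarray(sigma_y, dtype=float)
    w = 1.0 / sigma_y**2
    (slope, intercept), cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov="unscaled")
    r = float(np.corrcoef(x, y)[0, 1])
    return TrendResult(float(slope), float(intercept), r, float(np.sqrt(cov[0, 0])))
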