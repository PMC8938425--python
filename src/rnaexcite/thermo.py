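"""Exchange-parameter algebra, Boltzmann populations, Eyring conversions
and the modified van't Hoff fit.

The central object is the temperature dependence of the forward and
backward rate constants of a two-state GS <-> ES reaction,

    ln(k_i / T) = ln(kappa kB / h) - dG_i(Thm) / (R Thm)
                  - (dH_i / R) (1/T - 1/Thm),

a weighted linear fit of which yields the activation free energy at the
harmonic-mean temperature Thm and the activation enthalpy for each
direction; entropies follow from T dS = dH - dG, and net GS -> ES
quantities are forward minus backward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .exchange import ExchangeParams

__all__ = [
    "RateSeries",
    "VantHoffResult",
    "exchange_algebra",
    "pop_from_dG",
    "dG_from_pop",
    "eyring_rate",
    "eyring_dG",
    "harmonic_mean_T",
    "vant_hoff_fit",
]


def exchange_algebra(
    kex: float | None = None,
    pES: float | None = None,
    k1: float | None = None,
    kminus1: float | None = None,
    rtol: float = 1e-6,
) -> ExchangeParams:
    """Complete the two-state rate algebra from any sufficient pair of
    (kex, pES, k1, kminus1).

    Over-specified inputs are cross-checked: an inconsistency above
    ``rtol`` (relative) raises.  Lifetimes are available on the result as
    ``tau_GS`` (= 1/k1) and ``tau_ES`` (= 1/kminus1).
    """
    given = {
        k: v
        for k, v in {"kex": kex, "pES": pES, "k1": k1, "kminus1": kminus1}.items()
        if v is not None
    }
    if len(given) < 2:
        raise ValueError("need at least two of kex, pES, k1, kminus1")

    if kex is not None and pES is not None:
        params = ExchangeParams.from_populations(pES, kex)
    elif k1 is not None and kminus1 is not None:
        params = ExchangeParams.from_rates(k1, kminus1)
    elif k1 is not None and kex is not None:
        params = ExchangeParams.from_rates(k1, kex - k1)
    elif kminus1 is not None and kex is not None:
        params = ExchangeParams.from_rates(kex - kminus1, kminus1)
    elif k1 is not None and pES is not None:
        if not 0 < pES < 1:
            raise ValueError("pES must be in (0, 1)")
        params = ExchangeParams.from_rates(k1, k1 * (1.0 - pES) / pES)
    elif kminus1 is not None and pES is not None:
        params = ExchangeParams.from_rates(kminus1 * pES / (1.0 - pES), kminus1)
    else:  # pragma: no cover
        raise ValueError("unsupported combination")

    derived = {
        "kex": params.kex,
        "pES": params.pES,
        "k1": params.k1,
        "kminus1": params.kminus1,
    }
    for name, value in given.items():
        ref = derived[name]
        if abs(value - ref) > rtol * max(abs(ref), 1e-300):
            raise ValueError(
                f"inconsistent over-specified input: {name}={value} but the "
                f"remaining inputs imply {name}={ref}"
            )
    return params


def pop_from_dG(
    ddG: float, T: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Boltzmann ES population from the GS->ES free-energy gap (kcal/mol):
    pES = exp(-ddG/RT) / (1 + exp(-ddG/RT))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    x = math.exp(-ddG / (constants.R * T))
    return x / (1.0 + x)


def dG_from_pop(
    pES: float, T: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Inverse of :func:`pop_from_dG` (exact)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not 0 < pES < 1:
        raise ValueError("pES must be in (0, 1)")
    return -constants.R * T * math.log(pES / (1.0 - pES))


def eyring_rate(
    dG_act: float, T: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Transition-state-theory rate k = kappa (kB T / h) exp(-dG/RT)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return constants.attempt_frequency(T) * math.exp(-dG_act / (constants.R * T))


def eyring_dG(
    k: float, T: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Exact inverse of :func:`eyring_rate`."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if k <= 0:
        raise ValueError("rate must be positive")
    return constants.R * T * math.log(constants.attempt_frequency(T) / k)


def harmonic_mean_T(temps) -> float:
    """Harmonic mean n / sum(1/Ti) of Kelvin temperatures."""
    t = np.asarray(temps, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one temperature")
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    return float(t.size / np.sum(1.0 / t))


@dataclass
class RateSeries:
    """Forward/backward rate constants across temperatures (Kelvin)."""

    temperatures: np.ndarray
    k1_values: np.ndarray
    kminus1_values: np.ndarray
    k1_errors: np.ndarray | None = None
    kminus1_errors: np.ndarray | None = None
    construct: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.k1_values = np.asarray(self.k1_values, dtype=float)
        self.kminus1_values = np.asarray(self.kminus1_values, dtype=float)
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive Kelvin")
        n = self.temperatures.size
        if self.k1_values.size != n or self.kminus1_values.size != n:
            raise ValueError("rate arrays must match temperatures")
        for name in ("k1_errors", "kminus1_errors"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n or np.any(v <= 0):
                    raise ValueError(f"{name} must be positive and match length")
                setattr(self, name, v)

    @property
    def n_distinct_T(self) -> int:
        return int(np.unique(self.temperatures).size)


@dataclass(frozen=True)
class VantHoffResult:
    """Activation and net thermodynamics at the harmonic-mean temperature.

    All energies kcal/mol; TdS terms are evaluated at T_hm, so
    TdS = dH - dG holds for each direction and net = forward - backward.
    ``zero_dof`` marks a two-temperature fit (exactly determined, no
    residual degrees of freedom).
    """

    T_hm: float
    dG_act_fwd: float
    dH_act_fwd: float
    TdS_act_fwd: float
    dG_act_bwd: float
    dH_act_bwd: float
    TdS_act_bwd: float
    dG_net: float
    dH_net: float
    TdS_net: float
    zero_dof: bool = False


def _fit_direction(T, k, kerr, Thm, constants):
    x = 1.0 / T - 1.0 / Thm
    y = np.log(k / T)
    if kerr is not None:
        w = (k / kerr) ** 2  # sigma(ln k) ~ kerr / k
    else:
        w = np.ones_like(y)
    # weighted linear fit y = a + b x
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    if sxx <= 0:
        raise ValueError("singular design: need at least two distinct temperatures")
    b = np.sum(w * (x - xb) * (y - yb)) / sxx
    a = yb - b * xb
    dH = -b * constants.R
    dG = constants.R * Thm * (
        math.log(constants.kappa * constants.kB / constants.h) - a
    )
    return float(dG), float(dH)


def vant_hoff_fit(
    series: RateSeries, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> VantHoffResult:
    """Fit both rate directions to the modified van't Hoff equation.

    The fit of ln(k/T) against (1/T - 1/Thm) is weighted by
    sigma(ln k) ~ sigma_k / k when rate errors are given, unweighted
    otherwise.  Requires >= 2 distinct temperatures; exactly 2 gives a
    zero-degrees-of-freedom fit flagged via ``zero_dof``.
    """
    if series.n_distinct_T < 2:
        raise ValueError("need rates at >= 2 distinct temperatures")
    Thm = harmonic_mean_T(series.temperatures)
    dG_f, dH_f = _fit_direction(
        series.temperatures, series.k1_values, series.k1_errors, Thm, constants
    )
    dG_b, dH_b = _fit_direction(
        series.temperatures,
        series.kminus1_values,
        series.kminus1_errors,
        Thm,
        constants,
    )
    return VantHoffResult(
        T_hm=Thm,
        dG_act_fwd=dG_f,
        dH_act_fwd=dH_f,
        TdS_act_fwd=dH_f - dG_f,
        dG_act_bwd=dG_b,
        dH_act_bwd=dH_b,
        TdS_act_bwd=dH_b - dG_b,
        dG_net=dG_f - dG_b,
        dH_net=dH_f - dH_b,
        TdS_net=(dH_f - dG_f) - (dH_b - dG_b),
        zero_dof=series.n_distinct_T == 2,
    )


def vant_hoff_rate(
    dG_Thm: float,
    dH: float,
    T: float,
    Thm: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Rate constant at temperature T implied by the modified van't Hoff
    parameters (dG at Thm, dH); the inverse of :func:`vant_hoff_fit` used
    by the synthetic rate generator."""
    ln_k_over_T = (
        math.log(constants.kappa * constants.kB / constants.h)
        - dG_Thm / (constants.R * Thm)
        - dH / constants.R * (1.0 / T - 1.0 / Thm)
    )
    return T * math.exp(ln_k_over_T)
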