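"""Physical constants and unit helpers.

All free energies are in kcal/mol, rates in s^-1, temperatures in Kelvin
unless a function says otherwise.  File readers accept Celsius and convert
at the boundary; the model layer is Kelvin-only.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL_MOL_K = 1.98720425864e-3

#: Boltzmann constant, J K^-1 (CODATA 2018, exact).
KB_J_K = 1.380649e-23

#: Planck constant, J s (CODATA 2018, exact).
H_J_S = 6.62607015e-34

CELSIUS_OFFSET = 273.15

#: Larmor-frequency ratio gamma(X)/gamma(1H) by imino nucleus kind.
#: Used to derive the 15N (N1/N3) or 1H (H1/H3) Larmor frequency from the
#: spectrometer 1H frequency.  Magnitudes only; sign conventions are
#: irrelevant for shift conversions.
GYROMAGNETIC_RATIO_TO_H1 = {
    "H1": 1.0,
    "H3": 1.0,
    "N1": 0.10136767,
    "N3": 0.10136767,
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering transition-state-theory expressions.

    kappa is the transmission coefficient of the Eyring prefactor
    (dimensionless, assumed 1 by default).
    """

    R: float = R_KCAL_MOL_K
    kB: float = KB_J_K
    h: float = H_J_S
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.kappa <= 1.0):
            raise ValueError(f"kappa must be in (0, 1], got {self.kappa}")

    def attempt_frequency(self, T: float) -> float:
        """Eyring prefactor kappa*kB*T/h in s^-1."""
        return self.kappa * self.kB * T / self.h


DEFAULT_CONSTANTS = PhysicalConstants()


def celsius_to_kelvin(t_celsius):
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin):
    return t_kelvin - CELSIUS_OFFSET


def larmor_mhz(field_h1_MHz: float, nucleus: str) -> float:
    """Larmor frequency (MHz) of an imino nucleus on a spectrometer whose
    1H frequency is ``field_h1_MHz``."""
    try:
        ratio = GYROMAGNETIC_RATIO_TO_H1[nucleus]
    except KeyError:
        raise ValueError(
            f"unknown nucleus {nucleus!r}; expected one of "
            f"{sorted(GYROMAGNETIC_RATIO_TO_H1)}"
        ) from None
    return field_h1_MHz * ratio
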