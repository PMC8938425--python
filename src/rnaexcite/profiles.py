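"""Measured or simulated dispersion-data containers.

These are the in-memory forms of the TSV schemas in :mod:`rnaexcite.io`:
an :class:`R1rhoProfile` holds one probe's spin-lock series (either raw
peak-intensity decays or pre-fit R1rho values), a :class:`CESTProfile`
holds one saturation scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exchange import CESTSetting, SpinProbe


@dataclass
class R1rhoProfile:
    """Rotating-frame relaxation data for one probe.

    Per spin-lock setting, either peak-intensity decays (delays /
    intensities / errors, >= 3 delays each) or pre-fit R1rho values with
    standard deviations must be present.
    """

    probe: SpinProbe
    settings: list
    delays: list | None = None
    intensities: list | None = None
    errors: list | None = None
    r1rho: np.ndarray | None = None
    r1rho_err: np.ndarray | None = None
    construct: str = ""

    def __post_init__(self) -> None:
        n = len(self.settings)
        if self.intensities is not None:
            if self.delays is None or self.errors is None:
                raise ValueError("intensities require delays and errors")
            if not (len(self.delays) == len(self.intensities) == len(self.errors) == n):
                raise ValueError("per-setting lists must match settings length")
            for d, e in zip(self.delays, self.errors):
                if len(np.atleast_1d(d)) < 3:
                    raise ValueError("each setting needs >= 3 delays")
                if np.any(np.atleast_1d(e) <= 0):
                    raise ValueError("intensity errors must be positive")
        if self.r1rho is not None:
            self.r1rho = np.asarray(self.r1rho, dtype=float)
            if self.r1rho.size != n:
                raise ValueError("r1rho length must match settings")
            if self.r1rho_err is not None:
                self.r1rho_err = np.asarray(self.r1rho_err, dtype=float)
                if np.any(self.r1rho_err <= 0):
                    raise ValueError("r1rho errors must be positive")
        if self.intensities is None and self.r1rho is None:
            raise ValueError("profile needs intensities or pre-fit r1rho values")

    @property
    def has_intensities(self) -> bool:
        return self.intensities is not None

    def powers_Hz(self) -> np.ndarray:
        return np.array([s.power_Hz for s in self.settings])

    def offsets_Hz(self) -> np.ndarray:
        return np.array([s.offset_Hz for s in self.settings])


@dataclass
class CESTProfile:
    """One normalised saturation profile (alpha/beta spin-state component
    or their difference) on the carrier grid of its setting."""

    probe: SpinProbe
    setting: CESTSetting
    component: str
    intensity: np.ndarray
    reference_intensity: float = 1.0
    construct: str = ""

    def __post_init__(self) -> None:
        if self.component not in {"alpha", "beta", "difference"}:
            raise ValueError("component must be alpha, beta or difference")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.size != self.setting.grid.size:
            raise ValueError("intensity length must match carrier grid")

    @property
    def baseline_ok(self) -> bool:
        """Baseline (outer 10% of carriers on each side) within [0.9, 1.1]
        after normalisation.  Difference profiles sit near zero instead."""
        if self.component == "difference":
            return True
        k = max(1, self.intensity.size // 10)
        edges = np.concatenate([self.intensity[:k], self.intensity[-k:]])
        return bool(np.all((edges > 0.9) & (edges < 1.1)))
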