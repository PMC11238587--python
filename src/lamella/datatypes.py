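"""Shared lightweight containers used across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum1D",
    "SLDProfile",
    "StructureFactorSet",
    "ContrastSeries",
    "ATOMIC_MASS",
    "COHERENT_B",
]

# Atomic masses (u) and bound coherent neutron scattering lengths (fm) for
# the elements occurring in stratum-corneum lipid systems.  Deuterium is a
# first-class "element" here because H->D substitution is the whole point
# of the contrast experiments: b(H) is negative, b(D) positive.
ATOMIC_MASS = {"H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
               "S": 32.06, "P": 30.974}
COHERENT_B = {"H": -3.7390, "D": 6.671, "C": 6.6460, "N": 9.36, "O": 5.803,
              "S": 2.847, "P": 5.13}


@dataclass
class Spectrum1D:
    """Generic (x, y) series: I(q) patterns or FTIR absorbance.

    ``x_unit``/``y_unit`` are free-text metadata carried through I/O.
    """

    x: np.ndarray
    y: np.ndarray
    x_unit: str = ""
    y_unit: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")


@dataclass
class StructureFactorSet:
    """Bragg structure factors of a lamellar phase.

    ``F_abs`` are non-negative amplitudes per diffraction order; ``signs``
    are the phase signs (+1/-1) once determined, or None while unsigned.
    ``F0`` is the zero-order term (mean scattering density per unit volume).
    """

    d: float
    orders: np.ndarray
    F_abs: np.ndarray
    signs: np.ndarray | None = None
    F0: float = 0.0

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=int)
        self.F_abs = np.asarray(self.F_abs, dtype=float)
        if self.signs is not None:
            self.signs = np.asarray(self.signs, dtype=int)
            if self.signs.shape != self.orders.shape:
                raise ValueError("signs and orders length mismatch")
            if not np.all(np.isin(self.signs, (-1, 1))):
                raise ValueError("signs must be -1 or +1")
        if self.F_abs.shape != self.orders.shape:
            raise ValueError("F_abs and orders length mismatch")
        if np.any(self.F_abs < 0):
            raise ValueError("F_abs must be non-negative")
        if self.d <= 0:
            raise ValueError("repeat distance d must be positive")

    @property
    def signed_F(self) -> np.ndarray:
        if self.signs is None:
            raise ValueError("structure factors are unsigned; phase them first")
        return self.signs * self.F_abs


@dataclass
class ContrastSeries:
    """Unsigned structure-factor sets measured at several D2O fractions."""

    d2o_fractions: np.ndarray
    sets: list[StructureFactorSet]

    def __post_init__(self) -> None:
        self.d2o_fractions = np.asarray(self.d2o_fractions, dtype=float)
        if len(self.sets) != self.d2o_fractions.size:
            raise ValueError("one StructureFactorSet per contrast required")
        if np.any((self.d2o_fractions < 0) | (self.d2o_fractions > 1)):
            raise ValueError("D2O fractions must lie in [0, 1]")
        if np.unique(self.d2o_fractions).size < 2:
            raise ValueError("phasing needs at least two distinct contrasts")
        orders0 = self.sets[0].orders
        for s in self.sets:
            if not np.array_equal(s.orders, orders0):
                raise ValueError("all contrasts must report the same orders")


@dataclass
class SLDProfile:
    """Scattering-length-density profile across one unit cell.

    x = 0 is the unit-cell center; x spans [-d/2, d/2] on a uniform grid.
    ``scale_tag`` records the calibration state of rho.
    """

    x: np.ndarray
    rho: np.ndarray
    d: float
    scale_tag: str = "arbitrary"  # arbitrary | relative_absolute | scaled_0_100
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.x.shape != self.rho.shape or self.x.ndim != 1:
            raise ValueError("x and rho must be 1D arrays of equal length")
        if self.x.size > 1:
            # tolerance admits text round trips at ~12 significant digits
            steps = np.diff(self.x)
            if not np.allclose(steps, steps[0], rtol=1e-6,
                               atol=1e-9 * max(abs(self.d), 1.0)):
                raise ValueError("profile grid must be uniform")

    def same_grid(self, other: "SLDProfile", rtol: float = 1e-9) -> bool:
        return (self.x.size == other.x.size
                and np.isclose(self.d, other.d, rtol=rtol)
                and np.allclose(self.x, other.x, rtol=rtol, atol=1e-12))
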