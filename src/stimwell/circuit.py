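"""Equivalent-circuit model of parallel-plate stimulation wells.

A single well is a Randles-type cell: the electrode--electrolyte interface is
a double-layer capacitance ``C_dl`` (or a constant phase element, CPE) in
parallel with a faradaic charge-transfer resistance ``R_f``, in series with
the electrolyte bulk resistance ``R_e``.  Multi-well devices compose N
identical wells in parallel (voltage-controlled stimulation) or in series
(current-controlled stimulation).

Sign convention is the engineering one: capacitive impedance carries a
negative imaginary part, with angular frequency ``w = 2*pi*f``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

__all__ = [
    "Wiring",
    "CPEParams",
    "WellParams",
    "DeviceModel",
    "cpe_impedance",
    "well_impedance",
    "device_impedance",
    "simplified_equivalent",
    "time_constant",
    "cpe_to_cdl",
]


class Wiring(str, enum.Enum):
    """How the wells of a device are interconnected.

    Voltage-controlled devices wire wells in parallel (same voltage on every
    well); current-controlled devices wire them in series (same current
    through every well).
    """

    PARALLEL = "parallel"
    SERIES = "series"


@dataclass(frozen=True)
class CPEParams:
    """Constant phase element, Z = 1 / (q_mag * (j*2*pi*f)**n_exp).

    Parameters
    ----------
    q_mag : float
        CPE magnitude, S*s^n.  Equals the capacitance in farads when
        ``n_exp == 1``.
    n_exp : float
        Dimensionless exponent, 0 < n_exp <= 1.  ``n_exp = 1`` is an ideal
        capacitor; values below 1 model a distribution of interfacial time
        constants.
    """

    q_mag: float
    n_exp: float = 1.0

    def __post_init__(self) -> None:
        if not self.q_mag > 0:
            raise ValueError(f"q_mag must be positive, got {self.q_mag}")
        if not 0 < self.n_exp <= 1:
            raise ValueError(f"n_exp must lie in (0, 1], got {self.n_exp}")


@dataclass(frozen=True)
class WellParams:
    """Circuit parameters of a single stimulation well.

    At least one of ``c_dl`` (ideal capacitor, farads) or ``cpe`` must be
    given.  ``r_f`` is the faradaic charge-transfer resistance and ``r_e``
    the electrolyte resistance, both in ohms.
    """

    r_f: float
    r_e: float
    c_dl: float | None = None
    cpe: CPEParams | None = None

    def __post_init__(self) -> None:
        if not self.r_f > 0:
            raise ValueError(f"r_f must be positive, got {self.r_f}")
        if not self.r_e > 0:
            raise ValueError(f"r_e must be positive, got {self.r_e}")
        if self.c_dl is None and self.cpe is None:
            raise ValueError("one of c_dl or cpe must be provided")
        if self.c_dl is not None and not self.c_dl > 0:
            raise ValueError(f"c_dl must be positive, got {self.c_dl}")

    @property
    def interface(self) -> CPEParams:
        """The interfacial element as a CPE (ideal C has n_exp = 1)."""
        if self.cpe is not None:
            return self.cpe
        return CPEParams(q_mag=float(self.c_dl), n_exp=1.0)

    def effective_cdl(self, formula: str = "brug") -> float:
        """Double-layer capacitance in farads, converting a CPE if needed."""
        if self.c_dl is not None:
            return float(self.c_dl)
        return cpe_to_cdl(self.cpe, self.r_e, self.r_f, formula=formula)


@dataclass(frozen=True)
class DeviceModel:
    """N identical wells plus wiring mode and electrode spacing.

    ``spacing_d_mm`` is the parallel-plate electrode gap in millimetres
    (10 mm for the 8-well micro-dish geometry), used for field dosimetry.
    """

    well: WellParams
    n_wells: int = 1
    wiring: Wiring = Wiring.PARALLEL
    spacing_d_mm: float = 10.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_wells, (int, np.integer)) and self.n_wells >= 1):
            raise ValueError(f"n_wells must be an integer >= 1, got {self.n_wells}")
        if not self.spacing_d_mm > 0:
            raise ValueError(f"spacing_d_mm must be positive, got {self.spacing_d_mm}")
        object.__setattr__(self, "wiring", Wiring(self.wiring))


def _check_freq(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be strictly positive")
    return f


def cpe_impedance(cpe: CPEParams, f) -> Union[complex, np.ndarray]:
    """Impedance of a constant phase element at frequency ``f`` (Hz).

    Z = 1 / (q_mag * (j*2*pi*f)**n_exp); for n_exp = 1 this is the ideal
    capacitor 1/(j*2*pi*f*C).  The phase is constant at -n_exp*90 degrees.
    """
    f = _check_freq(f)
    jw = 1j * 2.0 * np.pi * f
    z = 1.0 / (cpe.q_mag * jw**cpe.n_exp)
    if z.ndim == 0:
        return complex(z)
    return z


def well_impedance(well: WellParams, f) -> Union[complex, np.ndarray]:
    """Impedance of one well: R_e in series with (R_f parallel interface)."""
    f = _check_freq(f)
    z_int = cpe_impedance(well.interface, f)
    z = well.r_e + (well.r_f * z_int) / (well.r_f + z_int)
    if np.ndim(z) == 0:
        return complex(z)
    return z


def device_impedance(device: DeviceModel, f) -> Union[complex, np.ndarray]:
    """Impedance of the N-well device under the identical-wells assumption.

    Parallel wiring divides the single-well impedance by N; series wiring
    multiplies it by N.
    """
    z = well_impedance(device.well, f)
    if device.wiring is Wiring.PARALLEL:
        return z / device.n_wells
    return z * device.n_wells


def simplified_equivalent(device: DeviceModel, cdl_formula: str = "brug") -> WellParams:
    """Lump the N-well device into a single Randles cell.

    Parallel: {C*N, R_f/N, R_e/N}; series: {C/N, R_f*N, R_e*N}.  The lumped
    model reproduces ``device_impedance`` exactly at every frequency.  Wells
    described by a CPE with n_exp < 1 are first converted to an effective
    C_dl (the lumped cell is then an ideal-capacitor approximation).
    """
    well = device.well
    n = device.n_wells
    if n == 1:
        return well
    c = well.effective_cdl(formula=cdl_formula)
    if device.wiring is Wiring.PARALLEL:
        return WellParams(c_dl=c * n, r_f=well.r_f / n, r_e=well.r_e / n)
    return WellParams(c_dl=c / n, r_f=well.r_f * n, r_e=well.r_e * n)


def time_constant(well: WellParams, cdl_formula: str = "brug") -> float:
    """Interface time constant tau = R_e * C_dl, in seconds.

    Governs the delivered-current decay in voltage-controlled mode and the
    electrode-voltage build-up in current-controlled mode.
    """
    return well.r_e * well.effective_cdl(formula=cdl_formula)


def cpe_to_cdl(
    cpe: CPEParams, r_e: float, r_f: float, formula: str = "brug"
) -> float:
    """Effective double-layer capacitance of a CPE, in farads.

    ``formula="brug"`` (default) uses the Brug expression for
    surface-distributed time constants with a series electrolyte resistance:

        C_dl = q**(1/n) * (1/R_e + 1/R_f)**((n - 1)/n)

    ``formula="hsu-mansfeld"`` uses the Hsu--Mansfeld variant based on the
    characteristic frequency of the parallel R_f--CPE arc:

        C_dl = q**(1/n) * R_f**((1 - n)/n)

    Both reduce to ``q_mag`` exactly when n = 1.
    """
    if cpe.n_exp <= 0:
        raise ValueError("n_exp must be positive")
    q, n = cpe.q_mag, cpe.n_exp
    if formula == "brug":
        return q ** (1.0 / n) * (1.0 / r_e + 1.0 / r_f) ** ((n - 1.0) / n)
    if formula == "hsu-mansfeld":
        return q ** (1.0 / n) * r_f ** ((1.0 - n) / n)
    raise ValueError(f"unknown CPE conversion formula: {formula!r}")
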