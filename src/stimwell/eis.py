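"""EIS spectrum simulation, equivalent-circuit fitting and life-cycle QC.

Spectra are fitted to a Randles-type cell (R_e in series with R_f parallel
to a CPE) by complex nonlinear least squares with modulus weighting, the
standard choice for spectra whose impedance spans orders of magnitude.  The
fitted CPE is converted to an effective double-layer capacitance so devices
can be compared on (C_dl, R_f) across uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
from scipy import stats

from .circuit import (
    CPEParams,
    DeviceModel,
    WellParams,
    cpe_to_cdl,
    device_impedance,
    well_impedance,
)

__all__ = [
    "ImpedanceSpectrum",
    "FitResult",
    "QCReport",
    "default_frequency_grid",
    "simulate_spectrum",
    "bode_transform",
    "fit_spectrum",
    "lifecycle_qc",
]

#: Measurement band used throughout: 10 mHz to 100 kHz.
FREQ_MIN_HZ = 1e-2
FREQ_MAX_HZ = 1e5


@dataclass
class ImpedanceSpectrum:
    """A measured or simulated impedance spectrum.

    ``freqs`` (Hz, strictly monotonic), ``z_real`` (Z', ohm) and ``z_imag``
    (Z'', ohm) have equal length >= 3.  ``meta`` carries free-form
    provenance (device id, use count, temperature, electrolyte ...).
    """

    freqs: np.ndarray
    z_real: np.ndarray
    z_imag: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.z_real = np.asarray(self.z_real, dtype=float)
        self.z_imag = np.asarray(self.z_imag, dtype=float)
        n = len(self.freqs)
        if not (len(self.z_real) == len(self.z_imag) == n):
            raise ValueError("freqs, z_real, z_imag must have equal length")
        if n < 3:
            raise ValueError("a spectrum needs at least 3 points")
        df = np.diff(self.freqs)
        if not (np.all(df > 0) or np.all(df < 0)):
            raise ValueError("freqs must be strictly monotonic")
        if np.any(self.freqs <= 0):
            raise ValueError("frequencies must be positive")

    @property
    def z(self) -> np.ndarray:
        """Complex impedance array Z' + j*Z''."""
        return self.z_real + 1j * self.z_imag


@dataclass
class FitResult:
    """Outcome of an equivalent-circuit fit.

    ``params`` holds the fitted Randles cell (with CPE); ``c_dl_effective``
    is the CPE converted to farads; ``residual`` is the weighted complex sum
    of squares; ``stderr`` maps parameter names to 1-sigma uncertainties
    (NaN when unavailable).
    """

    params: WellParams
    c_dl_effective: float
    residual: float
    stderr: Mapping[str, float]
    converged: bool

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


@dataclass
class QCReport:
    """Life-cycle QC summary across use-count groups.

    ``groups`` maps group label -> dict with per-parameter mean, std, n and
    relative drift vs the 'New' group; ``pvalues`` holds the one-way
    group-test p-value per parameter; ``flag`` is 'pass' or 'inspect'.
    """

    groups: dict
    pvalues: dict
    max_drift: float
    flag: str
    drift_threshold: float
    alpha: float


def default_frequency_grid(n_points: int = 50) -> np.ndarray:
    """Log-spaced grid over the standard 10 mHz--100 kHz band."""
    return np.logspace(np.log10(FREQ_MIN_HZ), np.log10(FREQ_MAX_HZ), n_points)


def simulate_spectrum(
    model: WellParams | DeviceModel,
    freqs: np.ndarray | None = None,
    meta: dict | None = None,
) -> ImpedanceSpectrum:
    """Evaluate a circuit model on a frequency grid.

    With ``freqs=None`` the default 50-point log grid over 10 mHz--100 kHz
    is used, matching the standard potentiostat sweep.
    """
    if freqs is None:
        freqs = default_frequency_grid()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency grid is empty")
    if isinstance(model, DeviceModel):
        z = device_impedance(model, freqs)
    else:
        z = well_impedance(model, freqs)
    z = np.atleast_1d(z)
    return ImpedanceSpectrum(
        freqs=freqs, z_real=z.real, z_imag=z.imag, meta=dict(meta or {})
    )


def bode_transform(spectrum: ImpedanceSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Return (|Z| in ohms, phase in degrees) for Bode plotting."""
    mag = np.hypot(spectrum.z_real, spectrum.z_imag)
    phase = np.degrees(np.arctan2(spectrum.z_imag, spectrum.z_real))
    return mag, phase


def _randles_z(freqs, r_e, r_f, q, n):
    well = WellParams(r_e=r_e, r_f=r_f, cpe=CPEParams(q_mag=q, n_exp=n))
    return well_impedance(well, freqs)


def _fit_residual(params, freqs, z_data):
    z_model = _randles_z(
        freqs, params["r_e"].value, params["r_f"].value,
        params["q"].value, params["n"].value,
    )
    # modulus weighting: each point contributes its relative complex error
    w = np.abs(z_data)
    diff = (z_model - z_data) / w
    return np.concatenate([diff.real, diff.imag])


def fit_spectrum(
    spectrum: ImpedanceSpectrum,
    topology: str = "cpe_randles",
    cdl_formula: str = "brug",
) -> FitResult:
    """Fit a Randles-type equivalent circuit to a spectrum.

    ``topology="cpe_randles"`` fits {R_e, R_f, q, n}; ``"ideal_randles"``
    pins n = 1 and fits an ideal capacitor.  Starting values need no user
    input: R_e from Re(Z) at the highest frequency, R_e + R_f from Re(Z) at
    the lowest, q from |Z''| at mid-band with n = 0.9.

    Non-convergent fits return best-effort parameters with
    ``converged=False``.  A degenerate all-real spectrum triggers an R-only
    fit (q pinned tiny) with a warning.
    """
    if topology not in ("cpe_randles", "ideal_randles"):
        raise ValueError(f"unknown topology: {topology!r}")
    freqs = spectrum.freqs
    span = np.log10(freqs.max() / freqs.min())
    if span < 2:
        raise ValueError("spectrum must cover at least 2 decades of frequency")
    z = spectrum.z

    order = np.argsort(freqs)
    f_sorted, z_sorted = freqs[order], z[order]
    r_e0 = max(float(z_sorted.real[-1]), 1e-6)
    r_lo = float(z_sorted.real[0])
    r_f0 = max(r_lo - r_e0, 1e-3)
    degenerate = np.allclose(z.imag, 0.0, atol=1e-12 * max(1.0, np.abs(z).max()))

    mid = len(f_sorted) // 2
    zpp_mid = abs(float(z_sorted.imag[mid]))
    w_mid = 2 * np.pi * f_sorted[mid]
    n0 = 1.0 if topology == "ideal_randles" else 0.9
    q0 = 1.0 / (max(zpp_mid, 1e-12) * w_mid**n0)

    params = lmfit.Parameters()
    params.add("r_e", value=r_e0, min=1e-9)
    params.add("r_f", value=r_f0, min=1e-9)
    if degenerate:
        warnings.warn(
            "spectrum has no imaginary part; fitting resistances only",
            stacklevel=2,
        )
        params.add("q", value=1e-15, vary=False)
        params.add("n", value=1.0, vary=False)
    else:
        params.add("q", value=q0, min=1e-15)
        params.add(
            "n", value=n0, min=0.3, max=1.0, vary=(topology == "cpe_randles")
        )

    out = lmfit.minimize(
        _fit_residual, params, args=(freqs, z), method="leastsq", nan_policy="omit"
    )
    p = out.params
    cpe = CPEParams(q_mag=p["q"].value, n_exp=min(p["n"].value, 1.0))
    well = WellParams(r_e=p["r_e"].value, r_f=p["r_f"].value, cpe=cpe)
    c_eff = cpe_to_cdl(cpe, well.r_e, well.r_f, formula=cdl_formula)
    stderr = {
        name: (p[name].stderr if p[name].stderr is not None else float("nan"))
        for name in ("r_e", "r_f", "q", "n")
    }
    return FitResult(
        params=well,
        c_dl_effective=c_eff,
        residual=float(np.sum(out.residual**2)),
        stderr=stderr,
        converged=bool(out.success),
    )


def lifecycle_qc(
    fits: Mapping[str, Sequence[FitResult]],
    drift_threshold: float = 0.25,
    alpha: float = 0.05,
) -> QCReport:
    """Compare device parameters across use-count groups against 'New'.

    ``fits`` maps a use-count label (one of them must be ``"New"``) to the
    fit results of that group.  For each of C_dl and R_f the report gives
    per-group mean/std and relative drift vs the New group, a one-way
    fixed-effects group comparison (ANOVA) p-value, and an overall flag:
    'inspect' when any drift exceeds ``drift_threshold`` or a group test
    rejects at the family-wise level ``alpha`` (Bonferroni-shared across the
    two monitored parameters), otherwise 'pass'.
    """
    if "New" not in fits:
        raise ValueError("a group labelled 'New' is required as baseline")
    if len(fits) < 2:
        raise ValueError("need at least 2 groups")
    for label, group in fits.items():
        if len(group) < 2:
            raise ValueError(f"group {label!r} needs at least 2 fits")

    values = {
        label: {
            "c_dl": np.array([f.c_dl_effective for f in group]),
            "r_f": np.array([f.params.r_f for f in group]),
        }
        for label, group in fits.items()
    }
    report_groups: dict = {}
    max_drift = 0.0
    for label, vals in values.items():
        entry = {}
        for pname in ("c_dl", "r_f"):
            v = vals[pname]
            ref = float(np.mean(values["New"][pname]))
            drift = abs(float(np.mean(v)) - ref) / ref
            entry[pname] = {
                "mean": float(np.mean(v)),
                "std": float(np.std(v, ddof=1)),
                "n": int(len(v)),
                "drift_vs_new": drift,
            }
            if label != "New":
                max_drift = max(max_drift, drift)
        report_groups[label] = entry

    pvalues = {}
    for pname in ("c_dl", "r_f"):
        samples = [vals[pname] for vals in values.values()]
        pvalues[pname] = float(stats.f_oneway(*samples).pvalue)

    flag = "pass"
    alpha_each = alpha / len(pvalues)  # Bonferroni over the parameter family
    if max_drift > drift_threshold or any(p < alpha_each for p in pvalues.values()):
        flag = "inspect"
    return QCReport(
        groups=report_groups,
        pvalues=pvalues,
        max_drift=max_drift,
        flag=flag,
        drift_threshold=drift_threshold,
        alpha=alpha,
    )
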