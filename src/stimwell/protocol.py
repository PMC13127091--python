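"""Stimulation waveforms and transient simulation of well devices.

Voltage-controlled (VC) mode drives a parallel-wired device through the
source output impedance and the monitoring shunt; the delivered current
decays as the double layer charges.  Current-controlled (CC) mode forces a
commanded current through series-wired wells; the electrode voltage builds
up as the double layer accumulates charge.  Both modes reduce, per constant
waveform segment, to a first-order linear ODE in the double-layer voltage
``V_c``, which is integrated exactly by exponential stepping (no truncation
error for piecewise-constant pulse trains).

Per-well outputs follow the monitoring definitions: ``V_well = I_e*R_e + V_c``
is checked against the safe voltage window, ``V_e = I_e*R_e`` is the voltage
across the culture area, and ``|E_e| = V_e/d`` is the field the cells see.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circuit import DeviceModel, Wiring

__all__ = [
    "WaveShape",
    "SourceMode",
    "WaveformSpec",
    "SourceSpec",
    "MonitorSpec",
    "SimulationResult",
    "ChargeSummary",
    "pulse_width",
    "segmentize",
    "simulate_vc",
    "simulate_cc",
    "charge_summary",
    "field_magnitude",
]


class WaveShape(str, enum.Enum):
    DC = "dc"
    MONOPHASIC = "monophasic"
    BIPHASIC_SYMMETRIC = "biphasic_symmetric"
    BIPHASIC_ASYMMETRIC = "biphasic_asymmetric"
    CUSTOM_SEGMENTS = "custom_segments"


class SourceMode(str, enum.Enum):
    VOLTAGE_CONTROLLED = "voltage_controlled"
    CURRENT_CONTROLLED = "current_controlled"


_PULSED = (
    WaveShape.MONOPHASIC,
    WaveShape.BIPHASIC_SYMMETRIC,
    WaveShape.BIPHASIC_ASYMMETRIC,
)


@dataclass(frozen=True)
class WaveformSpec:
    """Applied stimulation signal.

    ``amplitude`` is in volts for VC protocols and amps for CC protocols.
    ``duty_percent`` is the fraction of the period at the active level (per
    phase for biphasic shapes).  For ``biphasic_asymmetric`` the second
    phase is described by ``amplitude2``/``duty_percent2`` (defaults give a
    charge-balanced half-amplitude, double-width counterphase).
    ``custom_segments`` is a list of (duration_s, level) pairs covering one
    period.
    """

    shape: WaveShape
    amplitude: float = 0.0
    frequency: float = 0.0
    duty_percent: float = 50.0
    offset: float = 0.0
    interphase_break: float = 0.0
    amplitude2: float | None = None
    duty_percent2: float | None = None
    custom_segments: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", WaveShape(self.shape))
        if self.shape in _PULSED:
            if not self.frequency > 0:
                raise ValueError("pulsed shapes require frequency > 0")
            if not 0 < self.duty_percent <= 100:
                raise ValueError("duty_percent must lie in (0, 100]")
        if self.interphase_break < 0:
            raise ValueError("interphase_break must be non-negative")
        if self.shape is WaveShape.CUSTOM_SEGMENTS:
            if not self.custom_segments:
                raise ValueError("custom_segments shape requires segments")
            for dur, _level in self.custom_segments:
                if not dur > 0:
                    raise ValueError("segment durations must be positive")


@dataclass(frozen=True)
class SourceSpec:
    """Signal source: regulation mode, output impedance, compliance limits.

    Most bench voltage sources present ``z_output = 50`` ohm, so the system
    is a voltage divider and the well voltage differs from the nominal
    setting -- which is why the monitoring circuit exists.
    """

    mode: SourceMode = SourceMode.VOLTAGE_CONTROLLED
    z_output: float = 50.0
    i_max: float | None = None
    v_max: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", SourceMode(self.mode))
        if self.z_output < 0:
            raise ValueError("z_output must be non-negative")
        if self.i_max is not None and not self.i_max > 0:
            raise ValueError("i_max must be positive when set")
        if self.v_max is not None and not self.v_max > 0:
            raise ValueError("v_max must be positive when set")


@dataclass(frozen=True)
class MonitorSpec:
    """Monitoring shunt resistor in the stimulation loop (default 50 ohm)."""

    r_m: float = 50.0

    def __post_init__(self) -> None:
        if not self.r_m > 0:
            raise ValueError("r_m must be positive")


@dataclass
class SimulationResult:
    """Sampled transient response of a device under a protocol.

    All arrays share the time grid ``t`` (seconds).  ``v_source`` is the
    applied source trace, ``v_well``/``i_e``/``v_e`` are per-well, ``e_mag``
    is the culture-area field in mV/mm and ``q_cum`` the running integral of
    ``i_e`` in coulombs (zero at t = 0).  ``meta`` records the device,
    wiring, monitor and any compliance violations.
    """

    t: np.ndarray
    v_source: np.ndarray
    v_well: np.ndarray
    i_e: np.ndarray
    v_e: np.ndarray
    e_mag: np.ndarray
    q_cum: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = (self.v_source, self.v_well, self.i_e, self.v_e, self.e_mag, self.q_cum)
        if any(len(a) != len(self.t) for a in arrays):
            raise ValueError("all traces must share the time grid")
        if abs(self.q_cum[0]) > 0:
            raise ValueError("cumulative charge must start at zero")

    @property
    def i_total(self) -> np.ndarray:
        """Current through the source/monitor loop (N*i_e in parallel wiring)."""
        n = self.meta.get("n_wells", 1)
        if self.meta.get("wiring") == Wiring.SERIES:
            return self.i_e
        return n * self.i_e


@dataclass
class ChargeSummary:
    """Per-pulse charge accounting.

    ``q_inj`` integrates the delivered current over each pulse-on interval;
    ``q_rec`` is minus the integral from pulse end to the next pulse start
    (the current is negative there as the double layer discharges);
    ``q_acc = q_inj - q_rec`` is the residual charge per pulse.
    """

    q_inj: np.ndarray
    q_rec: np.ndarray
    q_acc: np.ndarray
    boundaries: list
    q_total: float

    def __post_init__(self) -> None:
        if not np.allclose(self.q_acc, self.q_inj - self.q_rec, rtol=0, atol=0):
            raise ValueError("q_acc must equal q_inj - q_rec")


def pulse_width(frequency: float, duty_percent: float) -> float:
    """Pulse width in seconds: duty_percent / (100 * frequency)."""
    if frequency <= 0:
        raise ValueError("frequency must be positive; use the dc shape for f = 0")
    if not 0 < duty_percent <= 100:
        raise ValueError("duty_percent must lie in (0, 100]")
    return duty_percent / (100.0 * frequency)


def segmentize(waveform: WaveformSpec) -> list[tuple[float, float]]:
    """Break one waveform period into (duration_s, level) segments.

    Pulsed shapes return segments summing to one period ``1/frequency``;
    dc returns a single unbounded segment.  Levels include the offset.
    """
    off = waveform.offset
    if waveform.shape is WaveShape.DC:
        return [(math.inf, waveform.amplitude + off)]
    if waveform.shape is WaveShape.CUSTOM_SEGMENTS:
        return [(float(d), float(v) + off) for d, v in waveform.custom_segments]

    period = 1.0 / waveform.frequency
    pw = pulse_width(waveform.frequency, waveform.duty_percent)
    a = waveform.amplitude
    if waveform.shape is WaveShape.MONOPHASIC:
        segs = [(pw, a + off)]
        if period - pw > 0:
            segs.append((period - pw, off))
        return segs

    brk = waveform.interphase_break
    if waveform.shape is WaveShape.BIPHASIC_SYMMETRIC:
        a2, pw2 = -a, pw
    else:  # charge-balanced default: half amplitude, double width
        a2 = waveform.amplitude2 if waveform.amplitude2 is not None else -a / 2.0
        pw2 = (
            pulse_width(waveform.frequency, waveform.duty_percent2)
            if waveform.duty_percent2 is not None
            else 2.0 * pw
        )
    used = pw + brk + pw2
    if used > period * (1 + 1e-12):
        raise ValueError("phases plus break exceed one period")
    segs = [(pw, a + off)]
    if brk > 0:
        segs.append((brk, off))
    segs.append((pw2, a2 + off))
    rest = period - used
    if rest > 1e-15 * period:
        segs.append((rest, off))
    return segs


def _tile_segments(
    segments: Sequence[tuple[float, float]], duration: float
) -> list[tuple[float, float, float]]:
    """Absolute (t_start, t_end, level) covering [0, duration]."""
    out = []
    t = 0.0
    i = 0
    nseg = len(segments)
    while t < duration * (1.0 - 1e-12):
        dur, level = segments[i % nseg]
        end = min(t + dur, duration) if math.isfinite(dur) else duration
        out.append((t, end, level))
        t = t + dur if math.isfinite(dur) else duration
        i += 1
    return out


def _sample_exponential(
    tiles, t_grid, tau_of_level, vinf_of_level, vc0=0.0
):
    """Exact V_c(t) for piecewise-constant drive, sampled on t_grid.

    Within each tile V_c relaxes exponentially from its value at the tile
    start toward the tile's asymptote; tile-boundary states are propagated
    analytically, so the only error is floating-point round-off.  Also
    returns the exact running integrals of the drive level and of V_c
    (needed for round-off-free charge accounting).
    """
    vc = np.empty_like(t_grid)
    level_arr = np.empty_like(t_grid)
    cum_level = np.empty_like(t_grid)
    cum_vc = np.empty_like(t_grid)
    starts = np.array([t0 for t0, _, _ in tiles])
    dt_ref = t_grid[1] - t_grid[0] if len(t_grid) > 1 else 1.0
    # right-continuous: a sample at a boundary belongs to the new tile; the
    # small nudge absorbs floating-point noise in accumulated boundary times
    idx = np.searchsorted(starts[1:], t_grid + 1e-9 * dt_ref, side="right")
    state = vc0
    acc_level = 0.0  # running integral of the drive up to the tile start
    acc_vc = 0.0  # running integral of V_c up to the tile start
    for k, (t0, t1, level) in enumerate(tiles):
        tau = tau_of_level(level)
        vinf = vinf_of_level(level)
        mask = idx == k
        dt_local = np.maximum(t_grid[mask] - t0, 0.0)
        em1 = np.expm1(-dt_local / tau)
        # vinf + (state - vinf) e^{-dt/tau}, written via expm1 so huge
        # asymptotes (R_f -> inf limits) do not cancel catastrophically
        vc[mask] = state + (state - vinf) * em1
        level_arr[mask] = level
        cum_level[mask] = acc_level + level * dt_local
        # integral of V_c over the tile prefix:
        #   state*dt + (vinf - state) * g(dt, tau),  g = int (1 - e^{-u/tau})
        cum_vc[mask] = acc_vc + state * dt_local + (vinf - state) * _relax_integral(
            dt_local, tau
        )
        span = t1 - t0
        em1_full = math.expm1(-span / tau)
        acc_level += level * span
        acc_vc += state * span + (vinf - state) * _relax_integral(span, tau)
        state = state + (state - vinf) * em1_full
    return vc, level_arr, cum_level, cum_vc


def _relax_integral(delta, tau):
    """g(d) = integral_0^d (1 - e^{-u/tau}) du, series-protected for d << tau.

    The direct form d + tau*expm1(-d/tau) cancels catastrophically when
    d/tau is tiny (the R_f -> infinity limit), so a Taylor series takes over
    there: g = d^2/(2 tau) * (1 - x/3 + x^2/12), x = d/tau.
    """
    delta = np.asarray(delta, dtype=float)
    x = delta / tau
    direct = delta + tau * np.expm1(-x)
    with np.errstate(invalid="ignore"):
        series = delta * x / 2.0 * (1.0 - x / 3.0 + x * x / 12.0)
    out = np.where(x < 1e-4, series, direct)
    return float(out) if out.ndim == 0 else out


def _time_grid(duration: float, dt: float) -> np.ndarray:
    if not duration > 0 or not dt > 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    return np.arange(n + 1) * dt


def field_magnitude(i_e, r_e: float, d_mm: float) -> np.ndarray:
    """Culture-area field |E_e| in mV/mm from the delivered current.

    |E_e| = V_e / d with V_e = I_e * R_e; the factor 1000 converts volts to
    millivolts so that 1 V across 10 mm reads 100 mV/mm.
    """
    if not d_mm > 0:
        raise ValueError("electrode spacing must be positive")
    return np.asarray(i_e) * r_e * 1000.0 / d_mm


def simulate_vc(
    device: DeviceModel,
    source: SourceSpec,
    monitor: MonitorSpec | None,
    waveform: WaveformSpec,
    duration: float,
    dt: float,
    vc0: float = 0.0,
) -> SimulationResult:
    """Simulate a voltage-controlled protocol on a parallel-wired device.

    The loop equation is ``V_source = I_total*(z_output + r_m) + V_well``
    with ``I_total = N*I_e`` and per-well ``V_well = I_e*R_e + V_c``,
    ``C_dl*dV_c/dt = I_e - V_c/R_f``.  Segments are integrated exactly.
    Exceeding the source current compliance flags the result and warns but
    does not abort.
    """
    if device.wiring is not Wiring.PARALLEL:
        raise ValueError("voltage-controlled devices are wired in parallel")
    if source.mode is not SourceMode.VOLTAGE_CONTROLLED:
        raise ValueError("source.mode must be voltage_controlled")
    well = device.well
    n = device.n_wells
    c = well.effective_cdl()
    r_m = monitor.r_m if monitor is not None else 0.0
    # series resistance seen by one well: the shared loop drop scales by N
    r_s = n * (source.z_output + r_m) + well.r_e
    r_f = well.r_f
    tau = c * (r_s * r_f) / (r_s + r_f)

    t = _time_grid(duration, dt)
    tiles = _tile_segments(segmentize(waveform), float(t[-1]))
    vc, v_src, cum_v, cum_vc = _sample_exponential(
        tiles,
        t,
        tau_of_level=lambda L: tau,
        vinf_of_level=lambda L: L * r_f / (r_s + r_f),
        vc0=vc0,
    )
    i_e = (v_src - vc) / r_s
    v_well = i_e * well.r_e + vc
    v_e = i_e * well.r_e
    e_mag = field_magnitude(i_e, well.r_e, device.spacing_d_mm)
    # exact integral of i_e = (v_source - v_c)/r_s, no quadrature error
    q_cum = (cum_v - cum_vc) / r_s

    meta = {
        "mode": SourceMode.VOLTAGE_CONTROLLED,
        "n_wells": n,
        "wiring": device.wiring,
        "r_m_ohm": r_m,
        "z_output_ohm": source.z_output,
        "compliance_ok": True,
        "dt_s": dt,
    }
    if source.i_max is not None:
        i_tot_max = float(np.max(np.abs(n * i_e)))
        if i_tot_max > source.i_max:
            meta["compliance_ok"] = False
            meta["i_total_peak_a"] = i_tot_max
            warnings.warn(
                f"source current compliance exceeded: peak |I_total| = "
                f"{i_tot_max:.3g} A > i_max = {source.i_max:.3g} A",
                stacklevel=2,
            )
    return SimulationResult(
        t=t, v_source=v_src, v_well=v_well, i_e=i_e, v_e=v_e,
        e_mag=e_mag, q_cum=q_cum, meta=meta,
    )


def simulate_cc(
    device: DeviceModel,
    source: SourceSpec,
    waveform: WaveformSpec,
    duration: float,
    dt: float,
    monitor: MonitorSpec | None = None,
    vc0: float = 0.0,
) -> SimulationResult:
    """Simulate a current-controlled protocol on a series-wired device.

    The commanded current flows through every well; per-well
    ``C_dl*dV_c/dt = I_e - V_c/R_f`` and ``V_well = I_e*R_e + V_c``.  The
    total source voltage is ``N*V_well`` plus the monitor drop when a
    monitor is in the loop.  Exceeding the voltage compliance flags the
    result and warns but does not abort.
    """
    if device.wiring is not Wiring.SERIES:
        raise ValueError("current-controlled devices are wired in series")
    if source.mode is not SourceMode.CURRENT_CONTROLLED:
        raise ValueError("source.mode must be current_controlled")
    well = device.well
    n = device.n_wells
    c = well.effective_cdl()
    r_f = well.r_f
    tau = r_f * c

    t = _time_grid(duration, dt)
    tiles = _tile_segments(segmentize(waveform), float(t[-1]))
    vc, i_cmd, cum_i, _cum_vc = _sample_exponential(
        tiles,
        t,
        tau_of_level=lambda L: tau,
        vinf_of_level=lambda L: L * r_f,
        vc0=vc0,
    )
    i_e = i_cmd
    v_well = i_e * well.r_e + vc
    r_m = monitor.r_m if monitor is not None else 0.0
    v_src = n * v_well + i_e * r_m
    v_e = i_e * well.r_e
    e_mag = field_magnitude(i_e, well.r_e, device.spacing_d_mm)
    q_cum = cum_i  # the commanded current integrates exactly

    meta = {
        "mode": SourceMode.CURRENT_CONTROLLED,
        "n_wells": n,
        "wiring": device.wiring,
        "r_m_ohm": r_m,
        "compliance_ok": True,
        "dt_s": dt,
    }
    if source.v_max is not None:
        v_peak = float(np.max(np.abs(v_src)))
        if v_peak > source.v_max:
            meta["compliance_ok"] = False
            meta["v_source_peak_v"] = v_peak
            warnings.warn(
                f"source voltage compliance exceeded: peak |V_source| = "
                f"{v_peak:.3g} V > v_max = {source.v_max:.3g} V",
                stacklevel=2,
            )
    return SimulationResult(
        t=t, v_source=v_src, v_well=v_well, i_e=i_e, v_e=v_e,
        e_mag=e_mag, q_cum=q_cum, meta=meta,
    )


def charge_summary(result: SimulationResult, waveform: WaveformSpec) -> ChargeSummary:
    """Per-pulse injected/recovered charge from a simulated trace.

    Pulse boundaries come from ``segmentize`` (not threshold crossing): the
    pulse-on interval of each period is the span of segments whose level
    differs from the offset baseline on the positive side, and the recovery
    interval runs from pulse end to the next pulse start.  Charges are read
    from the simulator's exact cumulative integral of ``i_e``.  A dc
    waveform has no pulse structure; only the cumulative charge is reported.
    """
    t = result.t
    q = result.q_cum
    q_total = float(q[-1])
    if waveform.shape is WaveShape.DC:
        empty = np.array([])
        return ChargeSummary(
            q_inj=empty, q_rec=empty, q_acc=empty, boundaries=[], q_total=q_total
        )

    segs = segmentize(waveform)
    period = sum(d for d, _ in segs)
    off = waveform.offset
    # pulse-on = leading segments above baseline (the injecting phase)
    on_end = 0.0
    for dur, level in segs:
        if level > off:
            on_end += dur
        else:
            break
    if on_end == 0.0:
        raise ValueError("waveform has no injecting phase above the offset")

    def q_at(time: float) -> float:
        return float(np.interp(time, t, q))

    q_inj, q_rec, bounds = [], [], []
    start = 0.0
    while start + period <= t[-1] + 1e-12:
        p_end = min(start + on_end, t[-1])
        nxt = min(start + period, t[-1])
        qi = q_at(p_end) - q_at(start)
        qr = -(q_at(nxt) - q_at(p_end))
        q_inj.append(qi)
        q_rec.append(qr)
        bounds.append((start, p_end, nxt))
        start += period
    q_inj = np.array(q_inj)
    q_rec = np.array(q_rec)
    return ChargeSummary(
        q_inj=q_inj, q_rec=q_rec, q_acc=q_inj - q_rec,
        boundaries=bounds, q_total=q_total,
    )
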