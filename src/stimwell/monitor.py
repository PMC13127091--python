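"""Reduction of two-channel oscilloscope captures to delivered quantities.

The monitoring circuit places a known shunt resistor R_m in the stimulation
loop; the differential voltage across it, V_R = V_CH2 - V_CH1, yields the
instantaneous loop current I = V_R / R_m.  In parallel (voltage-controlled)
wiring that loop current is the total over N wells, so the per-well current
is V_R / (R_m * N) and V_CH2 reads the common well voltage.  In series
(current-controlled) wiring the loop current is the per-well current and
V_CH2 is the total drop over all wells, so V_well = V_CH2 / N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .circuit import DeviceModel, Wiring
from .protocol import MonitorSpec

__all__ = ["ScopeTrace", "ReducedSignals", "reduce_trace", "integrate_charge"]


@dataclass
class ScopeTrace:
    """Raw two-channel capture plus acquisition metadata.

    ``meta`` should carry ``r_m_ohm``, ``n_wells`` and ``wiring`` so the
    trace is self-describing.
    """

    t: np.ndarray
    v_ch1: np.ndarray
    v_ch2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v_ch1 = np.asarray(self.v_ch1, dtype=float)
        self.v_ch2 = np.asarray(self.v_ch2, dtype=float)
        if not (len(self.t) == len(self.v_ch1) == len(self.v_ch2)):
            raise ValueError("t, v_ch1, v_ch2 must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class ReducedSignals:
    """Delivered per-well quantities recovered from a scope trace."""

    t: np.ndarray
    v_r: np.ndarray
    i_total: np.ndarray
    i_e_per_well: np.ndarray
    v_well: np.ndarray
    q_cum: np.ndarray
    e_mag: np.ndarray | None = None


def reduce_trace(
    trace: ScopeTrace,
    monitor: MonitorSpec,
    device: DeviceModel,
    polarity: int = 1,
    r_e: float | None = None,
) -> ReducedSignals:
    """Convert a scope capture into per-well delivered signals.

    ``polarity`` (+1/-1) flips the current sign for the opposite probe
    ordering.  If ``r_e`` is given (or available from the device), the
    culture-area field |E_e| = I_e*R_e/d is included in mV/mm.  In series
    wiring the monitor drop is not subtracted from V_CH2 before dividing by
    N (V_CH2 is taken as the total drop over the wells).
    """
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 or -1")
    n_meta = trace.meta.get("n_wells")
    if n_meta is not None and int(n_meta) != device.n_wells:
        raise ValueError(
            f"trace metadata n_wells={n_meta} does not match device N={device.n_wells}"
        )
    w_meta = trace.meta.get("wiring")
    if w_meta is not None and Wiring(w_meta) is not device.wiring:
        raise ValueError(
            f"trace metadata wiring={w_meta!r} does not match device {device.wiring.value!r}"
        )

    n = device.n_wells
    v_r = polarity * (trace.v_ch2 - trace.v_ch1)
    i_total = v_r / monitor.r_m
    if device.wiring is Wiring.PARALLEL:
        i_e = i_total / n
        v_well = trace.v_ch2.copy()
    elif device.wiring is Wiring.SERIES:
        i_e = i_total.copy()
        v_well = trace.v_ch2 / n
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unhandled wiring: {device.wiring}")

    q_cum = cumulative_trapezoid(i_e, trace.t, initial=0.0)
    r_e_val = r_e if r_e is not None else device.well.r_e
    e_mag = i_e * r_e_val * 1000.0 / device.spacing_d_mm
    return ReducedSignals(
        t=trace.t, v_r=v_r, i_total=i_total, i_e_per_well=i_e,
        v_well=v_well, q_cum=q_cum, e_mag=e_mag,
    )


def integrate_charge(i, t, pulse_boundaries=None, jump_times=None):
    """Cumulative charge and optional per-pulse injection/recovery split.

    ``pulse_boundaries`` is a list of (pulse_start, pulse_end, next_start)
    times; injected charge integrates the current over [start, end] and
    recovered charge is minus the integral over [end, next_start], matching
    the simulator's per-pulse accounting.  Returns ``(q_cum, summary)``
    where ``summary`` is None without boundaries, else a dict with
    ``q_inj``, ``q_rec`` and ``q_acc`` arrays.

    The current jumps at waveform segment edges, where a plain trapezoid
    smears the step over one sample interval.  ``jump_times`` lists the
    discontinuity times (defaulting to the pulse boundaries); where such a
    time coincides with a sample (samples there carry the post-jump value),
    the crossing interval is corrected using a linear left-limit
    extrapolation of the pre-jump branch, so the quadrature error stays
    second order.
    """
    i = np.asarray(i, dtype=float)
    t = np.asarray(t, dtype=float)
    q_cum = cumulative_trapezoid(i, t, initial=0.0)
    if pulse_boundaries is None and jump_times is None:
        return q_cum, None

    if jump_times is None:
        jump_times = {b for triple in pulse_boundaries for b in triple}
    edges = sorted(set(np.asarray(list(jump_times), dtype=float).tolist()))
    for b in edges:
        k = int(np.searchsorted(t, b - 1e-12 * max(1.0, abs(b))))
        if k < 2 or k >= len(t) or abs(t[k] - b) > 1e-9 * (t[1] - t[0]):
            continue
        i_left = i[k - 1] + (i[k - 1] - i[k - 2])  # pre-jump branch at t[k]
        delta = (i_left - i[k]) / 2.0 * (t[k] - t[k - 1])
        q_cum[k:] += delta

    if pulse_boundaries is None:
        return q_cum, None

    def q_at(time):
        return float(np.interp(time, t, q_cum))

    q_inj, q_rec = [], []
    for start, p_end, nxt in pulse_boundaries:
        if not (t[0] - 1e-12 <= start <= p_end <= nxt <= t[-1] + 1e-12):
            raise ValueError(f"pulse boundaries ({start}, {p_end}, {nxt}) outside trace span")
        q_inj.append(q_at(p_end) - q_at(start))
        q_rec.append(-(q_at(nxt) - q_at(p_end)))
    q_inj = np.array(q_inj)
    q_rec = np.array(q_rec)
    return q_cum, {"q_inj": q_inj, "q_rec": q_rec, "q_acc": q_inj - q_rec}
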