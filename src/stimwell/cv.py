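"""Cyclic-voltammetry safe-window estimation and protocol safety checks.

Applying excessive voltage to an electrode in culture medium eventually
triggers water electrolysis, with gas evolution and pH swings that kill
cells.  The safe electrochemical window is located by cyclic voltammetry:
the potential window is expanded step by step and, at each window, the
absolute current difference between consecutive cycles is read at both
voltage extremes.  A pronounced increase in that difference marks the
activation of a new charge-injection mechanism; the last window extreme
before the increase is the safe limit on that side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .protocol import SimulationResult, WaveformSpec, WaveShape, segmentize

__all__ = [
    "CVCycle",
    "CVData",
    "SafetyWindow",
    "WindowScanResult",
    "SafetyReport",
    "expanding_windows",
    "extreme_current_increase",
    "estimate_safe_window",
    "check_safety",
]


def expanding_windows(
    start: tuple[float, float] = (-0.55, 0.85),
    increment: float = 0.5,
    n: int = 4,
) -> list[tuple[float, float]]:
    """Symmetric window-expansion schedule for a CV safety scan.

    Starting below the generic water-splitting limits for Pt and widening
    both extremes by ``increment`` volts per step.
    """
    if increment <= 0 or n < 1:
        raise ValueError("increment must be positive and n >= 1")
    v_lo, v_hi = start
    return [(v_lo - increment * k, v_hi + increment * k) for k in range(n)]


@dataclass
class CVCycle:
    """One triangular sweep: sampled (potential, current) over a window."""

    potential_v: np.ndarray
    current_a: np.ndarray
    window: tuple[float, float]  # (v_lo, v_hi)
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.potential_v = np.asarray(self.potential_v, dtype=float)
        self.current_a = np.asarray(self.current_a, dtype=float)
        if len(self.potential_v) != len(self.current_a):
            raise ValueError("potential and current arrays must match")
        v_lo, v_hi = self.window
        if not v_lo < v_hi:
            raise ValueError("window must satisfy v_lo < v_hi")


@dataclass
class CVData:
    """A window-expansion CV scan: cycles grouped by potential window.

    ``sweep_rate`` in V/s and ``step`` in V describe the staircase the
    instrument applied; cycles sharing a window are consecutive and
    comparable for the current-increase readout.
    """

    cycles: list
    sweep_rate: float = 0.1
    step: float = 1e-3
    meta: dict = field(default_factory=dict)

    def windows(self) -> list[tuple[float, float]]:
        """Distinct windows in scan order."""
        seen: list[tuple[float, float]] = []
        for c in self.cycles:
            if c.window not in seen:
                seen.append(c.window)
        return seen

    def cycles_in(self, window: tuple[float, float]) -> list:
        return [c for c in self.cycles if c.window == window]


@dataclass(frozen=True)
class SafetyWindow:
    """Safe voltage range: cathodic limit ``v_min`` < 0 < anodic ``v_max``."""

    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if not (self.v_min < 0 < self.v_max):
            raise ValueError("expect v_min < 0 < v_max")

    def contains(self, v: float) -> bool:
        return self.v_min <= v <= self.v_max


@dataclass
class WindowScanResult:
    """Outcome of the window-expansion analysis.

    ``delta_i`` maps each window to its (cathodic, anodic) consecutive-cycle
    current differences in amps; ``window`` is the estimated safe range;
    the per-side flags read 'onset detected' or 'onset not reached'.
    """

    delta_i: dict
    window: SafetyWindow
    rel_threshold: float
    cathodic_flag: str
    anodic_flag: str


@dataclass
class SafetyReport:
    """Intervals (or waveform levels) where V_well leaves the safe window."""

    violations: list
    window: SafetyWindow

    @property
    def safe(self) -> bool:
        return not self.violations


def _extreme_current(cycle: CVCycle, side: str) -> float:
    """Current at the window extreme, read on the forward sweep.

    The forward sweep toward the anodic limit is the ascending branch; the
    sample closest to the limit while still moving toward it is used.
    """
    v = cycle.potential_v
    i = cycle.current_a
    dv = np.diff(v)
    if side == "anodic":
        moving = np.concatenate([dv > 0, [False]])
        target = cycle.window[1]
    else:
        moving = np.concatenate([dv < 0, [False]])
        target = cycle.window[0]
    if not np.any(moving):
        moving = np.ones_like(v, dtype=bool)
    idx_local = np.argmin(np.abs(v[moving] - target))
    return float(i[np.flatnonzero(moving)[idx_local]])


def extreme_current_increase(cycle_a: CVCycle, cycle_b: CVCycle) -> tuple[float, float]:
    """|I_b - I_a| at the cathodic and anodic window extremes, in amps.

    Both cycles must cover the same potential window.
    """
    if cycle_a.window != cycle_b.window:
        raise ValueError(
            f"cycles cover different windows: {cycle_a.window} vs {cycle_b.window}"
        )
    d_cat = abs(_extreme_current(cycle_b, "cathodic") - _extreme_current(cycle_a, "cathodic"))
    d_an = abs(_extreme_current(cycle_b, "anodic") - _extreme_current(cycle_a, "anodic"))
    return d_cat, d_an


def estimate_safe_window(scan: CVData, rel_threshold: float = 3.0) -> WindowScanResult:
    """Estimate the safe voltage range from a window-expansion scan.

    For each successively wider window the consecutive-cycle current
    difference is computed at both extremes.  The baseline is the median
    difference over the smallest window; the estimated limit on each side is
    the last window extreme *before* the difference first exceeds
    ``rel_threshold`` times that side's baseline.  The two sides are
    estimated independently.  If a side never exceeds the threshold the
    widest tested extreme is returned with the flag 'onset not reached'.
    """
    windows = scan.windows()
    if len(windows) < 2:
        raise ValueError("need at least 2 expansion windows")
    delta_i: dict = {}
    for w in windows:
        cycles = scan.cycles_in(w)
        if len(cycles) < 2:
            raise ValueError(f"window {w} needs at least 2 consecutive cycles")
        pair_deltas = [
            extreme_current_increase(cycles[k], cycles[k + 1])
            for k in range(len(cycles) - 1)
        ]
        delta_i[w] = (
            float(np.median([d[0] for d in pair_deltas])),
            float(np.median([d[1] for d in pair_deltas])),
        )

    base_cat, base_an = delta_i[windows[0]]
    base_cat = max(base_cat, 1e-30)
    base_an = max(base_an, 1e-30)

    def side_limit(side: int, base: float, extreme_of):
        prev = extreme_of(windows[0])
        for w in windows[1:]:
            if delta_i[w][side] > rel_threshold * base:
                return prev, "onset detected"
            prev = extreme_of(w)
        return prev, "onset not reached"

    v_min, cat_flag = side_limit(0, base_cat, lambda w: w[0])
    v_max, an_flag = side_limit(1, base_an, lambda w: w[1])
    return WindowScanResult(
        delta_i=delta_i,
        window=SafetyWindow(v_min=v_min, v_max=v_max),
        rel_threshold=rel_threshold,
        cathodic_flag=cat_flag,
        anodic_flag=an_flag,
    )


def check_safety(
    subject: SimulationResult | WaveformSpec | Sequence[float],
    window: SafetyWindow,
    t: np.ndarray | None = None,
) -> SafetyReport:
    """Check a per-well voltage trace or a waveform against a safe window.

    For a simulated result (or raw trace) the report lists the time
    intervals where ``v_well`` leaves [v_min, v_max]; for a waveform spec it
    lists the offending levels.  An empty report means safe.
    """
    if isinstance(subject, WaveformSpec):
        violations = []
        for dur, level in segmentize(subject):
            if not window.contains(level):
                violations.append({"level_v": level, "duration_s": dur})
        return SafetyReport(violations=violations, window=window)

    if isinstance(subject, SimulationResult):
        v = subject.v_well
        t = subject.t
    else:
        v = np.asarray(subject, dtype=float)
        if t is None:
            t = np.arange(len(v), dtype=float)
        t = np.asarray(t, dtype=float)

    bad = (v < window.v_min) | (v > window.v_max)
    violations = []
    in_run = False
    start = 0
    for k, flag in enumerate(bad):
        if flag and not in_run:
            in_run, start = True, k
        elif not flag and in_run:
            in_run = False
            violations.append(_interval(t, v, start, k - 1, window))
    if in_run:
        violations.append(_interval(t, v, start, len(v) - 1, window))
    return SafetyReport(violations=violations, window=window)


def _interval(t, v, k0, k1, window):
    seg = v[k0 : k1 + 1]
    return {
        "t_start_s": float(t[k0]),
        "t_end_s": float(t[k1]),
        "v_extreme_v": float(seg[np.argmax(np.abs(seg))]),
    }
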