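"""Synthetic instrument data from known ground truth.

Generators for EIS spectra, window-expansion CV scans and two-channel
oscilloscope traces, each a pure function of (truth, grid, seed).  They
exist so every analysis stage — equivalent-circuit fitting, safe-window
estimation, trace reduction — can be exercised against known parameters
without a potentiostat or oscilloscope on the bench.

The CV forward model is phenomenological: a capacitive rectangle
``C_dl * sweep_rate`` plus an ohmic leak ``V/R_f`` plus Tafel-type
exponential onsets for the anodic and cathodic reactions (water splitting
in culture medium).  The faradaic term grows from cycle to cycle once a
reaction is activated, which is what the consecutive-cycle current-increase
readout detects.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .circuit import DeviceModel, WellParams, Wiring
from .cv import CVCycle, CVData
from .eis import ImpedanceSpectrum, simulate_spectrum
from .monitor import ScopeTrace
from .protocol import MonitorSpec, SimulationResult

__all__ = ["NoiseKind", "NoiseModel", "CVGenParams", "gen_eis", "gen_cv", "gen_scope"]


class NoiseKind(str, enum.Enum):
    #: complex Gaussian perturbation proportional to |Z| (EIS spectra)
    PROPORTIONAL_COMPLEX_GAUSSIAN = "proportional_complex_gaussian"
    #: absolute Gaussian noise on sampled values (traces, CV currents)
    ADDITIVE_GAUSSIAN = "additive_gaussian"


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description with an explicit seed.

    ``sigma`` is a fraction of |Z| for proportional noise and an absolute
    value (amps or volts) for additive noise.  Identical seeds reproduce
    identical outputs bitwise; there is no global random state.
    """

    kind: NoiseKind = NoiseKind.ADDITIVE_GAUSSIAN
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", NoiseKind(self.kind))
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CVGenParams:
    """Ground truth for the CV forward model.

    ``v_ox``/``v_red`` are the anodic/cathodic reaction onset potentials in
    volts (the quantities the window scan is supposed to recover), ``b`` the
    Tafel-type slope in volts, ``i0`` the exchange-current scale in amps and
    ``cycle_growth`` the per-cycle fractional growth of the faradaic term
    once a reaction is active.
    """

    c_dl: float = 1e-5
    r_f: float = 1e5
    i0: float = 1e-6
    v_ox: float = 1.3
    v_red: float = -1.0
    b: float = 0.05
    sweep_rate: float = 0.1
    cycle_growth: float = 0.25

    def __post_init__(self) -> None:
        if not (self.v_red < 0 < self.v_ox):
            raise ValueError("expect v_red < 0 < v_ox")
        if not self.b > 0:
            raise ValueError("Tafel slope b must be positive")
        if self.i0 < 0 or self.c_dl <= 0 or self.r_f <= 0:
            raise ValueError("i0 must be >= 0; c_dl and r_f positive")


def gen_eis(
    truth: WellParams | DeviceModel,
    freqs: np.ndarray,
    noise: NoiseModel | None = None,
) -> ImpedanceSpectrum:
    """Simulate an EIS measurement of a known circuit.

    Proportional complex Gaussian noise perturbs each point by
    ``|Z| * sigma * (eps_re + j*eps_im)`` with unit-normal draws.
    """
    spec = simulate_spectrum(truth, freqs)
    meta = {"synthetic": True}
    if noise is not None and noise.sigma > 0:
        if noise.kind is not NoiseKind.PROPORTIONAL_COMPLEX_GAUSSIAN:
            raise ValueError("EIS noise must be proportional_complex_gaussian")
        rng = noise.rng()
        mag = np.abs(spec.z)
        eps = rng.standard_normal((2, len(mag)))
        z = spec.z + mag * noise.sigma * (eps[0] + 1j * eps[1])
        spec = ImpedanceSpectrum(freqs=spec.freqs, z_real=z.real, z_imag=z.imag)
        meta["seed"] = noise.seed
        meta["sigma_frac"] = noise.sigma
    spec.meta.update(meta)
    return spec


def _triangle_sweep(v_lo: float, v_hi: float, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Staircase 0 -> v_hi -> v_lo -> 0 and the sweep direction per sample."""
    up1 = np.arange(0.0, v_hi + step / 2, step)
    down = np.arange(v_hi, v_lo - step / 2, -step)
    up2 = np.arange(v_lo, 0.0 + step / 2, step)
    v = np.concatenate([up1, down[1:], up2[1:]])
    direction = np.concatenate(
        [np.ones(len(up1)), -np.ones(len(down) - 1), np.ones(len(up2) - 1)]
    )
    return v, direction


def gen_cv(
    params: CVGenParams,
    windows: list[tuple[float, float]],
    step: float = 1e-3,
    noise: NoiseModel | None = None,
    cycles_per_window: int = 2,
) -> CVData:
    """Generate a window-expansion CV scan from known onset potentials.

    For each window (ordered by expansion) ``cycles_per_window``
    consecutive triangular sweeps are produced; the faradaic exponentials
    grow by ``cycle_growth`` per cycle so consecutive cycles differ at the
    extremes once an onset lies inside the window.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rng = noise.rng() if noise is not None else None
    cycles = []
    for v_lo, v_hi in windows:
        if v_hi - v_lo < step:
            raise ValueError(f"window ({v_lo}, {v_hi}) narrower than step")
        v, direction = _triangle_sweep(v_lo, v_hi, step)
        for k in range(cycles_per_window):
            i_cap = params.c_dl * params.sweep_rate * direction
            i_ohm = v / params.r_f
            i_far = params.i0 * (
                np.exp((v - params.v_ox) / params.b)
                - np.exp(-(v - params.v_red) / params.b)
            )
            i = i_cap + i_ohm + (1.0 + params.cycle_growth * k) * i_far
            if rng is not None and noise.sigma > 0:
                i = i + noise.sigma * rng.standard_normal(len(i))
            cycles.append(
                CVCycle(potential_v=v, current_a=i, window=(v_lo, v_hi), cycle_index=k)
            )
    return CVData(
        cycles=cycles,
        sweep_rate=params.sweep_rate,
        step=step,
        meta={"synthetic": True, "truth_v_ox": params.v_ox, "truth_v_red": params.v_red},
    )


def gen_scope(
    sim: SimulationResult,
    monitor: MonitorSpec,
    noise: NoiseModel | None = None,
) -> ScopeTrace:
    """Synthesize the two-channel scope capture of a simulated protocol.

    Channels are built so that ``v_ch2 - v_ch1 = i_total * r_m`` and CH2
    carries the well voltage (parallel wiring) or the total drop over all
    wells (series wiring), matching the monitoring-circuit reduction.
    """
    n = sim.meta.get("n_wells", 1)
    wiring = Wiring(sim.meta.get("wiring", Wiring.PARALLEL))
    i_total = sim.i_total
    v_r = i_total * monitor.r_m
    if wiring is Wiring.PARALLEL:
        v_ch2 = sim.v_well.copy()
    else:
        v_ch2 = n * sim.v_well
    v_ch1 = v_ch2 - v_r
    if noise is not None and noise.sigma > 0:
        if noise.kind is not NoiseKind.ADDITIVE_GAUSSIAN:
            raise ValueError("scope noise must be additive_gaussian")
        rng = noise.rng()
        v_ch1 = v_ch1 + noise.sigma * rng.standard_normal(len(v_ch1))
        v_ch2 = v_ch2 + noise.sigma * rng.standard_normal(len(v_ch2))
    return ScopeTrace(
        t=sim.t,
        v_ch1=v_ch1,
        v_ch2=v_ch2,
        meta={
            "r_m_ohm": monitor.r_m,
            "n_wells": n,
            "wiring": wiring.value,
            "synthetic": True,
            "seed": noise.seed if noise is not None else None,
        },
    )
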