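"""Source-sizing helpers for multi-well stimulation devices.

Resistive back-of-the-envelope sizing: each well presents an effective load
(about 330 ohm for the 8-well micro-dish in culture medium), wells compose
in parallel for voltage-controlled devices and in series for
current-controlled ones, and the source must supply enough current
(parallel) or voltage headroom (series) for every connected device.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .circuit import Wiring

__all__ = [
    "SizingResult",
    "device_load",
    "max_devices_parallel",
    "compliance_voltage",
    "max_field",
    "sizing_report",
]


@dataclass
class SizingResult:
    """Summary of a source-sizing calculation."""

    device_load_ohm: float
    required_current_a: float | None = None
    compliance_voltage_v: float | None = None
    max_device_count: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.device_load_ohm > 0:
            raise ValueError("device load must be positive")
        if self.max_device_count is not None and self.max_device_count < 0:
            raise ValueError("device count must be non-negative")


def device_load(r_well: float, n: int, wiring: Wiring | str) -> float:
    """Total resistive load of N wells: r/N in parallel, N*r in series."""
    if not r_well > 0:
        raise ValueError("r_well must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if Wiring(wiring) is Wiring.PARALLEL:
        return r_well / n
    return r_well * n


def max_devices_parallel(i_max: float, v_target: float, load_ohm: float) -> int:
    """How many parallel devices a source can drive at the target voltage.

    Each device draws ``v_target / load_ohm``; the count is the floor of the
    available current over that draw.  Zero (with a warning) means the
    source cannot even drive one device.
    """
    if not (i_max > 0 and v_target > 0 and load_ohm > 0):
        raise ValueError("i_max, v_target and load_ohm must be positive")
    per_device = v_target / load_ohm
    count = math.floor(i_max / per_device + 1e-12)
    if count == 0:
        warnings.warn(
            f"source current {i_max:.3g} A cannot drive a single device "
            f"drawing {per_device:.3g} A",
            stacklevel=2,
        )
    return count


def compliance_voltage(i: float, device_loads_ohm: Sequence[float]) -> float:
    """Voltage headroom to push a current through series-connected loads."""
    if not i > 0:
        raise ValueError("current must be positive")
    loads = list(device_loads_ohm)
    if not loads:
        raise ValueError("device_loads_ohm must not be empty")
    return i * sum(loads)


def max_field(v_limit: float, d_mm: float) -> float:
    """Largest culture-area field (mV/mm) from a voltage limit over gap d."""
    if not d_mm > 0:
        raise ValueError("electrode spacing must be positive")
    return 1000.0 * v_limit / d_mm


def sizing_report(
    r_well: float,
    n: int,
    wiring: Wiring | str,
    i_max: float | None = None,
    v_target: float | None = None,
    i_deliver: float | None = None,
    n_devices: int = 1,
) -> SizingResult:
    """Compose the sizing calculations into one result.

    Parallel wiring with ``i_max`` and ``v_target`` reports how many devices
    the source supports; series wiring with ``i_deliver`` reports the
    compliance voltage for ``n_devices`` in series.
    """
    wiring = Wiring(wiring)
    load = device_load(r_well, n, wiring)
    result = SizingResult(device_load_ohm=load)
    if wiring is Wiring.PARALLEL and i_max is not None and v_target is not None:
        result.max_device_count = max_devices_parallel(i_max, v_target, load)
        result.required_current_a = v_target / load
        result.notes = (
            f"{result.max_device_count} device(s) of {load:.4g} ohm at "
            f"{v_target:.3g} V on a {i_max:.3g} A source"
        )
    elif wiring is Wiring.SERIES and i_deliver is not None:
        result.compliance_voltage_v = compliance_voltage(
            i_deliver, [load] * n_devices
        )
        result.notes = (
            f"{result.compliance_voltage_v:.4g} V to push {i_deliver:.3g} A "
            f"through {n_devices} device(s) of {load:.4g} ohm in series"
        )
    return result
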