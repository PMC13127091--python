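"""CSV dialects, structured config parsing and result export.

All tables are plain UTF-8 CSV: comma separator, '.' decimal, a mandatory
header row, and an optional metadata preamble of ``# key=value`` lines
before the header.  Units are encoded in column and key names (``_ohm``,
``_f`` for farads, ``_v``, ``_a``, ``_s``, ``_hz``, ``_mm``).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import CPEParams, DeviceModel, WellParams, Wiring
from .cv import CVCycle, CVData
from .eis import ImpedanceSpectrum
from .monitor import ScopeTrace
from .protocol import (
    MonitorSpec,
    SimulationResult,
    SourceMode,
    SourceSpec,
    WaveformSpec,
)

__all__ = [
    "DIALECT_COLUMNS",
    "read_table",
    "write_table",
    "RunConfig",
    "load_config",
]

DIALECT_COLUMNS = {
    "eis": ["freq_hz", "z_real_ohm", "z_imag_ohm"],
    "cv": ["cycle", "window_v_lo", "window_v_hi", "potential_v", "current_a"],
    "scope": ["t_s", "v_ch1_v", "v_ch2_v"],
    "simresult": ["t_s", "v_source_v", "v_well_v", "i_e_a", "v_e_v", "e_mvmm", "q_c"],
}


def _parse_preamble(path: Path) -> tuple[dict, int]:
    """Read leading '# key=value' lines; return (meta, lines to skip)."""
    meta: dict = {}
    skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = _coerce(val.strip())
    return meta, skip


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            continue
    return val


def _read_frame(path: Path, dialect: str) -> tuple[pd.DataFrame, dict]:
    cols = DIALECT_COLUMNS[dialect]
    meta, skip = _parse_preamble(path)
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: dialect {dialect!r} requires columns {cols}; "
            f"missing {missing}"
        )
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = vals
    return df, meta


def read_table(path, dialect: str):
    """Read a CSV in one of the known dialects into its typed object.

    Dialects: ``eis`` -> ImpedanceSpectrum, ``cv`` -> CVData, ``scope`` ->
    ScopeTrace, ``simresult`` -> SimulationResult.  A wrong header raises
    with the expected column names; a non-numeric cell raises with its row.
    """
    path = Path(path)
    if dialect not in DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {list(DIALECT_COLUMNS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    df, meta = _read_frame(path, dialect)

    if dialect == "eis":
        return ImpedanceSpectrum(
            freqs=df["freq_hz"].to_numpy(),
            z_real=df["z_real_ohm"].to_numpy(),
            z_imag=df["z_imag_ohm"].to_numpy(),
            meta=meta,
        )
    if dialect == "cv":
        cycles = []
        sweep_rate = meta.get("sweep_rate_v_per_s", 0.1)
        step = meta.get("step_v", 1e-3)
        for (lo, hi, cyc), grp in df.groupby(
            ["window_v_lo", "window_v_hi", "cycle"], sort=False
        ):
            cycles.append(
                CVCycle(
                    potential_v=grp["potential_v"].to_numpy(),
                    current_a=grp["current_a"].to_numpy(),
                    window=(float(lo), float(hi)),
                    cycle_index=int(cyc),
                )
            )
        return CVData(cycles=cycles, sweep_rate=sweep_rate, step=step, meta=meta)
    if dialect == "scope":
        return ScopeTrace(
            t=df["t_s"].to_numpy(),
            v_ch1=df["v_ch1_v"].to_numpy(),
            v_ch2=df["v_ch2_v"].to_numpy(),
            meta=meta,
        )
    # simresult
    return SimulationResult(
        t=df["t_s"].to_numpy(),
        v_source=df["v_source_v"].to_numpy(),
        v_well=df["v_well_v"].to_numpy(),
        i_e=df["i_e_a"].to_numpy(),
        v_e=df["v_e_v"].to_numpy(),
        e_mag=df["e_mvmm"].to_numpy(),
        q_cum=df["q_c"].to_numpy(),
        meta=meta,
    )


def write_table(obj, path, dialect: str) -> None:
    """Write a typed object to CSV in its dialect (inverse of read_table)."""
    path = Path(path)
    if dialect == "eis":
        df = pd.DataFrame(
            {"freq_hz": obj.freqs, "z_real_ohm": obj.z_real, "z_imag_ohm": obj.z_imag}
        )
        meta = obj.meta
    elif dialect == "cv":
        rows = []
        for c in obj.cycles:
            rows.append(
                pd.DataFrame(
                    {
                        "cycle": c.cycle_index,
                        "window_v_lo": c.window[0],
                        "window_v_hi": c.window[1],
                        "potential_v": c.potential_v,
                        "current_a": c.current_a,
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        meta = {**obj.meta, "sweep_rate_v_per_s": obj.sweep_rate, "step_v": obj.step}
    elif dialect == "scope":
        df = pd.DataFrame({"t_s": obj.t, "v_ch1_v": obj.v_ch1, "v_ch2_v": obj.v_ch2})
        meta = obj.meta
    elif dialect == "simresult":
        df = pd.DataFrame(
            {
                "t_s": obj.t,
                "v_source_v": obj.v_source,
                "v_well_v": obj.v_well,
                "i_e_a": obj.i_e,
                "v_e_v": obj.v_e,
                "e_mvmm": obj.e_mag,
                "q_c": obj.q_cum,
            }
        )
        meta = {
            k: v for k, v in obj.meta.items() if isinstance(v, (int, float, str))
        }
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    buf = _io.StringIO()
    for key, val in meta.items():
        if val is None:
            continue
        if isinstance(val, Wiring):
            val = val.value
        if isinstance(val, (int, float, str, bool)):
            buf.write(f"# {key}={val}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# structured run configuration

_WELL_KEYS = {"r_e_ohm", "r_f_ohm", "c_dl_f", "cpe_q", "cpe_n"}
_DEVICE_KEYS = {"n_wells", "wiring", "spacing_d_mm", "well"}
_SOURCE_KEYS = {"mode", "z_output_ohm", "i_max_a", "v_max_v"}
_MONITOR_KEYS = {"r_m_ohm"}
_WAVEFORM_KEYS = {
    "shape",
    "amplitude",
    "frequency_hz",
    "duty_percent",
    "offset",
    "interphase_break_s",
    "amplitude2",
    "duty_percent2",
    "custom_segments",
}
_SIM_KEYS = {"duration_s", "dt_s"}
_TOP_KEYS = {"device", "source", "monitor", "waveform", "sim", "io", "seed"}


class RunConfig:
    """Validated run configuration assembled from a YAML file.

    Sections: ``device`` (with nested ``well``), ``source``, ``monitor``,
    ``waveform``, ``sim`` (duration/step), ``io`` (paths) and ``seed``.
    Unknown keys anywhere are rejected with an explicit error.
    """

    def __init__(
        self,
        device: DeviceModel,
        source: SourceSpec | None = None,
        monitor: MonitorSpec | None = None,
        waveform: WaveformSpec | None = None,
        sim: dict | None = None,
        io: dict | None = None,
        seed: int = 0,
    ):
        self.device = device
        self.source = source
        self.monitor = monitor
        self.waveform = waveform
        self.sim = sim or {}
        self.io = io or {}
        self.seed = seed


def _num(val):
    """Coerce YAML scalars to float (PyYAML reads '1.0e5' as a string)."""
    if val is None or isinstance(val, (int, float)):
        return val
    return float(val)


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def _parse_well(section: dict) -> WellParams:
    _reject_unknown(section, _WELL_KEYS, "device.well")
    cpe = None
    if "cpe_q" in section:
        cpe = CPEParams(q_mag=_num(section["cpe_q"]), n_exp=_num(section.get("cpe_n", 1.0)))
    return WellParams(
        r_e=_num(section["r_e_ohm"]),
        r_f=_num(section["r_f_ohm"]),
        c_dl=_num(section.get("c_dl_f")),
        cpe=cpe,
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    _reject_unknown(raw, _TOP_KEYS, "config")
    if "device" not in raw:
        raise ValueError("config requires a 'device' section")
    dev = dict(raw["device"])
    _reject_unknown(dev, _DEVICE_KEYS, "device")
    device = DeviceModel(
        well=_parse_well(dict(dev.get("well", {}))),
        n_wells=dev.get("n_wells", 1),
        wiring=Wiring(dev.get("wiring", "parallel")),
        spacing_d_mm=_num(dev.get("spacing_d_mm", 10.0)),
    )

    source = None
    if "source" in raw:
        sec = dict(raw["source"])
        _reject_unknown(sec, _SOURCE_KEYS, "source")
        source = SourceSpec(
            mode=SourceMode(sec.get("mode", "voltage_controlled")),
            z_output=_num(sec.get("z_output_ohm", 50.0)),
            i_max=_num(sec.get("i_max_a")),
            v_max=_num(sec.get("v_max_v")),
        )

    monitor = None
    if "monitor" in raw:
        sec = dict(raw["monitor"])
        _reject_unknown(sec, _MONITOR_KEYS, "monitor")
        monitor = MonitorSpec(r_m=_num(sec.get("r_m_ohm", 50.0)))

    waveform = None
    if "waveform" in raw:
        sec = dict(raw["waveform"])
        _reject_unknown(sec, _WAVEFORM_KEYS, "waveform")
        waveform = WaveformSpec(
            shape=sec["shape"],
            amplitude=_num(sec.get("amplitude", 0.0)),
            frequency=_num(sec.get("frequency_hz", 0.0)),
            duty_percent=_num(sec.get("duty_percent", 50.0)),
            offset=_num(sec.get("offset", 0.0)),
            interphase_break=_num(sec.get("interphase_break_s", 0.0)),
            amplitude2=_num(sec.get("amplitude2")),
            duty_percent2=_num(sec.get("duty_percent2")),
            custom_segments=tuple(
                (float(d), float(v)) for d, v in sec.get("custom_segments", [])
            ),
        )

    sim = {k: _num(v) for k, v in dict(raw.get("sim", {})).items()}
    _reject_unknown(sim, _SIM_KEYS, "sim")
    return RunConfig(
        device=device,
        source=source,
        monitor=monitor,
        waveform=waveform,
        sim=sim,
        io=dict(raw.get("io", {})),
        seed=int(raw.get("seed", 0)),
    )
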