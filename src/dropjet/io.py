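"""Configuration, table, trace and panel I/O plus provenance blocks.

Configs are single YAML files with unit-suffixed keys (``q_aq_ul_min``,
``intra_spacing_ns``, ...) grouped into sections; unknown keys are rejected
on load so a typo cannot silently fall back to a default. Measurement
tables are plain CSV; traces are CSV (time_s, volts) or HDF5; panel stacks
are HDF5 3-D arrays.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .beam_schedule import FACILITIES, PulseSchedule
from .droplet_model import FluidSystem, FrequencyMeasurement, flow_condition
from .errors import InvalidInputError
from .trace_analysis import DetectorTrace
from . import units

# ---------------------------------------------------------------------------
# configuration

#: Allowed keys per config section; values are the defaults (None = required).
CONFIG_SCHEMA: dict[str, dict[str, object]] = {
    "fluid": {
        "viscosity_mpa_s": 13.3,
        "tension_mn_m": 12.0,
        "width_um": 100.0,
        "depth_um": 75.0,
        "dispersed_diameter_um": 50.0,
        "k_m_s": 3.7,
    },
    "schedule": {
        "facility": "euxfel",
        "train_period_s": None,
        "pulses_per_train": None,
        "intra_spacing_ns": 0.0,
        "calibration_pulses": 0,
        "record_stride": 1,
    },
    "jet": {
        "jet_speed_m_s": 50.0,
    },
    "beam": {
        "beam_diameter_um": 20.0,
        "crystal_density_per_ml": 5e6,
    },
    "simulation": {
        "f_d_hz": 10.0,
        "p_aq": 0.3,
        "mean_hit": 0.05,
        "n_trains": 1000,
        "interface_window_us": 0.0,
        "period_jitter_cv": 0.0,
        "synchronized": False,
    },
}


def validate_config(config: dict) -> dict:
    """Validate a config dict against the schema and fill in defaults."""
    if not isinstance(config, dict):
        raise InvalidInputError("config root must be a mapping")
    unknown_sections = set(config) - set(CONFIG_SCHEMA)
    if unknown_sections:
        raise InvalidInputError(f"unknown config sections: {sorted(unknown_sections)}")
    merged: dict[str, dict] = {}
    for section, schema in CONFIG_SCHEMA.items():
        given = config.get(section, {}) or {}
        unknown = set(given) - set(schema)
        if unknown:
            raise InvalidInputError(
                f"unknown keys in section {section!r}: {sorted(unknown)}"
            )
        merged[section] = {**schema, **given}
    return merged


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def fluid_from_config(config: dict) -> FluidSystem:
    c = config["fluid"]
    return FluidSystem.from_bench_units(
        viscosity_mpa_s=c["viscosity_mpa_s"],
        tension_mn_m=c["tension_mn_m"],
        width_um=c["width_um"],
        depth_um=c["depth_um"],
        dispersed_diameter_um=c["dispersed_diameter_um"],
    )


def schedule_from_config(config: dict) -> PulseSchedule:
    c = config["schedule"]
    if c.get("facility"):
        key = str(c["facility"]).lower()
        if key not in FACILITIES:
            raise InvalidInputError(
                f"unknown facility {key!r}; known: {sorted(FACILITIES)}"
            )
        return FACILITIES[key].schedule
    if c["train_period_s"] is None or c["pulses_per_train"] is None:
        raise InvalidInputError(
            "schedule needs either a facility name or explicit timing keys"
        )
    return PulseSchedule(
        train_period=float(c["train_period_s"]),
        pulses_per_train=int(c["pulses_per_train"]),
        intra_spacing=float(c["intra_spacing_ns"]) * 1e-9,
        calibration_pulses=int(c["calibration_pulses"]),
        record_stride=int(c["record_stride"]),
    )


# ---------------------------------------------------------------------------
# measurement tables

MEASUREMENT_COLUMNS = ("q_aq_ul_min", "q_oil_ul_min", "f_hz", "n_droplets")


def read_measurements_csv(path: str | Path, fluid: FluidSystem) -> list[FrequencyMeasurement]:
    """Read a droplet-frequency measurement table.

    Expects header columns ``q_aq_ul_min, q_oil_ul_min, f_hz, n_droplets``,
    one row per flow condition. A malformed row raises naming the row.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InvalidInputError(f"cannot parse measurement table {path}: {exc}") from exc
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"measurement table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise InvalidInputError("measurement table has no data rows")
    out = []
    for i, row in df.iterrows():
        try:
            cond = flow_condition(
                fluid,
                units.ul_min_to_m3_s(float(row["q_aq_ul_min"])),
                units.ul_min_to_m3_s(float(row["q_oil_ul_min"])),
            )
            out.append(
                FrequencyMeasurement(
                    condition=cond,
                    measured_frequency=float(row["f_hz"]),
                    n_droplets=int(row["n_droplets"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise InvalidInputError(f"malformed measurement row {i}: {exc}") from exc
    return out


def write_measurements_csv(
    measurements: list[FrequencyMeasurement], path: str | Path
) -> None:
    """Write measurements in the same CSV dialect :func:`read_measurements_csv` reads."""
    df = pd.DataFrame(
        {
            "q_aq_ul_min": [units.m3_s_to_ul_min(m.condition.q_aq) for m in measurements],
            "q_oil_ul_min": [units.m3_s_to_ul_min(m.condition.q_oil) for m in measurements],
            "f_hz": [m.measured_frequency for m in measurements],
            "n_droplets": [m.n_droplets for m in measurements],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# detector traces and panel stacks

def read_trace_csv(path: str | Path) -> DetectorTrace:
    """Read a trace from CSV with columns ``time_s, volts``."""
    df = pd.read_csv(path)
    missing = {"time_s", "volts"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"trace CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InvalidInputError("trace needs at least 2 samples")
    dt = np.median(np.diff(t))
    if not dt > 0:
        raise InvalidInputError("trace times must be increasing")
    return DetectorTrace(sample_rate=1.0 / dt, voltages=df["volts"].to_numpy(dtype=float))


def write_trace_csv(trace: DetectorTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "volts": trace.voltages}).to_csv(
        path, index=False
    )


def read_trace_hdf5(path: str | Path, dataset: str = "volts") -> DetectorTrace:
    """Read a trace from an HDF5 dataset carrying a ``sample_rate_hz`` attr."""
    with h5py.File(path, "r") as fh:
        if dataset not in fh:
            raise InvalidInputError(f"dataset {dataset!r} not found in {path}")
        dset = fh[dataset]
        if "sample_rate_hz" not in dset.attrs:
            raise InvalidInputError("trace dataset lacks a sample_rate_hz attribute")
        return DetectorTrace(
            sample_rate=float(dset.attrs["sample_rate_hz"]), voltages=dset[()]
        )


def write_trace_hdf5(trace: DetectorTrace, path: str | Path, dataset: str = "volts") -> None:
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset(dataset, data=trace.voltages)
        dset.attrs["sample_rate_hz"] = trace.sample_rate


def read_panels_hdf5(path: str | Path, dataset: str = "panels") -> np.ndarray:
    """Read a 3-D (image, row, column) panel stack from HDF5."""
    with h5py.File(path, "r") as fh:
        if dataset not in fh:
            raise InvalidInputError(f"dataset {dataset!r} not found in {path}")
        stack = fh[dataset][()]
    if stack.ndim != 3:
        raise InvalidInputError("panel dataset must be 3-D (image, row, column)")
    return stack


def write_panels_hdf5(stack: np.ndarray, path: str | Path, dataset: str = "panels") -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset(dataset, data=np.asarray(stack))


# ---------------------------------------------------------------------------
# provenance

def package_version() -> str:
    try:
        return _pkg_version("dropjet")
    except PackageNotFoundError:  # pragma: no cover - only in odd installs
        return "unknown"


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    """Machine-readable provenance block embedded in every report."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {
        "package": "dropjet",
        "version": package_version(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
    }


def write_json_report(payload: dict, path: str | Path) -> None:
    """Write a JSON report, converting numpy scalars/arrays on the way out."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        raise TypeError(f"cannot serialise {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
        fh.write("\n")
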