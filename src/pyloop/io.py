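"""Config parsing with unit-suffixed keys, CSV/JSON readers and writers,
run manifests and seed plumbing.

Configs are YAML or JSON mappings whose keys carry their unit as a suffix
(``cycle_period_ms``, ``g_max_uS``, ``tau_ad_min``); dimensionless fields
(factors, counts, modes) have no suffix and are whitelisted per schema.
Unknown keys are rejected, as are unit-bearing quantities without a suffix.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import AChannelParams, HChannelParams
from .core import SampledTrace, SpikeTrain, ValidationError
from .plasticity import ADCurveParams
from .synth import CommandWaveform, DAPreset, NetworkPreset

__all__ = [
    "load_config",
    "save_config",
    "write_result",
    "read_spike_csv",
    "write_spike_csv",
    "read_trace",
    "write_trace",
    "CONFIG_SCHEMAS",
]

#: schema: config kind -> {suffixed key: dataclass field}
CONFIG_SCHEMAS: dict[str, tuple[type, dict[str, str]]] = {
    "network_preset": (
        NetworkPreset,
        {
            "cycle_period_ms": "cycle_period",
            "pd_burst_duration_ms": "pd_burst_duration",
            "lp_burst_duration_ms": "lp_burst_duration",
            "lp_on_delay_ms": "lp_on_delay",
            "lp_spikes_per_burst": "lp_spikes_per_burst",
            "lp_mean_isi_ms": "lp_mean_isi",
            "spike_jitter_sd_ms": "spike_jitter_sd",
            "cycle_jitter_sd_ms": "cycle_jitter_sd",
            "pd_spikes_per_burst": "pd_spikes_per_burst",
        },
    ),
    "da_preset": (
        DAPreset,
        {
            "period_factor": "period_factor",
            "lp_burst_factor": "lp_burst_factor",
            "lp_on_phase_factor": "lp_on_phase_factor",
            "isi_factor": "isi_factor",
            "ia_gmax_factor": "ia_gmax_factor",
        },
    ),
    "command_waveform": (
        CommandWaveform,
        {
            "nadir_voltage_mV": "nadir_voltage",
            "peak_voltage_mV": "peak_voltage",
            "step_duration_ms": "step_duration",
            "cycle_period_ms": "cycle_period",
            "spike_mode": "spike_mode",
            "spike_peak_mV": "spike_peak",
            "spike_width_ms": "spike_width",
            "spike_count": "spike_count",
            "spike_isi_ms": "spike_isi",
            "n_cycles": "n_cycles",
        },
    ),
    "h_channel": (
        HChannelParams,
        {
            "g_max_uS": "g_max",
            "e_rev_mV": "e_rev",
            "v_half_mV": "v_half",
            "v_slope_mV": "v_slope",
            "tau_max_ms": "tau_max",
            "tau_v_half_mV": "tau_v_half",
            "tau_v_slope_mV": "tau_v_slope",
        },
    ),
    "a_channel": (
        AChannelParams,
        {
            "g_max_uS": "g_max",
            "e_rev_mV": "e_rev",
            "act_v_half_mV": "act_v_half",
            "act_v_slope_mV": "act_v_slope",
            "tau_act_ms": "tau_act",
            "inact_v_half_mV": "inact_v_half",
            "inact_v_slope_mV": "inact_v_slope",
            "tau_inact_ms": "tau_inact",
        },
    ),
    "ad_curve": (
        ADCurveParams,
        {
            "top_fold": "top",
            "bottom_fold": "bottom",
            "x_half_pct": "x_half",
            "x_slope_pct": "x_slope",
            "freq_factor_per_10pct": "freq_factor_per_10pct",
            "da_mode": "da_mode",
            "tau_ad_min": "tau_ad",
            "patterned_tau_multiplier": "patterned_tau_multiplier",
        },
    ),
}

_UNIT_SUFFIXES = ("_ms", "_mV", "_nA", "_uS", "_min", "_pct", "_nF", "_fold")


def _parse_mapping(path: Path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return data


def load_config(path, kind: str):
    """Load and validate a config of the given kind; defaults fill gaps.

    Unknown keys raise; so does a key matching a known field name but
    missing its unit suffix (the error names the expected key).
    """
    if kind not in CONFIG_SCHEMAS:
        raise ValidationError(f"unknown config kind {kind!r}; one of {sorted(CONFIG_SCHEMAS)}")
    cls, schema = CONFIG_SCHEMAS[kind]
    data = _parse_mapping(Path(path))
    bare_to_key = {field: key for key, field in schema.items()}
    kwargs = {}
    for key, value in data.items():
        if key in schema:
            kwargs[schema[key]] = value
        elif key in bare_to_key and bare_to_key[key] != key:
            expected = bare_to_key[key]
            unit = expected[len(key):].lstrip("_")
            raise ValidationError(f"key {key!r} is missing its unit suffix; expected {expected!r} ({unit})")
        else:
            raise ValidationError(f"unknown key {key!r} for {kind} config")
    obj = cls(**kwargs)
    return obj.validate() if hasattr(obj, "validate") else obj


def save_config(obj, path, kind: str) -> None:
    """Serialize a config dataclass with unit-suffixed keys (YAML or JSON)."""
    cls, schema = CONFIG_SCHEMAS[kind]
    if not isinstance(obj, cls):
        raise ValidationError(f"object of type {type(obj).__name__} is not a {kind} config")
    data = {key: getattr(obj, field) for key, field in schema.items()}
    path = Path(path)
    if str(path).endswith((".yaml", ".yml")):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=False) + "\n")


def _config_hash(config) -> str:
    if config is None:
        return ""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    else:
        payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_result(result, outdir, config=None, seed: int | None = None) -> dict:
    """Write an ExperimentResult as tidy CSV + JSON summary + run manifest.

    The CSV holds decimal text at 9 significant digits with a deterministic
    column order, so identical runs produce byte-identical CSVs (the
    manifest carries the timestamp and is excluded from that guarantee).
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = result.frame.copy()
    frame = frame[["time_min", "metric", "value"]].sort_values(["time_min", "metric"], kind="stable")
    csv_path = outdir / "result.csv"
    frame.to_csv(csv_path, index=False, float_format="%.9g")
    summary = {}
    if len(frame):
        t_last = frame["time_min"].max()
        last = frame.loc[frame["time_min"] == t_last]
        summary = {"final_time_min": float(t_last)} | {
            m: float(v) for m, v in zip(last["metric"], last["value"])
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = {
        "command_line": " ".join(sys.argv),
        "config_hash": _config_hash(config),
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": ["result.csv", "summary.json"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def write_spike_csv(trains: list[SpikeTrain], path) -> None:
    """Two-column spike CSV: cell_id, spike_time_ms (header required)."""
    rows = [(tr.cell_id, t) for tr in trains for t in tr.times_ms]
    pd.DataFrame(rows, columns=["cell_id", "spike_time_ms"]).to_csv(path, index=False, float_format="%.9g")


def read_spike_csv(path) -> dict[str, SpikeTrain]:
    frame = pd.read_csv(path)
    if list(frame.columns[:2]) != ["cell_id", "spike_time_ms"]:
        raise ValidationError(f"{path}: expected columns cell_id, spike_time_ms")
    return {
        str(cid): SpikeTrain(np.sort(sub["spike_time_ms"].to_numpy(dtype=float)), str(cid))
        for cid, sub in frame.groupby("cell_id", sort=True)
    }


def write_trace(trace: SampledTrace, path, seed: int | None = None, preset: dict | None = None) -> None:
    """Trace CSV (time_ms, value) plus a JSON sidecar with units and dt."""
    path = Path(path)
    pd.DataFrame({"time_ms": trace.time_ms(), "value": trace.values}).to_csv(path, index=False, float_format="%.9g")
    sidecar = {"units": trace.units, "dt_ms": trace.dt_ms, "kind": trace.kind, "seed": seed, "preset": preset}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_trace(path) -> SampledTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    frame = pd.read_csv(path)
    return SampledTrace(
        frame["value"].to_numpy(dtype=float),
        dt_ms=float(meta["dt_ms"]),
        units=meta["units"],
        kind=meta["kind"],
        t0_ms=float(frame["time_ms"].iloc[0]) if len(frame) else 0.0,
    )
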