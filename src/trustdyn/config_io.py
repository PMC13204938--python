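"""Configuration files and result serialization.

Configurations are YAML (or JSON) mappings with three sections --
``scenario``, ``calibration`` and ``network`` -- mirroring
:class:`~trustdyn.session.ScenarioConfig`,
:class:`~trustdyn.calibration.Calibration` and
:class:`~trustdyn.network.NetworkParams`.  Unknown keys are rejected
with an error naming them; omitted keys fall back to the package defaults
and the full effective configuration is echoed into every result directory.

A result directory contains:

* ``metrics.csv`` — one row per trial, floats printed with 17 significant
  digits so a write/read round trip is bit-exact;
* ``meta.yaml`` — config echo, seed, package version, final weights.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import Calibration
from .errors import ConfigurationError
from .network import CouplingScales, NetworkParams, TrialTrace
from .session import (
    ExpertProfile,
    ObserverProfile,
    OptionSpec,
    ScenarioConfig,
    SimulationResult,
    TrialRecord,
)

REQUIRED_KEYS = (
    ("scenario", "expert", "consistency"),
    ("scenario", "expert", "competence"),
    ("scenario", "n_trials"),
    ("scenario", "seed"),
)


def _fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def _check_unknown(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s) under {path!r}: {', '.join(unknown)}"
        )


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """A fully validated configuration bundle."""

    scenario: ScenarioConfig
    calibration: Calibration
    network: NetworkParams

    def __iter__(self):  # allow scenario, calibration[, network] unpacking
        return iter((self.scenario, self.calibration, self.network))


def read_config(path) -> RunConfig:
    """Read and validate a scenario/calibration/network configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    _check_unknown(raw, {"scenario", "calibration", "network"}, "<root>")

    missing = [
        ".".join(keys)
        for keys in REQUIRED_KEYS
        if _dig(raw, keys) is None
    ]
    if missing:
        raise ConfigurationError(
            f"missing required configuration key(s): {', '.join(missing)}"
        )

    scen_raw = dict(raw.get("scenario", {}))
    _check_unknown(scen_raw, _fields(ScenarioConfig), "scenario")
    if "options" in scen_raw:
        opts = []
        for entry in scen_raw["options"]:
            _check_unknown(entry, {"name", "v_emo", "v_rat"}, "scenario.options[]")
            opts.append(OptionSpec(**entry))
        scen_raw["options"] = tuple(opts)
    if "expert" in scen_raw:
        _check_unknown(scen_raw["expert"], _fields(ExpertProfile), "scenario.expert")
        scen_raw["expert"] = ExpertProfile(**scen_raw["expert"])
    if "observer" in scen_raw:
        _check_unknown(scen_raw["observer"], _fields(ObserverProfile), "scenario.observer")
        scen_raw["observer"] = ObserverProfile(**scen_raw["observer"])
    scenario = ScenarioConfig(**scen_raw)

    cal_raw = dict(raw.get("calibration", {}))
    _check_unknown(cal_raw, _fields(Calibration), "calibration")
    if "scales" in cal_raw:
        _check_unknown(cal_raw["scales"], _fields(CouplingScales), "calibration.scales")
        cal_raw["scales"] = CouplingScales(**cal_raw["scales"])
    for key in ("q_rat_map", "q_emo_map"):
        if key in cal_raw:
            cal_raw[key] = tuple(cal_raw[key])
    calibration = Calibration(**cal_raw)

    net_raw = dict(raw.get("network", {}))
    _check_unknown(net_raw, _fields(NetworkParams), "network")
    network = NetworkParams(**net_raw)
    return RunConfig(scenario, calibration, network)


def _dig(mapping, keys):
    node = mapping
    for key in keys:
        if not isinstance(node, dict) or key not in node:
            return None
        node = node[key]
    return node


# ---------------------------------------------------------------------------
# results

_VECTOR_FIELDS = ("w_emo", "w_rat", "f_emo", "f_rat", "v_emo", "v_rat", "v_final")
_SCALAR_FIELDS = (
    "trial",
    "action",
    "rewarded",
    "dbp",
    "beta",
    "q_emo",
    "q_rat",
    "w_rat_expert",
    "f_rat_expert",
    "pe_action",
    "pe_outcome",
    "choice",
)


def result_frame(result: SimulationResult) -> pd.DataFrame:
    """Flatten the per-trial records into a table (one row per trial)."""
    options = [o["name"] for o in result.config["scenario"]["options"]]
    rows = []
    for rec in result.records:
        row = {name: getattr(rec, name) for name in _SCALAR_FIELDS}
        for field in _VECTOR_FIELDS:
            for j, opt in enumerate(options):
                row[f"{field}_{opt}"] = getattr(rec, field)[j]
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_csv_text(result: SimulationResult) -> str:
    """The metrics table as CSV text (17 significant digits, UTF-8, '.')."""
    return result_frame(result).to_csv(index=False, float_format="%.17g")


def write_result(result: SimulationResult, out_dir) -> Path:
    """Write a result directory (metrics.csv + meta.yaml); returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.csv").write_text(metrics_csv_text(result))
    meta = {
        "seed": result.seed,
        "version": result.version,
        "config": result.config,
        "final_weights": {k: float(v) for k, v in result.final_weights.items()},
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def read_result(result_dir) -> SimulationResult:
    """Reconstruct a :class:`SimulationResult` from a result directory."""
    out = Path(result_dir)
    meta = yaml.safe_load((out / "meta.yaml").read_text())
    frame = pd.read_csv(out / "metrics.csv", float_precision="round_trip")
    options = [o["name"] for o in meta["config"]["scenario"]["options"]]
    records = []
    for _, row in frame.iterrows():
        kwargs = {name: row[name] for name in _SCALAR_FIELDS}
        kwargs["trial"] = int(kwargs["trial"])
        kwargs["rewarded"] = bool(kwargs["rewarded"])
        for field in _VECTOR_FIELDS:
            kwargs[field] = np.array([row[f"{field}_{opt}"] for opt in options])
        records.append(TrialRecord(**kwargs))
    return SimulationResult(
        records=records,
        final_weights=meta["final_weights"],
        config=meta["config"],
        seed=meta["seed"],
        version=meta.get("version", __version__),
    )


def write_trace(trace: TrialTrace, path) -> None:
    """Store a full within-trial trace as a compressed array container."""
    np.savez_compressed(
        path,
        time_ms=trace.time_ms,
        u=trace.u,
        g=trace.g,
        external=trace.external,
        dt=trace.config.dt,
        duration=trace.config.duration,
        transient=trace.config.transient,
    )
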