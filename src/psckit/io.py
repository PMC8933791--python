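"""File formats and run manifests.

The native trace container is HDF5 (one ``/current_pA`` dataset plus header
attributes); two-column CSV (``time_s,current_pA``) is the interchange
fallback, with the sampling rate inferred from the time column and strict
uniform-spacing validation.  Event catalogs and metrics travel as TSV with
units embedded in the column names, NSNA results and cohort comparisons as
JSON.  Every pipeline run writes a manifest recording the configuration
hash, input hashes, seeds and the parameters actually used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .detect import DetectedEvent, DetectionConfig, EventCatalog
from .metrics import CellSummary
from .nsna import NSNAFit
from .simulate import EventTrain, SimulationConfig, Trace
from .stats import CohortComparison, ComparisonPlan

__all__ = [
    "FORMAT_VERSION",
    "read_trace",
    "write_trace",
    "write_event_catalog",
    "read_event_catalog",
    "write_event_train",
    "write_metrics_table",
    "write_cell_summaries",
    "nsna_fit_to_dict",
    "write_nsna_json",
    "comparison_to_dict",
    "write_comparison_json",
    "load_simulation_config",
    "load_detection_config",
    "load_plan",
    "RunManifest",
]

FORMAT_VERSION = 1
_UNITS = "pA"
#: maximum relative jitter of the CSV time column before the file is
#: rejected as non-uniformly sampled
_MAX_TIME_JITTER = 1e-6

_HEADER_FIELDS = ("cell_id", "cohort", "recording_type", "holding_potential_mv", "filter")


def write_trace(path: str | Path, trace: Trace) -> None:
    """Write a trace to HDF5 (``.h5``/``.hdf5``) or two-column CSV."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("current_pA", data=trace.samples)
            ds.attrs["units"] = _UNITS
            f.attrs["format_version"] = FORMAT_VERSION
            f.attrs["sampling_rate_hz"] = trace.sampling_rate_hz
            f.attrs["t0_s"] = trace.t0_s
            for key in _HEADER_FIELDS:
                if key in trace.metadata:
                    f.attrs[key] = trace.metadata[key]
    elif path.suffix.lower() == ".csv":
        t = trace.times_s()
        with open(path, "w") as f:
            f.write("time_s,current_pA\n")
            for ti, xi in zip(t.tolist(), trace.samples.tolist()):
                f.write(f"{ti!r},{xi!r}\n")
    else:
        raise ValueError(f"unknown trace format: {path.suffix!r} (use .h5 or .csv)")


def read_trace(path: str | Path) -> Trace:
    """Read a trace container; CSV round-trips and HDF5 round-trips are
    bit-exact on the sample array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_trace_h5(path)
    if path.suffix.lower() == ".csv":
        return _read_trace_csv(path)
    raise ValueError(f"unknown trace format: {path.suffix!r} (use .h5 or .csv)")


def _read_trace_h5(path: Path) -> Trace:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"unrecognized trace format version: {version}")
        if "sampling_rate_hz" not in f.attrs:
            raise ValueError("trace file is missing the sampling rate")
        if "current_pA" not in f:
            raise ValueError("trace file is missing the /current_pA dataset")
        ds = f["current_pA"]
        if ds.attrs.get("units", _UNITS) != _UNITS:
            raise ValueError("trace units must be pA")
        samples = ds[()]
        if not np.issubdtype(samples.dtype, np.number):
            raise ValueError("trace samples are not numeric")
        meta = {k: _plain(f.attrs[k]) for k in _HEADER_FIELDS if k in f.attrs}
        return Trace(
            samples=np.asarray(samples, dtype=np.float64),
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            t0_s=float(f.attrs.get("t0_s", 0.0)),
            metadata=meta,
        )


def _read_trace_csv(path: Path) -> Trace:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "current_pA"]:
        raise ValueError("CSV trace must have columns time_s,current_pA")
    t = df["time_s"].to_numpy(dtype=np.float64)
    try:
        x = df["current_pA"].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError("trace samples are not numeric") from exc
    if t.size < 2:
        raise ValueError("CSV trace needs at least 2 samples to infer the rate")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0 or np.any(np.abs(dt - dt_med) > _MAX_TIME_JITTER * dt_med):
        raise ValueError("CSV time column is not uniformly spaced")
    return Trace(samples=x, sampling_rate_hz=1.0 / dt_med, t0_s=float(t[0]))


def _plain(value):
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.generic):
        return value.item()
    return value


# --- event tables ------------------------------------------------------------


def write_event_catalog(path: str | Path, catalog: EventCatalog) -> None:
    """TSV event table with the noise level recorded in comment lines."""
    fs = catalog.trace.sampling_rate_hz
    t0 = catalog.trace.t0_s
    with open(path, "w") as f:
        f.write(f"# rms_noise_pa = {catalog.rms_noise_pa!r}\n")
        f.write(f"# threshold_pa = {catalog.threshold_pa!r}\n")
        f.write(f"# sampling_rate_hz = {fs!r}\n")
        f.write("onset_s\tpeak_s\tbaseline_pa\tamplitude_pa\tsign\tflag\n")
        for e in catalog.events:
            f.write(
                f"{t0 + e.onset_index / fs!r}\t{t0 + e.peak_index / fs!r}\t"
                f"{e.baseline_pa!r}\t{e.amplitude_pa!r}\t{e.sign}\t{e.flag}\n"
            )


def read_event_catalog(path: str | Path, trace: Trace) -> EventCatalog:
    """Rebuild an event catalog from its TSV against the matching trace."""
    header: dict[str, float] = {}
    with open(path) as f:
        lines = f.readlines()
    rows = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            header[key.strip()] = float(value)
            continue
        rows.append(line.rstrip("\n"))
    df = pd.DataFrame(
        [r.split("\t") for r in rows[1:]], columns=rows[0].split("\t")
    )
    fs = trace.sampling_rate_hz
    events = [
        DetectedEvent(
            onset_index=int(round((float(r.onset_s) - trace.t0_s) * fs)),
            peak_index=int(round((float(r.peak_s) - trace.t0_s) * fs)),
            baseline_pa=float(r.baseline_pa),
            amplitude_pa=float(r.amplitude_pa),
            sign=int(r.sign),
            flag=r.flag,
        )
        for r in df.itertuples()
    ]
    return EventCatalog(
        events=events,
        trace=trace,
        rms_noise_pa=header.get("rms_noise_pa", 0.0),
        threshold_pa=header.get("threshold_pa", 0.0),
    )


def write_event_train(path: str | Path, train: EventTrain) -> None:
    """Ground-truth event train as TSV."""
    with open(path, "w") as f:
        f.write("onset_s\tn_channels\tunitary_pa\ttau_rise_ms\ttau_decay_ms\tp_peak\n")
        for k in range(train.n_events):
            f.write(
                f"{float(train.onset_times_s[k])!r}\t{int(train.n_channels[k])}\t"
                f"{float(train.unitary_current_pa[k])!r}\t{float(train.tau_rise_ms[k])!r}\t"
                f"{float(train.tau_decay_ms[k])!r}\t{float(train.peak_open_prob[k])!r}\n"
            )


def write_metrics_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_cell_summaries(path: str | Path, summaries: list[CellSummary]) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    df.to_csv(path, sep="\t", index=False)


# --- JSON reports ------------------------------------------------------------


def _json_safe(value):
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    return value


def nsna_fit_to_dict(fit: NSNAFit, curve=None) -> dict:
    out = {
        "unitary_current_pa": fit.unitary_current_pa,
        "n_channels": _json_safe(fit.n_channels),
        "background_variance_pa2": fit.background_variance_pa2,
        "channels_open_at_peak": fit.channels_open_at_peak,
        "r_squared": fit.r_squared,
        "residual_sd_pa2": fit.residual_sd_pa2,
        "n_points": fit.n_points,
        "n_events": fit.n_events,
        "n_unbounded": fit.n_unbounded,
        "warning": fit.warning,
    }
    if curve is not None:
        out["variance_mean_curve"] = {
            "mean_current_pa": curve.mean_current_pa.tolist(),
            "variance_pa2": curve.variance_pa2.tolist(),
            "weights": curve.weights.tolist(),
        }
    return out


def write_nsna_json(path: str | Path, fit: NSNAFit, curve=None) -> None:
    with open(path, "w") as f:
        json.dump(nsna_fit_to_dict(fit, curve), f, indent=2, sort_keys=True)
        f.write("\n")


def comparison_to_dict(comparisons: list[CohortComparison], plan: ComparisonPlan) -> dict:
    return {
        "plan": {
            "ks_variables": list(plan.ks_variables),
            "mw_variables": list(plan.mw_variables),
            "amplitude_cutoff_pa": plan.amplitude_cutoff_pa,
            "alpha": plan.alpha,
            "quantile_convention": "linear interpolation (type 7)",
        },
        "comparisons": [
            {
                "variable": c.variable,
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "significant": bool(c.p_value < plan.alpha),
                "summary_a": c.summary_a.as_dict(),
                "summary_b": c.summary_b.as_dict(),
            }
            for c in comparisons
        ],
    }


def write_comparison_json(
    path: str | Path, comparisons: list[CohortComparison], plan: ComparisonPlan
) -> None:
    with open(path, "w") as f:
        json.dump(comparison_to_dict(comparisons, plan), f, indent=2, sort_keys=True)
        f.write("\n")


# --- TOML configuration ------------------------------------------------------


def _load_toml(path: str | Path) -> dict:
    import tomllib

    with open(path, "rb") as f:
        return tomllib.load(f)


def load_simulation_config(source: str | Path | dict, **overrides) -> SimulationConfig:
    """Build a SimulationConfig from a TOML file or a plain mapping."""
    data = dict(_load_toml(source) if not isinstance(source, dict) else source)
    data.update(overrides)
    unknown = set(data) - {f.name for f in dataclasses.fields(SimulationConfig)}
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**data)


def load_detection_config(source: str | Path | dict, **overrides) -> DetectionConfig:
    data = dict(_load_toml(source) if not isinstance(source, dict) else source)
    data.update(overrides)
    if "artifact_rules" in data:
        data["artifact_rules"] = tuple(data["artifact_rules"])
    unknown = set(data) - {f.name for f in dataclasses.fields(DetectionConfig)}
    if unknown:
        raise ValueError(f"unknown detection config keys: {sorted(unknown)}")
    return DetectionConfig(**data)


def load_plan(source: str | Path | dict) -> ComparisonPlan:
    data = dict(_load_toml(source) if not isinstance(source, dict) else source)
    for key in ("ks_variables", "mw_variables"):
        if key in data:
            data[key] = tuple(data[key])
    unknown = set(data) - {f.name for f in dataclasses.fields(ComparisonPlan)}
    if unknown:
        raise ValueError(f"unknown plan keys: {sorted(unknown)}")
    return ComparisonPlan(**data)


# --- manifest ----------------------------------------------------------------


def _sha256_of_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one pipeline run.

    Timestamps live only here, so the analysis outputs themselves are
    byte-identical across reruns with the same configuration and seed.
    """

    tool: str
    version: str
    config: dict
    config_hash: str
    seed: int
    input_hashes: dict
    started_at: str
    finished_at: str
    stages: dict

    @classmethod
    def create(cls, config: dict, seed: int, input_paths: list[Path] | None = None):
        import datetime

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        now = datetime.datetime.now(datetime.timezone.utc).isoformat()
        from . import __version__

        return cls(
            tool="psckit",
            version=__version__,
            config=config,
            config_hash=hashlib.sha256(blob).hexdigest(),
            seed=seed,
            input_hashes={str(p): _sha256_of_file(Path(p)) for p in input_paths or []},
            started_at=now,
            finished_at="",
            stages={},
        )

    def finish(self) -> None:
        import datetime

        self.finished_at = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True, default=str)
            f.write("\n")
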