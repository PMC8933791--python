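"""End-to-end orchestration: simulate (or load) two cohorts of recordings,
detect events, compute metrics, run per-cell NSNA, and compare the cohorts.

A run is driven by one TOML (or dict) configuration with a section per
cohort, and is deterministic: the same configuration and seed reproduce
byte-identical event tables, NSNA JSON and comparison reports.  Timestamps
appear only in the run manifest.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from . import io as pio
from .detect import apply_artifact_rules, detect_events
from .metrics import compute_event_metrics, summarize_cell
from .nsna import AlignmentQualityError, analyze_cell
from .simulate import make_cohort_fixtures
from .stats import CellResult, compare_cohorts

__all__ = ["run_pipeline", "PipelineError", "process_cell"]

log = logging.getLogger("psckit")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cell id."""

    def __init__(self, stage: str, cell_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for cell {cell_id!r}: {cause}")
        self.stage = stage
        self.cell_id = cell_id
        self.cause = cause


def process_cell(trace, detection_config=None, nsna_options=None, run_nsna=True):
    """Detect → artifact rules → metrics → (optional) NSNA for one trace.

    Returns ``(CellResult, EventCatalog)``.
    """
    cell_id = str(trace.metadata.get("cell_id", ""))
    cohort = str(trace.metadata.get("cohort", ""))
    try:
        catalog = apply_artifact_rules(detect_events(trace, detection_config))
    except Exception as exc:
        raise PipelineError("detect", cell_id, exc) from exc
    log.info(
        "cell %s: rms_noise_pa=%.4g threshold_pa=%.4g events=%d accepted=%d",
        cell_id, catalog.rms_noise_pa, catalog.threshold_pa,
        len(catalog.events), len(catalog.accepted_events),
    )
    try:
        metrics = compute_event_metrics(catalog)
        summary = summarize_cell(metrics, trace.duration_s, cell_id=cell_id, cohort=cohort)
    except Exception as exc:
        raise PipelineError("metrics", cell_id, exc) from exc
    fit = None
    if run_nsna:
        try:
            fit = analyze_cell(catalog, **(nsna_options or {}))
        except (ValueError, AlignmentQualityError) as exc:
            # too few isolated events or imprecise alignment: the cell simply
            # contributes no NSNA estimates
            log.info("cell %s: excluded from NSNA (%s)", cell_id, exc)
        except Exception as exc:
            raise PipelineError("nsna", cell_id, exc) from exc
    return CellResult(cell_id=cell_id, cohort=cohort, metrics=metrics, summary=summary, nsna=fit), catalog


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run the whole pipeline from a configuration.

    The configuration needs ``[cohort_a]`` and ``[cohort_b]`` sections, each
    either a simulation section (SimulationConfig fields plus ``label`` and
    ``n_cells``) or ``traces = [paths...]``; optional ``[detection]``,
    ``[nsna]`` and ``[plan]`` sections tune the stages.  Returns the output
    directory, which receives per-cell event/metric/NSNA files, the cohort
    comparison report and the run manifest.
    """
    if not isinstance(config, dict):
        config = pio._load_toml(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)

    for section in ("cohort_a", "cohort_b"):
        if section not in config:
            raise ValueError(f"configuration is missing the [{section}] section")

    detection = pio.load_detection_config(config.get("detection", {}))
    nsna_options = dict(config.get("nsna", {}))
    run_nsna = bool(nsna_options.pop("enabled", True))
    plan = pio.load_plan(config.get("plan", {}))

    manifest = pio.RunManifest.create(config, seed)

    cohort_traces = _load_or_simulate_cohorts(config, seed)
    groups: list[list[CellResult]] = []
    for label, traces in cohort_traces:
        cells = []
        for trace in traces:
            cell, catalog = process_cell(trace, detection, nsna_options, run_nsna)
            stem = f"{cell.cell_id or 'cell'}"
            pio.write_event_catalog(out_dir / f"{stem}.events.tsv", catalog)
            pio.write_metrics_table(out_dir / f"{stem}.metrics.tsv", cell.metrics)
            if cell.nsna is not None:
                pio.write_nsna_json(out_dir / f"{stem}.nsna.json", cell.nsna)
            cells.append(cell)
        pio.write_cell_summaries(out_dir / f"{label}.summaries.tsv", [c.summary for c in cells])
        groups.append(cells)

    try:
        comparisons = compare_cohorts(groups[0], groups[1], plan)
    except Exception as exc:
        raise PipelineError("compare", "-", exc) from exc
    pio.write_comparison_json(out_dir / "comparison.json", comparisons, plan)

    manifest.stages = {
        "detection": dataclasses.asdict(detection),
        "nsna": {"enabled": run_nsna, **nsna_options},
        "plan": dataclasses.asdict(plan),
    }
    manifest.finish()
    manifest.write(out_dir / "manifest.json")
    return out_dir


def _load_or_simulate_cohorts(config: dict, seed: int):
    """Yield (label, traces) per cohort from files or from the simulator."""
    sections = [dict(config["cohort_a"]), dict(config["cohort_b"])]
    labels = [s.pop("label", default) for s, default in zip(sections, ("A", "B"))]
    if all("traces" in s for s in sections):
        out = []
        for label, s in zip(labels, sections):
            traces = []
            for p in s["traces"]:
                trace = pio.read_trace(p)
                trace.metadata.setdefault("cell_id", Path(p).stem)
                trace.metadata.setdefault("cohort", label)
                traces.append(trace)
            out.append((label, traces))
        return out
    if any("traces" in s for s in sections):
        raise ValueError("either both cohorts name trace files or both are simulated")
    n_cells = [int(s.pop("n_cells", 1)) for s in sections]
    cfgs = [pio.load_simulation_config(s) for s in sections]
    sim_a, sim_b = make_cohort_fixtures(
        cfgs[0], cfgs[1], (n_cells[0], n_cells[1]), seed=seed, labels=tuple(labels)
    )
    return [
        (labels[0], [t for t, _ in sim_a]),
        (labels[1], [t for t, _ in sim_b]),
    ]
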