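"""End-to-end pipeline: configuration, step orchestration, run report.

A :class:`PipelineConfig` names either input files or a simulation block,
the ordered steps to run, threshold overrides, an output directory and a
seed. :func:`run_pipeline` executes the steps in dependency order, writes
each module's outputs (TSV for tables, JSON for set-valued results) and a
self-contained ``report.json`` with per-step status, output checksums and
a counts summary. Re-running with the same config and seed reproduces
identical counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import pandas as pd
import yaml

from . import __version__
from .core_io import AnalysisThresholds, Dataset, DatasetError, load_dataset, write_dataset
from .synthetic import SimulationConfig, simulate_dataset
from . import heat_response, markers, preprocess, subgenome

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "validate_report"]

log = logging.getLogger("triadsc")

STEPS = ("qc", "normalize", "composition", "annotate", "markers", "dominance", "heat")
_DEPENDENCIES = {
    "annotate": ("normalize",),
    "markers": ("normalize",),
    "dominance": ("normalize",),
    "heat": ("normalize",),
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str
    steps: tuple = STEPS
    inputs: dict | None = None  # mtx/features/barcodes/cells/genes paths
    simulate: dict | None = None  # SimulationConfig overrides
    thresholds: dict | None = None
    marker_table: str | None = None  # TSV (cell_type, gene_id) for annotate
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = [s for s in self.steps if s not in STEPS]
        if unknown:
            raise ConfigError(f"unknown steps {unknown}; valid: {list(STEPS)}")
        self.steps = tuple(dict.fromkeys(self.steps))
        for step in self.steps:
            for dep in _DEPENDENCIES.get(step, ()):
                if dep not in self.steps or self.steps.index(dep) > self.steps.index(step):
                    raise ConfigError(f"step {step!r} requires {dep!r} to run first")
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError("exactly one of inputs / simulate must be given")
        if self.simulate is not None and self.seed is None and "seed" not in self.simulate:
            raise ConfigError("a seed is required when simulating")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, **kw):
    df.to_csv(path, sep="\t", index=False, **kw)
    return path


def _load_or_simulate(cfg: PipelineConfig):
    thresholds = AnalysisThresholds(**(cfg.thresholds or {}))
    if cfg.simulate is not None:
        sim_kw = dict(cfg.simulate)
        if "seed" not in sim_kw:
            sim_kw["seed"] = cfg.seed
        for key in ("cell_types", "conditions"):
            if key in sim_kw:
                sim_kw[key] = tuple(sim_kw[key])
        ds, truth = simulate_dataset(SimulationConfig(**sim_kw))
        ds = ds.with_thresholds(thresholds)
        return ds, truth
    inp = cfg.inputs
    required = ("mtx", "features", "barcodes")
    missing = [k for k in required if k not in inp]
    if missing:
        raise ConfigError(f"inputs block lacks {missing}")
    ds = load_dataset(
        inp["mtx"],
        inp["features"],
        inp["barcodes"],
        inp.get("cells"),
        inp.get("genes"),
        thresholds=thresholds,
    )
    return ds, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured steps and return the run report (also written
    to ``<out_dir>/report.json``)."""
    logging.basicConfig(level=cfg.log_level, stream=None)
    os.makedirs(cfg.out_dir, exist_ok=True)
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "steps": {},
        "outputs": {},
        "counts": {},
        "thresholds": None,
        "status": "ok",
    }
    outputs: dict[str, str] = {}

    def record(step, fn):
        t0 = time.monotonic()
        log.info("step %s: start", step)
        try:
            fn()
        except Exception as exc:
            report["steps"][step] = {"status": "failed", "error": str(exc)}
            report["status"] = "failed"
            log.error("step %s: failed: %s", step, exc)
            raise
        finally:
            report["steps"][step] = report["steps"].get(step) or {
                "status": "ok",
                "seconds": round(time.monotonic() - t0, 3),
            }
            _flush()
        log.info("step %s: done", step)

    def _flush():
        for name, path in outputs.items():
            if name not in report["outputs"] and os.path.exists(path):
                report["outputs"][name] = {"path": path, "sha256": _sha256(path)}
        with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)

    ds, truth = _load_or_simulate(cfg)
    report["thresholds"] = dataclasses.asdict(ds.thresholds)
    report["counts"]["cells_input"] = ds.n_cells
    report["counts"]["genes_input"] = ds.n_genes
    if cfg.simulate is not None:
        paths = write_dataset(ds, os.path.join(cfg.out_dir, "dataset"))
        for k, v in paths.items():
            outputs[f"dataset_{k}"] = v
        gt_path = os.path.join(cfg.out_dir, "dataset", "ground_truth.json")
        with open(gt_path, "w") as fh:
            fh.write(truth.to_json())
        outputs["ground_truth"] = gt_path

    state = {"ds": ds}

    def step_qc():
        filtered, qc_report = preprocess.qc_filter_cells(state["ds"])
        state["ds"] = filtered
        outputs["qc_report"] = _write_tsv(
            qc_report, os.path.join(cfg.out_dir, "qc_removed.tsv")
        )
        report["counts"]["cells_kept"] = filtered.n_cells
        report["counts"]["cells_removed"] = int(len(qc_report))

    def step_normalize():
        state["ds"] = preprocess.log_normalize(state["ds"])

    def step_composition():
        comp = preprocess.cluster_composition(state["ds"])
        outputs["composition"] = _write_tsv(
            comp.reset_index(), os.path.join(cfg.out_dir, "composition.tsv")
        )

    def step_annotate():
        if cfg.marker_table is None:
            raise ConfigError("annotate step requires marker_table")
        table = pd.read_csv(cfg.marker_table, sep="\t")
        assignment, dotplot, _ = preprocess.annotate_clusters(state["ds"], table)
        ds2 = state["ds"]
        ds2.cells["cell_type"] = ds2.cells["cluster_id"].map(
            lambda c: assignment.get(c, "unknown")
        )
        path = os.path.join(cfg.out_dir, "cluster_annotation.json")
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in assignment.items()}, fh, indent=1)
        outputs["annotation"] = path
        outputs["dotplot"] = _write_tsv(
            dotplot, os.path.join(cfg.out_dir, "dotplot.tsv")
        )

    def step_markers():
        enr = markers.cluster_enriched_genes(state["ds"])
        enr_table = (
            pd.concat(enr.values(), ignore_index=True)
            if enr
            else pd.DataFrame()
        )
        outputs["cluster_enriched"] = _write_tsv(
            enr_table, os.path.join(cfg.out_dir, "cluster_enriched.tsv")
        )
        report["counts"]["cluster_enriched_calls"] = int(len(enr_table))
        labels = state["ds"].cells["cell_type"]
        if labels.notna().any() and (labels[labels.notna()] != "unknown").sum():
            ctm = markers.cell_type_markers(state["ds"])
            ctm_table = pd.concat(ctm.values(), ignore_index=True)
            outputs["cell_type_markers"] = _write_tsv(
                ctm_table, os.path.join(cfg.out_dir, "cell_type_markers.tsv")
            )
            report["counts"]["cell_type_marker_calls"] = int(len(ctm_table))

    def step_dominance():
        ds2 = state["ds"]
        control = ds2
        if (ds2.cells["condition"] == "heat").any():
            control = ds2.subset_cells((ds2.cells["condition"] == "control").to_numpy())
        calls = subgenome.dominance_calls(control)
        rows = [
            {
                "group_id": c.group_id,
                "cell_type": c.cell_type,
                "dominant_subgenome": c.dominant or "none",
                "dominant_gene": c.dominant_gene or "",
            }
            for c in calls
        ]
        outputs["dominance"] = _write_tsv(
            pd.DataFrame(rows), os.path.join(cfg.out_dir, "dominance.tsv")
        )
        counts = subgenome.dominance_counts(calls)
        outputs["dominance_counts"] = _write_tsv(
            counts.reset_index(), os.path.join(cfg.out_dir, "dominance_counts.tsv")
        )
        report["counts"]["dominance_calls"] = int(
            sum(1 for c in calls if c.dominant is not None)
        )

    def step_heat():
        ds2 = state["ds"]
        if not (ds2.cells["condition"] == "heat").any():
            raise ConfigError("heat step requires heat-condition cells")
        heat = heat_response.heat_deg_table(ds2)
        for t, table in heat.items():
            outputs[f"degs_{t}"] = _write_tsv(
                table, os.path.join(cfg.out_dir, f"degs_{t}.tsv")
            )
        part = heat_response.deg_partition(heat)
        part_json = {
            "up": {"|".join(sorted(k)): sorted(v) for k, v in part.up.items()},
            "down": {"|".join(sorted(k)): sorted(v) for k, v in part.down.items()},
            "shared_all_up": sorted(part.shared_all_up),
            "shared_all_down": sorted(part.shared_all_down),
        }
        path = os.path.join(cfg.out_dir, "partition.json")
        with open(path, "w") as fh:
            json.dump(part_json, fh, indent=1, sort_keys=True)
        outputs["partition"] = path
        hm = heat_response.heat_marker_genes(part)
        outputs["heat_markers"] = _write_tsv(
            pd.DataFrame(
                [(t, g) for t in sorted(hm) for g in sorted(hm[t])],
                columns=["cell_type", "gene_id"],
            ),
            os.path.join(cfg.out_dir, "heat_markers.tsv"),
        )
        opp = heat_response.opposite_pattern_genes(heat)
        outputs["opposite"] = _write_tsv(
            pd.concat(
                [t.assign(cell_type=ct) for ct, t in opp.items()],
                ignore_index=True,
            )
            if any(len(t) for t in opp.values())
            else pd.DataFrame(columns=["gene_id", "sign", "cell_type"]),
            os.path.join(cfg.out_dir, "opposite.tsv"),
        )
        shifts = pd.DataFrame(
            [heat_response.umi_shift_test(ds2, t) for t in heat]
        )
        outputs["umi_shift"] = _write_tsv(
            shifts, os.path.join(cfg.out_dir, "umi_shift.tsv")
        )
        outputs["subgenome_deg_counts"] = _write_tsv(
            heat_response.subgenome_deg_counts(heat, ds2.genes),
            os.path.join(cfg.out_dir, "subgenome_deg_counts.tsv"),
        )
        report["counts"]["deg_counts"] = {
            t: int(len(table)) for t, table in heat.items()
        }
        report["counts"]["shared_all_up"] = len(part.shared_all_up)
        report["counts"]["shared_all_down"] = len(part.shared_all_down)

    handlers = {
        "qc": step_qc,
        "normalize": step_normalize,
        "composition": step_composition,
        "annotate": step_annotate,
        "markers": step_markers,
        "dominance": step_dominance,
        "heat": step_heat,
    }
    for step in cfg.steps:
        record(step, handlers[step])
    _flush()
    return report


# ---------------------------------------------------------------------------
# report schema (minimal structural validation; shipped as JSON alongside)
# ---------------------------------------------------------------------------

def validate_report(report: dict) -> None:
    """Check a run report against the shipped structural schema."""
    import importlib.resources

    schema = json.loads(
        importlib.resources.files("triadsc").joinpath("report_schema.json").read_text()
    )
    for key, kind in schema["required"].items():
        if key not in report:
            raise DatasetError(f"report lacks required key {key!r}")
        if kind == "object" and not isinstance(report[key], dict):
            raise DatasetError(f"report key {key!r} must be an object")
        if kind == "string" and not isinstance(report[key], str):
            raise DatasetError(f"report key {key!r} must be a string")
    for step, info in report["steps"].items():
        if info.get("status") not in ("ok", "failed"):
            raise DatasetError(f"step {step!r} has invalid status")
    for name, info in report["outputs"].items():
        if not os.path.exists(info["path"]):
            raise DatasetError(f"output {name!r} missing on disk: {info['path']}")
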