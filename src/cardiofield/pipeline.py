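"""Stage orchestration: configuration, seeding, manifests.

A :class:`RunConfig` names the stages to run, a single global seed and
per-stage parameter maps.  ``run`` executes each requested stage's
simulate -> analyze pair in order and writes a manifest (inputs, outputs,
parameters, seed, content hashes) from which a run can be reproduced
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cfio
from . import synthio
from .afm_hertz import find_contact_and_fit
from .occupancy_sim import run_simulation
from .optical_ap import extract_ap_features
from .qpm_motion import (QPMConfig, link_tracks, motion_metrics,
                         phase_to_mass, segment_frame)
from .respirometry import phase_levels, stress_params
from .scexpr import find_markers, lognormalize, qc_filter

__all__ = ["RunConfig", "ConfigError", "DependencyError", "run",
           "child_seed", "sha256_file"]

log = logging.getLogger(__name__)

STAGES = ("ap", "afm", "qpm", "markers", "occupancy", "mito")
_ALLOWED_KEYS = {"stages", "seed", "out_dir", "params", "log_level"}


class ConfigError(ValueError):
    """The run configuration violates the schema."""


class DependencyError(FileNotFoundError):
    """An upstream artifact required by a stage is missing."""


@dataclass
class RunConfig:
    """Validated run configuration.

    Unknown keys are rejected; the config round-trips through YAML
    unchanged.
    """

    stages: list[str]
    seed: int = 0
    out_dir: str = "cfp_out"
    params: dict[str, dict] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        bad = [k for k in self.params if k not in STAGES]
        if bad:
            raise ConfigError(f"params for unknown stage(s): {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" not in raw:
            raise ConfigError("config must list 'stages'")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "seed": self.seed,
                "out_dir": self.out_dir, "params": self.params,
                "log_level": self.log_level}


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_ap(out: Path, seed: int, params: dict) -> list[Path]:
    spec = synthio.SimSpec("ap", seed, params)
    traces, _ = synthio.gen_ap_traces(spec)
    table = extract_ap_features(traces)
    raw = out / "ap_traces.csv"
    feats = out / "ap_features.csv"
    cfio.write_voltage_csv(traces, raw)
    cfio.write_table(table, feats)
    return [raw, feats]


def _stage_afm(out: Path, seed: int, params: dict) -> list[Path]:
    spec = synthio.SimSpec("afm", seed, params, n_replicates=5)
    curves, _ = synthio.gen_force_curves(spec)
    rows = []
    for i, c in enumerate(curves):
        fit = find_contact_and_fit(c)
        rows.append({"curve": i, "contact_z_um": fit.contact_point_z,
                     "E_pa": fit.E, "rss": fit.rss,
                     "n_points": fit.n_points_fit})
    path = out / "afm_fits.csv"
    cfio.write_table(pd.DataFrame(rows), path)
    return [path]


def _stage_qpm(out: Path, seed: int, params: dict) -> list[Path]:
    params = dict(params) or {
        "n_frames": 6,
        "cells": [{"center": (40.0, 40.0), "mass_pg": 300.0,
                   "motion": "drift", "drift_px": (2.0, 0.0)}],
    }
    spec = synthio.SimSpec("qpm", seed, params)
    stack, _ = synthio.gen_phase_stack(spec)
    cfg = QPMConfig()
    masses = [phase_to_mass(f, stack.pixel_size_um, cfg.alpha)
              for f in stack.frames]
    masks = [segment_frame(f, cfg) for f in stack.frames]
    tracks = link_tracks(masks, masses, stack.pixel_size_um, cfg)
    rows = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        mm = motion_metrics(tr, masks, masses, stack.pixel_size_um,
                            stack.frame_interval_min, cfg)
        rows.append({"track": tr.track_id,
                     "mean_displacement_um": mm.mean_displacement_um,
                     "mean_pct_mass_fluct": mm.mean_pct_mass_fluctuation,
                     "mass_rate_pg_per_h":
                         mm.mass_accumulation_rate_pg_per_h})
    stack_path = out / "qpm_stack.tiff"
    cfio.write_stack(stack, stack_path)
    metrics_path = out / "qpm_metrics.csv"
    cfio.write_table(pd.DataFrame(rows), metrics_path)
    return [stack_path, stack_path.with_suffix(".json"), metrics_path]


def _stage_markers(out: Path, seed: int, params: dict
                   ) -> tuple[list[Path], pd.DataFrame]:
    params = dict(params)
    params.setdefault("markers", [
        {"gene": i, "group": i % 2, "log2fc": 2.0} for i in range(20)
    ])
    spec = synthio.SimSpec("counts", seed, params)
    mat, _ = synthio.gen_counts(spec)
    filtered, report = qc_filter(mat)
    norm = pd.DataFrame(lognormalize(filtered), index=filtered.genes)
    table = find_markers(norm, filtered.group_labels)
    path = out / "markers.csv"
    cfio.write_table(table, path)
    qc_path = out / "qc_report.json"
    qc_path.write_text(json.dumps({
        "removed_cells": report.removed_cells,
        "removed_genes": report.removed_genes,
    }, sort_keys=True))
    return [path, qc_path], table


def _stage_occupancy(out: Path, seed: int, params: dict,
                     markers: pd.DataFrame | None) -> list[Path]:
    if markers is None:
        markers_path = Path(params.get("markers_csv", out / "markers.csv"))
        if not markers_path.exists():
            raise DependencyError(
                f"occupancy stage needs marker table: {markers_path}"
            )
        markers = cfio.read_table(markers_path)
    sig = markers[markers["p_adj"] < 0.05] if "p_adj" in markers else markers
    enriched = list(sig.loc[sig["avg_log2FC"] > 0, "gene"].astype(str))
    spec = synthio.SimSpec("genome", seed, {
        "n_genes": int(params.get("n_genes", 2000)),
        "enriched_genes": enriched,
        "p_in": float(params.get("p_in", 0.8)),
        "p_out": float(params.get("p_out", 0.1)),
    })
    peaks, tss, _ = synthio.gen_genome_fixture(spec)
    bed_path = out / "peaks.bed"
    cfio.write_bed(peaks, bed_path)
    tss_path = out / "tss.tsv"
    cfio.write_table(tss, tss_path)
    result = run_simulation(
        markers=sig, universe=list(tss["gene"]),
        peaks_per_tf={"TF": peaks}, tss=tss,
        n_random=int(params.get("n_random", 10)),
        random_size=int(params.get("random_size", 150)),
        seed=seed,
    )
    res_path = out / "enrichment.csv"
    cfio.write_table(result, res_path)
    return [bed_path, tss_path, res_path]


def _stage_mito(out: Path, seed: int, params: dict) -> list[Path]:
    spec = synthio.SimSpec("ocr", seed, params, n_replicates=6)
    traces, _ = synthio.gen_ocr_trace(spec)
    rows = []
    for i, tr in enumerate(traces):
        sp = stress_params(phase_levels(tr), tr.cell_count)
        rows.append({"well": i, **sp.as_dict()})
    path = out / "mito_params.csv"
    cfio.write_table(pd.DataFrame(rows), path)
    return [path]


def run(config: RunConfig) -> dict:
    """Execute the requested stages and write a reproducibility manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    markers_table: pd.DataFrame | None = None

    order = [s for s in STAGES if s in config.stages]
    for stage in order:
        seed = child_seed(config.seed, stage)
        params = config.params.get(stage, {})
        log.info("running stage %s (seed %d)", stage, seed)
        if stage == "ap":
            artifacts += _stage_ap(out, seed, params)
        elif stage == "afm":
            artifacts += _stage_afm(out, seed, params)
        elif stage == "qpm":
            artifacts += _stage_qpm(out, seed, params)
        elif stage == "markers":
            paths, markers_table = _stage_markers(out, seed, params)
            artifacts += paths
        elif stage == "occupancy":
            artifacts += _stage_occupancy(out, seed, params, markers_table)
        elif stage == "mito":
            artifacts += _stage_mito(out, seed, params)

    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir")  # manifests compare across output locations
    manifest = {
        "config": cfg_dict,
        "seed": config.seed,
        "stage_seeds": {s: child_seed(config.seed, s) for s in order},
        "artifacts": {
            str(p.relative_to(out)): sha256_file(p) for p in artifacts
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
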