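"""End-to-end pipeline orchestration with seeded reproducibility.

A single :class:`PipelineConfig` drives simulate/read -> saturation gating
-> arcsinh transform -> equal-size pooling -> embedding -> gating ->
quantification -> map comparison -> rare-cluster detection, writing every
stage product plus a manifest of seeds, sizes and file checksums. Stage
seeds are derived deterministically from one master seed, so stages can be
re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .errors import PipelineStageError
from .fcio import read_events_csv
from .preprocess import (CROWD_LIMIT, arcsinh_transform, filter_saturated,
                         subsample_equal, transform_sample)
from .embedding import compute_visne
from .mapcompare import mmd_matrix
from .subpop import assign_gates, auto_gates, detect_small_clusters, GateSet, quantify

logger = logging.getLogger(__name__)


def derive_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31 from a master seed and label."""
    h = hashlib.blake2b(label.encode(), key=str(int(master)).encode(),
                        digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (round-trips through YAML)."""

    output_dir: str
    fixture: str | None = "field_analog"   # or None with input_csvs set
    input_csvs: list = field(default_factory=list)
    spike_site: str | None = "D"
    spike_fraction: float = 0.01
    n_per_site: int = 5_000
    cofactor: float = 150.0
    per_sample_n: int = 5_000
    crowd_limit: int = CROWD_LIMIT
    perplexity: float = 30.0
    n_iter: int = 1000
    engine: str = "auto"
    max_landmarks: int = 5_000
    gate_file: str | None = None
    gate_core_quantile: float = 0.95
    detect_min_points: int = 20
    detect_max_fraction: float = 0.02
    mmd_subsample_n: int = 3_000
    master_seed: int = 0

    def save(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, returning the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": config.master_seed, "stages": {}, "files": {}}
    t_all = time.time()

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # preserve partial outputs, name the stage
                _write_manifest(out, manifest)
                raise PipelineStageError(name, str(exc)) from exc
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
            logger.info("stage %s done in %.2fs", name, time.time() - t0)
            return result
        return wrap

    # --- input -------------------------------------------------------------
    def load_inputs():
        if config.fixture == "field_analog":
            return synthetic.field_analog_samples(
                n_per_site=config.n_per_site,
                seed=derive_seed(config.master_seed, "simulate"),
                spike_site=config.spike_site,
                spike_fraction=config.spike_fraction)
        if config.fixture is not None:
            raise ValueError(f"unknown fixture {config.fixture!r}")
        panel = synthetic.build_default_panel()
        return [read_events_csv(p, panel) for p in config.input_csvs]
    samples = stage("input")(load_inputs)

    # --- preprocess --------------------------------------------------------
    def preprocess():
        gated = []
        removed = 0
        for s in samples:
            g, r = filter_saturated(s)
            removed += r
            gated.append(transform_sample(g, config.cofactor))
        pool = subsample_equal(gated, config.per_sample_n,
                               derive_seed(config.master_seed, "subsample"),
                               config.crowd_limit)
        manifest["stages"].setdefault("preprocess", {})
        manifest["n_saturated_removed"] = removed
        return pool
    pool = stage("preprocess")(preprocess)

    # --- embedding ---------------------------------------------------------
    def embed():
        vmap = compute_visne(pool, config.perplexity, config.n_iter,
                             derive_seed(config.master_seed, "embed"),
                             config.engine, config.max_landmarks)
        vmap.save(out / "map")
        return vmap
    vmap = stage("embed")(embed)

    # --- gates -------------------------------------------------------------
    def gate():
        if config.gate_file:
            gates = GateSet.load(config.gate_file)
        else:
            if vmap.labels is None:
                raise ValueError("no gate file and no per-event labels for auto-gating")
            gates = auto_gates(vmap, core_quantile=config.gate_core_quantile)
        gates.save(out / "gates.txt")
        return gates
    gates = stage("gate")(gate)

    # --- quantify ----------------------------------------------------------
    def quant():
        labels = assign_gates(vmap, gates)
        table = quantify(labels, vmap.origin)
        table.counts.to_csv(out / "subpop_counts.csv")
        table.fractions.to_csv(out / "subpop_fractions.csv")
        return table
    table = stage("quantify")(quant)

    # --- map comparison ----------------------------------------------------
    def mmd():
        ids = pool.sample_ids
        sets = [vmap.coords[vmap.origin == sid] for sid in ids]
        matrix, _ = mmd_matrix(sets, names=ids,
                               subsample_n=config.mmd_subsample_n,
                               seed=derive_seed(config.master_seed, "mmd"))
        matrix.to_csv(out / "mmd_matrix.csv")
        return matrix
    stage("mmd")(mmd)

    # --- rare clusters -----------------------------------------------------
    def detect():
        clusters = detect_small_clusters(vmap, config.detect_min_points,
                                         config.detect_max_fraction)
        rows = []
        for i, cl in enumerate(clusters):
            rows.append({"cluster": i, "n_points": len(cl["indices"]),
                         "centroid_x": cl["centroid"][0],
                         "centroid_y": cl["centroid"][1],
                         **{f"n_{k}": v for k, v in cl["incidence"].items()}})
        pd.DataFrame(rows).to_csv(out / "rare_clusters.csv", index=False)
        return clusters
    stage("detect")(detect)

    # --- report ------------------------------------------------------------
    def report():
        cfg_path = out / "config.yaml"
        config.save(cfg_path)
        return cfg_path
    stage("report")(report)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _checksum(p)
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
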