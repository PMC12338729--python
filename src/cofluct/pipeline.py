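"""End-to-end pipeline driver: simulate/load -> score -> analyse -> write.

``run_pipeline`` executes the configured stages (standardize, amplitudes,
binning and scoring always; trajectory modeling, axis alignment and
condition contrasts on request), writes every artifact as TSV, and records
a manifest with input hashes, the seed, the package version and per-stage
timings.  Numeric outputs are deterministic functions of (inputs, config,
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import alignment_profile
from .contrasts import condition_contrast
from .io import (
    read_frame_mask,
    read_geometry,
    read_reference_map,
    read_scan,
    write_score_matrix,
    write_table,
)
from .edges import standardize_scan
from .scoring import group_average_scores, score_scan
from .synthetic import SyntheticCohortSpec, generate_cohort
from .trajectories import SmoothConfig, fit_all_regions, fits_to_frame

log = logging.getLogger(__name__)

ALL_STAGES = ("score", "trajectories", "alignment", "contrast")


@dataclass
class PipelineConfig:
    """Run configuration; defaults mirror the analysis conventions."""

    out_dir: str = "cofluct_out"
    seed: int = 0
    n_bins: int = 20
    fd_threshold: float = 0.2
    n_rotations: int = 10000
    high_range: tuple[float, float] = (0.9, 1.0)
    intermediate_range: tuple[float, float] = (0.4, 0.6)
    n_basis: int = 10
    stages: tuple[str, ...] = ("score",)
    # synthetic-cohort input (used when scan_paths is empty)
    simulate: dict = field(default_factory=dict)
    conditions: tuple[str, ...] = ("rest",)
    # real-data input
    scan_paths: tuple[str, ...] = ()
    fd_paths: tuple[str, ...] = ()
    covariates_path: str = ""
    geometry_path: str = ""
    reference_map_path: str = ""

    def __post_init__(self):
        if self.n_bins < 1 or self.n_rotations < 1 or self.n_basis < 4:
            raise ValueError("numeric config fields must be positive (n_basis >= 4)")
        for lo, hi in (self.high_range, self.intermediate_range):
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError("bin ranges must lie within [0, 1]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("high_range", "intermediate_range", "stages", "conditions",
                    "scan_paths", "fd_paths"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_subjects(config: PipelineConfig, condition: str):
    """Return (scans, covariates, geometry) from simulation or TSV inputs."""
    if not config.scan_paths:
        spec = SyntheticCohortSpec(seed=config.seed, **config.simulate)
        cohort = generate_cohort(spec, condition=condition)
        return cohort.scans, cohort.covariates, cohort.geometry
    from .io import read_table

    scans = []
    for k, sp in enumerate(config.scan_paths):
        raw, region_ids = read_scan(sp)
        mask = None
        if config.fd_paths:
            mask = read_frame_mask(config.fd_paths[k], config.fd_threshold)
        sid = Path(sp).stem
        scans.append(standardize_scan(raw, mask, region_ids=region_ids,
                                      scan_id=sid, subject_id=sid))
    covariates = read_table(config.covariates_path).set_index("subject_id", drop=False) \
        if config.covariates_path else None
    geometry = read_geometry(config.geometry_path) if config.geometry_path else None
    return scans, covariates, geometry


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
        "stages": {},
        "artifacts": [],
        "input_hashes": {str(p): _sha256(Path(p))
                         for p in (*config.scan_paths, *config.fd_paths)
                         if Path(p).exists()},
    }

    def _record(stage: str, t0: float, **counts):
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3), **counts}

    def _write(name: str, writer, obj):
        path = out / name
        writer(path, obj)
        manifest["artifacts"].append(name)

    stage = "score"
    try:
        t0 = time.perf_counter()
        per_condition: dict[str, list] = {}
        covariates = geometry = None
        for condition in config.conditions:
            scans, covariates, geometry = _load_subjects(config, condition)
            mats = [score_scan(s, config.n_bins, condition=condition) for s in scans]
            per_condition[condition] = mats
            for m in mats:
                _write(f"scores_{condition}_{m.subject_id}.tsv", write_score_matrix, m)
            group = group_average_scores(mats)
            _write(f"scores_{condition}_group.tsv", write_score_matrix, group)
        base_condition = config.conditions[0]
        mats = per_condition[base_condition]
        _record(stage, t0, n_subjects=len(mats), n_bins=config.n_bins)

        if "trajectories" in config.stages:
            stage = "trajectories"
            t0 = time.perf_counter()
            if covariates is None:
                raise ValueError("trajectory stage requires subject covariates")
            cfg = SmoothConfig(n_basis=config.n_basis)
            fits, failures = fit_all_regions(mats, covariates, cfg)
            _write("trajectories.tsv", lambda p, f: write_table(p, f), fits_to_frame(fits))
            _record(stage, t0, n_regions=len(fits), n_failed=len(failures))

        if "alignment" in config.stages:
            stage = "alignment"
            t0 = time.perf_counter()
            if geometry is None:
                raise ValueError("alignment stage requires parcel geometry")
            if config.reference_map_path:
                ref = read_reference_map(config.reference_map_path)
                ref = ref.set_index("region_id").loc[mats[0].region_ids, "value"].to_numpy()
                ref_name = Path(config.reference_map_path).stem
            else:
                ref = geometry.set_index("region_id").loc[
                    mats[0].region_ids, "sa_rank"].to_numpy(dtype=float)
                ref_name = "sa_rank"
            group = group_average_scores(mats)
            prof = alignment_profile(group, ref, geometry, config.n_rotations,
                                     config.seed, reference_name=ref_name)
            _write("alignment.tsv", lambda p, f: write_table(p, f), prof.to_frame())
            _record(stage, t0, n_bins=config.n_bins, n_rotations=config.n_rotations)

        if "contrast" in config.stages:
            stage = "contrast"
            t0 = time.perf_counter()
            if len(config.conditions) < 2:
                raise ValueError("contrast stage requires two conditions")
            a, b = (per_condition[c] for c in config.conditions[:2])
            for label, rng in (("high", config.high_range),
                               ("intermediate", config.intermediate_range)):
                res = condition_contrast(a, b, rng)
                _write(f"contrast_{label}.tsv", lambda p, f: write_table(p, f), res)
            _record(stage, t0, n_pairs=len(a))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
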