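"""TSV readers and writers for every pipeline artifact.

TSV is the single interchange format: scans are frames x regions tables
with a header row of region ids, geometry/covariate/result tables are plain
column-oriented TSVs, and score matrices carry their per-bin mean global
amplitude as a ``_bin_mean_global`` footer row.  All writers use a fixed
float format so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scoring import ScoreMatrix

FLOAT_FMT = "%.17g"   # round-trips IEEE doubles exactly


class ParseError(ValueError):
    pass


def read_scan(path) -> tuple[np.ndarray, list[str]]:
    """Read a frames x regions TSV; returns (matrix, region_ids)."""
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file or empty header")
        region_ids = header.rstrip("\n").split("\t")
        seen: set[str] = set()
        for rid in region_ids:
            if rid in seen:
                raise ParseError(f"{path}: duplicate region id {rid!r} in header")
            seen.add(rid)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(region_ids):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(region_ids)} columns, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float), region_ids


def write_scan(path, matrix: np.ndarray, region_ids: list[str]) -> None:
    pd.DataFrame(matrix, columns=region_ids).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_frame_mask(path, fd_threshold: float | None = None) -> np.ndarray:
    """One-column TSV of 0/1 retention flags or FD values plus a threshold."""
    col = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].to_numpy(dtype=float)
    if fd_threshold is None:
        if not np.isin(col, (0.0, 1.0)).all():
            raise ParseError(f"{path}: mask values must be 0/1 unless a threshold is given")
        return col.astype(bool)
    return col <= fd_threshold


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_geometry(path) -> pd.DataFrame:
    geom = read_table(path)
    required = {"region_id", "hemisphere", "x", "y", "z", "sa_rank"}
    missing = required - set(geom.columns)
    if missing:
        raise ParseError(f"{path}: geometry missing columns {sorted(missing)}")
    return geom


def read_reference_map(path) -> pd.DataFrame:
    """Two-column TSV (region_id, value) for SA-rank / myelin / gene maps."""
    ref = read_table(path)
    if ref.shape[1] < 2:
        raise ParseError(f"{path}: reference map needs (region_id, value) columns")
    return ref.iloc[:, :2].set_axis(["region_id", "value"], axis=1)


def write_score_matrix(path, sm: ScoreMatrix) -> None:
    frame = pd.DataFrame(sm.scores, index=sm.region_ids, columns=sm.bin_labels)
    frame.loc["_bin_mean_global"] = sm.bin_mean_global
    frame.index.name = "region_id"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_score_matrix(path, *, subject_id: str = "", condition: str = "") -> ScoreMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "_bin_mean_global" not in frame.index:
        raise ParseError(f"{path}: missing _bin_mean_global footer row")
    bin_mean = frame.loc["_bin_mean_global"].to_numpy(dtype=float)
    body = frame.drop(index="_bin_mean_global")
    return ScoreMatrix(
        scores=body.to_numpy(dtype=float),
        bin_mean_global=bin_mean,
        n_bins=frame.shape[1],
        region_ids=[str(r) for r in body.index],
        subject_id=subject_id,
        condition=condition,
    )
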