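"""Frame-wise edge co-fluctuation and its root-sum-square amplitudes.

The edge time series (ETS) of a region pair (i, j) is the element-wise
product of their z-scored BOLD timeseries, ``E_ij(t) = z_i(t) * z_j(t)``.
Its temporal mean equals the Pearson functional connectivity of the pair,
so the ETS decomposes static FC into frame-wise co-fluctuations.

Per frame, the global co-fluctuation amplitude is the root sum of squares
(RSS) of the ETS over all region pairs, and the regional amplitude is the
RSS over the edges incident to one region.  Both are evaluated through
closed forms in the z-values, so the N(N-1)/2 edge matrix is never
materialized::

    rss_global(t)   = sqrt(((sum_i z_i^2)^2 - sum_i z_i^4) / 2)
    rss_region(t,i) = sqrt(z_i^2 * (sum_j z_j^2 - z_i^2))

which satisfy ``sum_i rss_region^2 = 2 * rss_global^2`` at every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ZeroVarianceError(ValueError):
    """A region has zero variance over retained frames and cannot be z-scored."""


@dataclass
class ParcellatedScan:
    """One scan's standardized parcellated timeseries.

    ``values`` has one row per acquired frame; censored rows are NaN and
    excluded from every downstream computation.  Retained rows are z-scored
    per region (population SD) over retained frames only, so each retained
    column has mean 0 and variance 1.
    """

    values: np.ndarray            # (n_frames, n_regions), censored rows NaN
    frame_mask: np.ndarray        # (n_frames,) bool, True = retained
    region_ids: list[str]
    tr_seconds: float = 0.72
    scan_id: str = ""
    subject_id: str = ""

    @property
    def z(self) -> np.ndarray:
        """Retained-frame z-scored matrix, shape (n_retained, n_regions)."""
        return self.values[self.frame_mask]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.frame_mask.sum())

    def validate(self, mean_tol: float = 1e-8, var_tol: float = 1e-6) -> None:
        z = self.z
        if z.shape[0] < 2:
            raise ValueError("scan must retain at least 2 frames")
        if np.abs(z.mean(axis=0)).max() > mean_tol:
            raise ValueError("retained-frame column means exceed tolerance")
        if np.abs(z.var(axis=0) - 1.0).max() > var_tol:
            raise ValueError("retained-frame column variances exceed tolerance")


@dataclass
class AmplitudeSeries:
    """Per-retained-frame global and regional RSS amplitudes."""

    rss_global: np.ndarray        # (n_retained,)
    rss_region: np.ndarray        # (n_retained, n_regions)
    frame_index: np.ndarray       # original frame positions of retained frames
    region_ids: list[str] = field(default_factory=list)
    scan_id: str = ""
    subject_id: str = ""

    @property
    def n_retained(self) -> int:
        return self.rss_global.shape[0]

    def validate(self, rel_tol: float = 1e-8) -> None:
        if (self.rss_global < 0).any() or (self.rss_region < 0).any():
            raise ValueError("RSS values must be non-negative")
        lhs = (self.rss_region ** 2).sum(axis=1)
        rhs = 2.0 * self.rss_global ** 2
        scale = np.maximum(rhs, 1e-300)
        if (np.abs(lhs - rhs) / scale).max() > rel_tol:
            raise ValueError("sum rule sum_i rss_region^2 = 2 rss_global^2 violated")


def standardize_scan(
    raw: np.ndarray,
    frame_mask: np.ndarray | None = None,
    *,
    region_ids: list[str] | None = None,
    tr_seconds: float = 0.72,
    scan_id: str = "",
    subject_id: str = "",
) -> ParcellatedScan:
    """Z-score a raw frames x regions matrix over retained frames.

    Mean and SD (population, ddof=0) are computed over retained frames only,
    so censored frames cannot bias standardization; censored rows are set to
    NaN in the output.  A zero-variance region raises ZeroVarianceError.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw must be a 2-D frames x regions matrix")
    n_frames, n_regions = raw.shape
    if frame_mask is None:
        frame_mask = np.ones(n_frames, dtype=bool)
    frame_mask = np.asarray(frame_mask, dtype=bool)
    if frame_mask.shape != (n_frames,):
        raise ValueError("frame_mask length must match the number of frames")
    if frame_mask.sum() < 2:
        raise ValueError("at least 2 retained frames are required")
    kept = raw[frame_mask]
    if not np.isfinite(kept).all():
        raise ValueError("non-finite values among retained frames")
    if region_ids is None:
        region_ids = [f"R{i:03d}" for i in range(n_regions)]
    if len(region_ids) != n_regions:
        raise ValueError("region_ids length must match the number of regions")

    mu = kept.mean(axis=0)
    sd = kept.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(region_ids[i] for i in dead)
        raise ZeroVarianceError(f"zero-variance region(s) over retained frames: {names}")

    values = np.full_like(raw, np.nan)
    values[frame_mask] = (kept - mu) / sd
    return ParcellatedScan(
        values=values,
        frame_mask=frame_mask,
        region_ids=list(region_ids),
        tr_seconds=tr_seconds,
        scan_id=scan_id,
        subject_id=subject_id,
    )


def edge_timeseries(scan: ParcellatedScan, pair: tuple[int, int]) -> np.ndarray:
    """Edge co-fluctuation series E_ij(t) = z_i(t) z_j(t) over retained frames.

    Its mean over retained frames equals the Pearson correlation of the two
    region columns exactly (z-scores use the population SD).
    """
    i, j = pair
    if i == j:
        raise ValueError("edge requires two distinct regions (i != j)")
    z = scan.z
    n = z.shape[1]
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"region indices ({i}, {j}) out of range for {n} regions")
    return z[:, i] * z[:, j]


def compute_amplitudes(scan: ParcellatedScan) -> AmplitudeSeries:
    """Global and regional RSS co-fluctuation amplitudes via closed forms."""
    z = scan.z
    z2 = z ** 2
    s2 = z2.sum(axis=1)               # sum_i z_i^2 per frame
    s4 = (z2 ** 2).sum(axis=1)        # sum_i z_i^4 per frame
    rss_global = np.sqrt(np.clip((s2 ** 2 - s4) / 2.0, 0.0, None))
    rss_region = np.sqrt(np.clip(z2 * (s2[:, None] - z2), 0.0, None))
    return AmplitudeSeries(
        rss_global=rss_global,
        rss_region=rss_region,
        frame_index=np.flatnonzero(scan.frame_mask),
        region_ids=list(scan.region_ids),
        scan_id=scan.scan_id,
        subject_id=scan.subject_id,
    )
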