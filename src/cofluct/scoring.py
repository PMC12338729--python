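"""Amplitude-stratified co-fluctuation scoring.

Retained frames are sorted by global RSS amplitude and partitioned into
contiguous quantile bins (default 20, i.e. 5% of timepoints per bin).  A
region's co-fluctuation score in bin m is the ratio of within-bin means

    score[i, m] = mean_{t in T_m} rss_region[t, i] / mean_{t in T_m} rss_global[t]

quantifying the region's relative contribution to whole-brain co-fluctuation
at that amplitude stratum.  When all regions carry the identical signal every
score equals sqrt(2/N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edges import AmplitudeSeries


@dataclass
class BinAssignment:
    """Partition of retained frames into amplitude quantile bins."""

    n_bins: int
    bin_of_frame: np.ndarray        # bin index per retained frame
    bin_mean_global: np.ndarray     # per-bin mean of rss_global, non-decreasing
    bin_sizes: np.ndarray           # frames per bin; differ by at most 1


@dataclass
class ScoreMatrix:
    """Regions x bins co-fluctuation score matrix (ratio of within-bin means)."""

    scores: np.ndarray              # (n_regions, n_bins)
    bin_mean_global: np.ndarray     # (n_bins,)
    n_bins: int
    region_ids: list[str] = field(default_factory=list)
    subject_id: str = ""
    condition: str = ""

    @property
    def n_regions(self) -> int:
        return self.scores.shape[0]

    @property
    def bin_labels(self) -> list[str]:
        """Amplitude-percentile labels, e.g. '00-05' ... '95-100' for 20 bins."""
        edges = np.linspace(0, 100, self.n_bins + 1)
        return [f"{edges[m]:02.0f}-{edges[m + 1]:02.0f}" for m in range(self.n_bins)]

    def bins_in_range(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bins whose amplitude-fraction interval lies within [lo, hi].

        Bin m covers the fraction interval [m/B, (m+1)/B]; e.g. for 20 bins,
        (0.9, 1.0) selects the two highest-amplitude bins and (0.4, 0.6) the
        four intermediate ones.
        """
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("bin range must satisfy 0 <= lo < hi <= 1")
        b = self.n_bins
        eps = 1e-9
        sel = [m for m in range(b) if m / b >= lo - eps and (m + 1) / b <= hi + eps]
        if not sel:
            raise ValueError(f"bin range [{lo}, {hi}] selects no whole bin of {b}")
        return np.asarray(sel, dtype=int)


def bin_frames(amp: AmplitudeSeries, n_bins: int = 20) -> BinAssignment:
    """Sort retained frames by global RSS and split into near-equal bins.

    Frames are sorted ascending (stable, so ties keep original frame order)
    and cut into contiguous blocks; when T is not divisible by n_bins the
    remainder frames are spread over the highest-amplitude bins.
    """
    t = amp.n_retained
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if t < 2 * n_bins:
        raise ValueError(
            f"binning needs at least {2 * n_bins} retained frames (2 per bin), got {t}"
        )
    order = np.argsort(amp.rss_global, kind="stable")
    base, rem = divmod(t, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    if rem:
        sizes[-rem:] += 1
    bin_of_frame = np.empty(t, dtype=int)
    bin_mean_global = np.empty(n_bins)
    start = 0
    for m, size in enumerate(sizes):
        block = order[start:start + size]
        bin_of_frame[block] = m
        bin_mean_global[m] = amp.rss_global[block].mean()
        start += size
    return BinAssignment(
        n_bins=n_bins,
        bin_of_frame=bin_of_frame,
        bin_mean_global=bin_mean_global,
        bin_sizes=sizes,
    )


def cofluctuation_scores(
    amp: AmplitudeSeries,
    bins: BinAssignment,
    *,
    subject_id: str | None = None,
    condition: str = "",
) -> ScoreMatrix:
    """Per-region, per-bin co-fluctuation scores as the ratio of bin means."""
    if bins.bin_of_frame.shape[0] != amp.n_retained:
        raise ValueError("bin assignment does not match the amplitude series")
    n_regions = amp.rss_region.shape[1]
    scores = np.empty((n_regions, bins.n_bins))
    for m in range(bins.n_bins):
        frames = bins.bin_of_frame == m
        assert frames.any(), "empty bin cannot occur by construction"
        scores[:, m] = amp.rss_region[frames].mean(axis=0) / amp.rss_global[frames].mean()
    return ScoreMatrix(
        scores=scores,
        bin_mean_global=bins.bin_mean_global.copy(),
        n_bins=bins.n_bins,
        region_ids=list(amp.region_ids),
        subject_id=amp.subject_id if subject_id is None else subject_id,
        condition=condition,
    )


def score_scan(scan, n_bins: int = 20, *, condition: str = "") -> ScoreMatrix:
    """Convenience: amplitudes -> bins -> scores for one standardized scan."""
    from .edges import compute_amplitudes

    amp = compute_amplitudes(scan)
    return cofluctuation_scores(amp, bin_frames(amp, n_bins), condition=condition)


def group_average_scores(
    matrices: list[ScoreMatrix],
    grouping: dict[str, str] | None = None,
):
    """Element-wise unweighted mean of score matrices, optionally per group.

    With ``grouping`` (subject_id -> group label) a dict of group label ->
    ScoreMatrix is returned; otherwise a single pooled ScoreMatrix.
    ``bin_mean_global`` is averaged the same way.
    """
    if not matrices:
        raise ValueError("no score matrices to average")
    ref = matrices[0]
    bad = [
        m.subject_id or f"#{k}"
        for k, m in enumerate(matrices)
        if m.n_bins != ref.n_bins or m.region_ids != ref.region_ids
    ]
    if bad:
        raise ValueError(f"score matrices with mismatched bins/regions: {', '.join(bad)}")

    def _mean(mats: list[ScoreMatrix], label: str) -> ScoreMatrix:
        return ScoreMatrix(
            scores=np.mean([m.scores for m in mats], axis=0),
            bin_mean_global=np.mean([m.bin_mean_global for m in mats], axis=0),
            n_bins=ref.n_bins,
            region_ids=list(ref.region_ids),
            subject_id=label,
            condition=mats[0].condition if len({m.condition for m in mats}) == 1 else "",
        )

    if grouping is None:
        return _mean(matrices, "group")
    groups: dict[str, list[ScoreMatrix]] = {}
    for m in matrices:
        label = grouping[m.subject_id]
        groups.setdefault(label, []).append(m)
    return {label: _mean(mats, label) for label, mats in sorted(groups.items())}
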