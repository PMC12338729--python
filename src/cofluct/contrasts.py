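"""Group-level condition contrasts with BH-FDR control across regions.

Rest-versus-movie (or any paired) comparisons average each subject's scores
over a stated amplitude-bin range per condition, test the within-subject
differences region by region (two-sided paired t-test by default, Wilcoxon
signed-rank as an option), and control the false discovery rate across
regions with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import ScoreMatrix


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D collection")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def condition_contrast(
    scores_a: list[ScoreMatrix],
    scores_b: list[ScoreMatrix],
    bin_range: tuple[float, float],
    *,
    alpha: float = 0.05,
    method: str = "ttest",
) -> pd.DataFrame:
    """Paired regional contrast of bin-averaged scores between two conditions.

    Subjects are paired by ``subject_id``; ``mean_difference`` is condition
    A minus condition B.  Regions whose paired differences have zero
    variance are flagged (``degenerate``) and assigned p = 1.
    """
    if len(scores_a) < 5:
        raise ValueError("paired contrast requires at least 5 subject pairs")
    by_id_b = {m.subject_id: m for m in scores_b}
    missing = [m.subject_id for m in scores_a if m.subject_id not in by_id_b]
    extra = [s for s in by_id_b if s not in {m.subject_id for m in scores_a}]
    if missing or extra:
        raise ValueError(
            f"unpaired subjects: missing in B {missing}, missing in A {extra}"
        )
    ref = scores_a[0]
    sel = ref.bins_in_range(*bin_range)
    a = np.stack([m.scores[:, sel].mean(axis=1) for m in scores_a])          # (S, N)
    b = np.stack([by_id_b[m.subject_id].scores[:, sel].mean(axis=1) for m in scores_a])
    diff = a - b
    mean_diff = diff.mean(axis=0)
    degenerate = diff.std(axis=0) == 0

    t_stat = np.full(ref.n_regions, np.nan)
    p_raw = np.ones(ref.n_regions)
    live = ~degenerate
    if live.any():
        if method == "ttest":
            res = stats.ttest_rel(a[:, live], b[:, live], axis=0)
            t_stat[live], p_raw[live] = res.statistic, res.pvalue
        elif method == "wilcoxon":
            for j in np.flatnonzero(live):
                res = stats.wilcoxon(a[:, j], b[:, j])
                t_stat[j], p_raw[j] = res.statistic, res.pvalue
        else:
            raise ValueError(f"unknown contrast method {method!r}")
    p_fdr = bh_fdr(p_raw)
    return pd.DataFrame({
        "region_id": ref.region_ids,
        "mean_difference": mean_diff,
        "t_statistic": t_stat,
        "p_raw": p_raw,
        "p_fdr": p_fdr,
        "significant": p_fdr < alpha,
        "degenerate": degenerate,
    })
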