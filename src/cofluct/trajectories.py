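"""Penalized-smooth trajectories of co-fluctuation score versus amplitude.

Each region's score is modeled across subjects and amplitude bins as

    score ~ f(global_amplitude) + b1*sex + b2*mean_fd

where f is a penalized regression spline (P-spline: uniform cubic B-spline
basis, default dimension 10, second-order difference penalty) whose
smoothing parameter is selected by generalized cross-validation.  Because
the second-difference penalty leaves straight lines unpenalized, the fit
reproduces linear trends exactly in the heavy-smoothing limit.

The amplitude association is summarized by

* the *primary amplitude effect*: partial R^2 of the smooth term relative to
  a nested model without it, signed by the average first derivative of the
  fitted curve, and
* the *second amplitude effect*: the average second derivative of the fitted
  curve (negative = inverted-U, positive = U-shaped),

with derivatives taken by central finite differences on a 200-point uniform
amplitude grid.  Significance of the smooth is an F-type comparison of the
full versus reduced residual sums of squares using effective degrees of
freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space

from .scoring import ScoreMatrix

log = logging.getLogger(__name__)

#: second-derivative magnitudes below this are treated as numerically flat
SECOND_DERIV_FLOOR = 1e-3


@dataclass
class SmoothConfig:
    """Tunable knobs of the penalized-spline smooth."""

    n_basis: int = 10
    degree: int = 3
    lambdas: np.ndarray = field(default_factory=lambda: np.logspace(-6.0, 8.0, 57))
    criterion: str = "reml"        # "reml" or "gcv" smoothing-parameter selection
    grid_size: int = 200
    alpha: float = 0.05


@dataclass
class TrajectoryFit:
    """Per-region summary of the amplitude smooth."""

    region_id: str
    partial_r2: float
    p_smooth: float
    mean_first_derivative: float
    mean_second_derivative: float
    primary_effect: float
    fitted_curve: np.ndarray        # (grid_size, 2): amplitude, predicted score
    edf: float
    lambda_: float
    regime: str = ""


class PenalizedSpline:
    """Uniform-knot cubic P-spline with difference penalty and linear covariates.

    The B-spline basis is built on equally spaced knots extended beyond the
    observed range, so the null space of the second-order difference penalty
    corresponds exactly to linear functions of x.  A sum-to-zero constraint on
    the (centered) basis keeps the model identifiable next to the intercept.
    """

    def __init__(self, config: SmoothConfig | None = None):
        self.config = config or SmoothConfig()

    def _basis(self, x: np.ndarray) -> np.ndarray:
        k = self.config.degree
        # clip to the spline's base interval; knot arithmetic can differ from
        # (xmin, xmax) in the last ulp
        x = np.clip(x, self.knots_[k], self.knots_[-k - 1])
        return BSpline.design_matrix(x, self.knots_, k).toarray()

    def fit(self, x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None):
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = x.shape[0]
        self.xmin_, self.xmax_ = float(x.min()), float(x.max())
        if self.xmax_ <= self.xmin_:
            raise ValueError("smooth term requires non-constant x")
        nseg = cfg.n_basis - cfg.degree
        h = (self.xmax_ - self.xmin_) / nseg
        self.knots_ = self.xmin_ + h * np.arange(-cfg.degree, nseg + cfg.degree + 1)

        b = self._basis(x)
        self.b_colmeans_ = b.mean(axis=0)
        z = null_space(np.ones((1, cfg.n_basis)))          # (k, k-1)
        self.z_ = z
        bt = (b - self.b_colmeans_) @ z

        if covariates is None:
            covariates = np.empty((n, 0))
        self.cov_means_ = covariates.mean(axis=0) if covariates.size else np.empty(0)
        xmat = np.column_stack([np.ones(n), covariates, bt])
        p_lin = 1 + covariates.shape[1]
        d = np.diff(np.eye(cfg.n_basis), n=2, axis=0)
        s_small = z.T @ d.T @ d @ z
        pen = np.zeros((xmat.shape[1], xmat.shape[1]))
        pen[p_lin:, p_lin:] = s_small

        xtx = xmat.T @ xmat
        xty = xmat.T @ y
        p = xmat.shape[1]
        r_pen = np.linalg.matrix_rank(s_small)          # penalized dimensions
        m_null = p - r_pen                              # unpenalized dimensions
        best = None
        for lam in cfg.lambdas:
            a = xtx + lam * pen
            try:
                c = cho_factor(a)
            except np.linalg.LinAlgError:
                continue
            beta = cho_solve(c, xty)
            edf = float(np.trace(cho_solve(c, xtx)))
            resid = y - xmat @ beta
            sse = float(resid @ resid)
            if cfg.criterion == "gcv":
                denom = max(n - edf, 1e-8)
                crit = n * sse / denom ** 2
            elif cfg.criterion == "reml":
                # Gaussian restricted likelihood with sigma^2 profiled out:
                # (n - m_null) log(sig2) + log|X'X + lam*S| - rank(S) log(lam)
                pen_quad = float(lam * beta @ pen @ beta)
                sig2 = max((sse + pen_quad) / max(n - m_null, 1.0), 1e-30)
                logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
                crit = (n - m_null) * np.log(sig2) + logdet - r_pen * np.log(lam)
            else:
                raise ValueError(f"unknown smoothing criterion {cfg.criterion!r}")
            if best is None or crit < best[0]:
                best = (crit, lam, beta, edf, sse)
        if best is None:
            raise RuntimeError("penalized spline solve failed for every smoothing value")
        _, self.lambda_, self.beta_, self.edf_, self.sse_ = best
        self.n_ = n
        self.p_lin_ = p_lin
        return self

    def predict_curve(self, grid: np.ndarray) -> np.ndarray:
        """Predicted score on an amplitude grid at training-mean covariates."""
        bt = (self._basis(grid) - self.b_colmeans_) @ self.z_
        lin = np.column_stack([np.ones(len(grid)), np.tile(self.cov_means_, (len(grid), 1))])
        return np.column_stack([lin, bt]) @ self.beta_


def _as_observation_frame(observations) -> pd.DataFrame:
    obs = pd.DataFrame(observations)
    required = {"score", "global_amplitude"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    return obs


def fit_trajectory(
    observations,
    smooth_config: SmoothConfig | None = None,
    *,
    region_id: str = "",
    smooth_column: str = "global_amplitude",
    covariate_columns: tuple[str, ...] = ("sex", "mean_fd"),
) -> TrajectoryFit:
    """Fit the amplitude smooth for one region and extract its effects."""
    cfg = smooth_config or SmoothConfig()
    obs = _as_observation_frame(observations)
    if smooth_column != "global_amplitude":
        obs = obs.rename(columns={smooth_column: "global_amplitude"})
    x = obs["global_amplitude"].to_numpy(dtype=float)
    y = obs["score"].to_numpy(dtype=float)
    if len(obs) < 10:
        raise ValueError("at least 10 observations are required")
    if np.unique(x).size < 3:
        raise ValueError("at least 3 distinct amplitude values are required")

    cov_cols = []
    for c in covariate_columns:
        if c not in obs.columns:
            continue
        v = obs[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            log.warning("dropping constant covariate %r from trajectory model", c)
            continue
        cov_cols.append(v)
    covs = np.column_stack(cov_cols) if cov_cols else np.empty((len(obs), 0))

    # reduced model: intercept + linear covariates only
    xr = np.column_stack([np.ones(len(obs)), covs])
    beta_r, *_ = np.linalg.lstsq(xr, y, rcond=None)
    sse_r = float(np.sum((y - xr @ beta_r) ** 2))

    model = PenalizedSpline(cfg).fit(x, y, covs)
    sse_f = float(model.sse_)

    if float(np.var(y)) < 1e-15:
        partial_r2, p_smooth = 0.0, 1.0           # constant response: null model
    elif sse_r <= 0:
        partial_r2, p_smooth = 0.0, 1.0
    else:
        partial_r2 = float(np.clip((sse_r - sse_f) / sse_r, 0.0, 1.0))
        df1 = max(model.edf_ - xr.shape[1], 1e-6)
        df2 = max(len(obs) - model.edf_, 1.0)
        if sse_f <= 0:
            p_smooth = 0.0 if sse_r > sse_f else 1.0
        else:
            f_stat = ((sse_r - sse_f) / df1) / (sse_f / df2)
            p_smooth = float(stats.f.sf(max(f_stat, 0.0), df1, df2))

    grid = np.linspace(model.xmin_, model.xmax_, cfg.grid_size)
    pred = model.predict_curve(grid)
    d1 = np.gradient(pred, grid)
    d2 = np.gradient(d1, grid)
    mean_d1 = float(d1.mean())
    mean_d2 = float(d2.mean())
    return TrajectoryFit(
        region_id=region_id,
        partial_r2=partial_r2,
        p_smooth=p_smooth,
        mean_first_derivative=mean_d1,
        mean_second_derivative=mean_d2,
        primary_effect=float(np.sign(mean_d1) * partial_r2),
        fitted_curve=np.column_stack([grid, pred]),
        edf=float(model.edf_),
        lambda_=float(model.lambda_),
    )


def classify_regime(fit: TrajectoryFit, alpha: float = 0.05) -> str:
    """Label a trajectory {increasing, inverted-U, decreasing, flat}.

    A region is flat when the smooth is not significant; inverted-U when the
    scale-normalized average second derivative (curvature in units of score
    range per squared amplitude range, so the floor is invariant to the
    units of either axis) is below the numerical floor and the fitted curve
    peaks strictly inside the amplitude range; otherwise the sign of the
    primary effect decides.
    """
    if fit.p_smooth >= alpha:
        return "flat"
    grid, pred = fit.fitted_curve[:, 0], fit.fitted_curve[:, 1]
    y_range = max(float(np.ptp(pred)), 1e-300)
    curvature = fit.mean_second_derivative * float(np.ptp(grid)) ** 2 / y_range
    k = int(np.argmax(pred))
    interior_peak = 0 < k < len(pred) - 1 and pred[k] > max(pred[0], pred[-1])
    if curvature < -SECOND_DERIV_FLOOR and interior_peak:
        return "inverted-U"
    return "increasing" if fit.primary_effect > 0 else "decreasing"


def build_observations(
    score_matrices: list[ScoreMatrix],
    covariates: pd.DataFrame,
    region_index: int,
) -> pd.DataFrame:
    """Stack subject x bin observations for one region.

    ``covariates`` must be indexed by subject_id with columns sex, mean_fd
    (and optionally age); the amplitude regressor is each subject's own
    per-bin mean global RSS.
    """
    frames = []
    for m in score_matrices:
        cov = covariates.loc[m.subject_id]
        frames.append(pd.DataFrame({
            "score": m.scores[region_index],
            "global_amplitude": m.bin_mean_global,
            "sex": float(cov["sex"]),
            "mean_fd": float(cov["mean_fd"]),
            "subject_id": m.subject_id,
        }))
    return pd.concat(frames, ignore_index=True)


def fit_all_regions(
    score_matrices: list[ScoreMatrix],
    covariates: pd.DataFrame,
    smooth_config: SmoothConfig | None = None,
) -> tuple[list[TrajectoryFit], dict[str, str]]:
    """Fit every region's trajectory; failures are collected, not fatal.

    Returns the successful fits (with ``regime`` labels attached) and a dict
    of region_id -> error message for regions that failed.
    """
    cfg = smooth_config or SmoothConfig()
    ref = score_matrices[0]
    bad = [m.subject_id for m in score_matrices if m.region_ids != ref.region_ids]
    if bad:
        raise ValueError(f"inconsistent region sets for subjects: {bad}")
    fits: list[TrajectoryFit] = []
    failures: dict[str, str] = {}
    for i, rid in enumerate(ref.region_ids):
        obs = build_observations(score_matrices, covariates, i)
        try:
            fit = fit_trajectory(obs, cfg, region_id=rid)
        except Exception as exc:  # propagate per-region, keep the batch alive
            failures[rid] = str(exc)
            log.warning("trajectory fit failed for region %s: %s", rid, exc)
            continue
        fit.regime = classify_regime(fit, cfg.alpha)
        fits.append(fit)
    return fits, failures


def fits_to_frame(fits: list[TrajectoryFit]) -> pd.DataFrame:
    return pd.DataFrame({
        "region_id": [f.region_id for f in fits],
        "partial_r2": [f.partial_r2 for f in fits],
        "p_smooth": [f.p_smooth for f in fits],
        "primary_effect": [f.primary_effect for f in fits],
        "mean_first_derivative": [f.mean_first_derivative for f in fits],
        "mean_second_derivative": [f.mean_second_derivative for f in fits],
        "edf": [f.edf for f in fits],
        "regime": [f.regime for f in fits],
    })


def age_effect(
    score_matrices: list[ScoreMatrix],
    covariates: pd.DataFrame,
    bin_range: tuple[float, float],
    smooth_config: SmoothConfig | None = None,
) -> pd.DataFrame:
    """Smooth age effect on mean scores over a bin range, per region.

    For each subject the scores are averaged over the requested amplitude
    bins; the same penalized-spline machinery is then fitted with age as the
    smooth term and sex + mean FD as linear covariates.  Returns a frame
    with the signed partial R^2 (sign of the average first derivative with
    respect to age) and p-value per region.
    """
    cfg = smooth_config or SmoothConfig()
    if len(score_matrices) < 15:
        raise ValueError("age effect requires at least 15 subjects")
    ages = covariates.loc[[m.subject_id for m in score_matrices], "age"].to_numpy(float)
    if np.unique(ages).size < 3:
        raise ValueError("age effect requires at least 3 distinct ages")
    ref = score_matrices[0]
    sel = ref.bins_in_range(*bin_range)
    rows = []
    for i, rid in enumerate(ref.region_ids):
        obs = pd.DataFrame({
            "score": [m.scores[i, sel].mean() for m in score_matrices],
            "global_amplitude": ages,
            "sex": covariates.loc[[m.subject_id for m in score_matrices], "sex"].to_numpy(float),
            "mean_fd": covariates.loc[[m.subject_id for m in score_matrices], "mean_fd"].to_numpy(float),
        })
        fit = fit_trajectory(obs, cfg, region_id=rid)
        rows.append((rid, fit.primary_effect, fit.p_smooth))
    return pd.DataFrame(rows, columns=["region_id", "age_effect", "p_value"])


def trajectory_similarity(profile_a, profile_b) -> float:
    """Spearman rank correlation between two per-bin profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("profiles must be equal-length 1-D sequences of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant profile: rank correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)
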