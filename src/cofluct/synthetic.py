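"""Synthetic BOLD cohorts with known amplitude-dependent co-fluctuation.

The generator stands in for access-controlled resting-state fMRI cohorts.
Each frame draws a latent global-amplitude state ``a ~ Uniform(0, 1)`` and
one shared factor per region class; region i of class k observes

    x_i(t) = sqrt(g_k(a(t))) * f_k(t) + noise_sd * eps_i(t)

so regions of one class co-fluctuate through their shared factor with an
amplitude-dependent coupling gain g_k.  Three classes emulate the three
empirical regimes of amplitude-dependent engagement:

* ``S`` (sensorimotor-like):  g_S(a) = 0.1 + 1.8 a^2        (increasing)
* ``A`` (association-like):   g_A(a) = 0.1 + 3.6 a (1 - a)  (inverted-U)
* ``L`` (limbic-like):        g_L(a) = 0.1 + 0.45 (1 - a)^2 (decreasing)

The gain amplitudes are scaled so the summed coupling increases with ``a``:
that makes the realized global RSS a monotone (noisy) readout of the latent
state, which is what lets quantile binning on realized amplitude recover
the three regimes.  Mirror-symmetric gains would leave the realized
amplitude uninformative about ``a`` and no class could appear "decreasing".

Parcel geometry places centroids uniformly on a unit hemisphere pair and
derives a spatially autocorrelated sensorimotor-association (SA) rank from
latitude; classes are assigned by SA-rank tertile (S lowest).  A
developmental option sharpens the gain contrast with age, and a "movie"
condition boosts the coupling of the visual subset of S regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .edges import ParcellatedScan, standardize_scan

log = logging.getLogger(__name__)

_CONDITION_CODES = {"rest": 0, "movie": 1}

#: (baseline, modulation amplitude) per region class
_GAIN_AMPLITUDES = {"S": 1.8, "A": 0.9, "L": 0.45}
_BASELINE = 0.1


def _unit_modulation(region_class: str, a: np.ndarray) -> np.ndarray:
    """Class modulation shape, mapped to [0, 1]."""
    if region_class == "S":
        return a ** 2
    if region_class == "A":
        return 4.0 * a * (1.0 - a)
    if region_class == "L":
        return (1.0 - a) ** 2
    raise ValueError(f"unknown region class {region_class!r}")


@dataclass
class GainProfile:
    """Amplitude-to-coupling gain of one region class."""

    region_class: str
    gain_function: callable
    baseline: float = _BASELINE

    def validate(self, n_grid: int = 401) -> None:
        a = np.linspace(0.0, 1.0, n_grid)
        g = self.gain_function(a)
        if self.baseline <= 0 or (g < self.baseline - 1e-12).any():
            raise ValueError(f"gain must stay >= baseline > 0 for class {self.region_class}")
        d = np.diff(g)
        if self.region_class == "S" and (d < -1e-12).any():
            raise ValueError("S gain must be non-decreasing")
        if self.region_class == "L" and (d > 1e-12).any():
            raise ValueError("L gain must be non-increasing")
        if self.region_class == "A":
            k = int(np.argmax(g))
            if k == 0 or k == n_grid - 1 or not ((d[:k] >= -1e-12).all() and (d[k:] <= 1e-12).all()):
                raise ValueError("A gain must be unimodal with an interior maximum")


def gain_profile(region_class: str, *, gamma: float = 1.0, boost: float = 1.0) -> GainProfile:
    """Default gain for a class; ``gamma`` sharpens the contrast, ``boost`` scales it."""
    amp = _GAIN_AMPLITUDES[region_class] * boost
    g = max(gamma, 0.05)

    def fn(a, _amp=amp, _g=g, _cls=region_class):
        return _BASELINE + _amp * _unit_modulation(_cls, np.asarray(a, dtype=float)) ** _g

    return GainProfile(region_class=region_class, gain_function=fn)


@dataclass
class SyntheticCohortSpec:
    """Study-condition parameters of one synthetic cohort."""

    n_subjects: int = 20
    n_regions_per_class: tuple[int, int, int] = (20, 20, 20)
    n_frames: int = 2000
    noise_sd: float = 0.25
    age_range: tuple[float, float] = (22.0, 36.0)
    dev_sharpening: float = 0.0      # gain-contrast exponent slope per year past age 6
    seed: int = 0
    fd_threshold: float = 0.2        # mm; frames above are censored
    ar_coef: float = 0.0             # AR(1) coefficient of the latent state (off by default)
    movie_gain_boost: float = 1.5    # coupling boost of visual S regions under "movie"

    def __post_init__(self):
        if self.n_subjects < 1 or min(self.n_regions_per_class) < 1 or self.n_frames < 2:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_regions(self) -> int:
        return int(sum(self.n_regions_per_class))

    def scan_seed(self, subject_index: int, condition: str = "rest") -> int:
        """Deterministic per-scan seed derived from the cohort seed."""
        code = _CONDITION_CODES[condition]
        ss = np.random.SeedSequence(self.seed, spawn_key=(1, subject_index, code))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_parcel_geometry(n_regions: int, seed: int) -> pd.DataFrame:
    """Parcel centroids on the unit sphere with a latitude-driven SA rank.

    Half the parcels go to each hemisphere.  The SA rank is the rank of a
    smooth function of latitude (plus a small longitude ripple), so the
    axis is spatially autocorrelated; region classes are SA-rank tertiles
    (S = lowest ranks, A = middle, L = highest).
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even (split across hemispheres)")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    rows = []
    for hemi in ("L", "R"):
        v = rng.standard_normal((half, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[:, 0] = np.abs(v[:, 0]) * (-1.0 if hemi == "L" else 1.0)
        for c in v:
            rows.append((hemi, *c))
    geom = pd.DataFrame(rows, columns=["hemisphere", "x", "y", "z"])
    geom.insert(0, "region_id", [f"R{i:03d}" for i in range(n_regions)])
    axis_value = geom["z"] + 0.15 * np.sin(3.0 * np.arctan2(geom["y"], geom["x"]))
    geom["sa_rank"] = rankdata(axis_value, method="ordinal").astype(int)
    tertile = np.searchsorted(
        np.quantile(geom["sa_rank"], [1 / 3, 2 / 3]), geom["sa_rank"], side="left"
    )
    geom["region_class"] = np.array(["S", "A", "L"])[tertile]
    networks = {
        "S": ("Vis", "SomMot"),
        "A": ("DorsAttn", "Cont"),
        "L": ("Limbic", "Default"),
    }
    labels = []
    counters: dict[str, int] = {}
    for cls in geom["region_class"]:
        k = counters.get(cls, 0)
        counters[cls] = k + 1
        labels.append(networks[cls][k % 2])
    geom["network_label"] = labels
    return geom


def _latent_amplitude(rng: np.random.Generator, n: int, ar_coef: float) -> np.ndarray:
    if ar_coef == 0.0:
        return rng.uniform(0.0, 1.0, n)
    # AR(1) Gaussian latent mapped through the normal CDF -> Uniform(0,1) margins
    e = rng.standard_normal(n)
    g = np.empty(n)
    g[0] = e[0]
    s = np.sqrt(1.0 - ar_coef ** 2)
    for t in range(1, n):
        g[t] = ar_coef * g[t - 1] + s * e[t]
    return norm.cdf(g)


def generate_scan(
    spec: SyntheticCohortSpec,
    geometry: pd.DataFrame,
    subject_params,
    seed: int,
) -> ParcellatedScan:
    """One subject's scan: latent-state-gated class factors plus i.i.d. noise.

    ``subject_params`` carries age, mean_fd, condition and subject_id.  The
    gain-contrast exponent grows with age as ``1 + dev_sharpening * (age - 6)``,
    and under the "movie" condition the visual S regions get their coupling
    amplitude multiplied by ``movie_gain_boost``.  Columns are z-scored over
    retained (low-motion) frames.
    """
    classes = geometry["region_class"].to_numpy()
    counts = tuple(int((classes == c).sum()) for c in ("S", "A", "L"))
    if counts != tuple(spec.n_regions_per_class):
        raise ValueError(
            f"geometry class counts {counts} do not match spec {spec.n_regions_per_class}"
        )
    t = spec.n_frames
    if t < 10 * 20:
        log.warning(
            "n_frames=%d gives fewer than 10 frames per default bin; bins will be thin", t
        )
    age = float(subject_params.get("age", 30.0))
    mean_fd = float(subject_params.get("mean_fd", 0.1))
    condition = str(subject_params.get("condition", "rest"))
    gamma = 1.0 + spec.dev_sharpening * (age - 6.0)

    rng = np.random.default_rng(seed)
    a = _latent_amplitude(rng, t, spec.ar_coef)
    factors = {c: rng.standard_normal(t) for c in ("S", "A", "L")}
    noise = rng.standard_normal((t, spec.n_regions))
    fd = np.abs(rng.normal(mean_fd, 0.04, t))

    is_movie_vis = (classes == "S") & (geometry["network_label"].to_numpy() == "Vis")
    x = np.empty((t, spec.n_regions))
    gains = {
        (c, b): np.sqrt(gain_profile(c, gamma=gamma, boost=b).gain_function(a))
        for c in ("S", "A", "L")
        for b in ({1.0, spec.movie_gain_boost if condition == "movie" else 1.0})
    }
    for i in range(spec.n_regions):
        c = classes[i]
        boost = spec.movie_gain_boost if (condition == "movie" and is_movie_vis[i]) else 1.0
        x[:, i] = gains[(c, boost)] * factors[c] + spec.noise_sd * noise[:, i]

    mask = fd <= spec.fd_threshold
    if mask.sum() < 2:
        mask = np.ones(t, dtype=bool)   # degenerate motion draw: keep the scan usable
        log.warning("FD censoring would drop nearly all frames; mask disabled")
    subject_id = str(subject_params.get("subject_id", ""))
    return standardize_scan(
        x,
        mask,
        region_ids=list(geometry["region_id"]),
        scan_id=f"{subject_id}_{condition}",
        subject_id=subject_id,
    )


@dataclass
class SyntheticCohort:
    geometry: pd.DataFrame
    scans: list[ParcellatedScan]
    covariates: pd.DataFrame     # indexed by subject_id: age, sex, mean_fd, condition
    spec: SyntheticCohortSpec = field(repr=False, default=None)


def generate_cohort(spec: SyntheticCohortSpec, condition: str = "rest") -> SyntheticCohort:
    """A seeded cohort of subjects: geometry, covariates and one scan each.

    Ages are Uniform over ``age_range``, sex Bernoulli(0.5), mean FD
    |N(0.1, 0.03)|.  Scan seeds derive from the cohort seed per subject and
    condition, so the "rest" and "movie" cohorts of one spec share subjects
    (and covariates) while their scans differ.
    """
    if condition not in _CONDITION_CODES:
        raise ValueError(f"unknown condition {condition!r}")
    geometry = generate_parcel_geometry(spec.n_regions, spec.seed)
    cov_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    n = spec.n_subjects
    lo, hi = spec.age_range
    covariates = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "age": cov_rng.uniform(lo, hi, n),
        "sex": cov_rng.integers(0, 2, n).astype(float),
        "mean_fd": np.abs(cov_rng.normal(0.1, 0.03, n)),
        "condition": condition,
    }).set_index("subject_id", drop=False)
    scans = []
    for i, (sid, row) in enumerate(covariates.iterrows()):
        scans.append(generate_scan(spec, geometry, row, spec.scan_seed(i, condition)))
    return SyntheticCohort(geometry=geometry, scans=scans, covariates=covariates, spec=spec)
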