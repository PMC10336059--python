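"""Behavioral metrics from per-second 2-D tracking detections.

One detection per second is emitted while the fish is outside its refuge;
undetected seconds mean the fish is hidden.  From such tracks the test
battery derives, per individual and trial:

* exploration / sociability — time outside the refuge, minimum distance to
  a stimulus centroid (with a fixed imputed distance when the fish never
  left the refuge: 250 px for the novel object, 350 px for the
  conspecific), and time spent within a 100 px interaction radius;
* activity — time outside, travelled distance, Von Mises mean turning
  angle and concentration, and the 95% / 50% kernel utilization areas.

Spatial metrics are in pixels; ``px_to_cm`` applies the camera calibration
(1 cm = 16.7 px) for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.ndimage import gaussian_filter

from .config import ArenaConfig

__all__ = [
    "Track",
    "MetricSet",
    "InsufficientDataError",
    "time_outside_refuge",
    "min_distance_to_point",
    "interaction_time",
    "total_distance",
    "turning_angles",
    "fit_von_mises",
    "VonMisesFit",
    "utilization_area",
    "compute_metricset",
    "metrics_table",
    "px_to_cm",
]

#: Imputed minimum distance (px) when a fish never leaves the refuge,
#: per test: the average refuge-to-stimulus distance.
IMPUTE_PX = {"exploration": 250.0, "sociability": 350.0}
INTERACTION_RADIUS_PX = 100.0
MIN_POSITIONS = 20  # activity metrics require at least this many detections
KAPPA_CEILING = 500.0


class InsufficientDataError(ValueError):
    """Too few detections to compute the requested metric."""


@dataclass(frozen=True)
class Track:
    """Per-second detections of one individual in one test.

    ``t_s`` are strictly increasing integer seconds in ``[0, duration_s)``;
    a missing second means the fish was inside the refuge.
    """

    id: str
    trial: int
    test: str
    duration_s: int
    t_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=int)
        x = np.asarray(self.x_px, dtype=float)
        y = np.asarray(self.y_px, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t_s, x_px, y_px must have equal length")
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= self.duration_s):
            raise ValueError("t_s must be strictly increasing within [0, duration_s)")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "x_px", x)
        object.__setattr__(self, "y_px", y)

    @property
    def n_detections(self) -> int:
        return len(self.t_s)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_px, self.y_px])


@dataclass
class MetricSet:
    """Metrics relevant to one test; irrelevant or omitted entries are NaN.

    ``flags`` records why a metric is absent (e.g. fewer than the required
    20 positions for the activity metrics).
    """

    id: str
    trial: int
    test: str
    n_positions: int
    time_outside_s: float = np.nan
    min_distance_px: float = np.nan
    interaction_time_s: float = np.nan
    total_distance_px: float = np.nan
    turn_mu_rad: float = np.nan
    turn_kappa: float = np.nan
    area95_px2: float = np.nan
    area50_px2: float = np.nan
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "time_outside_s", "min_distance_px", "interaction_time_s",
            "total_distance_px", "turn_mu_rad", "turn_kappa",
            "area95_px2", "area50_px2", "n_positions")}
        return d


def time_outside_refuge(track: Track) -> int:
    """Seconds outside the refuge: one detection is emitted per such second."""
    return track.n_detections


def min_distance_to_point(track: Track, point: tuple[float, float],
                          impute_px: float) -> float:
    """Minimum Euclidean distance (px) from any detection to ``point``.

    A track with zero detections (the fish stayed in the refuge for the
    whole test) gets the imputed refuge-to-stimulus distance instead.
    """
    if impute_px <= 0:
        raise ValueError("impute_px must be positive")
    if track.n_detections == 0:
        return float(impute_px)
    d = np.hypot(track.x_px - point[0], track.y_px - point[1])
    return float(d.min())


def interaction_time(track: Track, point: tuple[float, float],
                     radius_px: float = INTERACTION_RADIUS_PX) -> int:
    """Detected seconds within ``radius_px`` (inclusive) of ``point``."""
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if track.n_detections == 0:
        return 0
    d = np.hypot(track.x_px - point[0], track.y_px - point[1])
    return int(np.count_nonzero(d <= radius_px))


def total_distance(track: Track) -> float:
    """Sum of Euclidean distances between consecutive detections (px).

    Detections separated by undetected (refuge) seconds still form one
    consecutive pair; positions are not interpolated across the gap.
    """
    if track.n_detections < 2:
        return 0.0
    steps = np.hypot(np.diff(track.x_px), np.diff(track.y_px))
    return float(steps.sum())


def turning_angles(track: Track) -> np.ndarray:
    """Signed turning angles in (−π, π] between consecutive displacements.

    Zero-length displacements carry no heading and are skipped.  Requires
    at least three detections (two displacements).
    """
    if track.n_detections < 3:
        raise InsufficientDataError("turning angles need at least 3 detections")
    dx, dy = np.diff(track.x_px), np.diff(track.y_px)
    moving = (dx != 0) | (dy != 0)
    headings = np.arctan2(dy[moving], dx[moving])
    if len(headings) < 2:
        return np.empty(0)
    d = np.diff(headings)
    d = d - 2.0 * np.pi * np.floor((d + np.pi) / (2.0 * np.pi))  # to [-pi, pi)
    d[d <= -np.pi] += 2.0 * np.pi
    return d


@dataclass(frozen=True)
class VonMisesFit:
    mu: float
    kappa: float
    saturated: bool = False  # mean resultant length at 1: kappa capped

    def __iter__(self):
        return iter((self.mu, self.kappa))


def _a1inv(rbar: float) -> float:
    """Invert A(k) = I1(k)/I0(k) = rbar (Best & Fisher starting value)."""
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar**3 - 4.0 * rbar**2 + 3.0 * rbar)


def fit_von_mises(angles, kappa_ceiling: float = KAPPA_CEILING) -> VonMisesFit:
    """Maximum-likelihood Von Mises fit (circular mean, concentration).

    ``mu`` is the direction of the mean resultant vector.  ``kappa`` solves
    ``I1(k)/I0(k) = rbar`` via the closed-form approximation refined by
    Newton steps; it is capped at ``kappa_ceiling`` because the MLE
    diverges as the mean resultant length approaches 1 (the ``saturated``
    flag marks that case).
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 2:
        raise InsufficientDataError("need at least 2 angles")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    rbar = float(np.hypot(c, s))
    mu = float(np.arctan2(s, c))
    if rbar < 1e-12:
        return VonMisesFit(mu, 0.0)
    if rbar >= 1.0 - 1e-12:
        return VonMisesFit(mu, float(kappa_ceiling), saturated=True)
    kappa = _a1inv(rbar)
    for _ in range(25):  # Newton on A(kappa) - rbar
        A = special.i1e(kappa) / special.i0e(kappa)
        dA = 1.0 - A / kappa - A * A
        if dA <= 0:
            break
        step = (A - rbar) / dA
        kappa -= step
        if kappa <= 0:
            kappa = 1e-8
        if abs(step) < 1e-10:
            break
    if kappa >= kappa_ceiling:
        return VonMisesFit(mu, float(kappa_ceiling), saturated=True)
    return VonMisesFit(mu, float(kappa))


def _silverman_sigma(v: np.ndarray) -> float:
    # d=2 Silverman factor (4/(d+2))^(1/(d+4)) = 1, so h = sd * n^(-1/6)
    return float(np.std(v) * len(v) ** (-1.0 / 6.0))


def utilization_area(track: Track, prob: float, *,
                     bounds: tuple[float, float, float, float] | None = None,
                     grid: int = 256,
                     bandwidth_px: tuple[float, float] | None = None,
                     min_positions: int = MIN_POSITIONS) -> float:
    """Area (px²) of the smallest region holding ``prob`` of the estimated
    positional density (utilization distribution).

    The density is a binned Gaussian kernel estimate: detections are
    histogrammed on a ``grid``×``grid`` lattice over ``bounds`` (the arena;
    defaults to the data extent padded by three bandwidths) and smoothed
    with a Gaussian kernel, per-axis Silverman bandwidth by default, using
    reflection at the boundary.  Cells are then accumulated in decreasing
    density order until ``prob`` of the mass is covered; the area is the
    cell count times the cell area (highest-density region).
    """
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    if track.n_detections < min_positions:
        raise InsufficientDataError(
            f"utilization area needs >= {min_positions} positions, "
            f"got {track.n_detections}")
    x, y = track.x_px, track.y_px
    if bandwidth_px is None:
        bandwidth_px = (max(_silverman_sigma(x), 1e-9),
                        max(_silverman_sigma(y), 1e-9))
    hx, hy = bandwidth_px
    if bounds is None:
        bounds = (x.min() - 3 * hx, x.max() + 3 * hx,
                  y.min() - 3 * hy, y.max() + 3 * hy)
    x0, x1, y0, y1 = bounds
    H, _, _ = np.histogram2d(x, y, bins=grid, range=[[x0, x1], [y0, y1]])
    cell_w, cell_h = (x1 - x0) / grid, (y1 - y0) / grid
    dens = gaussian_filter(H, sigma=(hx / cell_w, hy / cell_h), mode="reflect")
    mass = np.sort(dens.ravel())[::-1]
    mass = mass / mass.sum()
    n_cells = int(np.searchsorted(np.cumsum(mass), prob) + 1)
    return float(n_cells * cell_w * cell_h)


def compute_metricset(track: Track, arena: ArenaConfig,
                      test_type: str | None = None) -> MetricSet:
    """Dispatch the metrics relevant to one test.

    exploration — time outside, min distance to the novel object (250 px
    imputed), interaction time; sociability — same against the conspecific
    centroid (350 px imputed); activity — time outside, travelled distance,
    Von Mises (μ, κ) of turning angles and 95%/50% utilization areas,
    all omitted (NaN, flagged) below 20 detections.
    """
    test = test_type or track.test
    ms = MetricSet(id=track.id, trial=track.trial, test=test,
                   n_positions=track.n_detections)
    ms.time_outside_s = float(time_outside_refuge(track))
    if test in ("exploration", "sociability"):
        point = arena.object_point if test == "exploration" else arena.conspecific_point
        if point is None:
            raise ValueError(f"arena has no stimulus point for {test!r} test")
        ms.min_distance_px = min_distance_to_point(track, point, IMPUTE_PX[test])
        ms.interaction_time_s = float(interaction_time(track, point))
    elif test == "activity":
        if track.n_detections < MIN_POSITIONS:
            ms.flags.append(f"fewer than {MIN_POSITIONS} positions: activity metrics omitted")
            return ms
        ms.total_distance_px = total_distance(track)
        try:
            fit = fit_von_mises(turning_angles(track))
            ms.turn_mu_rad, ms.turn_kappa = fit.mu, fit.kappa
            if fit.saturated:
                ms.flags.append("kappa capped (mean resultant length ~ 1)")
        except InsufficientDataError:
            ms.flags.append("too few distinct displacements for turning angles")
        bounds = (0.0, arena.width_px, 0.0, arena.height_px)
        ms.area95_px2 = utilization_area(track, 0.95, bounds=bounds)
        ms.area50_px2 = utilization_area(track, 0.50, bounds=bounds)
    else:
        raise ValueError(f"unknown test type {test!r}")
    return ms


def metrics_table(tracks, arena: ArenaConfig) -> pd.DataFrame:
    """Long-format metric table (id, trial, test, metric, value) for many tracks."""
    rows = []
    for tr in tracks:
        ms = compute_metricset(tr, arena)
        for metric, value in ms.as_dict().items():
            if np.isfinite(value):
                rows.append({"id": ms.id, "trial": ms.trial, "test": ms.test,
                             "metric": metric, "value": float(value)})
    return pd.DataFrame(rows, columns=["id", "trial", "test", "metric", "value"])


def px_to_cm(value_px, px_per_cm: float = 16.7):
    """Convert pixels (or px², with ``px_per_cm**2``) to centimetres."""
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    return value_px / px_per_cm
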