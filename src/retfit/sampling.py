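"""Synthetic feeding-trial data: collection schemes, interval censoring,
Latin Hypercube parameter designs and vector-movement models.

A feeding trial force-feeds propagules at time 0 and collects droppings at a
fixed schedule of times (the *sampling scheme*); only the number of
propagules retrieved per collection interval is observed, so retention time
is interval-censored.  ``simulate_censored`` emulates such trials by drawing
exact retention times from a known distribution and binning them into a
scheme, which is the basis of every benchmarking study in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .distributions import FAMILIES, RetentionDistribution

__all__ = [
    "SamplingScheme",
    "CensoredSample",
    "MovementModel",
    "regular_scheme",
    "mode_varied_scheme",
    "tail_varied_scheme",
    "last_interval_scheme",
    "make_scheme",
    "figure_schemes",
    "simulate_censored",
    "bin_times",
    "lhs_parameter_sets",
    "simulate_movement",
    "write_censored_csv",
    "read_censored_csv",
    "DEFAULT_LHS_RANGES",
    "DEFAULT_ORIGINAL",
]

#: Stand-in parameter ranges for the per-family Latin Hypercube designs:
#: right-skewed unimodal shapes with modes around 2-8 h and negligible
#: mass beyond the 52 h trial horizon.
DEFAULT_LHS_RANGES = {
    "lognormal": {"mu": (1.0, 2.5), "sigma": (0.3, 1.0)},
    "gamma": {"mu": (1.5, 5.0), "sigma": (0.2, 1.0)},
    "weibull": {"mu": (1.2, 2.5), "sigma": (5.0, 15.0)},
}

#: Default original retention-time distribution (median ~6 h, right-skewed,
#: P(T > 52 h) < 1e-3), used by the sample-size and interval studies.
DEFAULT_ORIGINAL = RetentionDistribution("lognormal", 1.8, 0.6)

_EPS = 1e-9


@dataclass(frozen=True)
class SamplingScheme:
    """Ordered dropping-collection times of a feeding trial.

    ``breakpoints`` start at 0 and increase strictly; successive pairs
    delimit the half-open censoring intervals ``(lower, upper]``.
    """

    breakpoints: tuple

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size < 2:
            raise ValueError("a scheme needs at least 2 breakpoints")
        if abs(bp[0]) > _EPS:
            raise ValueError("breakpoints must start at 0")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in bp))

    @property
    def horizon(self) -> float:
        """Final collection time (hours)."""
        return self.breakpoints[-1]

    @property
    def lowers(self) -> np.ndarray:
        return np.asarray(self.breakpoints[:-1])

    @property
    def uppers(self) -> np.ndarray:
        return np.asarray(self.breakpoints[1:])

    @property
    def n_intervals(self) -> int:
        return len(self.breakpoints) - 1


def _segment(start: float, stop: float, width: float, *, strict: bool) -> list:
    """Breakpoints covering (start, stop] with steps of ``width``.

    With ``strict`` the width must divide the segment exactly; otherwise the
    last interval is clipped at ``stop`` (e.g. 8 h steps after 8 h end with
    a shorter 48-52 h interval).
    """
    if width <= 0:
        raise ValueError("interval width must be positive")
    span = stop - start
    n = span / width
    if strict and abs(n - round(n)) > 1e-9:
        raise ValueError(f"width {width} h does not divide the segment ({start}, {stop}] h")
    points = list(np.arange(start + width, stop + _EPS, width))
    if not points or points[-1] < stop - _EPS:
        points.append(stop)
    points[-1] = stop
    return points


def regular_scheme(width: float, horizon: float = 52.0) -> SamplingScheme:
    """Collections every ``width`` hours up to ``horizon``."""
    return SamplingScheme(tuple([0.0] + _segment(0.0, horizon, width, strict=True)))


def mode_varied_scheme(first_width: float, horizon: float = 52.0, switch: float = 8.0,
                       tail_width: float = 4.0) -> SamplingScheme:
    """``first_width``-hour collections up to ``switch`` (around the mode),
    then ``tail_width``-hour collections to ``horizon``."""
    bp = [0.0] + _segment(0.0, switch, first_width, strict=True)
    bp += _segment(switch, horizon, tail_width, strict=False)
    return SamplingScheme(tuple(bp))


def tail_varied_scheme(tail_width: float, horizon: float = 52.0, switch: float = 8.0) -> SamplingScheme:
    """Hourly collections up to ``switch``, then ``tail_width``-hour
    collections over the tail to ``horizon``."""
    bp = [0.0] + _segment(0.0, switch, 1.0, strict=True)
    bp += _segment(switch, horizon, tail_width, strict=False)
    return SamplingScheme(tuple(bp))


def last_interval_scheme(stop: float, horizon: float = 52.0) -> SamplingScheme:
    """Hourly collections to 8 h, 4-hour collections to ``stop``, then a
    single final collection bout at ``horizon``."""
    bp = [0.0] + _segment(0.0, 8.0, 1.0, strict=True)
    if stop > 8.0:
        bp += _segment(8.0, stop, 4.0, strict=True)
    if stop < horizon:
        bp.append(horizon)
    return SamplingScheme(tuple(bp))


def make_scheme(spec) -> SamplingScheme:
    """Build a scheme from a descriptor.

    Accepts an existing scheme, an explicit breakpoint sequence, or a dict
    ``{"kind": ..., ...}`` with kinds ``regular`` (width, horizon),
    ``mode_varied`` (first_width, ...), ``tail_varied`` (tail_width, ...),
    ``last_interval`` (stop, ...) or ``breakpoints``.
    """
    if isinstance(spec, SamplingScheme):
        return spec
    if isinstance(spec, (list, tuple, np.ndarray)):
        return SamplingScheme(tuple(float(b) for b in spec))
    if not isinstance(spec, dict):
        raise ValueError(f"cannot interpret scheme descriptor {spec!r}")
    spec = dict(spec)
    kind = spec.pop("kind")
    builders = {
        "regular": regular_scheme,
        "mode_varied": mode_varied_scheme,
        "tail_varied": tail_varied_scheme,
        "last_interval": last_interval_scheme,
    }
    if kind == "breakpoints":
        return SamplingScheme(tuple(float(b) for b in spec["breakpoints"]))
    if kind not in builders:
        raise ValueError(f"unknown scheme kind {kind!r}")
    return builders[kind](**spec)


def figure_schemes() -> dict:
    """The ten distinct collection schemes of the interval-length study.

    Regular 1/2/4 h to 52 h; 1/2 h around the mode (to 8 h) then 4 h
    (4 h around the mode coincides with the regular 4 h scheme); hourly to
    8 h then 2/4/8 h over the tail; and hourly to 8 h, 4 h to 36/24/12 h,
    then one final bout at 52 h.
    """
    return {
        "regular_1h": regular_scheme(1.0),
        "regular_2h": regular_scheme(2.0),
        "regular_4h": regular_scheme(4.0),
        "mode_2h": mode_varied_scheme(2.0),
        "tail_2h": tail_varied_scheme(2.0),
        "tail_4h": tail_varied_scheme(4.0),
        "tail_8h": tail_varied_scheme(8.0),
        "last_36h": last_interval_scheme(36.0),
        "last_24h": last_interval_scheme(24.0),
        "last_12h": last_interval_scheme(12.0),
    }


#: Default mixed scheme (hourly around the mode, 4 h over the tail) used by
#: the method-comparison and sample-size studies.
def default_scheme() -> SamplingScheme:
    return tail_varied_scheme(4.0)


@dataclass(frozen=True)
class CensoredSample:
    """Interval counts of retrieved propagules from one feeding trial.

    ``lower``/``upper``/``counts`` describe the ordered censoring intervals
    ``(lower, upper]`` partitioning (0, horizon]; ``right_censored`` counts
    propagules not retrieved by the horizon.
    """

    lower: np.ndarray
    upper: np.ndarray
    counts: np.ndarray
    right_censored: int = 0

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if not (lower.shape == upper.shape == counts.shape) or lower.ndim != 1 or lower.size == 0:
            raise ValueError("lower, upper and counts must be equal-length 1-d arrays")
        if np.any(lower >= upper):
            raise ValueError("each interval needs lower < upper")
        if abs(lower[0]) > _EPS:
            raise ValueError("the first interval must start at 0")
        if not np.allclose(lower[1:], upper[:-1], atol=1e-9):
            raise ValueError("intervals must be contiguous (partition of (0, horizon])")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.right_censored < 0:
            raise ValueError("right_censored must be non-negative")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "right_censored", int(self.right_censored))

    @property
    def horizon(self) -> float:
        return float(self.upper[-1])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum()) + self.right_censored

    @property
    def breakpoints(self) -> np.ndarray:
        return np.concatenate([[self.lower[0]], self.upper])


def bin_times(times, scheme: SamplingScheme) -> CensoredSample:
    """Assign exact retention times to a scheme's censoring intervals.

    A time t lands in the interval ``(lower, upper]`` with lower < t <=
    upper (a retrieval at a collection time belongs to the just-ended
    interval); times beyond the horizon are right-censored.
    """
    times = np.asarray(times, dtype=float)
    bp = np.asarray(scheme.breakpoints)
    idx = np.searchsorted(bp, times, side="left") - 1
    in_range = (times > bp[0]) & (times <= bp[-1])
    counts = np.bincount(idx[in_range], minlength=scheme.n_intervals)
    right_censored = int(np.sum(times > bp[-1]))
    return CensoredSample(scheme.lowers, scheme.uppers, counts, right_censored)


def simulate_censored(dist: RetentionDistribution, n: int, scheme: SamplingScheme, seed) -> CensoredSample:
    """Simulate one feeding trial: draw ``n`` retention times from ``dist``
    and bin them into ``scheme``'s collection intervals."""
    if n < 1:
        raise ValueError("n must be at least 1")
    times = dist.sample(n, seed)
    return bin_times(times, scheme)


def lhs_parameter_sets(family: str, k: int, seed, ranges: dict | None = None) -> list:
    """Latin Hypercube design of ``k`` (mu, sigma) pairs for ``family``.

    Each parameter's range is cut into ``k`` equal-width strata and exactly
    one design point falls in every stratum of every parameter.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if k < 1:
        raise ValueError("k must be at least 1")
    ranges = ranges if ranges is not None else DEFAULT_LHS_RANGES[family]
    lo = np.array([ranges["mu"][0], ranges["sigma"][0]], dtype=float)
    hi = np.array([ranges["mu"][1], ranges["sigma"][1]], dtype=float)
    if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("each parameter range needs finite min < max")
    unit = qmc.LatinHypercube(d=2, seed=np.random.default_rng(seed)).random(n=k)
    scaled = qmc.scale(unit, lo, hi)
    return [(float(mu), float(sigma)) for mu, sigma in scaled]


@dataclass(frozen=True)
class MovementModel:
    """Vector movement used to turn retention times into distances.

    Kinds: ``fixed_speed`` (a constant speed in km/h), ``speed_distribution``
    (speeds drawn from a positive distribution, independent of retention
    time), or ``distance_table`` (a tabulated retention-time -> distance
    mapping, interpolated linearly).
    """

    kind: str
    speed_kmh: float | None = None
    speed_dist: RetentionDistribution | None = None
    table_times_h: tuple = ()
    table_distances_km: tuple = ()

    def __post_init__(self) -> None:
        if self.kind == "fixed_speed":
            if self.speed_kmh is None or self.speed_kmh <= 0:
                raise ValueError("fixed_speed needs a positive speed_kmh")
        elif self.kind == "speed_distribution":
            if self.speed_dist is None:
                raise ValueError("speed_distribution needs a speed_dist")
        elif self.kind == "distance_table":
            t = np.asarray(self.table_times_h, dtype=float)
            d = np.asarray(self.table_distances_km, dtype=float)
            if t.size < 2 or t.shape != d.shape:
                raise ValueError("distance_table needs matching time and distance arrays (>= 2 rows)")
            if np.any(np.diff(t) <= 0) or np.any(d <= 0) or np.any(t <= 0):
                raise ValueError("table times must increase and all values must be positive")
            object.__setattr__(self, "table_times_h", tuple(t))
            object.__setattr__(self, "table_distances_km", tuple(d))
        else:
            raise ValueError(f"unknown movement model kind {self.kind!r}")

    @classmethod
    def fixed_speed(cls, speed_kmh: float) -> "MovementModel":
        return cls(kind="fixed_speed", speed_kmh=float(speed_kmh))

    @classmethod
    def speed_distribution(cls, dist: RetentionDistribution) -> "MovementModel":
        return cls(kind="speed_distribution", speed_dist=dist)

    @classmethod
    def distance_table(cls, times_h: Sequence[float], distances_km: Sequence[float]) -> "MovementModel":
        return cls(kind="distance_table", table_times_h=tuple(times_h),
                   table_distances_km=tuple(distances_km))

    def distances_for(self, times_h) -> np.ndarray:
        """Distances for given retention times under a distance_table model."""
        if self.kind != "distance_table":
            raise ValueError("distances_for applies to distance_table models only")
        return np.interp(np.asarray(times_h, dtype=float),
                         self.table_times_h, self.table_distances_km)


def simulate_movement(model: MovementModel, n: int, seed, times_h=None) -> np.ndarray:
    """Draw ``n`` movement values: speeds (km/h) for speed-based models, or
    distances (km) for a distance table evaluated at ``times_h``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if model.kind == "fixed_speed":
        return np.full(int(n), float(model.speed_kmh))
    if model.kind == "speed_distribution":
        return model.speed_dist.sample(n, seed)
    if times_h is None:
        raise ValueError("distance_table models need the retention times (times_h)")
    times_h = np.asarray(times_h, dtype=float)
    if times_h.size != n:
        raise ValueError("times_h must have length n")
    return model.distances_for(times_h)


def write_censored_csv(sample: CensoredSample, path) -> None:
    """Write a censored sample as CSV (columns lower_h, upper_h, count);
    a right-censored remainder becomes a final row with upper_h = inf."""
    lower = list(sample.lower)
    upper = list(sample.upper)
    counts = list(sample.counts)
    if sample.right_censored > 0:
        lower.append(sample.horizon)
        upper.append(np.inf)
        counts.append(sample.right_censored)
    pd.DataFrame({"lower_h": lower, "upper_h": upper, "count": counts}).to_csv(path, index=False)


def read_censored_csv(path) -> CensoredSample:
    """Read a censored sample written by :func:`write_censored_csv`."""
    df = pd.read_csv(path)
    upper = df["upper_h"].astype(float).to_numpy()
    open_tail = ~np.isfinite(upper)
    right_censored = int(df.loc[open_tail, "count"].sum())
    df = df.loc[~open_tail]
    return CensoredSample(
        df["lower_h"].to_numpy(dtype=float),
        df["upper_h"].to_numpy(dtype=float),
        df["count"].to_numpy(dtype=np.int64),
        right_censored,
    )
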