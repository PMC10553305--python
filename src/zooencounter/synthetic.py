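"""Synthetic per-station microplastic concentration sets.

The study reports only summary statistics of the measured station
concentrations (n, mean, SD, range) — not the per-station values.  This
module generates non-negative station sets matching a requested summary, so
the full pipeline is runnable and testable without any field data:

June:    n = 10, mean 13.5, SD 7.1, range [7, 26] particles L^-1
October: n =  7, mean  2.0, SD 1.7, range [0,  6] particles L^-1

Strategy: draw from a base distribution, affine-adjust the draw to hit the
target mean and SD exactly, clip to the range, and reject-and-retry if
clipping pushed the summary outside tolerance (mean within 5%, SD within
15%).  Infeasible requests (SD beyond the Bhatia–Davis bound for the range
and mean) fail fast with a diagnostic.

Two frozen station sets generated this way ship with the package
(``data/*.csv``) and are the default inputs of every scenario; they are
synthetic stand-ins for the unpublished field measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict

import numpy as np
from scipy import stats

from .exceptions import FeasibilityError, ValidationError
from .stations import StationSet, load_stations

__all__ = ["StationSpec", "generate_stations", "packaged_fixtures",
           "JUNE_SPEC", "OCTOBER_SPEC", "MEAN_RTOL", "SD_RTOL"]

#: Relative tolerances the generated sample summary must satisfy.
MEAN_RTOL = 0.05
SD_RTOL = 0.15

_DISTRIBUTIONS = ("truncated-normal", "scaled-beta", "integer-uniform-adjusted")


@dataclass(frozen=True)
class StationSpec:
    """Target summary for a synthetic station set (all in particles L^-1)."""

    n_stations: int
    target_mean: float
    target_sd: float
    min_val: float
    max_val: float
    distribution: str = "truncated-normal"
    seed: int = 0
    integer_values: bool = False
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_stations < 2:
            raise ValidationError("n_stations must be >= 2")
        if self.min_val < 0:
            raise ValidationError("min_val must be >= 0")
        if not (self.min_val <= self.target_mean <= self.max_val):
            raise ValidationError("need min_val <= target_mean <= max_val")
        if self.target_sd < 0:
            raise ValidationError("target_sd must be >= 0")
        if self.distribution not in _DISTRIBUTIONS:
            raise ValidationError(
                f"unknown distribution {self.distribution!r}; "
                f"choose from {_DISTRIBUTIONS}")


#: Specs matching the two published seasonal summaries.
JUNE_SPEC = StationSpec(n_stations=10, target_mean=13.5, target_sd=7.1,
                        min_val=7.0, max_val=26.0, seed=20180601)
OCTOBER_SPEC = StationSpec(n_stations=7, target_mean=2.0, target_sd=1.7,
                           min_val=0.0, max_val=6.0, seed=20191001)


def _max_feasible_sd(spec: StationSpec) -> float:
    """Largest sample SD (ddof=1) achievable in [min, max] at the target mean.

    Bhatia–Davis bound on the population variance, rescaled to ddof=1.
    """
    pop_var = (spec.target_mean - spec.min_val) * (spec.max_val - spec.target_mean)
    return math.sqrt(pop_var * spec.n_stations / (spec.n_stations - 1))


def _base_draw(spec: StationSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi, m, s = spec.min_val, spec.max_val, spec.target_mean, spec.target_sd
    if spec.distribution == "truncated-normal":
        scale = max(s, 1e-12)
        a, b = (lo - m) / scale, (hi - m) / scale
        return stats.truncnorm.rvs(a, b, loc=m, scale=scale,
                                   size=spec.n_stations, random_state=rng)
    if spec.distribution == "scaled-beta":
        # method-of-moments Beta on [lo, hi]; fall back to Beta(2, 2) if the
        # requested moments sit outside the Beta family's feasible region
        width = hi - lo
        mu = (m - lo) / width
        var = (s / width) ** 2
        common = mu * (1 - mu) / max(var, 1e-12) - 1
        alpha, beta = mu * common, (1 - mu) * common
        if not (alpha > 0 and beta > 0):
            alpha = beta = 2.0
        return lo + width * rng.beta(alpha, beta, size=spec.n_stations)
    # integer-uniform-adjusted
    return rng.integers(int(math.floor(lo)), int(math.floor(hi)) + 1,
                        size=spec.n_stations).astype(float)


def generate_stations(spec: StationSpec, season_label: str = "") -> StationSet:
    """Generate a station set whose sample summary matches ``spec``.

    Reproducible under ``spec.seed``.  Raises :class:`FeasibilityError` when
    the requested SD exceeds what the range allows, or when no draw within
    ``max_attempts`` satisfies the tolerances after clipping.
    """
    lo, hi, m, s = spec.min_val, spec.max_val, spec.target_mean, spec.target_sd
    if lo == hi:
        if s > 0:
            raise FeasibilityError(
                f"degenerate range [{lo}, {hi}] cannot produce SD {s} > 0")
        return StationSet(season_label or "synthetic",
                          np.full(spec.n_stations, float(lo)))
    if s > _max_feasible_sd(spec):
        raise FeasibilityError(
            f"target SD {s} exceeds the maximum {_max_feasible_sd(spec):.3g} "
            f"achievable with mean {m} in [{lo}, {hi}] (n={spec.n_stations})")
    rng = np.random.default_rng(spec.seed)
    mean_tol = MEAN_RTOL * m if m > 0 else MEAN_RTOL
    for _ in range(spec.max_attempts):
        draw = _base_draw(spec, rng)
        # affine adjustment: exact sample mean/SD before clipping
        sd0 = draw.std(ddof=1)
        if sd0 > 0 and s > 0:
            draw = m + (draw - draw.mean()) * (s / sd0)
        else:
            draw = draw - draw.mean() + m
        values = np.clip(draw, lo, hi)
        if spec.integer_values:
            values = np.round(values)
        got_mean = values.mean()
        got_sd = values.std(ddof=1)
        if abs(got_mean - m) <= mean_tol and abs(got_sd - s) <= SD_RTOL * max(s, 1e-12):
            return StationSet(season_label or "synthetic", values)
    raise FeasibilityError(
        f"no draw satisfied mean {m}±{MEAN_RTOL:.0%} and SD {s}±{SD_RTOL:.0%} "
        f"within [{lo}, {hi}] after {spec.max_attempts} attempts "
        f"(distribution={spec.distribution}, n={spec.n_stations})")


def packaged_fixtures() -> Dict[str, StationSet]:
    """The two frozen synthetic station sets shipped with the package."""
    out: Dict[str, StationSet] = {}
    for season in ("june", "october"):
        ref = resources.files("zooencounter").joinpath(f"data/{season}_stations.csv")
        with resources.as_file(ref) as path:
            out[season] = load_stations(path, season_label=season)
    return out
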