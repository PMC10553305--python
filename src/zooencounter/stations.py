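"""Station concentration tables and the bootstrap resampling engine.

Surface microplastic concentrations are measured per station in particles
per liter; the encounter-rate formulas consume particles per cubic meter
(x 1000).  Uncertainty in the seasonal mean concentration is propagated into
the encounter rates by a classical bootstrap: resample the station set with
replacement, take the mean concentration of each resample, push it through
the rate function, and report the mean and SD of the resulting rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import StationParseError, ValidationError

__all__ = [
    "StationSet",
    "BootstrapConfig",
    "BootstrapResult",
    "load_stations",
    "to_density",
    "bootstrap_rate",
]

#: Column names required in a station table.
STATION_COLUMNS = ("station_id", "particles_per_L")


@dataclass(frozen=True)
class StationSet:
    """Per-station microplastic concentrations (particles L^-1) for one season."""

    season_label: str
    concentrations: np.ndarray
    station_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        if conc.size < 1:
            raise ValidationError("a station set needs at least one station")
        if np.any(conc < 0) or np.any(~np.isfinite(conc)):
            raise ValidationError("station concentrations must be finite and >= 0")
        if self.station_ids is not None and len(self.station_ids) != conc.size:
            raise ValidationError("station_ids length must match concentrations")

    @property
    def n(self) -> int:
        return int(self.concentrations.size)

    def summary(self) -> dict:
        """Sample mean, SD (ddof=1 when n > 1), min, max and n."""
        c = self.concentrations
        sd = float(np.std(c, ddof=1)) if c.size > 1 else 0.0
        return {"n": self.n, "mean": float(np.mean(c)), "sd": sd,
                "min": float(np.min(c)), "max": float(np.max(c))}

    def to_frame(self) -> pd.DataFrame:
        ids = (list(self.station_ids) if self.station_ids is not None
               else [f"S{i + 1:02d}" for i in range(self.n)])
        return pd.DataFrame({"station_id": ids,
                             "particles_per_L": self.concentrations})


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: 1000 repetitions by default, seeded for reproducibility.

    ``resample_size`` defaults to the number of stations.  ``mode`` selects
    what each repetition draws: ``"mean"`` (default) resamples a full-size
    station set and applies the rate to its mean concentration;
    ``"single"`` draws one station per repetition.  For a rate linear in N
    both give the same mean and differ only in SD.
    """

    n_reps: int = 1000
    seed: int = 42
    resample_size: Optional[int] = None
    mode: str = "mean"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.resample_size is not None and self.resample_size < 1:
            raise ValidationError("resample_size must be >= 1")
        if self.mode not in ("mean", "single"):
            raise ValidationError(f"unknown bootstrap mode {self.mode!r}")


@dataclass(frozen=True)
class BootstrapResult:
    """Mean and SD of the bootstrapped rates, with the settings that made them."""

    mean_rate: float
    sd_rate: float
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.sd_rate < 0:
            raise ValidationError("sd_rate must be >= 0")


def load_stations(path: Union[str, Path], season_label: str = "") -> StationSet:
    """Read a station table (CSV with header ``station_id,particles_per_L``).

    Optional extra columns (e.g. lat, lon) are ignored.  Malformed rows are
    reported with their line numbers (header = line 1).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise StationParseError(f"{path}: {exc}") from exc
    missing = [c for c in STATION_COLUMNS if c not in table.columns]
    if missing:
        raise StationParseError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"found {list(table.columns)}")
    if len(table) == 0:
        raise StationParseError(f"{path}: no station rows")
    values = pd.to_numeric(table["particles_per_L"], errors="coerce")
    bad = table.index[values.isna() | (values < 0)]
    if len(bad) > 0:
        lines = ", ".join(str(i + 2) for i in bad)  # +2: header + 1-based
        raise StationParseError(
            f"{path}: non-numeric or negative particles_per_L at line(s) {lines}")
    return StationSet(
        season_label=season_label or path.stem,
        concentrations=values.to_numpy(dtype=float),
        station_ids=table["station_id"].astype(str).tolist(),
    )


def to_density(concentration_per_liter):
    """Convert particles L^-1 to particles m^-3 (exact x 1000)."""
    c = np.asarray(concentration_per_liter, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be >= 0")
    out = c * 1000.0
    return float(out) if np.ndim(concentration_per_liter) == 0 else out


def resample_concentrations(stations: StationSet, cfg: BootstrapConfig) -> np.ndarray:
    """The per-repetition concentration statistic, shape (n_reps,).

    This is the single source of the bootstrap's randomness: the pipeline
    reuses one such draw across all depths of a profile so that depth
    variation reflects turbulence only, not resampling noise.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.resample_size or stations.n
    if cfg.mode == "single":
        idx = rng.integers(0, stations.n, size=cfg.n_reps)
        return stations.concentrations[idx]
    idx = rng.integers(0, stations.n, size=(cfg.n_reps, size))
    return stations.concentrations[idx].mean(axis=1)


def bootstrap_rate(
    stations: StationSet,
    rate_fn: Callable[[np.ndarray], np.ndarray],
    cfg: BootstrapConfig = BootstrapConfig(),
) -> BootstrapResult:
    """Bootstrap the encounter rate over station concentrations.

    ``rate_fn`` maps a particle density (particles m^-3) to a rate; it is
    called with the densities of all repetitions at once if it broadcasts,
    falling back to an element-wise loop otherwise.  The SD is the population
    SD (ddof=0) over the n_reps bootstrapped rates.
    """
    densities = to_density(resample_concentrations(stations, cfg))
    try:
        rates = np.asarray(rate_fn(densities), dtype=float)
        if rates.shape != densities.shape:
            raise ValueError
    except (ValueError, TypeError):
        rates = np.array([float(rate_fn(d)) for d in densities])
    # identical resamples have exactly zero spread; don't let pairwise
    # summation round-off report otherwise
    sd = 0.0 if np.all(rates == rates[0]) else float(np.std(rates, ddof=0))
    return BootstrapResult(
        mean_rate=float(np.mean(rates)),
        sd_rate=sd,
        n_reps=cfg.n_reps,
        seed=cfg.seed,
    )
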