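"""Brute-force Monte-Carlo validation of the analytic encounter formulas.

A searcher of encounter radius R moves ballistically through a periodic box
seeded with Poisson-distributed particles that themselves move ballistically
with independent random directions.  Encounters — entries of a particle into
the moving perception sphere — are detected in continuous time by solving
the quadratic |r0 + v_rel t| = R for every (particle, periodic image) pair,
so there are no time-step artifacts.  A particle that leaves the sphere and
re-enters later is counted again: the analytic formulas are rates of
crossing events, not of unique particles.

Turbulence is emulated the way the Rothschild–Osborn substitution assumes:
each agent's ballistic velocity gains an independent, isotropically oriented
component of fixed magnitude w.  This validates the effective-speed algebra,
not turbulence physics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .kinetics import SPEED_TOL

__all__ = ["SimConfig", "OracleResult", "simulate_encounters", "analytic_rate"]


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo settings: geometry, kinematics and replication."""

    R: float                 # encounter radius, m
    N: float                 # particle density, m^-3
    y: float                 # searcher speed, m s^-1
    x: float = 0.0           # particle speed, m s^-1
    w: float = 0.0           # added isotropic turbulent speed, m s^-1
    box_side: float = 0.5    # periodic box edge, m
    duration: float = 30.0   # per-trial simulated time, s
    n_trials: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.N < 0 or self.y < 0 or self.x < 0 or self.w < 0:
            raise ValidationError("R must be > 0 and N, y, x, w >= 0")
        if self.box_side <= 2 * self.R:
            raise ValidationError(
                f"degenerate geometry: box_side {self.box_side} <= 2R {2 * self.R}")
        if self.duration <= 0 or self.n_trials < 1:
            raise ValidationError("duration must be > 0 and n_trials >= 1")


@dataclass(frozen=True)
class OracleResult:
    """Empirical encounter rate (s^-1) with its standard error over trials."""

    rate: float
    se: float
    n_trials: int
    total_encounters: int

    def agrees_with(self, analytic: float, n_se: float = 3.0) -> bool:
        """Is the analytic rate within n_se standard errors of the empirical one?"""
        return abs(self.rate - analytic) <= n_se * self.se


def analytic_rate(cfg: SimConfig) -> float:
    """The closed-form rate (s^-1) the simulation should reproduce."""
    from .kinetics import ParticleField, Swimmer, effective_speed, gs_rate

    y_eff = effective_speed(cfg.y, cfg.w)
    x_eff = effective_speed(cfg.x, cfg.w)
    if y_eff <= SPEED_TOL and x_eff <= SPEED_TOL:
        return 0.0
    return float(gs_rate(Swimmer("oracle", speed=y_eff, radius=cfg.R),
                         ParticleField(cfg.N, speed=x_eff)).value)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def _count_entries(r0: np.ndarray, v: np.ndarray, R: float, L: float,
                   T: float) -> int:
    """Entry events of |r0 + v t - nL| <= R for t in (0, T], all images n."""
    a = np.einsum("ij,ij->i", v, v)
    moving = a > 0
    if not moving.any():
        return 0
    r0, v, a = r0[moving], v[moving], a[moving]
    end = r0 + v * T
    lo = np.minimum(r0, end).min(axis=0) - R
    hi = np.maximum(r0, end).max(axis=0) + R
    n_ranges = [range(math.ceil(lo[i] / L), math.floor(hi[i] / L) + 1)
                for i in range(3)]
    total = 0
    for n in itertools.product(*n_ranges):
        d0 = r0 - L * np.asarray(n, dtype=float)
        b = 2.0 * np.einsum("ij,ij->i", d0, v)
        c = np.einsum("ij,ij->i", d0, d0) - R * R
        disc = b * b - 4.0 * a * c
        ok = disc > 0
        if not ok.any():
            continue
        t_enter = (-b[ok] - np.sqrt(disc[ok])) / (2.0 * a[ok])
        total += int(np.count_nonzero((t_enter > 0) & (t_enter <= T)))
    return total


def simulate_encounters(cfg: SimConfig) -> OracleResult:
    """Run the Monte-Carlo trials and return the empirical rate ± SE.

    Each trial draws Poisson(N * box^3) particles uniformly in the box, gives
    every agent a fresh random direction (plus an independent turbulent
    component of magnitude w when configured), and counts sphere entries in
    continuous time under periodic boundaries.
    """
    expected = analytic_rate(cfg) * cfg.duration
    if 0 < expected < 10:
        warnings.warn(
            f"expected only {expected:.1f} encounters per trial; "
            "comparisons with the analytic rate will be noisy", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    L = cfg.box_side
    counts = np.zeros(cfg.n_trials)
    for trial in range(cfg.n_trials):
        n_particles = rng.poisson(cfg.N * L ** 3)
        if n_particles == 0:
            continue
        pos = rng.uniform(0, L, size=(n_particles, 3))
        v_searcher = cfg.y * _unit_vectors(rng, 1)[0]
        v_particles = cfg.x * _unit_vectors(rng, n_particles)
        if cfg.w > 0:
            v_searcher = v_searcher + cfg.w * _unit_vectors(rng, 1)[0]
            v_particles = v_particles + cfg.w * _unit_vectors(rng, n_particles)
        # searcher rest frame; wrap starting separations to the central image
        r0 = (pos - L / 2.0 + L / 2.0) % L - L / 2.0
        v_rel = v_particles - v_searcher
        counts[trial] = _count_entries(r0, v_rel, cfg.R, L, cfg.duration)
    rates = counts / cfg.duration
    se = (float(np.std(rates, ddof=1)) / math.sqrt(cfg.n_trials)
          if cfg.n_trials > 1 else 0.0)
    return OracleResult(rate=float(np.mean(rates)), se=se,
                        n_trials=cfg.n_trials,
                        total_encounters=int(counts.sum()))
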