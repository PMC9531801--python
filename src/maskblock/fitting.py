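"""Calibration of the two cloth parameters and the study's statistics.

The cloth model has two free parameters: tunneling probability ``p`` and
deceleration factor ``f``.  They are estimated by minimising the weighted
sum of squares

    sum_i  w_i (SBBC_i(p, f) - BBC_i)^2,      w_i = 1 / sigma_i^2,

over the observed blocking capacities BBC_i at the measured barrier
positions.  SBBC here is the variance-free expected-volume estimator (see
:mod:`maskblock.simulator`): for one barrier it factorises as
``SBBC = 100 (1 - p * V(f, d) / V_no)``, exactly affine in p, so the
objective is a closed-form quadratic in p at each f.  The fit therefore
sweeps a grid in f (reusing one common droplet population across the whole
sweep), solves for the optimal p exactly, and refines f on a fine local
grid.  Deterministic given the emission seed.

Also here: the ordinary least-squares line of blocking capacity against
barrier position (the observed trend is close to linear), the relative slope
difference between experiment and model, and an exact one-tailed
Mann-Whitney U test for the tiny replicate counts of the source-control vs
wearer-protection comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .physics import FluidEnvironment, flight_arrays
from .simulator import (
    Barrier,
    EmissionModel,
    ExperimentGeometry,
    _sample_emission,
)

__all__ = [
    "BlockingObservation",
    "FitResult",
    "LinearFit",
    "fit_pf",
    "linear_fit",
    "slope_relative_difference",
    "mann_whitney_one_tailed",
]

EXACT_MW_MAX_N = 12  # combined sample size up to which the test enumerates exactly


@dataclass(frozen=True)
class BlockingObservation:
    """One measured blocking capacity at one barrier position."""

    distance_from_nozzle: float  # m
    bbc: float  # percent
    sigma: float  # percent, > 0 (weights are 1/sigma^2)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be strictly positive to define weights")
        if not self.distance_from_nozzle > 0:
            raise ValueError("distance_from_nozzle must be positive")


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    residuals: tuple[float, ...]
    extrapolation_flagged: bool = False  # fitted line exceeds 100 % inside the data span


@dataclass(frozen=True)
class FitResult:
    """Outcome of the (p, f) calibration."""

    p_hat: float
    f_hat: float
    objective: float  # weighted sum of squares at the optimum
    sbbc: tuple[float, ...]  # fitted SBBC at each observed position
    distances: tuple[float, ...]
    observed_fit: Optional[LinearFit] = None
    simulated_fit: Optional[LinearFit] = None
    slope_relative_difference_percent: Optional[float] = None


def linear_fit(xs: Sequence[float], ys: Sequence[float]) -> LinearFit:
    """Ordinary least-squares line y = a x + b; exact on collinear input.

    Fitted values above 100 % inside the data span are flagged (blocking
    capacities beyond 100 % are unphysical and extrapolations there should
    be ignored), not clamped.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least 2 distinct x values")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = slope * x + intercept
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        residuals=tuple((y - fitted).tolist()),
        extrapolation_flagged=bool(np.any(fitted > 100.0)),
    )


def slope_relative_difference(slope_experimental: float, slope_simulated: float) -> float:
    """|slope_sim - slope_exp| / |slope_exp| * 100, in percent."""
    if slope_experimental == 0:
        raise ValueError("reference (experimental) slope must be nonzero")
    return abs(slope_simulated - slope_experimental) / abs(slope_experimental) * 100.0


def _optimal_p(v: np.ndarray, w: np.ndarray, bbc: np.ndarray) -> tuple[float, float]:
    """Exact minimiser over p in [0, 1] of sum w (100(1 - p v) - bbc)^2.

    The objective is quadratic in p; returns (p*, objective(p*)).  When every
    v is zero the objective is constant in p and the tie breaks to p = 0.
    """
    a = float(np.sum(w * (100.0 * v) ** 2))
    target = 100.0 - bbc  # SBBC shortfall the model must reproduce
    if a == 0:
        p = 0.0
    else:
        p = float(np.sum(w * 100.0 * v * target) / a)
        p = min(max(p, 0.0), 1.0)
    obj = float(np.sum(w * (100.0 * p * v - target) ** 2))
    return p, obj


def fit_pf(
    observations: Sequence[BlockingObservation],
    model: EmissionModel = EmissionModel(),
    geometry: ExperimentGeometry = ExperimentGeometry(),
    env: FluidEnvironment = FluidEnvironment(),
    f_grid_size: int = 101,
    refine_step: float = 1e-3,
    with_linear_fits: bool = True,
) -> FitResult:
    """Weighted least-squares calibration of (p, f) against BBC observations.

    A single droplet population (drawn once from ``model.seed``) is shared by
    every candidate (p, f) — common random numbers — so the objective surface
    is deterministic.  A coarse grid in f (default 101 points on [0, 1]) with
    the exact per-f minimiser in p locates the optimum; f is then refined on
    a local grid of step ``refine_step``.  Ties break to the smallest p, then
    the smallest f.
    """
    obs = list(observations)
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    distances = np.array([o.distance_from_nozzle for o in obs])
    bbc = np.array([o.bbc for o in obs])
    w = np.array([1.0 / o.sigma**2 for o in obs])

    seq = np.random.SeedSequence(model.seed)
    emit_rng = np.random.Generator(np.random.PCG64(seq.spawn(2)[0]))
    radii, angles = _sample_emission(model, emit_rng)
    volume = (4.0 / 3.0) * np.pi * radii**3

    # Common droplet population for the whole sweep; the nozzle->barrier leg
    # and the barrier-free reference volume do not depend on (p, f), so they
    # are computed once per distance.
    reached0, y_s, _, _ = flight_arrays(radii, geometry.nozzle_height, model.speed, angles, geometry.screen_distance, env)
    free_ok = reached0 & (y_s >= 0.0)
    in_roi = free_ok & (np.abs(y_s - geometry.nozzle_height) <= geometry.roi_half_height)
    in_roi &= (y_s >= geometry.screen_y_min) & (y_s <= geometry.screen_y_max)
    v_no = float(volume[in_roi].sum())
    if not v_no > 0:
        raise ValueError("no droplet volume reaches the screen centre without a barrier")

    segments = []
    for d in distances:
        if not 0 < d < geometry.screen_distance:
            raise ValueError("barrier plane must lie strictly between nozzle and screen")
        reached, y_b, vx, vy = flight_arrays(radii, geometry.nozzle_height, model.speed, angles, d, env)
        ok = reached & (y_b >= 0.0)
        segments.append(
            (
                radii[ok],
                volume[ok],
                y_b[ok],
                np.hypot(vx[ok], vy[ok]),
                np.arctan2(vy[ok], vx[ok]),
                geometry.screen_distance - d,
            )
        )

    def v_profile(f: float) -> np.ndarray:
        out = np.empty(len(segments))
        for i, (r, vol, y_b, sp, ang, dx) in enumerate(segments):
            reached, y_end, _, _ = flight_arrays(r, y_b, sp * f, ang, dx, env)
            ok = reached & (y_end >= 0.0)
            roi = ok & (np.abs(y_end - geometry.nozzle_height) <= geometry.roi_half_height)
            roi &= (y_end >= geometry.screen_y_min) & (y_end <= geometry.screen_y_max)
            out[i] = float(vol[roi].sum()) / v_no
        return out

    def best_over_f(f_values: np.ndarray) -> tuple[float, float, float]:
        best = None
        for f in f_values:
            p, obj = _optimal_p(v_profile(float(f)), w, bbc)
            key = (obj, p, f)
            if best is None or key < best:
                best = key
        obj, p, f = best
        return float(p), float(f), float(obj)

    coarse = np.linspace(0.0, 1.0, f_grid_size)
    p_hat, f_hat, obj = best_over_f(coarse)
    # local refinement of f at fixed grid-free resolution; p stays exact per f
    half_window = (coarse[1] - coarse[0]) if f_grid_size > 1 else 0.0
    if half_window > 0 and refine_step > 0:
        lo = max(0.0, f_hat - half_window)
        hi = min(1.0, f_hat + half_window)
        n_fine = int(round((hi - lo) / refine_step)) + 1
        p_hat, f_hat, obj = best_over_f(np.linspace(lo, hi, n_fine))

    v_best = v_profile(f_hat)
    sbbc_fit = 100.0 * (1.0 - p_hat * v_best)

    observed_fit = simulated_fit = None
    rel_diff = None
    if with_linear_fits and np.ptp(distances) > 0:
        observed_fit = linear_fit(distances, bbc)
        simulated_fit = linear_fit(distances, sbbc_fit)
        if observed_fit.slope != 0:
            rel_diff = slope_relative_difference(observed_fit.slope, simulated_fit.slope)

    return FitResult(
        p_hat=p_hat,
        f_hat=f_hat,
        objective=obj,
        sbbc=tuple(sbbc_fit.tolist()),
        distances=tuple(distances.tolist()),
        observed_fit=observed_fit,
        simulated_fit=simulated_fit,
        slope_relative_difference_percent=rel_diff,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U, one-tailed, exact for tiny replicate counts
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample b against sample a: #{b_j > a_i} + 0.5 #{b_j == a_i}."""
    diff = b[:, None] - a[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_one_tailed(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """One-tailed Mann-Whitney p-value for H1: sample_b stochastically larger.

    For combined sample sizes up to 12 the p-value is exact: every split of
    the pooled values into groups of the observed sizes is enumerated and the
    fraction with U at least as extreme as observed is returned (valid under
    ties as a permutation test).  Larger samples fall back to the normal
    approximation (scipy, tie-corrected, continuity-corrected).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n = a.size + b.size
    if n <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        u_obs = _u_statistic(a, b)
        idx = range(n)
        count = total = 0
        for b_idx in combinations(idx, b.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(b_idx)] = True
            u = _u_statistic(pooled[~mask], pooled[mask])
            count += u >= u_obs - 1e-12
            total += 1
        return count / total
    res = _scipy_stats.mannwhitneyu(b, a, alternative="greater", method="asymptotic")
    return float(res.pvalue)
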