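"""Statistical decision theory for risky magnitude reproduction.

A responder produces a magnitude (a duration in ms, or a distance in mm)
drawn from a Gaussian distribution centred on an intended *aim point* S with
standard deviation sigma.  A payoff scheme rewards responses landing inside
a symmetric window around a target magnitude and may penalize responses
falling short of the window ("too early" / "too close").  The expected gain
of an aim point is

    EG(S) = G_early * P(X < L) + G_hit * P(L <= X <= U) + G_late * P(X > U)

with X ~ N(S, sigma^2), L = (1 - m) * target and U = (1 + m) * target for
margin fraction m.  When early responses are penalized, the EG-maximizing
aim shifts beyond the target by an amount that grows with sigma: noisier
responders must place their mean further from the penalty region.

This module provides outcome classification, the response-class
probabilities, expected gain, the optimal aim point, and expected-reward
surfaces over (aim, sigma) grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "PayoffScheme",
    "GaussianResponder",
    "RewardSurface",
    "classify_response",
    "response_probabilities",
    "expected_gain",
    "optimal_aim",
    "max_expected_gain",
    "reward_surface",
    "timing_scheme",
    "distance_scheme",
    "default_schemes",
    "BLOCK_EARLY_GAINS",
    "TIMING_TARGET_MS",
    "DISTANCE_TARGET_MM",
    "HIT_MARGIN",
    "POINT_VALUE_EUROCENT",
]

# Design constants of the experiment the model describes: a 750-ms interval
# reproduction task and a 55-mm distance estimation task, both rewarded with
# 5 points inside a +/-30% window around the target.  Blocks P (practice,
# unrewarded) and 1..5 differ only in the early/close penalty.
TIMING_TARGET_MS = 750.0
DISTANCE_TARGET_MM = 55.0
HIT_MARGIN = 0.30
HIT_REWARD = 5.0
BLOCK_EARLY_GAINS = {"P": 0.0, "1": 0.0, "2": -5.0, "3": 0.0, "4": -30.0, "5": 0.0}
POINT_VALUE_EUROCENT = 0.69

EARLY, HIT, LATE = "early", "hit", "late"


@dataclass(frozen=True)
class PayoffScheme:
    """Reward/penalty structure of one experimental block.

    Parameters
    ----------
    target
        Magnitude at the centre of the rewarded window (ms or mm).
    margin_fraction
        Half-width of the rewarded window as a fraction of the target;
        the window is [(1 - m) * target, (1 + m) * target].
    gain_hit, gain_early, gain_late
        Points awarded per outcome class; penalties are non-positive.
    modality_label
        "timing" or "distance"; carried for bookkeeping only.
    """

    target: float
    margin_fraction: float = HIT_MARGIN
    gain_hit: float = HIT_REWARD
    gain_early: float = 0.0
    gain_late: float = 0.0
    modality_label: str = "timing"

    def __post_init__(self) -> None:
        if not self.target > 0:
            raise ValueError(f"target must be positive, got {self.target}")
        if not 0 < self.margin_fraction < 1:
            raise ValueError(
                f"margin_fraction must lie in (0, 1), got {self.margin_fraction}"
            )
        if self.gain_early > 0 or self.gain_late > 0:
            raise ValueError("penalty gains must be <= 0")
        if not (self.gain_hit > self.gain_early and self.gain_hit > self.gain_late):
            # Degenerate all-equal schemes (e.g. practice: all zero) are allowed.
            if not (
                self.gain_hit == self.gain_early == self.gain_late
            ):
                raise ValueError("gain_hit must exceed the penalty gains")
        if self.modality_label not in ("timing", "distance"):
            raise ValueError(f"unknown modality_label {self.modality_label!r}")

    @property
    def lower(self) -> float:
        """Lower edge L of the rewarded window."""
        return (1.0 - self.margin_fraction) * self.target

    @property
    def upper(self) -> float:
        """Upper edge U of the rewarded window."""
        return (1.0 + self.margin_fraction) * self.target

    @property
    def gains(self) -> tuple[float, float, float]:
        return (self.gain_early, self.gain_hit, self.gain_late)


@dataclass(frozen=True)
class GaussianResponder:
    """An intended aim point S and response noise sigma."""

    aim: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.aim > 0:
            raise ValueError(f"aim must be positive, got {self.aim}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class RewardSurface:
    """Expected points per trial over a (sigma, aim) grid, plus the ridge.

    ``expected_points[i, j]`` is the expected gain of aim ``aim_grid[j]`` at
    noise level ``sigma_grid[i]``; ``optimal_ridge[i]`` is the EG-maximizing
    aim at ``sigma_grid[i]`` (continuous optimum, not restricted to the grid).
    """

    aim_grid: np.ndarray
    sigma_grid: np.ndarray
    expected_points: np.ndarray
    optimal_ridge: np.ndarray
    scheme: PayoffScheme = field(repr=False, default=None)  # type: ignore[assignment]


def timing_scheme(block: str = "1", margin_fraction: float = HIT_MARGIN) -> PayoffScheme:
    """Payoff scheme of one timing block (target 750 ms)."""
    block = str(block)
    return PayoffScheme(
        target=TIMING_TARGET_MS,
        margin_fraction=margin_fraction,
        gain_hit=0.0 if block == "P" else HIT_REWARD,
        gain_early=BLOCK_EARLY_GAINS[block],
        gain_late=0.0,
        modality_label="timing",
    )


def distance_scheme(block: str = "1", margin_fraction: float = HIT_MARGIN) -> PayoffScheme:
    """Payoff scheme of one distance block (target 55 mm).

    The distance task mirrors the timing payoff structure; its hit margin is
    an explicit parameter defaulting to the same 30% fraction.
    """
    block = str(block)
    return PayoffScheme(
        target=DISTANCE_TARGET_MM,
        margin_fraction=margin_fraction,
        gain_hit=0.0 if block == "P" else HIT_REWARD,
        gain_early=BLOCK_EARLY_GAINS[block],
        gain_late=0.0,
        modality_label="distance",
    )


def default_schemes(modality: str, margin_fraction: float = HIT_MARGIN) -> dict[str, PayoffScheme]:
    """All six block schemes (P, 1..5) for one modality."""
    maker = {"timing": timing_scheme, "distance": distance_scheme}[modality]
    return {b: maker(b, margin_fraction) for b in ("P", "1", "2", "3", "4", "5")}


def classify_response(x: float, scheme: PayoffScheme) -> tuple[str, float]:
    """Classify one response magnitude and return (outcome, points).

    The rewarded window is closed on both ends: L <= x <= U is a hit.
    """
    if x < 0:
        raise ValueError(f"response magnitude must be non-negative, got {x}")
    if x < scheme.lower:
        return EARLY, scheme.gain_early
    if x > scheme.upper:
        return LATE, scheme.gain_late
    return HIT, scheme.gain_hit


def classify_responses(x: np.ndarray, scheme: PayoffScheme) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`classify_response`."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("response magnitudes must be non-negative")
    early = x < scheme.lower
    late = x > scheme.upper
    outcome = np.where(early, EARLY, np.where(late, LATE, HIT))
    points = np.where(early, scheme.gain_early, np.where(late, scheme.gain_late, scheme.gain_hit))
    return outcome, points


def response_probabilities(
    r: GaussianResponder, scheme: PayoffScheme
) -> tuple[float, float, float]:
    """Probabilities of (early, hit, late) outcomes for a Gaussian responder."""
    z_lo = (scheme.lower - r.aim) / r.sigma
    z_hi = (scheme.upper - r.aim) / r.sigma
    p_early = norm.cdf(z_lo)
    p_late = norm.sf(z_hi)
    p_hit = max(0.0, 1.0 - p_early - p_late)
    return float(p_early), float(p_hit), float(p_late)


def expected_gain(r: GaussianResponder, scheme: PayoffScheme) -> float:
    """Expected points per trial for aim S and noise sigma under a scheme."""
    p_early, p_hit, p_late = response_probabilities(r, scheme)
    return (
        scheme.gain_early * p_early
        + scheme.gain_hit * p_hit
        + scheme.gain_late * p_late
    )


def _expected_gain_vec(aim: np.ndarray, sigma: float, scheme: PayoffScheme) -> np.ndarray:
    aim = np.asarray(aim, dtype=float)
    p_early = norm.cdf((scheme.lower - aim) / sigma)
    p_late = norm.sf((scheme.upper - aim) / sigma)
    p_hit = 1.0 - p_early - p_late
    return scheme.gain_early * p_early + scheme.gain_hit * p_hit + scheme.gain_late * p_late


def optimal_aim(sigma: float, scheme: PayoffScheme) -> float:
    """Aim point maximizing expected gain at noise level ``sigma``.

    Bounded scalar maximization over S in [L - 2 sigma, U + 4 sigma] with
    tolerance 1e-4 * target.  When the maximum is a plateau (within a tiny
    EG tolerance), the plateau point closest to the target is returned, so
    that zero-penalty schemes yield the window midpoint (the target) exactly
    and optimal_aim -> target as sigma -> 0.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    lo = scheme.lower - 2.0 * sigma
    hi = scheme.upper + 4.0 * sigma
    xatol = 1e-4 * scheme.target

    res = minimize_scalar(
        lambda s: -_expected_gain_vec(s, sigma, scheme),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    best_aim, best_eg = float(res.x), float(-res.fun)

    # Guard against local optima of multimodal EG (possible when penalties
    # carve a trough inside the bracket): coarse grid scan, refine the best
    # grid cell if it beats the first solution.
    grid = np.linspace(lo, hi, 513)
    eg_grid = _expected_gain_vec(grid, sigma, scheme)
    i = int(np.argmax(eg_grid))
    if eg_grid[i] > best_eg:
        res2 = minimize_scalar(
            lambda s: -_expected_gain_vec(s, sigma, scheme),
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
            method="bounded",
            options={"xatol": xatol},
        )
        if -res2.fun > best_eg:
            best_aim, best_eg = float(res2.x), float(-res2.fun)

    # Plateau tie-break: prefer the admissible point closest to the target.
    gain_span = max(abs(g) for g in scheme.gains)
    plateau_tol = max(gain_span, 1.0) * 1e-12
    target = float(np.clip(scheme.target, lo, hi))
    if _expected_gain_vec(target, sigma, scheme) >= best_eg - plateau_tol:
        return target
    if abs(best_aim - target) <= xatol:
        return target
    return best_aim


def max_expected_gain(sigma: float, scheme: PayoffScheme) -> float:
    """Expected gain at the optimal aim point (points per trial)."""
    s_star = optimal_aim(sigma, scheme)
    return expected_gain(GaussianResponder(aim=s_star, sigma=sigma), scheme)


def reward_surface(
    sigma_grid: np.ndarray, aim_grid: np.ndarray, scheme: PayoffScheme
) -> RewardSurface:
    """Expected-reward surface over a (sigma, aim) grid with its optimal ridge."""
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    aim_grid = np.asarray(aim_grid, dtype=float)
    for name, g in (("sigma_grid", sigma_grid), ("aim_grid", aim_grid)):
        if g.size == 0:
            raise ValueError(f"{name} must be non-empty")
        if g.ndim != 1 or (g.size > 1 and not np.all(np.diff(g) > 0)):
            raise ValueError(f"{name} must be a strictly increasing vector")
    if np.any(sigma_grid <= 0):
        raise ValueError("sigma_grid entries must be positive")

    expected = np.empty((sigma_grid.size, aim_grid.size))
    ridge = np.empty(sigma_grid.size)
    for i, sig in enumerate(sigma_grid):
        expected[i] = _expected_gain_vec(aim_grid, sig, scheme)
        ridge[i] = optimal_aim(sig, scheme)
    return RewardSurface(
        aim_grid=aim_grid,
        sigma_grid=sigma_grid,
        expected_points=expected,
        optimal_ridge=ridge,
        scheme=scheme,
    )
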