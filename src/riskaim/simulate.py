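"""Synthetic cohorts with the experiment's design and known ground truth.

Each simulated participant performs both tasks: a practice block of 50
trials plus five experimental blocks of 50 trials per modality, under the
standard payoff scheme (5 points per hit; early/close penalties of 0, -5,
0, -30, 0 points in blocks 1-5).  Ground-truth strategy parameters are
drawn per participant:

* ``sigma`` — response SD per modality, log-normal across participants;
* ``bias`` — baseline aim offset from the target, Gaussian around 0,
  applied in every block;
* ``lambda`` — adjustment propensity: in a penalty block the participant
  aims at ``aim_1 + lambda * (S* - aim_1)`` where ``S*`` is the
  expected-gain-optimal aim for their sigma.  ``lambda = 1`` is optimal,
  ``lambda < 1`` underadjustment.  The timing and distance lambdas of one
  participant are correlated (``rho``), encoding a modality-shared risk
  propensity.

Responses are Gaussian around the block aim, floored at a small positive
magnitude, with a small probability of being replaced by a contaminant
drawn uniformly from a wide implausible range.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .payoff import (
    DISTANCE_TARGET_MM,
    HIT_MARGIN,
    TIMING_TARGET_MS,
    classify_responses,
    default_schemes,
    optimal_aim,
)
from .preprocess import PENALTY_BLOCKS

__all__ = ["CohortConfig", "simulate_participant", "simulate_cohort"]

BLOCK_ORDER = ("P", "1", "2", "3", "4", "5")
MODALITIES = ("timing", "distance")
RESPONSE_FLOOR = {"timing": 1.0, "distance": 0.1}


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth and design parameters of a synthetic cohort.

    Scale parameters are in native units (ms for timing, mm for distance).
    ``sigma_median_*`` and ``sigma_log_sd`` parameterize the log-normal
    between-participant distribution of response SDs.  The timing median of
    80 ms matches the precision range of interval reproduction at 750 ms;
    the distance median of 5.9 mm gives the same precision *relative to the
    rewarded window* (sigma/target = 80/750), keeping the two tasks
    symmetric the way their identical payoff structure intends.
    ``lambda_mean = 1.0`` centres the cohort on the optimal strategy and
    ``lambda_sd = 0.7`` spreads adjustment propensities widely enough that
    individual strategies are resolvable against the estimation noise of a
    50-trial block; ``rho = 0.6`` couples the two modalities.  Baseline
    biases are kept small relative to the hit window (8 ms / 0.6 mm).
    """

    n_participants: int = 36
    trials_per_block: int = 50
    practice_trials: int = 50
    sigma_median_timing: float = 80.0
    sigma_median_distance: float = 5.9
    sigma_log_sd: float = 0.15
    bias_sd_timing: float = 8.0
    bias_sd_distance: float = 0.6
    lambda_mean: float = 1.0
    lambda_sd: float = 0.7
    rho: float = 0.6
    outlier_rate: float = 0.02
    outlier_range_timing: tuple[float, float] = (100.0, 3000.0)
    outlier_range_distance: tuple[float, float] = (5.0, 200.0)
    margin_fraction: float = HIT_MARGIN
    scalar_sigma: bool = False  # sigma grows with aim (scalar property) if set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_block < 1 or self.practice_trials < 0:
            raise ValueError("trial counts must be positive")
        for name in (
            "sigma_median_timing", "sigma_median_distance", "sigma_log_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")

    def with_(self, **kwargs) -> "CohortConfig":
        """Copy of the config with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ParticipantDraw:
    """One participant's ground-truth parameters for both modalities."""

    participant_id: str
    sigma: dict[str, float]
    bias: dict[str, float]
    lam: dict[str, float]


def _draw_participants(config: CohortConfig, rng: np.random.Generator) -> list[ParticipantDraw]:
    n = config.n_participants
    sig_t = config.sigma_median_timing * np.exp(
        rng.normal(0.0, config.sigma_log_sd, size=n)
    )
    sig_d = config.sigma_median_distance * np.exp(
        rng.normal(0.0, config.sigma_log_sd, size=n)
    )
    bias_t = rng.normal(0.0, config.bias_sd_timing, size=n)
    bias_d = rng.normal(0.0, config.bias_sd_distance, size=n)
    cov = config.lambda_sd**2 * np.array([[1.0, config.rho], [config.rho, 1.0]])
    lam = rng.multivariate_normal(
        [config.lambda_mean, config.lambda_mean], cov, size=n, method="cholesky"
    ) if config.lambda_sd > 0 else np.full((n, 2), config.lambda_mean)
    return [
        ParticipantDraw(
            participant_id=f"p{i + 1:02d}",
            sigma={"timing": float(sig_t[i]), "distance": float(sig_d[i])},
            bias={"timing": float(bias_t[i]), "distance": float(bias_d[i])},
            lam={"timing": float(lam[i, 0]), "distance": float(lam[i, 1])},
        )
        for i in range(n)
    ]


def simulate_participant(
    config: CohortConfig,
    draw: ParticipantDraw,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate all trials of one participant (both modalities).

    Returns trial rows with columns participant, modality, block, trial,
    response, outcome, points.
    """
    frames = []
    for modality in MODALITIES:
        target = TIMING_TARGET_MS if modality == "timing" else DISTANCE_TARGET_MM
        schemes = default_schemes(modality, config.margin_fraction)
        sigma = draw.sigma[modality]
        aim_base = target + draw.bias[modality]
        floor = RESPONSE_FLOOR[modality]
        lo, hi = (
            config.outlier_range_timing
            if modality == "timing"
            else config.outlier_range_distance
        )
        for block in BLOCK_ORDER:
            n_trials = (
                config.practice_trials if block == "P" else config.trials_per_block
            )
            if n_trials == 0:
                continue
            if block in PENALTY_BLOCKS:
                s_star = optimal_aim(sigma, schemes[block])
                aim = aim_base + draw.lam[modality] * (s_star - aim_base)
            else:
                aim = aim_base
            block_sigma = sigma * (aim / target) if config.scalar_sigma else sigma
            resp = rng.normal(aim, block_sigma, size=n_trials)
            if config.outlier_rate > 0:
                is_out = rng.random(n_trials) < config.outlier_rate
                resp[is_out] = rng.uniform(lo, hi, size=int(is_out.sum()))
            resp = np.maximum(resp, floor)
            outcome, points = classify_responses(resp, schemes[block])
            frames.append(
                pd.DataFrame(
                    {
                        "participant": draw.participant_id,
                        "modality": modality,
                        "block": block,
                        "trial": np.arange(1, n_trials + 1),
                        "response": resp,
                        "outcome": outcome,
                        "points": points,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trials, ground_truth) DataFrames.

    The ground-truth table records each participant's sigma, baseline bias
    and lambda per modality.  Output is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    draws = _draw_participants(config, rng)
    trials = pd.concat(
        [simulate_participant(config, d, rng) for d in draws], ignore_index=True
    )
    truth = pd.DataFrame(
        [
            {
                "participant": d.participant_id,
                "modality": m,
                "sigma": d.sigma[m],
                "bias": d.bias[m],
                "lam": d.lam[m],
            }
            for d in draws
            for m in MODALITIES
        ]
    )
    return trials, truth
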