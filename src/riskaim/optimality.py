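"""Per-participant optimality and efficiency statistics.

For each penalty block the *actual adjustment* is the shift of the mean
response relative to the no-punishment Block 1, and the *optimal
adjustment* is the shift that would place the mean at the expected-gain
maximizing aim given the penalty block's empirical SD.  Their difference is
the *optimality score*: negative values mean the participant should have
adjusted more (risk-seeking underadjustment), positive values mean
overadjustment.  *Efficiency* is the percentage of points actually earned
in a block relative to the maximum expected amount given the participant's
SD; lucky streaks can push it above 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .payoff import PayoffScheme, default_schemes, max_expected_gain, optimal_aim
from .preprocess import PENALTY_BLOCKS, BlockSummary

__all__ = [
    "OptimalityResult",
    "optimal_adjustment",
    "optimality_score",
    "efficiency",
    "ridge_side_fraction",
    "participant_optimality",
    "results_to_frame",
]


@dataclass
class OptimalityResult:
    """Optimality statistics for one participant x modality x penalty block."""

    participant_id: str
    modality: str
    block: str
    sigma_used: float
    actual_adjustment: float
    optimal_adjustment: float
    optimality: float
    efficiency: float


def optimal_adjustment(
    block_summary: BlockSummary,
    block1_summary: BlockSummary,
    scheme: PayoffScheme,
    sigma_source: str = "block",
) -> float:
    """Shift from the Block-1 mean needed to reach the optimal aim.

    The noise level entering the optimal-aim computation is the penalty
    block's own empirical SD by default (``sigma_source="block"``); Block-1
    SD can be used instead (``sigma_source="block1"``).
    """
    if not block1_summary.valid:
        raise ValueError("valid Block-1 summary required")
    if not block_summary.valid:
        raise ValueError(f"invalid summary for block {block_summary.block}")
    sigma = {
        "block": block_summary.sd_response,
        "block1": block1_summary.sd_response,
    }[sigma_source]
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"cannot use non-positive SD {sigma}")
    return optimal_aim(sigma, scheme) - block1_summary.mean_response


def optimality_score(actual_adjustment: float, optimal_adjustment: float) -> float:
    """Actual minus optimal adjustment (negative = underadjustment)."""
    if not (np.isfinite(actual_adjustment) and np.isfinite(optimal_adjustment)):
        raise ValueError("adjustments must be finite")
    return actual_adjustment - optimal_adjustment


def efficiency(block_summary: BlockSummary, scheme: PayoffScheme) -> float:
    """Realized points as a percentage of the maximum expected amount.

    The denominator is the number of kept trials times the maximum expected
    gain at the block's empirical SD.  Raises when the maximum expected
    gain is not positive (efficiency undefined).
    """
    if not block_summary.valid or block_summary.n_kept < 2:
        raise ValueError("need a valid summary with >= 2 kept trials")
    meg = max_expected_gain(block_summary.sd_response, scheme)
    if meg <= 0:
        raise ValueError(
            f"maximum expected gain {meg} <= 0; efficiency undefined"
        )
    return 100.0 * block_summary.total_points / (block_summary.n_kept * meg)


def ridge_side_fraction(results: list[OptimalityResult] | pd.DataFrame) -> float:
    """Percent of participants whose mean response sits short of the ridge.

    A negative optimality score places the mean response on the early/close
    side of the optimal ridge for that participant's SD.
    """
    if isinstance(results, pd.DataFrame):
        scores = results["optimality"].to_numpy(dtype=float)
    else:
        scores = np.array([r.optimality for r in results], dtype=float)
    if scores.size == 0:
        raise ValueError("no optimality results given")
    return 100.0 * float(np.mean(scores < 0))


def participant_optimality(
    summaries: list[BlockSummary],
    schemes: dict[str, PayoffScheme] | None = None,
    sigma_source: str = "block",
) -> list[OptimalityResult]:
    """Optimality statistics for the penalty blocks of one participant x modality.

    ``summaries`` are the block summaries of a single participant and
    modality (see :func:`riskaim.preprocess.summarize_blocks`).  Blocks
    without a valid summary are skipped.
    """
    by_block = {s.block: s for s in summaries}
    base = by_block.get("1")
    if base is None or not base.valid:
        raise ValueError("valid Block-1 summary required")
    if schemes is None:
        schemes = default_schemes(base.modality)

    results = []
    for b in PENALTY_BLOCKS:
        s = by_block.get(b)
        if s is None or not s.valid:
            continue
        scheme = schemes[b]
        actual = s.mean_response - base.mean_response
        optimal = optimal_adjustment(s, base, scheme, sigma_source=sigma_source)
        sigma = s.sd_response if sigma_source == "block" else base.sd_response
        results.append(
            OptimalityResult(
                participant_id=s.participant_id,
                modality=s.modality,
                block=b,
                sigma_used=sigma,
                actual_adjustment=actual,
                optimal_adjustment=optimal,
                optimality=optimality_score(actual, optimal),
                efficiency=efficiency(s, scheme),
            )
        )
    return results


def results_to_frame(results: list[OptimalityResult]) -> pd.DataFrame:
    """Flatten OptimalityResult records into a DataFrame."""
    return pd.DataFrame([vars(r) for r in results])
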