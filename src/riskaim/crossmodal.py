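"""Cross-modal association of optimality scores.

Tests whether a participant's degree of under/over-adjustment in the
distance task predicts their under/over-adjustment in the timing task,
across punishment levels.  Inference is ordinary least squares — timing
optimality regressed on distance optimality plus a punishment-level
indicator (5-point punishment as the reference) — with 95% confidence
intervals from a participant-clustered bootstrap: participants are
resampled with replacement and the model refit on each resample, so the
within-participant dependence of the two punishment rows is respected
without mixed-model machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionReport",
    "build_crossmodal_rows",
    "crossmodal_regression",
    "adjustment_model",
]

PUNISHMENT_BY_BLOCK = {"2": 5, "4": 30}


@dataclass
class RegressionReport:
    """OLS point estimates with cluster-bootstrap confidence intervals."""

    params: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_obs: int
    n_clusters: int
    n_boot: int
    seed: int
    term_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                t: {
                    "estimate": self.params[t],
                    "ci_low": self.ci_low[t],
                    "ci_high": self.ci_high[t],
                }
                for t in self.term_names
            },
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def build_crossmodal_rows(optimality_df: pd.DataFrame) -> pd.DataFrame:
    """Merge timing and distance optimality into one row per participant x level.

    ``optimality_df`` holds OptimalityResult rows for both modalities
    (columns participant_id, modality, block, optimality).  Returns columns
    participant_id, punishment_level, timing_optimality, distance_optimality,
    keeping only participant x block cells present in both modalities.
    """
    df = optimality_df.copy()
    df["block"] = df["block"].astype(str)
    df["punishment_level"] = df["block"].map(PUNISHMENT_BY_BLOCK)
    wide = df.pivot_table(
        index=["participant_id", "punishment_level"],
        columns="modality",
        values="optimality",
    ).reset_index()
    wide = wide.rename(
        columns={"timing": "timing_optimality", "distance": "distance_optimality"}
    )
    wide = wide.dropna(subset=["timing_optimality", "distance_optimality"])
    if not np.isfinite(wide[["timing_optimality", "distance_optimality"]].to_numpy()).all():
        raise ValueError("optimality values must be finite")
    return wide[
        ["participant_id", "punishment_level", "timing_optimality", "distance_optimality"]
    ]


def _cluster_bootstrap(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    n_boot: int,
    seed: int,
) -> np.ndarray:
    """Bootstrap OLS coefficients by resampling clusters with replacement."""
    rng = np.random.default_rng(seed)
    ids = np.unique(clusters)
    rows_by_id = {c: np.flatnonzero(clusters == c) for c in ids}
    out = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        chosen = rng.choice(ids, size=ids.size, replace=True)
        idx = np.concatenate([rows_by_id[c] for c in chosen])
        beta, _, rank, _ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
        out[b] = beta if rank == X.shape[1] else np.nan
    return out


def _ols_with_cluster_ci(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    term_names: list[str],
    n_boot: int,
    seed: int,
    alpha: float = 0.05,
) -> RegressionReport:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    boot = _cluster_bootstrap(X, y, clusters, n_boot, seed)
    boot = boot[np.isfinite(boot).all(axis=1)]
    lo = np.percentile(boot, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    return RegressionReport(
        params={t: float(b) for t, b in zip(term_names, fit.params)},
        ci_low={t: float(v) for t, v in zip(term_names, lo)},
        ci_high={t: float(v) for t, v in zip(term_names, hi)},
        n_obs=int(len(y)),
        n_clusters=int(np.unique(clusters).size),
        n_boot=n_boot,
        seed=seed,
        term_names=list(term_names),
    )


def crossmodal_regression(
    rows: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    standardize: bool = False,
) -> RegressionReport:
    """OLS of timing optimality on distance optimality + punishment level.

    The punishment indicator codes the 30-point level against the 5-point
    reference.  With ``standardize`` the two optimality variables are
    z-scored (each within its own modality/units) before fitting, giving a
    unit-free slope.  CIs are percentile intervals from ``n_boot``
    participant-cluster resamples.
    """
    if rows["participant_id"].nunique() < 5:
        raise ValueError("need at least 5 participants with both modalities")
    y = rows["timing_optimality"].to_numpy(dtype=float)
    x = rows["distance_optimality"].to_numpy(dtype=float)
    if standardize:
        y = (y - y.mean()) / y.std(ddof=1)
        x = (x - x.mean()) / x.std(ddof=1)
    X = np.column_stack(
        [
            np.ones(len(rows)),
            x,
            (rows["punishment_level"].to_numpy() == 30).astype(float),
        ]
    )
    clusters = rows["participant_id"].to_numpy()
    return _ols_with_cluster_ci(
        X, y, clusters,
        term_names=["intercept", "distance_optimality", "punishment_30"],
        n_boot=n_boot, seed=seed,
    )


def adjustment_model(
    summaries_df: pd.DataFrame,
    modality: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> RegressionReport:
    """Per-modality OLS of adjustment on punishment level and block SD.

    ``summaries_df`` holds BlockSummary rows (both penalty blocks and
    Block 1) for one modality across participants.  The response is the
    penalty-block mean minus the participant's Block-1 mean; predictors are
    the 30-punishment indicator and the penalty block's SD.
    """
    df = summaries_df[summaries_df["modality"] == modality].copy()
    df["block"] = df["block"].astype(str)
    base = df[df["block"] == "1"].set_index("participant_id")["mean_response"]
    pen = df[df["block"].isin(PUNISHMENT_BY_BLOCK)].copy()
    pen = pen[pen["valid"]] if "valid" in pen.columns else pen
    pen["adjustment"] = pen["mean_response"] - pen["participant_id"].map(base).astype(float)
    pen = pen.dropna(subset=["adjustment", "sd_response"])
    if pen["participant_id"].nunique() < 5:
        raise ValueError("need at least 5 participants")
    X = np.column_stack(
        [
            np.ones(len(pen)),
            (pen["block"] == "4").astype(float).to_numpy(),
            pen["sd_response"].to_numpy(dtype=float),
        ]
    )
    y = pen["adjustment"].to_numpy(dtype=float)
    return _ols_with_cluster_ci(
        X, y, pen["participant_id"].to_numpy(),
        term_names=["intercept", "punishment_30", "sd"],
        n_boot=n_boot, seed=seed,
    )
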