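"""Configuration, file formats, and the end-to-end analysis pipeline.

Trial-level data travel as CSV with columns participant, modality, block,
trial, response (comma-delimited, header required; responses in ms for
timing, mm for distance).  Payoff schemes can be loaded from a YAML or
JSON file; the built-in default encodes the standard scheme (blocks P,1-5
with early penalties 0,0,-5,0,-30,0 and a 5-point hit reward in the
experimental blocks).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossmodal, optimality, preprocess
from .payoff import (
    DISTANCE_TARGET_MM,
    HIT_MARGIN,
    BLOCK_EARLY_GAINS,
    TIMING_TARGET_MS,
    PayoffScheme,
    RewardSurface,
)

__all__ = [
    "PipelineConfig",
    "read_trials",
    "write_trials",
    "load_schemes",
    "default_scheme_dict",
    "run_analysis",
    "write_surface",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("participant", "modality", "block", "trial", "response")


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis pipeline reproducibly."""

    mad_k: float = 3.0
    mad_normalized: bool = True
    sigma_source: str = "block"  # SD entering optimal_aim: penalty block or block1
    n_boot: int = 2000
    bootstrap_seed: int = 0
    standardize_crossmodal: bool = False
    margin_fraction: float = HIT_MARGIN
    scheme_file: str | None = None

    def log_values(self) -> None:
        for k, v in vars(self).items():
            log.info("config %s = %r", k, v)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-level CSV, validating columns and rejecting bad rows.

    Rows with a missing or non-positive response, or an unknown block or
    modality, are logged with their row numbers and dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV missing columns: {missing}")
    if df.empty:
        raise ValueError(f"input CSV {path} contains no trials")
    df["block"] = df["block"].astype(str)
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    bad = (
        df["response"].isna()
        | (df["response"] <= 0)
        | ~df["block"].isin(("P", "1", "2", "3", "4", "5"))
        | ~df["modality"].isin(("timing", "distance"))
    )
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        log.warning("rejecting %d malformed rows (file rows %s)", bad.sum(), rows[:20])
        df = df[~bad].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no valid trials left after validation of {path}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


def default_scheme_dict(margin_fraction: float = HIT_MARGIN) -> dict:
    """The standard payoff scheme as a plain serializable dict."""
    return {
        modality: {
            "target": TIMING_TARGET_MS if modality == "timing" else DISTANCE_TARGET_MM,
            "margin_fraction": margin_fraction,
            "blocks": {
                b: {
                    "gain_early": BLOCK_EARLY_GAINS[b],
                    "gain_hit": 0.0 if b == "P" else 5.0,
                    "gain_late": 0.0,
                }
                for b in ("P", "1", "2", "3", "4", "5")
            },
        }
        for modality in ("timing", "distance")
    }


def load_schemes(
    path: str | Path | None = None, margin_fraction: float = HIT_MARGIN
) -> dict[str, dict[str, PayoffScheme]]:
    """Load per-modality, per-block payoff schemes from YAML/JSON.

    Without a path the built-in defaults are used.  Returns
    ``{modality: {block: PayoffScheme}}``.
    """
    if path is None:
        raw = default_scheme_dict(margin_fraction)
    else:
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    out: dict[str, dict[str, PayoffScheme]] = {}
    for modality, entry in raw.items():
        out[modality] = {
            str(b): PayoffScheme(
                target=float(entry["target"]),
                margin_fraction=float(entry.get("margin_fraction", margin_fraction)),
                gain_hit=float(g["gain_hit"]),
                gain_early=float(g["gain_early"]),
                gain_late=float(g["gain_late"]),
                modality_label=modality,
            )
            for b, g in entry["blocks"].items()
        }
    return out


def run_analysis(
    trials: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """Filter, summarize, score optimality, and fit the cross-modal model.

    Returns a dict with DataFrames ``summaries`` and ``optimality`` and a
    JSON-serializable ``report`` holding exclusion fractions per modality,
    per-block efficiency medians, ridge-side fractions, and the regression
    reports.
    """
    config = config or PipelineConfig()
    config.log_values()
    schemes = load_schemes(config.scheme_file, config.margin_fraction)

    filtered = preprocess.filter_trials(
        trials, k=config.mad_k, normalized=config.mad_normalized
    )
    exclusion = {
        m: preprocess.exclusion_fraction(filtered, m)
        for m in filtered["modality"].unique()
    }
    for m, frac in sorted(exclusion.items()):
        log.info("excluded %.1f%% of the %s trials", 100 * frac, m)

    all_summaries: list[preprocess.BlockSummary] = []
    all_results: list[optimality.OptimalityResult] = []
    for (pid, mod), grp in filtered.groupby(["participant", "modality"], sort=True):
        summ = preprocess.summarize_blocks(grp, schemes[mod])
        all_summaries.extend(summ)
        try:
            all_results.extend(
                optimality.participant_optimality(
                    summ, schemes[mod], sigma_source=config.sigma_source
                )
            )
        except ValueError as exc:
            log.warning("skipping optimality for %s/%s: %s", pid, mod, exc)

    summaries_df = preprocess.summaries_to_frame(all_summaries)
    results_df = optimality.results_to_frame(all_results)

    report: dict = {
        "exclusion_fraction": {m: float(f) for m, f in exclusion.items()},
        "n_participants": int(filtered["participant"].nunique()),
        "efficiency_median": {},
        "ridge_side_fraction": {},
    }
    for (mod, block), grp in results_df.groupby(["modality", "block"]):
        report["efficiency_median"][f"{mod}_block{block}"] = float(
            grp["efficiency"].median()
        )
        report["ridge_side_fraction"][f"{mod}_block{block}"] = (
            optimality.ridge_side_fraction(grp)
        )

    rows = crossmodal.build_crossmodal_rows(results_df)
    try:
        report["crossmodal"] = crossmodal.crossmodal_regression(
            rows,
            n_boot=config.n_boot,
            seed=config.bootstrap_seed,
            standardize=config.standardize_crossmodal,
        ).to_dict()
    except ValueError as exc:
        log.warning("cross-modal regression not fit: %s", exc)
        report["crossmodal"] = None
    report["adjustment_models"] = {}
    for mod in sorted(summaries_df["modality"].unique()):
        try:
            report["adjustment_models"][mod] = crossmodal.adjustment_model(
                summaries_df, mod, n_boot=config.n_boot, seed=config.bootstrap_seed
            ).to_dict()
        except ValueError as exc:
            log.warning("adjustment model for %s not fit: %s", mod, exc)
            report["adjustment_models"][mod] = None

    return {
        "filtered": filtered,
        "summaries": summaries_df,
        "optimality": results_df,
        "crossmodal_rows": rows,
        "report": report,
    }


def write_surface(surface: RewardSurface, out_dir: str | Path, stem: str) -> None:
    """Write an expected-reward surface and its ridge as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = pd.DataFrame(
        surface.expected_points,
        index=pd.Index(surface.sigma_grid, name="sigma"),
        columns=[f"{a:g}" for a in surface.aim_grid],
    )
    mat.to_csv(out / f"{stem}_surface.csv", float_format="%.6f")
    pd.DataFrame(
        {"sigma": surface.sigma_grid, "optimal_aim": surface.optimal_ridge}
    ).to_csv(out / f"{stem}_ridge.csv", index=False, float_format="%.6f")
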