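"""Differential AP-MS / BioID interactomics.

The layer takes SAINT-scored interactor lists and label-free MS1 intensity
tables, filters to high-confidence interactors, normalizes prey intensities
to the bait, imputes missing-not-at-random values from a down-shifted normal
distribution anchored at the 5th percentile of the observed log2 intensities,
tests each mutant condition against the wild-type reference, and summarizes
regulation calls and cancer-driver-protein (CDP) enrichment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import InteractomeThresholds, ValidationError
from .stats import differential_long, fisher_two_sided

logger = logging.getLogger("mlproteo.interactome")

__all__ = [
    "filter_high_confidence",
    "bait_normalize",
    "impute_low_quantile",
    "differential_interactome",
    "count_regulated",
    "cdp_enrichment",
    "replicate_cv",
]

_METHODS = frozenset({"APMS", "BioID"})


def filter_high_confidence(records: pd.DataFrame,
                           thresholds: InteractomeThresholds | None = None,
                           ) -> pd.DataFrame:
    """Select high-confidence interactors and remove likely contaminants.

    AP-MS preys need a SAINT score strictly above ``saint_apms``; BioID
    preys need a score of at least ``saint_bioid`` (default: exactly 1).
    Surviving preys are then removed if they appear in more than
    ``control_freq_max`` of the contaminant-control runs or in the GFP
    control pulldowns.
    """
    t = thresholds or InteractomeThresholds()
    unknown = set(records["method"]) - _METHODS
    if unknown:
        raise ValidationError(f"unknown interaction method(s): {sorted(unknown)}")
    is_apms = records["method"] == "APMS"
    confident = np.where(
        is_apms,
        records["saint_score"] > t.saint_apms,
        records["saint_score"] >= t.saint_bioid,
    )
    contaminant = (records["control_frequency"] > t.control_freq_max) | records[
        "in_gfp_control"
    ].astype(bool)
    kept = records[confident & ~contaminant].reset_index(drop=True)
    logger.info("filter_high_confidence: kept %d of %d records",
                len(kept), len(records))
    return kept


def bait_normalize(records: pd.DataFrame, bait_id: str) -> pd.DataFrame:
    """Divide every intensity by the bait intensity of the same run.

    The bait must be quantified (present, > 0) in every (condition,
    replicate); the bait analyte itself maps to exactly 1.0. Missing prey
    intensities stay missing.
    """
    bait = records[records["analyte_id"] == bait_id]
    runs = records[["condition", "replicate"]].drop_duplicates()
    bait_by_run = {
        (row.condition, row.replicate): row.intensity
        for row in bait.itertuples()
    }
    for row in runs.itertuples():
        run = (row.condition, row.replicate)
        v = bait_by_run.get(run)
        if v is None or not np.isfinite(v) or v <= 0:
            raise ValidationError(
                f"bait not quantified in {run[0]}/{run[1]}"
            )
    out = records.copy()
    denom = np.array([
        bait_by_run[(c, r)] for c, r in zip(out["condition"], out["replicate"])
    ])
    out["intensity"] = out["intensity"].astype(float) / denom
    # the bait maps to exactly 1.0 (avoid fp residue from the division)
    out.loc[out["analyte_id"] == bait_id, "intensity"] = 1.0
    return out


def impute_low_quantile(records: pd.DataFrame, q: float = 0.05,
                        width_factor: float = 0.3, seed: int = 0,
                        min_condition_detection: float = 0.5) -> pd.DataFrame:
    """Impute missing intensities from a down-shifted normal distribution.

    Missing log2 intensities are drawn from
    ``Normal(mean = q-th percentile of observed log2 intensities,
    sd = width_factor * sd of observed log2 intensities)``, truncated below
    at the observed minimum minus three observed standard deviations, then
    exponentiated back. Observed values are untouched; imputation is seeded
    and reproducible.

    Only analytes detected in at least ``min_condition_detection`` of the
    runs of at least one condition are imputed; analytes missing everywhere
    (or below that detection floor) are flagged in an ``imputed``-free state
    and left missing. At least 20 observed values are required for the
    percentile to be meaningful.
    """
    out = records.copy()
    observed = out["intensity"].dropna().astype(float)
    if out["intensity"].isna().sum() == 0:
        out["imputed"] = False
        return out
    if len(observed) < 20:
        raise ValidationError(
            f"need >= 20 observed intensities to anchor the imputation "
            f"quantile, got {len(observed)}"
        )
    log_obs = np.log2(observed.to_numpy())
    center = float(np.percentile(log_obs, 100.0 * q))
    sd_obs = float(log_obs.std(ddof=1))
    sd_draw = width_factor * sd_obs
    floor = float(log_obs.min() - 3.0 * sd_obs)

    n_runs_per_cond = (
        records[["condition", "replicate"]].drop_duplicates()
        .groupby("condition").size()
    )
    det = out.dropna(subset=["intensity"]).groupby(
        ["analyte_id", "condition"]).size()
    eligible = set()
    for (aid, cond), n_det in det.items():
        if n_det / n_runs_per_cond[cond] >= min_condition_detection:
            eligible.add(aid)

    rng = np.random.default_rng(seed)
    out["imputed"] = False
    missing_mask = out["intensity"].isna() & out["analyte_id"].isin(eligible)
    n_missing = int(missing_mask.sum())
    draws = rng.normal(center, sd_draw, size=n_missing)
    draws = np.maximum(draws, floor)
    out.loc[missing_mask, "intensity"] = np.exp2(draws)
    out.loc[missing_mask, "imputed"] = True
    n_flagged = int((out["intensity"].isna()).sum())
    if n_flagged:
        logger.info("impute_low_quantile: %d value(s) of never/rarely detected "
                    "analytes left missing", n_flagged)
    return out


def differential_interactome(records: pd.DataFrame, reference: str,
                             thresholds: InteractomeThresholds | None = None,
                             ) -> pd.DataFrame:
    """Differential interaction testing of each mutant against the reference.

    ``records`` must be bait-normalized and imputed. Per prey and mutant
    condition: log2FC of mean log2 intensities, pooled-variance two-sided
    t-test, BH adjustment within the contrast, and a regulation call at
    ``|log2FC| > fc_thresh`` and ``adj p <= adj_p_thresh``.
    """
    t = thresholds or InteractomeThresholds()
    return differential_long(records, reference, fc_thresh=t.fc_thresh,
                             adj_p_thresh=t.adj_p_thresh)


def count_regulated(results: pd.DataFrame, condition: str,
                    ) -> tuple[int, int, int]:
    """(n_up, n_down, n_total) regulation calls for one condition."""
    sub = results[results["condition"] == condition]
    n_up = int((sub["regulated"] == "up").sum())
    n_down = int((sub["regulated"] == "down").sum())
    return n_up, n_down, n_up + n_down


def cdp_enrichment(interactors: set[str], cdp_list: set[str],
                   background: set[str]) -> tuple[float, float]:
    """Fraction of cancer-driver proteins among interactors and Fisher p.

    The two-sided Fisher test contrasts CDP membership between the
    interactor set and the rest of the measured background.
    """
    if not interactors:
        raise ValidationError("interactor set is empty")
    if not interactors <= background:
        raise ValidationError("interactors must be a subset of the background")
    n_int_cdp = len(interactors & cdp_list)
    n_int = len(interactors)
    rest = background - interactors
    n_rest_cdp = len(rest & cdp_list)
    table = [
        [n_int_cdp, n_int - n_int_cdp],
        [n_rest_cdp, len(rest) - n_rest_cdp],
    ]
    return n_int_cdp / n_int, fisher_two_sided(table)


def replicate_cv(records: pd.DataFrame, qc_bound: float = 0.21,
                 ) -> tuple[pd.DataFrame, dict]:
    """Coefficient of variation across replicates, per analyte and condition.

    CV = sd / mean of the raw intensities of one analyte in one condition
    (replicates with missing intensity are dropped; at least two are
    required). The summary reports the median CV and the fraction of
    (analyte, condition) cells exceeding ``qc_bound``.
    """
    obs = records.dropna(subset=["intensity"])
    rows = []
    for (aid, cond), g in obs.groupby(["analyte_id", "condition"]):
        v = g["intensity"].to_numpy(dtype=float)
        if v.size < 2:
            continue
        rows.append((aid, cond, float(v.std(ddof=1) / v.mean())))
    per = pd.DataFrame(rows, columns=["analyte_id", "condition", "cv"])
    summary = {
        "median_cv": float(per["cv"].median()) if len(per) else float("nan"),
        "fraction_above_bound": (
            float((per["cv"] > qc_bound).mean()) if len(per) else float("nan")
        ),
        "qc_bound": qc_bound,
        "n": len(per),
    }
    return per, summary
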