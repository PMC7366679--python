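"""Quantitative cross-linking layer.

Cross-link identifications (lysine residue pairs from a DSS cross-linker,
scored by a linear-discriminant confidence) are filtered, their targeted
PRM transition traces are screened by an automated surrogate of manual
peak review (retention-time match, light/heavy co-elution, transition-pattern
shape correlation), quantified by summing transition areas across both
isotope channels, normalized to two non-cross-linked reference peptides,
imputed with the global minimum, and tested differentially. Cross-links are
finally mapped onto a C-alpha structure and classified against the
cross-linker's distance restraint (~30 A for DSS).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .datamodel import StructureModel, ValidationError, XlThresholds
from .stats import differential_long

logger = logging.getLogger("mlproteo.xlink")

__all__ = [
    "filter_identifications",
    "accept_peak",
    "quantify_crosslink",
    "quantify_all",
    "normalize_to_reference",
    "impute_minimum",
    "replicate_pearson",
    "pca_scores",
    "differential_crosslinks",
    "check_distance_restraint",
    "map_restraints",
]


def filter_identifications(xls: pd.DataFrame,
                           thresholds: XlThresholds | None = None) -> pd.DataFrame:
    """Keep identifications with ld score strictly above the cut-off and both
    peptide arms of at least the minimum length."""
    t = thresholds or XlThresholds()
    keep = (
        (xls["ld_score"] > t.ld_min)
        & (xls["peptide_len_a"] >= t.min_pep_len)
        & (xls["peptide_len_b"] >= t.min_pep_len)
    )
    return xls[keep].reset_index(drop=True)


def _paired_areas(run: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    light = run[run["channel"] == "light"].set_index("transition_index")["area"]
    heavy = run[run["channel"] == "heavy"].set_index("transition_index")["area"]
    common = sorted(set(light.index) & set(heavy.index))
    l = light.loc[common].to_numpy(dtype=float)
    h = heavy.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(l) & np.isfinite(h)
    return l[ok], h[ok]


def _shape_correlation(light: np.ndarray, heavy: np.ndarray) -> float:
    # zero-variance patterns: identical flat traces are perfectly matching
    if light.std() == 0.0 or heavy.std() == 0.0:
        return 1.0 if light.std() == heavy.std() == 0.0 else 0.0
    return float(np.corrcoef(light, heavy)[0, 1])


def accept_peak(measurements: pd.DataFrame, library_rt: float,
                thresholds: XlThresholds | None = None,
                ) -> tuple[bool, list[str]]:
    """Automated surrogate of manual PRM peak review for one run of one
    cross-link.

    Acceptance requires (1) the median transition apex within
    ``rt_tolerance_min`` of the library retention time, (2) light and heavy
    apexes co-eluting within ``coelution_tol_min``, and (3) a Pearson
    correlation of at least ``shape_corr_min`` between the paired light and
    heavy transition areas. Returns ``(accepted, reasons)`` where reasons
    name every failed criterion.
    """
    t = thresholds or XlThresholds()
    reasons: list[str] = []
    channels = set(measurements["channel"])
    if not {"light", "heavy"} <= channels:
        raise ValidationError("both light and heavy channels are required")
    light_m = measurements[measurements["channel"] == "light"]
    heavy_m = measurements[measurements["channel"] == "heavy"]
    l_areas, h_areas = _paired_areas(measurements)
    if l_areas.size < 3:
        return False, ["insufficient transitions"]
    apex = float(measurements["apex_rt"].median())
    if abs(apex - library_rt) > t.rt_tolerance_min:
        reasons.append("rt_mismatch")
    coelution = abs(float(light_m["apex_rt"].median())
                    - float(heavy_m["apex_rt"].median()))
    if coelution > t.coelution_tol_min:
        reasons.append("no_coelution")
    if _shape_correlation(l_areas, h_areas) < t.shape_corr_min:
        reasons.append("shape_mismatch")
    return not reasons, reasons


def quantify_crosslink(measurements: pd.DataFrame,
                       thresholds: XlThresholds | None = None) -> float:
    """Abundance of one cross-link in one run: the summed area of its
    transitions (up to six per isotope channel, twelve in total) after
    excluding transitions with signal-to-noise below the cut-off. Returns
    NaN when no transition survives."""
    t = thresholds or XlThresholds()
    kept = measurements[
        (measurements["snr"] >= t.snr_min) & measurements["area"].notna()
    ]
    if kept.empty:
        return float("nan")
    return float(kept["area"].sum())


def quantify_all(measurements: pd.DataFrame, library_rt: dict[str, float],
                 thresholds: XlThresholds | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak-screen and quantify every (cross-link, condition, replicate).

    Returns ``(abundances, rejected)``: a long table with columns
    ``xl_id, condition, replicate, abundance`` (NaN where rejected or
    empty) and a log of rejected runs with their reason codes.
    """
    t = thresholds or XlThresholds()
    rows, rejected = [], []
    for (xl, cond, rep), run in measurements.groupby(
            ["xl_id", "condition", "replicate"]):
        accepted, reasons = accept_peak(run, library_rt[xl], t)
        if not accepted:
            rejected.append((xl, cond, rep, ";".join(reasons)))
            rows.append((xl, cond, rep, float("nan")))
            continue
        rows.append((xl, cond, rep, quantify_crosslink(run, t)))
    abund = pd.DataFrame(rows, columns=["xl_id", "condition", "replicate",
                                        "abundance"])
    rej = pd.DataFrame(rejected, columns=["xl_id", "condition", "replicate",
                                          "reasons"])
    if len(rej):
        logger.info("quantify_all: %d run(s) rejected by peak screening",
                    len(rej))
    return abund, rej


def normalize_to_reference(abundances: pd.DataFrame,
                           reference_intensities: pd.DataFrame,
                           how: str = "mean") -> pd.DataFrame:
    """Normalize cross-link abundances to two non-cross-linked reference
    peptides acquired in the same runs.

    ``reference_intensities`` has columns ``condition, replicate,
    intensity`` with exactly two positive reference values per run;
    each abundance is divided by their mean (or sum with ``how='sum'``).
    """
    if how not in ("mean", "sum"):
        raise ValidationError("how must be 'mean' or 'sum'")
    factors = {}
    for (cond, rep), g in reference_intensities.groupby(["condition", "replicate"]):
        vals = g["intensity"].to_numpy(dtype=float)
        if len(vals) != 2 or not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValidationError(
                f"need exactly 2 positive reference intensities in {cond}/{rep}"
            )
        factors[(cond, rep)] = vals.mean() if how == "mean" else vals.sum()
    out = abundances.copy()
    denom = []
    for row in out.itertuples():
        run = (row.condition, row.replicate)
        if run not in factors:
            raise ValidationError(
                f"reference peptides not quantified in {run[0]}/{run[1]}"
            )
        denom.append(factors[run])
    out["abundance"] = out["abundance"].astype(float) / np.asarray(denom)
    return out


def impute_minimum(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace every missing cell with the global minimum observed value."""
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).all():
        raise ValidationError("all values missing; nothing to impute from")
    return matrix.fillna(float(np.nanmin(values)))


def _matrix(abundances: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long abundance table to cross-links x (condition, replicate)."""
    return abundances.pivot_table(index="xl_id", columns=["condition", "replicate"],
                                  values="abundance", dropna=False)


def replicate_pearson(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise Pearson correlation between replicate runs, and the average
    over within-condition pairs for each condition.

    ``matrix`` is cross-links x runs with a (condition, replicate) column
    MultiIndex.
    """
    corr = matrix.corr(method="pearson")
    averages: dict[str, float] = {}
    for cond in sorted({c for c, _ in matrix.columns}):
        reps = [col for col in matrix.columns if col[0] == cond]
        pair_rs = [corr.loc[a, b] for a, b in itertools.combinations(reps, 2)]
        if pair_rs:
            averages[cond] = float(np.mean(pair_rs))
    return corr, averages


def pca_scores(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the runs over log2 cross-link abundances.

    Samples are the runs (matrix columns), features the cross-links.
    Features are mean-centered; components come from the eigendecomposition
    of the sample covariance; explained-variance fractions sum to 1. The
    sign of each component is fixed so that its largest-magnitude loading
    is positive.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 features")
    x = np.log2(matrix.to_numpy(dtype=float).T)  # samples x features
    if not np.isfinite(x).all():
        raise ValidationError("PCA input must be complete and positive; "
                              "impute first")
    x = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    evr = eigvals / total if total > 0 else np.zeros_like(eigvals)
    scores = u * s
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            scores[:, k] = -scores[:, k]
    score_df = pd.DataFrame(
        scores, index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return score_df, evr


def differential_crosslinks(matrix: pd.DataFrame, reference: str,
                            fc_thresh: float = 1.0, adj_p_thresh: float = 0.05,
                            ) -> pd.DataFrame:
    """Differential cross-link abundance per mutant condition vs reference
    (two-sided pooled-variance t on log2 abundances, BH within contrast)."""
    long = (matrix.stack(["condition", "replicate"], future_stack=True)
            .rename("intensity").reset_index())
    long = long.rename(columns={"xl_id": "analyte_id"})
    return differential_long(long, reference, fc_thresh=fc_thresh,
                             adj_p_thresh=adj_p_thresh)


def check_distance_restraint(pos_a: int, pos_b: int, structure: StructureModel,
                             thresholds: XlThresholds | None = None,
                             offset: int = 0) -> tuple[str, float]:
    """Classify one cross-link against the structural distance restraint.

    Residue positions (plus an optional numbering ``offset`` reconciling
    construct vs deposited-structure numbering) are mapped to C-alpha
    coordinates; the Euclidean distance is compared against
    ``distance_max_A`` (inclusive). Residues outside the covered range or
    lacking a C-alpha give ``("unmappable", nan)``.
    """
    t = thresholds or XlThresholds()
    a = structure.ca(pos_a + offset)
    b = structure.ca(pos_b + offset)
    if a is None or b is None:
        return "unmappable", float("nan")
    d = float(np.linalg.norm(a - b))
    return ("satisfied" if d <= t.distance_max_A else "violated"), d


def map_restraints(xls: pd.DataFrame, structure: StructureModel,
                   thresholds: XlThresholds | None = None,
                   offset: int = 0) -> pd.DataFrame:
    """Distance-restraint classification for a table of cross-links."""
    rows = []
    for row in xls.itertuples():
        status, d = check_distance_restraint(row.pos_a, row.pos_b, structure,
                                             thresholds, offset)
        rows.append((row.xl_id, row.pos_a, row.pos_b, d, status))
    return pd.DataFrame(rows, columns=["xl_id", "pos_a", "pos_b",
                                       "distance_A", "status"])
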