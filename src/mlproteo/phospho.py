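"""DIA (SWATH-style) phospho- and total-proteome layer.

Fragment-level features scored upstream (m-score per feature, decoy flags)
are quality-filtered, the decoy counts converted into an FDR estimate via
the fraction-of-false-targets (FFT) scaling, runs are normalized to equal
total ion signal, fragments are rolled up to peptides with
correlation-based fragment selection, and peptides are tested
differentially against the wild-type reference. Downregulated
phosphopeptides are screened for the kinase substrate consensus
(R/K-x-x(-x)-S/T-P) and tested for motif enrichment; phospho fold changes
are correlated against protein-level fold changes to separate genuine
phosphorylation changes from abundance effects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import DiaThresholds, MotifSpec, ValidationError
from .stats import differential_long, fisher_two_sided

logger = logging.getLogger("mlproteo.phospho")

__all__ = [
    "filter_dia_features",
    "fdr_from_fft",
    "tis_normalize",
    "select_fragments",
    "rollup_peptide",
    "differential_phospho",
    "summarize_regulation",
    "motif_match",
    "motif_enrichment",
    "phospho_protein_correlation",
]


def filter_dia_features(records: pd.DataFrame, mscore_max: float = 0.01,
                        detection_rate_min: float = 0.30) -> pd.DataFrame:
    """Quality-filter DIA features on m-score and detection completeness.

    A feature (analyte) is kept iff its best (smallest) m-score across runs
    is at or below ``mscore_max`` and it is detected (non-missing
    intensity) in at least ``detection_rate_min`` of all runs in the table
    (inclusive, across all conditions).
    """
    n_runs = len(records[["condition", "replicate"]].drop_duplicates())
    best = records.groupby("analyte_id")["mscore"].min()
    detected = (records.dropna(subset=["intensity"])
                .groupby("analyte_id").size())
    keep = {
        aid for aid in best.index
        if best[aid] <= mscore_max
        and detected.get(aid, 0) / n_runs >= detection_rate_min
    }
    out = records[records["analyte_id"].isin(keep)].reset_index(drop=True)
    logger.info("filter_dia_features: kept %d of %d features",
                len(keep), best.size)
    return out


def fdr_from_fft(n_decoy: int, n_target: int, fft: float = 0.46) -> float:
    """Decoy-based FDR estimate scaled by the fraction of false targets:
    ``FDR = fft * n_decoy / n_target``."""
    if n_target <= 0:
        raise ValidationError("n_target must be > 0")
    if n_decoy < 0:
        raise ValidationError("n_decoy must be >= 0")
    return fft * n_decoy / n_target


def tis_normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Total-ion-signal normalization: scale each run so its intensity total
    equals the mean run total. The grand total is conserved."""
    out = records.copy()
    obs = out.dropna(subset=["intensity"])
    totals = obs.groupby(["condition", "replicate"])["intensity"].sum()
    target = totals.mean()
    scale = {run: target / tot for run, tot in totals.items()}
    factors = np.array([
        scale.get((c, r), 1.0)
        for c, r in zip(out["condition"], out["replicate"])
    ])
    out["intensity"] = out["intensity"].astype(float) * factors
    return out


def _fragment_correlations(frag_matrix: pd.DataFrame) -> pd.Series:
    """Pearson correlation of each fragment's run profile against the mean
    fragment profile of its peptide. Zero-variance profiles correlate 1.0
    when both profiles are flat, 0.0 otherwise."""
    mean_profile = frag_matrix.mean(axis=0, skipna=True)
    out = {}
    for frag, profile in frag_matrix.iterrows():
        ok = profile.notna() & mean_profile.notna()
        x = profile[ok].to_numpy(dtype=float)
        m = mean_profile[ok].to_numpy(dtype=float)
        if x.size < 2:
            out[frag] = 0.0
        elif x.std() == 0.0 or m.std() == 0.0:
            out[frag] = 1.0 if x.std() == m.std() == 0.0 else 0.0
        else:
            out[frag] = float(np.corrcoef(x, m)[0, 1])
    return pd.Series(out)


def select_fragments(fragments: pd.DataFrame,
                     thresholds: DiaThresholds | None = None) -> pd.DataFrame:
    """Correlation-based fragment selection before peptide roll-up.

    ``fragments`` is a long table with columns ``analyte_id`` (fragment),
    ``peptide_id``, ``condition``, ``replicate``, ``intensity``. Per
    peptide, each fragment's run profile is correlated against the
    peptide's mean fragment profile; fragments with r below
    ``frag_corr_min`` are dropped, the top ``frag_max`` fragments by total
    intensity are kept, and the peptide is retained only if at least
    ``frag_min`` fragments survive.
    """
    t = thresholds or DiaThresholds()
    kept_parts = []
    for pep, g in fragments.groupby("peptide_id"):
        mat = g.pivot_table(index="analyte_id",
                            columns=["condition", "replicate"],
                            values="intensity", dropna=False)
        corr = _fragment_correlations(mat)
        surviving = corr[corr >= t.frag_corr_min].index
        totals = mat.loc[surviving].sum(axis=1, skipna=True)
        top = totals.sort_values(ascending=False, kind="mergesort").index[: t.frag_max]
        if len(top) < t.frag_min:
            logger.info("select_fragments: peptide %s dropped "
                        "(%d fragment(s) survive)", pep, len(top))
            continue
        kept_parts.append(g[g["analyte_id"].isin(top)])
    if not kept_parts:
        return fragments.iloc[0:0].copy()
    return pd.concat(kept_parts, ignore_index=True)


def rollup_peptide(fragments: pd.DataFrame) -> pd.DataFrame:
    """Sum kept fragment intensities to one peptide intensity per run."""
    obs = fragments.dropna(subset=["intensity"])
    rolled = (obs.groupby(["peptide_id", "condition", "replicate"],
                          as_index=False)["intensity"].sum())
    rolled = rolled.rename(columns={"peptide_id": "analyte_id"})
    return rolled


def differential_phospho(peptides: pd.DataFrame, reference: str,
                         thresholds: DiaThresholds | None = None) -> pd.DataFrame:
    """Per-peptide differential testing of each mutant vs the reference
    (pooled-variance two-sided t on log2 intensities, BH within contrast,
    calls at the layer thresholds)."""
    t = thresholds or DiaThresholds()
    return differential_long(peptides, reference, fc_thresh=t.fc_thresh,
                             adj_p_thresh=t.adj_p_thresh)


def summarize_regulation(results: pd.DataFrame,
                         adj_p_thresh: float = 0.05) -> pd.DataFrame:
    """Per-condition counts and fractions of up/down calls among significant
    analytes.

    The denominator is the number of analytes with ``adj p <=
    adj_p_thresh`` in that contrast (the significant set), so the reported
    fractions are "share of significant analytes moving each way".
    """
    rows = []
    for cond, sub in results.groupby("condition"):
        significant = sub[sub["adj_pvalue"] <= adj_p_thresh]
        n_sig = len(significant)
        n_up = int((significant["regulated"] == "up").sum())
        n_down = int((significant["regulated"] == "down").sum())
        rows.append((cond, n_sig, n_up, n_down,
                     n_up / n_sig if n_sig else 0.0,
                     n_down / n_sig if n_sig else 0.0))
    return pd.DataFrame(rows, columns=["condition", "n_significant", "n_up",
                                       "n_down", "fraction_up", "fraction_down"])


def motif_match(sequence: str, site_index: int,
                motif: MotifSpec | None = None) -> bool:
    """Does the phosphosite carry the kinase substrate consensus?

    True iff the residue at ``site_index`` (1-based) is a valid
    phosphoacceptor, the +1 residue is the required proline, and an R or K
    sits at one of the allowed upstream offsets. Positions beyond either
    terminus count as non-matching.
    """
    m = motif or MotifSpec()
    seq = sequence.upper()
    if not 1 <= site_index <= len(seq):
        raise ValidationError(f"site_index {site_index} outside sequence")
    if seq[site_index - 1] not in m.site_residues:
        return False
    if site_index + 1 > len(seq) or seq[site_index] != m.plus_one:
        return False
    for off in m.basic_offsets:
        pos = site_index + off
        if pos >= 1 and seq[pos - 1] in ("R", "K"):
            return True
    return False


def motif_enrichment(regulated_down: pd.DataFrame, all_quantified: pd.DataFrame,
                     motif: MotifSpec | None = None) -> tuple[float, float]:
    """Fraction of downregulated phosphopeptides carrying the motif, with a
    two-sided Fisher p contrasting motif frequency between downregulated
    and non-downregulated quantified peptides.

    Both inputs are phosphopeptide tables (``peptide_id``, ``sequence``,
    ``site_index``); ``regulated_down`` must be a subset of
    ``all_quantified``.
    """
    m = motif or MotifSpec()
    if regulated_down.empty:
        return 0.0, 1.0
    down_ids = set(regulated_down["peptide_id"])
    has_motif = {
        row.peptide_id: motif_match(row.sequence, row.site_index, m)
        for row in all_quantified.itertuples()
    }
    missing = down_ids - set(has_motif)
    if missing:
        raise ValidationError(
            f"downregulated peptide(s) absent from quantified set: "
            f"{sorted(missing)[:3]}"
        )
    n_down_motif = sum(has_motif[pid] for pid in down_ids)
    n_down = len(down_ids)
    rest = [pid for pid in has_motif if pid not in down_ids]
    n_rest_motif = sum(has_motif[pid] for pid in rest)
    table = [
        [n_down_motif, n_down - n_down_motif],
        [n_rest_motif, len(rest) - n_rest_motif],
    ]
    return n_down_motif / n_down, fisher_two_sided(table)


def phospho_protein_correlation(phospho_results: pd.DataFrame,
                                protein_results: pd.DataFrame,
                                peptide_to_protein: dict[str, str],
                                condition: str) -> float:
    """R^2 between phosphopeptide and matched protein log2 fold changes for
    one condition. Requires at least three matched pairs."""
    ph = phospho_results[phospho_results["condition"] == condition].copy()
    pr = protein_results[protein_results["condition"] == condition]
    ph["protein_id"] = ph["analyte_id"].map(peptide_to_protein)
    merged = ph.dropna(subset=["protein_id"]).merge(
        pr, left_on="protein_id", right_on="analyte_id",
        suffixes=("_phospho", "_protein"),
    )
    if len(merged) < 3:
        raise ValidationError(
            f"need >= 3 matched phospho/protein pairs, got {len(merged)}"
        )
    r = np.corrcoef(merged["log2fc_phospho"], merged["log2fc_protein"])[0, 1]
    return float(r**2)
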