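"""Core domain types shared across the analysis layers.

Quantitative tables (one measured intensity per analyte, condition and
replicate) are carried as long-format :class:`pandas.DataFrame` objects with
documented canonical columns; the dataclasses here hold structured
configuration (thresholds, simulation parameters) and the few objects that
are not naturally tabular (a residue-indexed structure model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SchemaError",
    "ValidationError",
    "QUANT_COLUMNS",
    "INTERACTOR_COLUMNS",
    "CROSSLINK_COLUMNS",
    "TRANSITION_COLUMNS",
    "PHOSPHOPEPTIDE_COLUMNS",
    "ANALYTE_KINDS",
    "StructureModel",
    "AnnotationSets",
    "InteractomeThresholds",
    "XlThresholds",
    "DiaThresholds",
    "MotifSpec",
    "IntegrationCriteria",
    "SimConfig",
]


class SchemaError(ValueError):
    """A table header does not match the documented schema."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


#: Canonical column order for quantitative tables. ``intensity`` may be
#: missing (empty cell / NA in TSV, NaN in memory) but never 0.
QUANT_COLUMNS = (
    "analyte_id",
    "analyte_kind",
    "condition",
    "replicate",
    "intensity",
    "mscore",
    "decoy",
)

ANALYTE_KINDS = frozenset({"prey", "phosphopeptide", "protein", "crosslink", "fragment"})

INTERACTOR_COLUMNS = (
    "bait_id",
    "prey_id",
    "method",
    "saint_score",
    "control_frequency",
    "in_gfp_control",
)

CROSSLINK_COLUMNS = (
    "xl_id",
    "pos_a",
    "pos_b",
    "ld_score",
    "peptide_len_a",
    "peptide_len_b",
    "library_rt",
)

TRANSITION_COLUMNS = (
    "xl_id",
    "condition",
    "replicate",
    "channel",
    "transition_index",
    "area",
    "snr",
    "apex_rt",
)

PHOSPHOPEPTIDE_COLUMNS = (
    "peptide_id",
    "protein_id",
    "sequence",
    "site_index",
    "localized",
    "flr",
)


@dataclass(frozen=True)
class StructureModel:
    """Residue-indexed C-alpha coordinates of one chain.

    ``residues`` maps the author residue number (1-based) to a
    ``(residue_name, (x, y, z))`` pair with coordinates in Angstrom.
    ``covered_range`` is the ``(min, max)`` residue index present.
    """

    chain: str
    residues: dict[int, tuple[str, tuple[float, float, float]]]
    covered_range: tuple[int, int]

    def __post_init__(self) -> None:
        for idx, (_, xyz) in self.residues.items():
            if not all(np.isfinite(c) for c in xyz):
                raise ValidationError(f"non-finite coordinate at residue {idx}")

    def ca(self, index: int) -> np.ndarray | None:
        """C-alpha coordinate of ``index`` or None if not covered."""
        entry = self.residues.get(index)
        if entry is None:
            return None
        return np.asarray(entry[1], dtype=float)


@dataclass
class AnnotationSets:
    """User-supplied annotation resources for the integration layer.

    ``ppi_edges`` rows are ``(id_a, id_b, evidence_kind, pubmed_ids)`` with
    endpoints in canonical (sorted) order and duplicates removed;
    ``pubmed_ids`` is a tuple of strings (possibly empty).
    """

    cdp_list: set[str]
    ppi_edges: list[tuple[str, str, str, tuple[str, ...]]]
    term_sets: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        canonical = []
        seen = set()
        for a, b, kind, pmids in self.ppi_edges:
            a, b = sorted((a, b))
            if (a, b) in seen:
                continue
            seen.add((a, b))
            canonical.append((a, b, kind, tuple(pmids)))
        self.ppi_edges = canonical


@dataclass(frozen=True)
class InteractomeThresholds:
    """Filtering and regulation-call thresholds for the interaction layer.

    AP-MS interactors require a SAINT score strictly above ``saint_apms``;
    proximity-labelling (BioID) interactors require equality with
    ``saint_bioid`` (score of exactly 1). Preys seen in more than
    ``control_freq_max`` of contaminant-control runs, or in the GFP
    control pulldowns, are removed. Regulation calls require
    ``|log2FC| > fc_thresh`` and BH-adjusted p <= ``adj_p_thresh``.
    """

    saint_apms: float = 0.95
    saint_bioid: float = 1.0
    control_freq_max: float = 0.15
    fc_thresh: float = 1.0
    adj_p_thresh: float = 0.05

    def __post_init__(self) -> None:
        for name in ("saint_apms", "saint_bioid", "control_freq_max", "adj_p_thresh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.fc_thresh <= 0:
            raise ValidationError("fc_thresh must be > 0")


@dataclass(frozen=True)
class XlThresholds:
    """Thresholds for the cross-linking layer.

    Identifications need a linear-discriminant score strictly above
    ``ld_min`` and both peptide arms at least ``min_pep_len`` residues.
    Transitions below ``snr_min`` signal-to-noise are excluded from
    quantification. Peak acceptance requires the apex within
    ``rt_tolerance_min`` minutes of the library retention time, light/heavy
    co-elution within ``coelution_tol_min`` minutes and a light-vs-heavy
    transition-pattern correlation of at least ``shape_corr_min``.
    ``distance_max_A`` is the lysine-reactive cross-linker's C-alpha
    distance restraint (~30 A for DSS), inclusive.
    """

    ld_min: float = 25.0
    min_pep_len: int = 5
    snr_min: float = 5.0
    rt_tolerance_min: float = 2.0
    coelution_tol_min: float = 0.2
    shape_corr_min: float = 0.8
    distance_max_A: float = 30.0


@dataclass(frozen=True)
class DiaThresholds:
    """Thresholds for the DIA phospho- and total-proteome layer."""

    mscore_max_phospho: float = 0.01
    detection_rate_min: float = 0.30
    mscore_max_proteome: float = 3.9811e-5
    fft: float = 0.46
    frag_corr_min: float = 0.1
    frag_min: int = 3
    frag_max: int = 6
    fc_thresh: float = 1.0
    adj_p_thresh: float = 0.05
    # stricter profile used for heatmap-style inclusion
    strong_p_thresh: float = 0.01
    strong_fc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fft <= 1.0:
            raise ValidationError("fft must be in (0, 1]")
        if self.frag_min > self.frag_max:
            raise ValidationError("frag_min must be <= frag_max")


@dataclass(frozen=True)
class MotifSpec:
    """A kinase substrate consensus of the proline-directed R/K-x-x(-x)-S/T-P form.

    The phosphoacceptor (``site_residues``) must be followed by
    ``plus_one`` at +1 and preceded by an R or K at one of the
    ``basic_offsets`` (negative positions relative to the site).
    """

    basic_offsets: tuple[int, ...] = (-3, -4)
    plus_one: str = "P"
    site_residues: frozenset[str] = frozenset({"S", "T"})


@dataclass(frozen=True)
class IntegrationCriteria:
    """Node-selection and edge-evidence criteria for the driver network.

    Both layer criteria use strict inequalities on the adjusted p-value
    (``adj p < threshold``); ``evidence_required`` controls whether
    reference edges must be experimentally validated with PubMed support.
    """

    phospho_fc: float = 1.0
    phospho_fdr: float = 0.05
    interaction_fc: float = 1.0
    interaction_adj_p: float = 0.05
    evidence_required: str = "experimental_with_pubmed"  # or "any"

    def __post_init__(self) -> None:
        if self.evidence_required not in ("experimental_with_pubmed", "any"):
            raise ValidationError(
                f"unknown evidence_required: {self.evidence_required!r}"
            )


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the mutant-panel design: a wild-type reference plus
    kinase-dead (KR) and cancer-associated point/truncation mutants, three
    biological replicates per condition, log-normal intensity noise of
    0.3 log2 units and logistic intensity-dependent (MNAR) missingness.
    ``planted_effects`` maps an analyte id to a ``(condition, log2fc)``
    ground-truth effect.
    """

    seed: int = 0
    n_preys: int = 200
    n_phosphopeptides: int = 300
    n_proteins: int = 300
    n_crosslinks: int = 14
    conditions: tuple[str, ...] = ("WT", "KR", "RL", "SX", "SL", "SP", "PL")
    reference: str = "WT"
    n_replicates: int = 3
    noise_sd_log2: float = 0.3
    planted_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    missing_midpoint: float = 17.0
    missing_slope: float = 1.2
    motif_fraction_down: float = 0.5
    fraction_decoy: float = 0.1
    cdp_rate: float = 0.1
    contaminant_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_preys", "n_phosphopeptides", "n_proteins", "n_crosslinks"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.reference not in self.conditions:
            raise ValidationError("reference condition must be listed in conditions")
        if self.noise_sd_log2 < 0:
            raise ValidationError("noise_sd_log2 must be >= 0")
        for name in ("motif_fraction_down", "fraction_decoy", "cdp_rate",
                     "contaminant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
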