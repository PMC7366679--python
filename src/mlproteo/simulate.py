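"""Seeded generators for every input table, with planted ground truth.

Each generator emulates one layer of the mutant-panel study design: a
wild-type reference plus six mutant conditions, three biological replicates,
log-normal intensity noise and logistic intensity-dependent (MNAR)
missingness. Planted fold changes, motif-bearing phosphosites and
distance-violating cross-links are recorded in truth tables so every
downstream stage has a parameter-recovery test.

Analyte id schemes are deterministic so planted effects can be addressed in
:attr:`SimConfig.planted_effects`: preys are ``P0001``.., cross-links
``XL01``.., phosphopeptides ``PP0001``.., proteins ``PR0001``..; the bait
analyte is ``BAIT`` and the two non-cross-linked reference peptides are
``REF1``/``REF2``.

Each generator draws from its own RNG stream seeded by the config seed plus
a stage-specific offset, so stages are independently reproducible and
byte-identical under an identical config.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import AnnotationSets, SimConfig, StructureModel

__all__ = [
    "default_study_effects",
    "gen_interactome",
    "gen_structure_and_crosslinks",
    "gen_phospho",
    "gen_proteome",
    "gen_annotations",
]


def default_study_effects() -> dict[str, tuple[str, float]]:
    """Planted effects emulating the mutant panel's observed pattern.

    The truncation (SX) and kinase-dead (KR) mutants carry the strongest
    interactome remodelling, the activation-loop mutant (RL) an
    intermediate one and the remaining point mutants mild effects; the
    kinase-dead mutant loses an N-terminal cross-link contact strongly
    (log2FC -2.8) while the activation-loop mutant shows a mixed pattern;
    phosphosites go down predominantly in the catalytically compromised
    mutants, with an upregulated set in the mild mutants. Magnitudes sit in
    the 1.5-3 log2-unit range typical of the quantified changes.
    """
    effects: dict[str, tuple[str, float]] = {}
    spec = [
        ("SX", 15, 5), ("KR", 9, 1), ("RL", 5, 1),
        ("PL", 1, 1), ("SL", 1, 0), ("SP", 1, 0),
    ]
    i = 0
    for cond, n_down, n_up in spec:
        for _ in range(n_down):
            effects[f"P{i + 1:04d}"] = (cond, -3.0 + (i % 3) * 0.5)
            i += 1
        for _ in range(n_up):
            effects[f"P{i + 1:04d}"] = (cond, 2.0 + (i % 2) * 0.5)
            i += 1
    effects.update({
        "XL01": ("KR", -2.8),
        "XL02": ("RL", 1.6),
        "XL03": ("RL", -1.8),
        "XL05": ("KR", -1.5),
    })
    j = 0
    for cond, n_down, n_up in [("KR", 30, 2), ("SX", 20, 8), ("RL", 8, 4),
                               ("PL", 2, 15), ("SL", 2, 4), ("SP", 2, 4)]:
        for _ in range(n_down):
            effects[f"PP{j + 1:04d}"] = (cond, -2.5 + (j % 4) * 0.3)
            j += 1
        for _ in range(n_up):
            effects[f"PP{j + 1:04d}"] = (cond, 1.8 + (j % 3) * 0.4)
            j += 1
    # total proteome: only a handful of modest changes
    for k, (cond, fc) in enumerate([("RL", -1.2), ("RL", 0.9), ("SL", -0.8),
                                    ("SL", 1.1), ("SX", 1.5)]):
        effects[f"PR{k + 1:04d}"] = (cond, fc)
    return effects

# stage offsets for independent, reproducible RNG streams
_STAGE_INTERACTOME = 101
_STAGE_XLINK = 211
_STAGE_PHOSPHO = 307
_STAGE_PROTEOME = 401
_STAGE_ANNOTATION = 503


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, cfg.seed])


def _runs(cfg: SimConfig):
    for cond in cfg.conditions:
        for rep in range(1, cfg.n_replicates + 1):
            yield cond, rep


def _planted_shift(cfg: SimConfig, analyte: str, condition: str) -> float:
    planted = cfg.planted_effects.get(analyte)
    if planted is not None and planted[0] == condition:
        return planted[1]
    return 0.0


def _missing_prob(log2_intensity: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Logistic MNAR: P(missing) rises as log2 intensity falls."""
    z = cfg.missing_slope * (np.asarray(log2_intensity) - cfg.missing_midpoint)
    return 1.0 / (1.0 + np.exp(z))


def gen_interactome(cfg: SimConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bait-prey MS1 intensity table, SAINT-scored interactor list, truth.

    Prey log2 intensities are ``base + planted effect + run shift +
    Normal(0, noise_sd_log2)``; the run-level shift is itself
    ``Normal(0, noise_sd_log2)`` and also enters the bait intensity, so
    bait normalization cancels it exactly. The bait is present in every
    run and never missing. True interactors carry SAINT scores near 1
    (exactly 1 for proximity-labelling preys) and low contaminant-control
    frequencies; contaminants carry uniform SAINT scores and high control
    frequencies.
    """
    rng = _rng(cfg, _STAGE_INTERACTOME)
    preys = [f"P{i + 1:04d}" for i in range(cfg.n_preys)]
    base = rng.uniform(18.0, 26.0, size=cfg.n_preys)
    # planted analytes emulate core-complex subunits: abundant preys whose
    # binding the mutants gain or lose, so their base sits in the upper range
    hi_base = rng.uniform(21.0, 26.0, size=cfg.n_preys)
    planted_mask = np.array([p in cfg.planted_effects for p in preys])
    base = np.where(planted_mask, hi_base, base)
    is_true = rng.random(cfg.n_preys) >= cfg.contaminant_rate
    methods = np.where(np.arange(cfg.n_preys) % 2 == 0, "APMS", "BioID")

    run_shift = {run: rng.normal(0.0, cfg.noise_sd_log2) for run in _runs(cfg)}

    quant_rows = []
    for cond, rep in _runs(cfg):
        shift = run_shift[(cond, rep)]
        quant_rows.append(("BAIT", "prey", cond, rep, 2.0 ** (27.0 + shift),
                           np.nan, False))
        noise = rng.normal(0.0, cfg.noise_sd_log2, size=cfg.n_preys)
        log2i = np.array([
            base[i] + _planted_shift(cfg, preys[i], cond) + shift + noise[i]
            for i in range(cfg.n_preys)
        ])
        miss = rng.random(cfg.n_preys) < _missing_prob(log2i, cfg)
        for i, prey in enumerate(preys):
            quant_rows.append((
                prey, "prey", cond, rep,
                np.nan if miss[i] else float(2.0 ** log2i[i]),
                np.nan, False,
            ))
    quant = pd.DataFrame(quant_rows, columns=[
        "analyte_id", "analyte_kind", "condition", "replicate", "intensity",
        "mscore", "decoy"])

    saint = np.where(
        is_true,
        np.where(methods == "BioID", 1.0,
                 np.round(rng.uniform(0.96, 1.0, size=cfg.n_preys), 4)),
        np.round(rng.uniform(0.0, 1.0, size=cfg.n_preys), 4),
    )
    control_freq = np.where(
        is_true,
        np.round(rng.uniform(0.0, 0.10, size=cfg.n_preys), 4),
        np.round(rng.uniform(0.20, 0.90, size=cfg.n_preys), 4),
    )
    in_gfp = (~is_true) & (rng.random(cfg.n_preys) < 0.3)
    interactors = pd.DataFrame({
        "bait_id": "BAIT",
        "prey_id": preys,
        "method": methods,
        "saint_score": saint,
        "control_frequency": control_freq,
        "in_gfp_control": in_gfp,
    })

    truth = pd.DataFrame({
        "analyte_id": preys,
        "base_log2": base,
        "is_true_interactor": is_true,
        "method": methods,
        "planted_condition": [
            cfg.planted_effects.get(p, (None, 0.0))[0] for p in preys],
        "planted_log2fc": [
            cfg.planted_effects.get(p, (None, 0.0))[1] for p in preys],
    })
    return quant, interactors, truth


def gen_structure_and_crosslinks(
        cfg: SimConfig,
        ) -> tuple[StructureModel, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Toy C-alpha structure, cross-link identifications, PRM transition
    areas, reference-peptide intensities and truth tables.

    The structure is a straight C-alpha trace (3.8 A per residue, chain A,
    residues 10..130) so pairwise distances are controlled exactly by the
    residue separation. Cross-link lysine pairs are placed so that a
    declared subset satisfies the ~30 A restraint, a declared subset
    violates it, and the rest involve residues outside the covered range
    (unmappable). Three decoy-grade identifications (low ld score or a
    short peptide arm) are appended for filter testing.

    Transition areas carry planted per-condition fold changes; both isotope
    channels share the fold change and a run-level scale that the two
    reference peptides also carry, so reference normalization cancels it.
    Four randomly chosen transition slots are assigned signal-to-noise
    below 5 and recorded in the truth.

    Returns ``(structure, crosslinks, transitions, references, truth)``
    where truth is a dict with keys ``crosslinks`` and ``low_snr``.
    """
    rng = _rng(cfg, _STAGE_XLINK)
    lo, hi, spacing = 10, 130, 3.8
    residues = {
        i: ("LYS" if i % 10 == 0 else "ALA",
            (spacing * i, 0.0, 0.0))
        for i in range(lo, hi + 1)
    }
    structure = StructureModel(chain="A", residues=residues,
                               covered_range=(lo, hi))

    # residue-separation recipes per planted status
    n = cfg.n_crosslinks
    n_sat = max(1, round(n * 4 / 14))
    n_vio = max(1, round(n * 2 / 14))
    statuses = (["satisfied"] * n_sat + ["violated"] * n_vio
                + ["unmappable"] * (n - n_sat - n_vio))
    xl_rows, truth_rows = [], []
    anchor = 20
    for k, status in enumerate(statuses):
        xl_id = f"XL{k + 1:02d}"
        if status == "satisfied":
            pos_a = anchor + 3 * k
            pos_b = pos_a + int(rng.integers(2, 8))  # <= 7 residues: <= 26.6 A
        elif status == "violated":
            pos_a = anchor + 3 * k
            pos_b = pos_a + int(rng.integers(9, 25))  # >= 34.2 A
        else:
            pos_a = int(rng.integers(1, lo))  # N-terminal, outside coverage
            pos_b = anchor + 3 * k
        ld = float(np.round(rng.uniform(26.0, 45.0), 2))
        xl_rows.append((xl_id, pos_a, pos_b, ld,
                        int(rng.integers(5, 15)), int(rng.integers(5, 15)),
                        float(np.round(rng.uniform(20.0, 60.0), 2))))
        truth_rows.append((xl_id, status, True,
                           cfg.planted_effects.get(xl_id, (None, 0.0))[0],
                           cfg.planted_effects.get(xl_id, (None, 0.0))[1]))
    # identifications that must fail the ld / peptide-length filter
    for xl_id, ld, len_a in (("XLBAD1", 18.5, 9), ("XLBAD2", 24.9, 7),
                             ("XLBAD3", 38.0, 4)):
        xl_rows.append((xl_id, anchor, anchor + 4, ld, len_a, 9,
                        float(np.round(rng.uniform(20.0, 60.0), 2))))
        truth_rows.append((xl_id, "filtered", False, None, 0.0))
    xls = pd.DataFrame(xl_rows, columns=[
        "xl_id", "pos_a", "pos_b", "ld_score", "peptide_len_a",
        "peptide_len_b", "library_rt"])
    truth_xl = pd.DataFrame(truth_rows, columns=[
        "xl_id", "restraint_status", "passes_id_filter", "planted_condition",
        "planted_log2fc"])

    run_shift = {run: rng.normal(0.0, cfg.noise_sd_log2) for run in _runs(cfg)}
    accepted = xls[xls["xl_id"].str.startswith("XL") &
                   ~xls["xl_id"].str.startswith("XLBAD")]
    lib_rt = dict(zip(accepted["xl_id"], accepted["library_rt"]))
    base_total = {xl: 2.0 ** rng.uniform(14.0, 18.0) for xl in lib_rt}
    weights = {xl: rng.dirichlet(np.full(6, 8.0)) for xl in lib_rt}
    heavy_ratio = {xl: rng.uniform(0.8, 1.2) for xl in lib_rt}

    rows = []
    for xl in lib_rt:
        for cond, rep in _runs(cfg):
            shift = run_shift[(cond, rep)]
            fc = _planted_shift(cfg, xl, cond)
            noise = rng.normal(0.0, cfg.noise_sd_log2)
            total = base_total[xl] * 2.0 ** (fc + shift + noise)
            apex = lib_rt[xl] + rng.normal(0.0, 0.02)
            for channel in ("light", "heavy"):
                scale = 1.0 if channel == "light" else heavy_ratio[xl]
                for t_idx in range(1, 7):
                    area = total * scale * weights[xl][t_idx - 1]
                    rows.append((xl, cond, rep, channel, t_idx, area,
                                 float(np.round(rng.uniform(8.0, 40.0), 2)),
                                 apex))
    transitions = pd.DataFrame(rows, columns=[
        "xl_id", "condition", "replicate", "channel", "transition_index",
        "area", "snr", "apex_rt"])

    # declare 4 low-SNR transition traces (a weak fragment ion is weak in
    # every run), excluded from quantification everywhere
    traces = transitions[["xl_id", "channel", "transition_index"]].drop_duplicates()
    n_low = min(4, len(traces))
    low_traces = traces.iloc[rng.choice(len(traces), size=n_low,
                                        replace=False)].copy()
    low_traces["low_snr"] = np.round(rng.uniform(1.0, 4.5, size=n_low), 2)
    transitions = transitions.merge(low_traces, how="left",
                                    on=["xl_id", "channel",
                                        "transition_index"])
    hit = transitions["low_snr"].notna()
    transitions.loc[hit, "snr"] = transitions.loc[hit, "low_snr"]
    transitions = transitions.drop(columns="low_snr")
    truth_low = low_traces.rename(columns={"low_snr": "snr"}).reset_index(
        drop=True)

    ref_rows = []
    for cond, rep in _runs(cfg):
        shift = run_shift[(cond, rep)]
        for ref, base in (("REF1", 20.0), ("REF2", 21.0)):
            ref_rows.append((ref, cond, rep, 2.0 ** (base + shift)))
    references = pd.DataFrame(ref_rows, columns=[
        "peptide_id", "condition", "replicate", "intensity"])

    truth = {"crosslinks": truth_xl, "low_snr": truth_low}
    return structure, xls, transitions, references, truth


_FLANK_ALPHABET = np.array(list("AGLVED"))  # no R/K/P: cannot form the motif


def _make_sequence(rng: np.random.Generator, with_motif: bool,
                   site_residue: str) -> tuple[str, int]:
    """11-mer with the phosphosite at position 6; optionally motif-bearing."""
    seq = list(rng.choice(_FLANK_ALPHABET, size=11))
    site = 6
    seq[site - 1] = site_residue
    if with_motif:
        offset = int(rng.choice([-3, -4]))
        seq[site - 1 + offset] = str(rng.choice(["R", "K"]))
        seq[site] = "P"
    return "".join(seq), site


def gen_phospho(cfg: SimConfig, sequences: dict[str, str] | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Phosphopeptide quant table, peptide annotations and truth.

    A fraction ``motif_fraction_down`` of peptides with planted negative
    fold changes carry the kinase consensus motif around their site; all
    other peptides are built from a motif-free flank alphabet. Decoy
    analytes are flagged at ``fraction_decoy`` and a tenth of target
    features receive large (noise) m-scores for filter testing. If
    ``sequences`` is given, peptide protein ids are drawn from its keys.
    """
    rng = _rng(cfg, _STAGE_PHOSPHO)
    n = cfg.n_phosphopeptides
    peptides = [f"PP{i + 1:04d}" for i in range(n)]
    protein_ids = (sorted(sequences) if sequences
                   else [f"PR{i + 1:04d}" for i in range(cfg.n_proteins)])
    proteins = [protein_ids[i % len(protein_ids)] for i in range(n)]
    base = rng.uniform(16.0, 24.0, size=n)
    # planted substrate peptides are drawn from the well-quantified range
    hi_base = rng.uniform(20.0, 24.0, size=n)
    planted_mask = np.array([p in cfg.planted_effects for p in peptides])
    base = np.where(planted_mask, hi_base, base)
    is_decoy = rng.random(n) < cfg.fraction_decoy
    is_noise_feature = (~is_decoy) & (rng.random(n) < 0.1)

    pep_rows, truth_rows = [], []
    for i, pid in enumerate(peptides):
        cond, fc = cfg.planted_effects.get(pid, (None, 0.0))
        planted_down = cond is not None and fc < 0
        with_motif = planted_down and (rng.random() < cfg.motif_fraction_down)
        site_residue = str(rng.choice(["S", "T"]))
        seq, site = _make_sequence(rng, with_motif, site_residue)
        flr = float(np.round(rng.uniform(0.0, 0.009), 4))
        pep_rows.append((pid, proteins[i], seq, site, True, flr))
        truth_rows.append((pid, proteins[i], cond, fc, with_motif,
                           bool(is_decoy[i]), bool(is_noise_feature[i])))
    pep_table = pd.DataFrame(pep_rows, columns=[
        "peptide_id", "protein_id", "sequence", "site_index", "localized",
        "flr"])
    truth = pd.DataFrame(truth_rows, columns=[
        "analyte_id", "protein_id", "planted_condition", "planted_log2fc",
        "has_motif", "is_decoy", "is_noise_feature"])

    quant_rows = []
    mscores = np.where(is_noise_feature,
                       rng.uniform(0.02, 0.10, size=n),
                       rng.uniform(1e-4, 5e-3, size=n))
    for cond, rep in _runs(cfg):
        noise = rng.normal(0.0, cfg.noise_sd_log2, size=n)
        log2i = np.array([
            base[i] + _planted_shift(cfg, peptides[i], cond) + noise[i]
            for i in range(n)
        ])
        miss = rng.random(n) < _missing_prob(log2i, cfg)
        for i, pid in enumerate(peptides):
            quant_rows.append((
                pid, "phosphopeptide", cond, rep,
                np.nan if miss[i] else float(2.0 ** log2i[i]),
                float(mscores[i]), bool(is_decoy[i]),
            ))
    quant = pd.DataFrame(quant_rows, columns=[
        "analyte_id", "analyte_kind", "condition", "replicate", "intensity",
        "mscore", "decoy"])
    return quant, pep_table, truth


def gen_proteome(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total-proteome quant table (mostly null effects) and truth.

    Planted effects address protein analytes (``PR0001``..); the layer is
    generated independently of the phospho layer so that, absent planted
    coupling, phospho and protein fold changes are uncorrelated.
    """
    rng = _rng(cfg, _STAGE_PROTEOME)
    n = cfg.n_proteins
    proteins = [f"PR{i + 1:04d}" for i in range(n)]
    base = rng.uniform(17.0, 25.0, size=n)
    hi_base = rng.uniform(20.0, 25.0, size=n)
    planted_mask = np.array([p in cfg.planted_effects for p in proteins])
    base = np.where(planted_mask, hi_base, base)
    is_decoy = rng.random(n) < cfg.fraction_decoy
    quant_rows = []
    mscores = rng.uniform(1e-6, 3e-5, size=n)
    for cond, rep in _runs(cfg):
        noise = rng.normal(0.0, cfg.noise_sd_log2, size=n)
        log2i = np.array([
            base[i] + _planted_shift(cfg, proteins[i], cond) + noise[i]
            for i in range(n)
        ])
        miss = rng.random(n) < _missing_prob(log2i, cfg)
        for i, pid in enumerate(proteins):
            quant_rows.append((
                pid, "protein", cond, rep,
                np.nan if miss[i] else float(2.0 ** log2i[i]),
                float(mscores[i]), bool(is_decoy[i]),
            ))
    quant = pd.DataFrame(quant_rows, columns=[
        "analyte_id", "analyte_kind", "condition", "replicate", "intensity",
        "mscore", "decoy"])
    truth = pd.DataFrame({
        "analyte_id": proteins,
        "planted_condition": [
            cfg.planted_effects.get(p, (None, 0.0))[0] for p in proteins],
        "planted_log2fc": [
            cfg.planted_effects.get(p, (None, 0.0))[1] for p in proteins],
        "is_decoy": is_decoy,
    })
    return quant, truth


def gen_annotations(cfg: SimConfig, protein_ids: list[str] | None = None,
                    n_terms: int = 5) -> tuple[AnnotationSets, pd.DataFrame]:
    """Annotation resources: CDP list, evidence-flagged reference edges and
    term sets over the generated proteins.

    A fraction ``cdp_rate`` of proteins (rounded) is designated cancer
    drivers. Reference edges are random pairs; 70% are experimentally
    validated with PubMed ids and the rest are predicted without PubMed
    support (so the evidence filter always has something to reject).
    Returns the sets plus an edge truth table.
    """
    rng = _rng(cfg, _STAGE_ANNOTATION)
    proteins = (list(protein_ids) if protein_ids is not None
                else [f"PR{i + 1:04d}" for i in range(cfg.n_proteins)])
    n = len(proteins)
    n_cdp = round(cfg.cdp_rate * n)
    cdps = ({str(p) for p in rng.choice(proteins, size=n_cdp, replace=False)}
            if n_cdp else set())

    n_edges = max(2 * n, 4)
    edges, edge_rows = [], []
    seen = set()
    while len(edges) < n_edges:
        a, b = (str(x) for x in rng.choice(proteins, size=2, replace=False))
        a, b = sorted((a, b))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        experimental = rng.random() < 0.7
        if experimental:
            pmids = tuple(str(int(rng.integers(10_000_000, 35_000_000)))
                          for _ in range(int(rng.integers(1, 3))))
            kind = "experimental"
        else:
            pmids, kind = (), "predicted"
        edges.append((a, b, kind, pmids))
        edge_rows.append((a, b, kind, len(pmids) > 0))
    # guarantee at least one non-experimental edge
    if all(kind == "experimental" for _, _, kind, _ in edges):
        a, b, _, _ = edges[0]
        edges[0] = (a, b, "predicted", ())
        edge_rows[0] = (a, b, "predicted", False)

    term_sets = {}
    for t in range(n_terms):
        size = int(rng.integers(max(3, n // 20), max(4, n // 5)))
        term_sets[f"TERM{t + 1:02d}"] = {
            str(p) for p in rng.choice(proteins, size=min(size, n),
                                       replace=False)}

    ann = AnnotationSets(cdp_list=cdps, ppi_edges=edges, term_sets=term_sets,
                         background=set(proteins))
    edge_truth = pd.DataFrame(edge_rows, columns=[
        "id_a", "id_b", "evidence_kind", "has_pubmed"])
    return ann, edge_truth
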