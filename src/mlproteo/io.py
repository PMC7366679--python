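"""Readers and writers for the long-format tables, PDB structures and FASTA.

All tables are UTF-8, tab-separated, long format, with the canonical column
orders defined in :mod:`mlproteo.datamodel`. Missing intensities are encoded
as an empty cell or ``NA`` — never 0, so that downstream missing-not-at-random
imputation can distinguish absence from small values.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .datamodel import (
    ANALYTE_KINDS,
    CROSSLINK_COLUMNS,
    INTERACTOR_COLUMNS,
    PHOSPHOPEPTIDE_COLUMNS,
    QUANT_COLUMNS,
    TRANSITION_COLUMNS,
    AnnotationSets,
    SchemaError,
    StructureModel,
    ValidationError,
)

logger = logging.getLogger("mlproteo.io")

_NA_VALUES = ["", "NA"]


def _read_tsv(path, columns) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES,
                     keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: header lacks required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def _to_float(df: pd.DataFrame, col: str, path, allow_missing: bool) -> pd.Series:
    try:
        out = pd.to_numeric(df[col], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{Path(path).name}: column {col!r}: {exc}") from exc
    if not allow_missing and out.isna().any():
        row = int(out.index[out.isna()][0]) + 2  # 1-based + header line
        raise ValidationError(f"{Path(path).name}: missing {col!r} at line {row}")
    return out.astype(float)


def read_quant_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a long-format quantitative table.

    Parameters
    ----------
    path:
        TSV file with the canonical quant columns.
    schema:
        Optional expected ``analyte_kind``; rows of another kind raise.

    Returns a DataFrame with missing intensities as NaN. Zero or negative
    intensities are rejected with the offending line number.
    """
    df = _read_tsv(path, QUANT_COLUMNS)
    out = pd.DataFrame({
        "analyte_id": df["analyte_id"].astype(str),
        "analyte_kind": df["analyte_kind"].astype(str),
        "condition": df["condition"].astype(str),
        "replicate": _to_float(df, "replicate", path, allow_missing=False).astype(int),
        "intensity": _to_float(df, "intensity", path, allow_missing=True),
        "mscore": _to_float(df, "mscore", path, allow_missing=True),
        "decoy": df["decoy"].map(
            {"True": True, "False": False, "true": True, "false": False}
        ),
    })
    bad_kind = ~out["analyte_kind"].isin(ANALYTE_KINDS)
    if bad_kind.any():
        row = int(out.index[bad_kind][0]) + 2
        raise ValidationError(
            f"{Path(path).name}: unknown analyte_kind at line {row}"
        )
    if schema is not None and not (out["analyte_kind"] == schema).all():
        off = out.index[out["analyte_kind"] != schema][0] + 2
        raise ValidationError(
            f"{Path(path).name}: expected analyte_kind {schema!r}, "
            f"other kind at line {off}"
        )
    nonpos = out["intensity"] <= 0
    if nonpos.any():
        row = int(out.index[nonpos][0]) + 2
        raise ValidationError(
            f"{Path(path).name}: non-positive intensity at line {row} "
            "(missing values must be empty or NA, never 0)"
        )
    if (out["replicate"] < 1).any():
        raise ValidationError(f"{Path(path).name}: replicate indices must be >= 1")
    dup = out.duplicated(subset=["analyte_id", "condition", "replicate"])
    if dup.any():
        row = int(out.index[dup][0]) + 2
        raise ValidationError(
            f"{Path(path).name}: duplicate (analyte_id, condition, replicate) "
            f"at line {row}"
        )
    logger.info("read_quant_table: %d records from %s", len(out), path)
    return out


def write_quant_table(df: pd.DataFrame, path) -> None:
    """Write a quant table in canonical column order (missing -> empty cell)."""
    out = df.loc[:, list(QUANT_COLUMNS)].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_interactor_table(path) -> pd.DataFrame:
    df = _read_tsv(path, INTERACTOR_COLUMNS)
    out = pd.DataFrame({
        "bait_id": df["bait_id"].astype(str),
        "prey_id": df["prey_id"].astype(str),
        "method": df["method"].astype(str),
        "saint_score": _to_float(df, "saint_score", path, allow_missing=False),
        "control_frequency": _to_float(df, "control_frequency", path,
                                       allow_missing=False),
        "in_gfp_control": df["in_gfp_control"].map(
            {"True": True, "False": False, "true": True, "false": False}
        ).astype(bool),
    })
    for col in ("saint_score", "control_frequency"):
        bad = (out[col] < 0) | (out[col] > 1)
        if bad.any():
            row = int(out.index[bad][0]) + 2
            raise ValidationError(f"{Path(path).name}: {col} out of [0,1] at line {row}")
    return out


def read_crosslink_table(path) -> pd.DataFrame:
    df = _read_tsv(path, CROSSLINK_COLUMNS)
    out = pd.DataFrame({
        "xl_id": df["xl_id"].astype(str),
        "pos_a": _to_float(df, "pos_a", path, False).astype(int),
        "pos_b": _to_float(df, "pos_b", path, False).astype(int),
        "ld_score": _to_float(df, "ld_score", path, False),
        "peptide_len_a": _to_float(df, "peptide_len_a", path, False).astype(int),
        "peptide_len_b": _to_float(df, "peptide_len_b", path, False).astype(int),
        "library_rt": _to_float(df, "library_rt", path, False),
    })
    # canonical residue ordering: pos_a <= pos_b
    swap = out["pos_a"] > out["pos_b"]
    out.loc[swap, ["pos_a", "pos_b"]] = out.loc[swap, ["pos_b", "pos_a"]].values
    if (out[["peptide_len_a", "peptide_len_b"]] < 1).any().any():
        raise ValidationError(f"{Path(path).name}: peptide lengths must be >= 1")
    return out


def read_transition_table(path) -> pd.DataFrame:
    df = _read_tsv(path, TRANSITION_COLUMNS)
    out = pd.DataFrame({
        "xl_id": df["xl_id"].astype(str),
        "condition": df["condition"].astype(str),
        "replicate": _to_float(df, "replicate", path, False).astype(int),
        "channel": df["channel"].astype(str),
        "transition_index": _to_float(df, "transition_index", path, False).astype(int),
        "area": _to_float(df, "area", path, True),
        "snr": _to_float(df, "snr", path, False),
        "apex_rt": _to_float(df, "apex_rt", path, False),
    })
    if not out["channel"].isin(["light", "heavy"]).all():
        raise ValidationError(f"{Path(path).name}: channel must be light or heavy")
    counts = out.groupby(["xl_id", "condition", "replicate", "channel"]).size()
    if (counts > 6).any():
        raise ValidationError(
            f"{Path(path).name}: more than 6 transitions for one channel/run"
        )
    return out


def read_phosphopeptide_table(path) -> pd.DataFrame:
    df = _read_tsv(path, PHOSPHOPEPTIDE_COLUMNS)
    out = pd.DataFrame({
        "peptide_id": df["peptide_id"].astype(str),
        "protein_id": df["protein_id"].astype(str),
        "sequence": df["sequence"].astype(str).str.upper(),
        "site_index": _to_float(df, "site_index", path, False).astype(int),
        "localized": df["localized"].map(
            {"True": True, "False": False, "true": True, "false": False}
        ).astype(bool),
        "flr": _to_float(df, "flr", path, True),
    })
    for i, row in out.iterrows():
        seq, si = row["sequence"], row["site_index"]
        if not 1 <= si <= len(seq) or seq[si - 1] not in "STY":
            raise ValidationError(
                f"{Path(path).name}: line {i + 2}: site_index {si} does not point "
                f"to S/T/Y in sequence"
            )
    return out


def read_annotation_sets(cdp_path, ppi_path, term_path, background_path) -> AnnotationSets:
    """Assemble annotation resources from four plain-text tables.

    ``cdp_path`` and ``background_path`` hold one protein id per line;
    ``ppi_path`` is a TSV with columns ``id_a, id_b, evidence_kind,
    pubmed_ids`` (semicolon-separated ids, possibly empty); ``term_path``
    is a TSV with columns ``term_id, protein_id``.
    """
    cdp = {l.strip() for l in Path(cdp_path).read_text().splitlines() if l.strip()}
    background = {
        l.strip() for l in Path(background_path).read_text().splitlines() if l.strip()
    }
    ppi = pd.read_csv(ppi_path, sep="\t", dtype=str, na_values=_NA_VALUES,
                      keep_default_na=False)
    for col in ("id_a", "id_b", "evidence_kind", "pubmed_ids"):
        if col not in ppi.columns:
            raise SchemaError(f"PPI table lacks column {col!r}")
    edges = []
    for _, row in ppi.iterrows():
        pmids = tuple(
            p for p in str(row["pubmed_ids"] or "").split(";") if p and p != "nan"
        )
        edges.append((row["id_a"], row["id_b"], row["evidence_kind"], pmids))
    terms_df = pd.read_csv(term_path, sep="\t", dtype=str)
    if not {"term_id", "protein_id"}.issubset(terms_df.columns):
        raise SchemaError("term table requires columns term_id, protein_id")
    term_sets = {
        t: set(g["protein_id"]) for t, g in terms_df.groupby("term_id")
    }
    return AnnotationSets(cdp_list=cdp, ppi_edges=edges, term_sets=term_sets,
                          background=background)


def read_structure(path, chain: str, parser: PDBParser | None = None) -> StructureModel:
    """Parse one chain of a PDB file into a residue -> C-alpha coordinate map.

    Residue indices follow the author (PDB residue sequence) numbering.
    Alternate locations resolve to the highest-occupancy conformer (ties:
    first in file, the Bio.PDB default). Residues lacking a C-alpha are
    skipped with a logged warning.
    """
    parser = parser or PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("model", str(path))
    model = next(structure.get_models())
    available = [c.id for c in model.get_chains()]
    if chain not in available:
        raise ValidationError(
            f"chain {chain!r} not present; available chains: {sorted(available)}"
        )
    residues: dict[int, tuple[str, tuple[float, float, float]]] = {}
    for res in model[chain].get_residues():
        hetflag, resseq, _icode = res.get_id()
        if hetflag.strip():
            continue
        if "CA" not in res:
            logger.warning("residue %s %d lacks a C-alpha; skipped",
                           res.get_resname(), resseq)
            continue
        atom = res["CA"]
        if atom.is_disordered():
            atom = atom.selected_child  # highest occupancy, first on ties
        x, y, z = (float(v) for v in atom.get_coord())
        residues[int(resseq)] = (res.get_resname(), (x, y, z))
    if not residues:
        raise ValidationError(f"chain {chain!r} contains no C-alpha atoms")
    idx = sorted(residues)
    return StructureModel(chain=chain, residues=residues,
                          covered_range=(idx[0], idx[-1]))


def write_structure(model: StructureModel, path) -> None:
    """Write a minimal single-chain PDB (C-alpha trace) for a StructureModel."""
    lines = []
    serial = 1
    for idx in sorted(model.residues):
        name, (x, y, z) = model.residues[idx]
        lines.append(
            f"ATOM  {serial:>5}  CA  {name:<3} {model.chain}{idx:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping.

    Duplicate identifiers are an error.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValidationError(f"duplicate FASTA id: {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences
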