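"""Cross-layer integration into a regulated cancer-driver network.

Cancer driver proteins (CDPs, Cancer Gene Census annotations supplied as a
plain id list) regulated at the interaction and/or phosphorylation layer are
selected, reference protein-protein interaction edges among them are mapped
subject to evidence filters (experimentally validated with PubMed support),
interactome overlap/novelty against the reference database is computed, and
user-supplied term sets are tested for over-representation with either a
standard two-sided Fisher test or the conservative EASE variant (one hit
removed from the overlap, upper tail only).
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import AnnotationSets, IntegrationCriteria, ValidationError
from .stats import bh_adjust, fisher_two_sided

logger = logging.getLogger("mlproteo.network")

__all__ = [
    "select_regulated_cdps",
    "build_network",
    "dual_regulation_table",
    "reference_overlap",
    "ease_ora",
]


def _layer_calls(results: pd.DataFrame, id_col: str, fc: float, adj_p: float,
                 ) -> pd.DataFrame:
    """Regulation calls recomputed under the integration criteria (strict
    ``adj p <`` inequality) from a differential-results table."""
    sub = results[(results["adj_pvalue"] < adj_p)
                  & (results["log2fc"].abs() > fc)].copy()
    sub["direction"] = np.where(sub["log2fc"] > 0, "up", "down")
    return sub[[id_col, "condition", "direction"]]


def select_regulated_cdps(phospho_results: pd.DataFrame,
                          interaction_results: pd.DataFrame,
                          ann: AnnotationSets,
                          criteria: IntegrationCriteria | None = None,
                          ) -> pd.DataFrame:
    """Select cancer driver proteins regulated in at least one layer.

    Both inputs are differential-results tables carrying a ``protein_id``
    column (for the phospho layer the peptide-to-protein mapping must be
    applied upstream; for the interaction layer the prey id is the protein
    id). A protein is selected iff it is in the CDP list and regulated —
    under the integration criteria — at the phospho and/or interaction
    layer in at least one mutant condition. The returned long table has one
    row per (protein, layer, condition, direction) flag.
    """
    c = criteria or IntegrationCriteria()
    flags = []
    ph = _layer_calls(phospho_results, "protein_id", c.phospho_fc, c.phospho_fdr)
    for row in ph.itertuples():
        flags.append((row.protein_id, "phospho", row.condition, row.direction))
    ia = _layer_calls(interaction_results, "protein_id",
                      c.interaction_fc, c.interaction_adj_p)
    for row in ia.itertuples():
        flags.append((row.protein_id, "interaction", row.condition, row.direction))
    table = pd.DataFrame(flags, columns=["protein_id", "layer", "condition",
                                         "direction"])
    table = table[table["protein_id"].isin(ann.cdp_list)]
    return table.sort_values(["protein_id", "layer", "condition"]).reset_index(
        drop=True)


def _edge_passes(kind: str, pmids: tuple[str, ...], requirement: str) -> bool:
    if requirement == "any":
        return True
    return kind == "experimental" and len(pmids) > 0


def build_network(node_flags: pd.DataFrame, ann: AnnotationSets,
                  criteria: IntegrationCriteria | None = None) -> nx.Graph:
    """Build the regulated-CDP graph from selected nodes and reference edges.

    Edges are reference interactions with both endpoints selected and
    evidence passing the criteria; symmetric duplicates are collapsed.
    Selected proteins without any qualifying edge stay in the graph as
    isolated nodes (flagged ``isolated=True``). Per-node regulation flags
    are attached as node attributes, so the graph is reproducible from the
    two differential inputs alone.
    """
    c = criteria or IntegrationCriteria()
    nodes = sorted(set(node_flags["protein_id"]))
    g = nx.Graph()
    for node in nodes:
        sub = node_flags[node_flags["protein_id"] == node]
        g.add_node(node, flags=[
            (r.layer, r.condition, r.direction) for r in sub.itertuples()
        ])
    node_set = set(nodes)
    for a, b, kind, pmids in ann.ppi_edges:
        if a in node_set and b in node_set and a != b:
            if _edge_passes(kind, pmids, c.evidence_required):
                g.add_edge(a, b, evidence_kind=kind, pubmed_ids=pmids)
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree[node] == 0
    return g


def dual_regulation_table(node_flags: pd.DataFrame,
                          conditions: list[str] | None = None) -> pd.DataFrame:
    """Per-node, per-mutant table pairing the interaction and phospho calls
    (the two color codes of a dual-annotation network rendering).

    One row per (protein, condition) with ``interaction_regulation`` and
    ``phospho_regulation`` in {up, down, none}.
    """
    if node_flags.empty:
        return pd.DataFrame(columns=["protein_id", "condition",
                                     "interaction_regulation",
                                     "phospho_regulation"])
    conds = conditions or sorted(set(node_flags["condition"]))
    lookup = {
        (r.protein_id, r.condition, r.layer): r.direction
        for r in node_flags.itertuples()
    }
    rows = []
    for node in sorted(set(node_flags["protein_id"])):
        for cond in conds:
            rows.append((
                node, cond,
                lookup.get((node, cond, "interaction"), "none"),
                lookup.get((node, cond, "phospho"), "none"),
            ))
    return pd.DataFrame(rows, columns=["protein_id", "condition",
                                       "interaction_regulation",
                                       "phospho_regulation"])


def reference_overlap(detected: dict[str, set[str]],
                      reference_edges: list[tuple]) -> dict:
    """Overlap of detected interactor sets with a reference interactome.

    For each bait: recall = fraction of its detected interactors already
    reported as reference neighbors of that bait; novel fraction = 1 -
    recall. Also reports the number of preys shared by every bait set and
    the mean pairwise overlap (Jaccard-style intersection over the smaller
    set) between baits.
    """
    neighbors: dict[str, set[str]] = {}
    for a, b, *_ in reference_edges:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    per_bait = {}
    for bait, preys in detected.items():
        if not preys:
            raise ValidationError(f"empty detected set for bait {bait!r}")
        known = preys & neighbors.get(bait, set())
        recall = len(known) / len(preys)
        per_bait[bait] = {"recall": recall, "novel_fraction": 1.0 - recall,
                          "n_detected": len(preys), "n_known": len(known)}
    shared_all = set.intersection(*detected.values()) if detected else set()
    pair_overlaps = []
    for a, b in itertools.combinations(sorted(detected), 2):
        smaller = min(len(detected[a]), len(detected[b]))
        pair_overlaps.append(len(detected[a] & detected[b]) / smaller)
    return {
        "per_bait": per_bait,
        "mean_recall": float(np.mean([v["recall"] for v in per_bait.values()])),
        "mean_novel_fraction": float(np.mean(
            [v["novel_fraction"] for v in per_bait.values()])),
        "shared_by_all": len(shared_all),
        "shared_by_all_ids": sorted(shared_all),
        "mean_pairwise_overlap": (float(np.mean(pair_overlaps))
                                  if pair_overlaps else float("nan")),
    }


def ease_ora(hit_set: set[str], term_sets: dict[str, set[str]],
             background: set[str], variant: str = "ease") -> pd.DataFrame:
    """Over-representation analysis of term sets with BH across terms.

    ``variant='fisher'`` uses the standard two-sided Fisher exact test on
    the (in-term vs not) x (hit vs background-only) table. ``variant='ease'``
    is the conservative modified Fisher test of the DAVID tool: the
    in-term hit count is reduced by one (floored at 0) and an upper-tail
    (over-representation only) hypergeometric p is computed, which is never
    smaller than the plain one-sided p.
    """
    if not hit_set:
        raise ValidationError("hit set is empty")
    if not hit_set <= background:
        raise ValidationError("hit set must be a subset of the background")
    if variant not in ("fisher", "ease"):
        raise ValidationError(f"unknown variant {variant!r}")
    n_bg = len(background)
    n_hit = len(hit_set)
    rows = []
    for term, members in sorted(term_sets.items()):
        members = members & background
        k = len(hit_set & members)
        m = len(members)
        if variant == "fisher":
            table = [[k, n_hit - k], [m - k, n_bg - n_hit - (m - k)]]
            p = fisher_two_sided(table)
        else:
            k_ease = max(k - 1, 0)
            # P(X >= k_ease) for X ~ Hypergeom(N=n_bg, K=m, n=n_hit)
            p = float(sps.hypergeom.sf(k_ease - 1, n_bg, m, n_hit))
        rows.append((term, k, m, p))
    out = pd.DataFrame(rows, columns=["term_id", "n_hits_in_term",
                                      "term_size", "pvalue"])
    out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
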