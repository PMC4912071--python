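"""Pathway-to-pathway and molecular similarity network constructions.

Two graph projections of the metabolic response:

* **Pathway overlap** — pathways are linked by the number of metabolites
  they share, normalised by the smaller of the two pathway metabolite
  sets; pathways whose best overlap falls below the threshold are attached
  to a designated ``Self`` sink node so the rendering keeps every pathway.
* **Molecular similarity** — metabolites are linked to their single
  closest structural match by Levenshtein edit distance between raw SMILES
  strings, normalised by the longer string; molecules without a
  sufficiently close partner (or without a SMILES) attach to ``Self``.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import edlib
import networkx as nx

from .enrichment import EnrichmentResult
from .reporter import ReporterScore
from .tabio import MetabolicModel

__all__ = [
    "SELF_NODE",
    "pathway_network",
    "smiles_similarity",
    "molecular_network",
]

#: Sink node collecting elements with no retained partner.
SELF_NODE = "Self"

DEFAULT_PATHWAY_THRESHOLD = 0.3
DEFAULT_SIM_THRESHOLD = 0.4


def pathway_network(
    model: MetabolicModel,
    results: Mapping[str, EnrichmentResult] | None = None,
    threshold: float = DEFAULT_PATHWAY_THRESHOLD,
) -> nx.Graph:
    """Pathway graph weighted by shared-metabolite overlap.

    Edge weight between pathways a and b is ``|Ma ∩ Mb| / min(|Ma|, |Mb|)``
    over compartment-stripped metabolite ids; edges below ``threshold``
    are dropped and pathways left without any edge are attached to the
    ``Self`` node.  Enrichment score/direction, when provided, are stored
    as node attributes for rendering.
    """
    met_sets: dict[str, frozenset[str]] = {}
    for pid in model.pathways:
        mets = frozenset(
            model.metabolite_base_id(m) for m in model.pathway_metabolites(pid)
        )
        if not mets:
            warnings.warn(
                f"pathway {pid!r} has no metabolites; excluded", stacklevel=2
            )
            continue
        met_sets[pid] = mets

    graph = nx.Graph()
    for pid in met_sets:
        attrs = {"kind": "pathway", "name": model.pathways[pid][0]}
        res = (results or {}).get(pid)
        if res is not None:
            attrs.update(
                score=res.score if not math.isnan(res.score) else 0.0,
                n_up=res.n_up,
                n_down=res.n_down,
                dominant_fraction=(
                    res.dominant_fraction
                    if not math.isnan(res.dominant_fraction)
                    else 0.0
                ),
            )
        graph.add_node(pid, **attrs)

    ids = sorted(met_sets)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            shared = len(met_sets[a] & met_sets[b])
            norm = shared / min(len(met_sets[a]), len(met_sets[b]))
            if norm >= threshold and shared > 0:
                graph.add_edge(a, b, weight=norm, shared=shared)

    orphans = [pid for pid in ids if graph.degree(pid) == 0]
    if orphans:
        graph.add_node(SELF_NODE, kind="self")
        for pid in orphans:
            graph.add_edge(pid, SELF_NODE, weight=0.0, shared=0)
    return graph


def smiles_similarity(s1: str, s2: str) -> float:
    """Normalised string similarity of two SMILES strings.

    ``1 - d / max(|s1|, |s2|)`` with d the Levenshtein edit distance
    (unit-cost insert/delete/substitute) on the raw text, without any
    canonicalisation; identical strings score 1.0.
    """
    if not s1 or not s2:
        raise ValueError("SMILES strings must be non-empty")
    d = edlib.align(s1, s2, task="distance")["editDistance"]
    return 1.0 - d / max(len(s1), len(s2))


def molecular_network(
    reporters: Sequence[ReporterScore],
    min_score: float = 1.64,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
) -> nx.Graph:
    """Closest-match molecular network of enriched reporter metabolites.

    Nodes are reporters with enrichment score >= ``min_score``.  Each node
    is linked to its single highest-similarity partner (ties broken
    lexicographically by partner id); if that similarity falls below
    ``sim_threshold``, or the molecule has no SMILES, the node attaches to
    ``Self`` instead.  Reciprocal closest pairs yield one undirected edge.
    """
    included = [
        r
        for r in reporters
        if not math.isnan(r.score) and r.score >= min_score
    ]
    graph = nx.Graph()
    for r in included:
        graph.add_node(
            r.metabolite_id,
            kind="metabolite",
            name=r.name,
            score=r.score,
            n_up=r.n_up,
            n_down=r.n_down,
            dominant_fraction=(
                r.dominant_fraction if not math.isnan(r.dominant_fraction) else 0.0
            ),
        )

    def attach_self(node: str) -> None:
        if SELF_NODE not in graph:
            graph.add_node(SELF_NODE, kind="self")
        graph.add_edge(node, SELF_NODE, weight=0.0)

    with_smiles = [r for r in included if r.smiles]
    for r in included:
        if not r.smiles:
            warnings.warn(
                f"metabolite {r.metabolite_id!r} has no SMILES; attached to Self",
                stacklevel=2,
            )
            attach_self(r.metabolite_id)
            continue
        best_partner, best_sim = None, -1.0
        for other in with_smiles:
            if other.metabolite_id == r.metabolite_id:
                continue
            sim = smiles_similarity(r.smiles, other.smiles)
            if sim > best_sim or (
                sim == best_sim
                and best_partner is not None
                and other.metabolite_id < best_partner
            ):
                best_partner, best_sim = other.metabolite_id, sim
        if best_partner is not None and best_sim >= sim_threshold:
            graph.add_edge(r.metabolite_id, best_partner, weight=best_sim)
        else:
            attach_self(r.metabolite_id)
    return graph
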