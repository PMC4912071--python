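"""Reporter-metabolite scoring and the metabolite–enzyme network.

A reporter metabolite is one whose neighbouring enzymes — the genes of
every reaction that consumes or produces it — are collectively enriched in
differential expression.  Each metabolite's neighbourhood gene set is
scored exactly like a GO gene set, except that the bootstrap background is
drawn from enzyme-encoding genes only: metabolic genes are, as a group,
more differentially expressed than the genome at large, and a genome-wide
background would therefore overstate the enrichment of every metabolite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enrichment import (
    BackgroundTable,
    EnrichmentResult,
    background_stats,
    enrichment_score,
)
from .tabio import ExpressionRecord, MetabolicModel

__all__ = [
    "ReporterScore",
    "metabolite_neighbourhood",
    "reporter_scores",
    "reporter_enzyme_network",
]

#: Score above which a metabolite counts as enriched (one-sided p=0.05).
ENRICHED_THRESHOLD = 1.64
#: Stricter cutoff used for the focused metabolite–enzyme network.
FOCUS_THRESHOLD = 3.0


@dataclass(frozen=True)
class ReporterScore:
    metabolite_id: str
    name: str
    neighbour_genes: frozenset[str]
    k: int
    total_z: float
    bg_mean: float
    bg_sd: float
    score: float
    n_up: int
    n_down: int
    smiles: str | None = None

    @property
    def dominant_fraction(self) -> float:
        total = self.n_up + self.n_down
        if total == 0:
            return math.nan
        return max(self.n_up, self.n_down) / total


def metabolite_neighbourhood(
    metabolite_id: str, model: MetabolicModel
) -> frozenset[str]:
    """Genes of every reaction involving the metabolite, either side."""
    if metabolite_id not in model.metabolites:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    genes: set[str] = set()
    for rxn in model.reactions.values():
        if metabolite_id in rxn.stoichiometry:
            genes |= rxn.genes
    return frozenset(genes)


def reporter_scores(
    model: MetabolicModel,
    zmap: Mapping[str, float],
    de: Mapping[str, ExpressionRecord] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    exclude: Iterable[str] = (),
    merge_compartments: bool = False,
) -> list[ReporterScore]:
    """Score every metabolite of the model as a reporter metabolite.

    The background universe is the set of genes mapped to at least one
    reaction.  Metabolites with an empty neighbourhood (no gene-linked
    reaction) are skipped.  ``exclude`` is an opt-in currency-metabolite
    exclusion list; by default every metabolite, including cofactors, is
    scored.  With ``merge_compartments`` the per-compartment instances of
    a compound are pooled under their base id before scoring.
    """
    enzyme_universe = set(model.genes()) & set(zmap)
    if not enzyme_universe:
        raise ValueError("model has no gene-linked reactions in the Z-map")
    excluded = set(exclude)

    neighbourhoods: dict[str, tuple[str, str | None, set[str]]] = {}
    for mid, met in model.metabolites.items():
        if mid in excluded:
            continue
        genes = set(metabolite_neighbourhood(mid, model)) & enzyme_universe
        if not genes:
            continue
        key = model.metabolite_base_id(mid) if merge_compartments else mid
        if key in neighbourhoods:
            neighbourhoods[key][2].update(genes)
        else:
            neighbourhoods[key] = (met.name, met.smiles, genes)

    sizes = {len(g) for _, _, g in neighbourhoods.values()}
    if not sizes:
        return []
    if max(sizes) > len(enzyme_universe):
        raise ValueError("enzyme universe smaller than largest neighbourhood")
    background = background_stats(
        zmap,
        sizes,
        n_boot=n_boot,
        seed=seed,
        universe=enzyme_universe,
        universe_label="enzyme_genes",
    )
    out = []
    for mid in sorted(neighbourhoods):
        name, smiles, genes = neighbourhoods[mid]
        res = enrichment_score(
            genes, zmap, background, de=de, set_id=mid, name=name
        )
        out.append(
            ReporterScore(
                metabolite_id=mid,
                name=name,
                neighbour_genes=frozenset(genes),
                k=res.k,
                total_z=res.total_z,
                bg_mean=res.bg_mean,
                bg_sd=res.bg_sd,
                score=res.score,
                n_up=res.n_up,
                n_down=res.n_down,
                smiles=smiles,
            )
        )
    return out


def reporter_enzyme_network(
    scores: Sequence[ReporterScore],
    de: Mapping[str, ExpressionRecord],
    score_threshold: float = FOCUS_THRESHOLD,
    q_threshold: float = 0.05,
) -> nx.Graph:
    """Bipartite graph of enriched metabolites and their DE enzyme genes.

    Retained metabolite nodes have enrichment score >= ``score_threshold``;
    retained gene nodes have q < ``q_threshold`` and at least one retained
    metabolite neighbour.  Node attributes carry the rendering metadata
    (score, direction counts, dominant fraction; gene log2 fold change).
    """
    graph = nx.Graph()
    for rep in scores:
        if math.isnan(rep.score) or rep.score < score_threshold:
            continue
        graph.add_node(
            rep.metabolite_id,
            kind="metabolite",
            name=rep.name,
            score=rep.score,
            n_up=rep.n_up,
            n_down=rep.n_down,
            dominant_fraction=(
                rep.dominant_fraction if not math.isnan(rep.dominant_fraction) else 0.0
            ),
        )
        for gene in sorted(rep.neighbour_genes):
            rec = de.get(gene)
            if rec is None or rec.q_value >= q_threshold:
                continue
            if gene not in graph:
                graph.add_node(
                    gene, kind="gene", log2_fc=rec.log2_fc, q_value=rec.q_value
                )
            graph.add_edge(rep.metabolite_id, gene)
    return graph
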