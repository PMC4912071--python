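"""Reaction-level expression summaries behind painted pathway maps.

A reaction's expression state pools all genes mapped to it (isozymes from
paralogs or multi-functional proteins).  Two rendering schemes are
supported: the log2 fold-change scheme colours each reaction by the member
gene with the largest-magnitude fold change, and the classification scheme
labels each reaction up / down / constitutive / isozyme_switching — the
last meaning some significantly up- AND some significantly down-regulated
isozymes, a pattern that often marks compartment-specific rerouting.
Genes are placed into subcellular compartments through their GO
cellular_component annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .tabio import ExpressionRecord, MetabolicModel, Reaction

__all__ = [
    "ReactionExpression",
    "COMPARTMENT_LABELS",
    "DEFAULT_CC_TERM_MAP",
    "summarise_reaction",
    "summarise_model",
    "assign_compartments",
    "compartment_view",
]

COMPARTMENT_LABELS = (
    "cytoplasm",
    "mitochondrion",
    "peroxisome",
    "nucleus",
    "plasma_membrane",
    "extracellular",
    "other",
    "unknown",
)

#: Default GO cellular_component term → compartment label map, covering
#: the yeast GO-slim terms; unmapped cellular_component terms fall back
#: to "other" (handled by the caller supplying the cc term universe).
DEFAULT_CC_TERM_MAP: dict[str, str] = {
    "GO:0005737": "cytoplasm",
    "GO:0005829": "cytoplasm",        # cytosol
    "GO:0005739": "mitochondrion",
    "GO:0005777": "peroxisome",
    "GO:0005634": "nucleus",
    "GO:0005886": "plasma_membrane",
    "GO:0016020": "plasma_membrane",  # membrane
    "GO:0005576": "extracellular",    # extracellular region
    "GO:0005618": "other",            # cell wall
}


@dataclass(frozen=True)
class ReactionExpression:
    """Pooled two-condition expression state of one reaction."""

    reaction_id: str
    genes: frozenset[str]
    total_a: float
    total_b: float
    rep_log2_fc: float  # NaN when no member gene is in the DE table
    any_significant: bool
    klass: str  # up | down | constitutive | isozyme_switching | no_gene


def summarise_reaction(
    reaction: Reaction,
    de: Mapping[str, ExpressionRecord],
    gene_subset: Iterable[str] | None = None,
) -> ReactionExpression:
    """Summarise a reaction's expression over its member genes.

    Totals sum abundances per condition; the representative fold change is
    that of the member gene with the largest |log2 FC| (sign preserved).
    Classes: ``isozyme_switching`` needs significant genes in both
    directions, ``up``/``down`` need >= 1 significant gene with all
    significant genes sharing a sign, ``constitutive`` means no
    significant gene, ``no_gene`` means no member gene in the DE table.
    """
    members = set(reaction.genes)
    if gene_subset is not None:
        members &= set(gene_subset)
    records = [de[g] for g in sorted(members) if g in de]
    if not records:
        return ReactionExpression(
            reaction_id=reaction.id,
            genes=frozenset(members),
            total_a=0.0,
            total_b=0.0,
            rep_log2_fc=math.nan,
            any_significant=False,
            klass="no_gene",
        )
    total_a = sum(r.value_a for r in records)
    total_b = sum(r.value_b for r in records)
    rep = max(records, key=lambda r: abs(r.log2_fc))
    sig = [r for r in records if r.significant]
    has_up = any(r.log2_fc > 0 for r in sig)
    has_down = any(r.log2_fc < 0 for r in sig)
    if has_up and has_down:
        klass = "isozyme_switching"
    elif has_up:
        klass = "up"
    elif has_down:
        klass = "down"
    else:
        klass = "constitutive"
    return ReactionExpression(
        reaction_id=reaction.id,
        genes=frozenset(r.gene_id for r in records),
        total_a=total_a,
        total_b=total_b,
        rep_log2_fc=rep.log2_fc,
        any_significant=bool(sig),
        klass=klass,
    )


def summarise_model(
    model: MetabolicModel,
    de: Mapping[str, ExpressionRecord],
) -> dict[str, ReactionExpression]:
    """Per-reaction expression summaries for a whole model."""
    return {
        rid: summarise_reaction(rxn, de) for rid, rxn in model.reactions.items()
    }


def assign_compartments(
    annotations: Mapping[str, Iterable[str]],
    cc_term_map: Mapping[str, str] | None = None,
) -> dict[str, frozenset[str]]:
    """Map each gene to subcellular compartment labels via GO terms.

    Every cellular_component term of a gene contributes its mapped label,
    so multi-localised genes appear in every mapped compartment (a gene
    annotated to both a membrane and an organelle appears in both views).
    Genes with no mapped term get ``{"unknown"}``.
    """
    term_map = DEFAULT_CC_TERM_MAP if cc_term_map is None else cc_term_map
    out: dict[str, frozenset[str]] = {}
    for gene, terms in annotations.items():
        labels = {term_map[t] for t in terms if t in term_map}
        out[gene] = frozenset(labels) if labels else frozenset({"unknown"})
    return out


def compartment_view(
    model: MetabolicModel,
    de: Mapping[str, ExpressionRecord],
    compartments: Mapping[str, frozenset[str]],
    target: str,
) -> dict[str, ReactionExpression]:
    """Re-summarise reactions using only genes assigned to ``target``.

    Reactions with no gene in the target compartment are omitted, so an
    isozyme-switching reaction can resolve to a clean up or down call
    within a single compartment.
    """
    if target not in COMPARTMENT_LABELS:
        raise ValueError(f"unknown compartment label {target!r}")
    view: dict[str, ReactionExpression] = {}
    for rid, rxn in model.reactions.items():
        subset = {
            g for g in rxn.genes if target in compartments.get(g, frozenset())
        }
        if not subset:
            continue
        summary = summarise_reaction(rxn, de, gene_subset=subset)
        if summary.klass == "no_gene":
            continue
        view[rid] = summary
    return view
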