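"""Readers and writers for every external format the pipeline touches.

The pipeline consumes four kinds of input: a two-condition differential
expression table (tab-separated, CuffDiff-style columns), a Gene Ontology
subset in OBO format (only ``is_a`` parentage is honoured), a metabolic
model in a flat JSON schema, and per-condition measured exchange rates
(JSON).  Result graphs are written as GraphML or a three-column edge TSV.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionRecord",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ExchangeMeasurement",
    "DEFormatError",
    "ModelFormatError",
    "OntologyError",
    "DE_COLUMNS",
    "read_de_table",
    "write_de_table",
    "read_annotations",
    "write_annotations",
    "read_obo_subset",
    "read_model",
    "write_model",
    "read_rates",
    "write_rates",
    "write_network",
    "read_network",
]


class DEFormatError(ValueError):
    """Malformed differential-expression table."""


class ModelFormatError(ValueError):
    """Malformed metabolic-model document."""


class OntologyError(ValueError):
    """Malformed or cyclic ontology."""


#: Canonical column order of the differential-expression TSV.
DE_COLUMNS = [
    "gene_id",
    "value_a",
    "value_b",
    "log2_fc",
    "p_value",
    "q_value",
    "significant",
    "protein_names",
    "gene_names",
    "go_terms",
]

_REQUIRED_DE_COLUMNS = ["gene_id", "value_a", "value_b", "p_value", "q_value"]


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's two-condition abundances and differential statistics.

    ``value_a``/``value_b`` are FPKM-like transcript abundances in the two
    conditions (A = reference, e.g. glucose; B = perturbation, e.g. xylose);
    ``log2_fc`` is log2(B/A).  ``significant`` is recomputed from the
    q-value at load time rather than trusted from the file.
    """

    gene_id: str
    value_a: float
    value_b: float
    log2_fc: float
    p_value: float
    q_value: float
    significant: bool
    protein_names: str = ""
    gene_names: str = ""
    go_terms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    smiles: str | None = None
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]  # metabolite id -> signed coefficient
    reversible: bool = False
    genes: frozenset[str] = frozenset()
    compartment: str = ""
    pathways: frozenset[str] = frozenset()


@dataclass
class MetabolicModel:
    """A compartmentalised stoichiometric model.

    Stoichiometric coefficients are negative for substrates and positive
    for products.  ``exchanges`` lists boundary reactions (single-metabolite
    stoichiometry by convention; positive flux exports the metabolite).
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    pathways: dict[str, tuple[str, frozenset[str]]]  # id -> (name, reaction ids)
    biomass_reaction: str
    exchanges: frozenset[str]

    def validate(self) -> None:
        for rid, rxn in self.reactions.items():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelFormatError(
                        f"reaction {rid!r} references undeclared metabolite {mid!r}"
                    )
        if self.biomass_reaction not in self.reactions:
            raise ModelFormatError(
                f"biomass reaction {self.biomass_reaction!r} is not declared"
            )
        for pid, (_, rids) in self.pathways.items():
            for rid in rids:
                if rid not in self.reactions:
                    raise ModelFormatError(
                        f"pathway {pid!r} references unknown reaction {rid!r}"
                    )
        for ex in self.exchanges:
            if ex not in self.reactions:
                raise ModelFormatError(f"exchange reaction {ex!r} is not declared")

    # -- derived views -------------------------------------------------

    def genes(self) -> frozenset[str]:
        """All genes mapped to at least one reaction (the enzyme universe)."""
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return frozenset(out)

    def pathway_metabolites(self, pathway_id: str) -> frozenset[str]:
        """Union of the metabolites of a pathway's reactions."""
        _, rids = self.pathways[pathway_id]
        mets: set[str] = set()
        for rid in rids:
            mets |= set(self.reactions[rid].stoichiometry)
        return frozenset(mets)

    def metabolite_base_id(self, metabolite_id: str) -> str:
        """Metabolite id with its compartment tag stripped.

        Supports ``glc[c]``-style bracket suffixes and ``glc_c``-style
        underscore suffixes matching the declared compartment label.
        """
        met = self.metabolites.get(metabolite_id)
        mid = metabolite_id
        if mid.endswith("]") and "[" in mid:
            return mid[: mid.rindex("[")]
        if met is not None and met.compartment:
            suffix = "_" + met.compartment
            if mid.endswith(suffix):
                return mid[: -len(suffix)]
        return mid


@dataclass(frozen=True)
class ExchangeMeasurement:
    """Measured specific exchange rates for one condition.

    Rates are in mmol h^-1 (g dry weight)^-1; by this package's convention
    a positive exchange flux exports the species, so uptake rates are
    negative.  ``fixed_zero`` lists exchanges clamped to zero (species
    absent from the medium and not produced); exchanges in neither mapping
    are left free.
    """

    condition: str
    rates: Mapping[str, float]
    fixed_zero: frozenset[str] = frozenset()

    def validate(self, model: MetabolicModel) -> None:
        for ex, rate in self.rates.items():
            if ex not in model.exchanges:
                raise ModelFormatError(
                    f"measured exchange {ex!r} is not an exchange reaction of the model"
                )
            if not math.isfinite(rate):
                raise ValueError(f"rate for {ex!r} is not finite")
        for ex in self.fixed_zero:
            if ex not in model.exchanges:
                raise ModelFormatError(
                    f"zero-fixed exchange {ex!r} is not an exchange reaction of the model"
                )


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------


def _parse_go_terms(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(t.strip() for t in text.split(";") if t.strip())


def read_de_table(
    path: str | Path, q_cutoff: float = 0.05
) -> list[ExpressionRecord]:
    """Read a differential-expression TSV into :class:`ExpressionRecord` rows.

    Significance is recomputed as ``q_value < q_cutoff``; a ``significant``
    column in the file is ignored (disagreements are counted and logged).
    When both abundances are positive the log2 fold change is recomputed
    from them, otherwise the file's ``log2_fc`` column is used as-is.
    Rows with non-numeric abundances are rejected with their row indices
    reported in a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_DE_COLUMNS if c not in df.columns]
    if missing:
        raise DEFormatError(f"missing required column(s): {', '.join(missing)}")

    dup = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dup:
        raise DEFormatError(f"duplicate gene_id(s): {', '.join(sorted(dup))}")

    records: list[ExpressionRecord] = []
    bad_rows: list[int] = []
    disagreements = 0
    has_flag = "significant" in df.columns
    for idx, row in df.iterrows():
        try:
            value_a = float(row["value_a"])
            value_b = float(row["value_b"])
            p_value = float(row["p_value"])
            q_value = float(row["q_value"])
        except (TypeError, ValueError):
            bad_rows.append(int(idx))
            continue
        if value_a < 0 or value_b < 0:
            bad_rows.append(int(idx))
            continue
        if not (0.0 <= q_value <= 1.0):
            raise DEFormatError(
                f"row {idx}: q_value {q_value} outside [0, 1]"
            )
        if value_a > 0 and value_b > 0:
            log2_fc = math.log2(value_b / value_a)
        else:
            try:
                log2_fc = float(row.get("log2_fc", "nan"))
            except (TypeError, ValueError):
                log2_fc = math.nan
        significant = q_value < q_cutoff
        if has_flag:
            file_flag = str(row["significant"]).strip().lower() in {
                "yes", "true", "1",
            }
            if file_flag != significant:
                disagreements += 1
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene_id"]),
                value_a=value_a,
                value_b=value_b,
                log2_fc=log2_fc,
                p_value=p_value,
                q_value=q_value,
                significant=significant,
                protein_names=str(row.get("protein_names", "")),
                gene_names=str(row.get("gene_names", "")),
                go_terms=_parse_go_terms(row.get("go_terms")),
            )
        )
    if bad_rows:
        warnings.warn(
            f"rejected {len(bad_rows)} row(s) with non-numeric or negative "
            f"abundances at indices {bad_rows}",
            stacklevel=2,
        )
    if disagreements:
        logger.info(
            "significance flag recomputed at q<%g: %d disagreement(s) with file",
            q_cutoff,
            disagreements,
        )
    return records


def write_de_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "value_a": repr(r.value_a),
                "value_b": repr(r.value_b),
                "log2_fc": repr(r.log2_fc),
                "p_value": repr(r.p_value),
                "q_value": repr(r.q_value),
                "significant": "yes" if r.significant else "no",
                "protein_names": r.protein_names,
                "gene_names": r.gene_names,
                "go_terms": ";".join(sorted(r.go_terms)),
            }
        )
    pd.DataFrame(rows, columns=DE_COLUMNS).to_csv(path, sep="\t", index=False)


#: Column-name mapping from deposited supplementary XLSX tables
#: (glucose = condition A, xylose = condition B) onto the canonical header.
XLSX_COLUMN_MAP = {
    "Id": "gene_id",
    "Value (Glc)": "value_a",
    "Value (Xyl)": "value_b",
    "log2(FC)": "log2_fc",
    "pvalue": "p_value",
    "qvalue": "q_value",
    "signt": "significant",
    "Protein names": "protein_names",
    "Gene names": "gene_names",
    "GO terms": "go_terms",
}


def read_de_xlsx(
    path: str | Path,
    q_cutoff: float = 0.05,
    column_map: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> list[ExpressionRecord]:
    """Read a supplementary-table XLSX through the canonical TSV schema.

    Columns are renamed via ``column_map`` (default covers the deposited
    main-data-table layout), then parsed with the same rules as
    :func:`read_de_table` — significance recomputed, fold changes
    recomputed from positive abundance pairs.
    """
    import tempfile

    df = pd.read_excel(path, sheet_name=sheet)
    df = df.rename(columns=column_map or XLSX_COLUMN_MAP)
    if "p_value" not in df.columns and "q_value" in df.columns:
        df["p_value"] = df["q_value"]
    keep = [c for c in DE_COLUMNS if c in df.columns]
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        df[keep].to_csv(fh, sep="\t", index=False)
        tmp = fh.name
    try:
        return read_de_table(tmp, q_cutoff=q_cutoff)
    finally:
        Path(tmp).unlink(missing_ok=True)


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column gene→terms TSV (terms semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in df.columns or "go_terms" not in df.columns:
        raise DEFormatError("annotation table needs columns gene_id, go_terms")
    return {
        str(row["gene_id"]): _parse_go_terms(row["go_terms"])
        for _, row in df.iterrows()
    }


def write_annotations(
    annotations: Mapping[str, Iterable[str]], path: str | Path
) -> None:
    rows = [
        {"gene_id": g, "go_terms": ";".join(sorted(ts))}
        for g, ts in sorted(annotations.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "go_terms"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


def read_obo_subset(path: str | Path) -> nx.DiGraph:
    """Read an OBO file, keeping only named terms and ``is_a`` edges.

    Returns a directed graph with child→parent edges and a ``name`` node
    attribute.  Obsolete terms are dropped (obonet's default), dangling
    ``is_a`` references are dropped with a warning, and a cyclic closure
    raises :class:`OntologyError` naming one cycle.
    """
    multigraph = obonet.read_obo(str(path))
    graph = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        if "name" not in data:
            continue  # stub created by a dangling reference
        graph.add_node(node, name=data["name"])
    dangling = []
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if child in graph and parent in graph:
            graph.add_edge(child, parent)
        else:
            dangling.append((child, parent))
    if dangling:
        warnings.warn(
            f"dropped {len(dangling)} dangling is_a edge(s): {dangling[:5]}",
            stacklevel=2,
        )
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyError(f"cyclic is_a closure, e.g. {cycle}")
    return graph


# ---------------------------------------------------------------------------
# Metabolic model
# ---------------------------------------------------------------------------


def read_model(path: str | Path) -> MetabolicModel:
    """Load a metabolic model from the flat JSON schema.

    Top-level keys: ``metabolites``, ``reactions``, ``pathways``,
    ``biomass_reaction``, ``exchanges``.  Stoichiometric coefficients are
    negative for substrates.  Every referenced metabolite/reaction must be
    declared; nothing is silently dropped.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("metabolites", "reactions", "biomass_reaction"):
        if key not in doc:
            raise ModelFormatError(f"model document missing key {key!r}")

    metabolites: dict[str, Metabolite] = {}
    for mid, m in doc["metabolites"].items():
        if mid in metabolites:
            raise ModelFormatError(f"duplicate metabolite id {mid!r}")
        metabolites[mid] = Metabolite(
            id=mid,
            name=m.get("name", mid),
            smiles=m.get("smiles"),
            compartment=m.get("compartment", ""),
        )

    reactions: dict[str, Reaction] = {}
    raw_reactions = doc["reactions"]
    if isinstance(raw_reactions, list):
        ids = [r["id"] for r in raw_reactions]
        dups = {i for i in ids if ids.count(i) > 1}
        if dups:
            raise ModelFormatError(f"duplicate reaction id(s): {sorted(dups)}")
        raw_reactions = {r["id"]: r for r in raw_reactions}
    for rid, r in raw_reactions.items():
        reactions[rid] = Reaction(
            id=rid,
            stoichiometry={m: float(c) for m, c in r["stoichiometry"].items()},
            reversible=bool(r.get("reversible", False)),
            genes=frozenset(r.get("genes", [])),
            compartment=r.get("compartment", ""),
            pathways=frozenset(r.get("pathways", [])),
        )

    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for pid, p in doc.get("pathways", {}).items():
        pathways[pid] = (p.get("name", pid), frozenset(p["reactions"]))

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        pathways=pathways,
        biomass_reaction=doc["biomass_reaction"],
        exchanges=frozenset(doc.get("exchanges", [])),
    )
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    doc = {
        "metabolites": {
            m.id: {
                "name": m.name,
                **({"smiles": m.smiles} if m.smiles is not None else {}),
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        },
        "reactions": {
            r.id: {
                "stoichiometry": dict(r.stoichiometry),
                "reversible": r.reversible,
                "genes": sorted(r.genes),
                "compartment": r.compartment,
                "pathways": sorted(r.pathways),
            }
            for r in model.reactions.values()
        },
        "pathways": {
            pid: {"name": name, "reactions": sorted(rids)}
            for pid, (name, rids) in model.pathways.items()
        },
        "biomass_reaction": model.biomass_reaction,
        "exchanges": sorted(model.exchanges),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_rates(path: str | Path, condition: str = "") -> ExchangeMeasurement:
    """Read a rates JSON: ``{exchange_id: rate | "free" | 0}``.

    A numeric value fixes the exchange flux; the string ``"free"`` leaves
    it unconstrained.  A ``condition`` key in the document, if present,
    names the condition.
    """
    with open(path) as fh:
        doc = json.load(fh)
    condition = doc.pop("condition", condition)
    rates: dict[str, float] = {}
    zeros: set[str] = set()
    for ex, value in doc.items():
        if isinstance(value, str):
            if value.lower() != "free":
                raise ValueError(f"rate for {ex!r} must be numeric or 'free'")
            continue
        rate = float(value)
        if rate == 0.0:
            zeros.add(ex)
        else:
            rates[ex] = rate
    return ExchangeMeasurement(
        condition=condition, rates=rates, fixed_zero=frozenset(zeros)
    )


def write_rates(measurement: ExchangeMeasurement, path: str | Path) -> None:
    doc: dict[str, object] = {"condition": measurement.condition}
    doc.update({ex: rate for ex, rate in sorted(measurement.rates.items())})
    doc.update({ex: 0 for ex in sorted(measurement.fixed_zero)})
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_NETWORK_FORMATS = {"graphml", "edge-tsv"}


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a result graph as GraphML or a weighted edge TSV.

    GraphML round-trips node/edge attributes (numbers preserved to full
    float precision); the edge TSV keeps only source, target and weight.
    """
    if fmt not in _NETWORK_FORMATS:
        raise ValueError(f"unsupported network format {fmt!r}")
    if fmt == "graphml":
        nx.write_graphml(graph, str(path))
    else:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in graph.edges(data=True):
                fh.write(f"{u}\t{v}\t{data.get('weight', 1.0)!r}\n")


def read_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    if fmt not in _NETWORK_FORMATS:
        raise ValueError(f"unsupported network format {fmt!r}")
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    graph = nx.Graph()
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    for _, row in df.iterrows():
        graph.add_edge(row["source"], row["target"], weight=float(row["weight"]))
    return graph
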