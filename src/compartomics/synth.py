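"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a two-condition RNA-seq comparison of a yeast-like
genome together with a small compartmentalised metabolic model:

* a genome-wide differential-expression table with a null majority
  (q ~ Uniform(0,1), near-zero fold changes) and planted up/down genes
  whose q-values concentrate below 0.05 (defaults mirror a 4953-gene
  genome with 329 up- and 251 down-regulated genes);
* a toy is_a ontology with one planted enriched term plus the standard
  cellular_component terms used for compartment assignment;
* a feasible metabolic model — substrate uptake feeding a linear backbone
  through two compartments into biomass, a measurable byproduct branch
  that is shut off in the second condition, a zero-flux side branch
  hosting a planted reporter metabolite and a planted isozyme-switching
  reaction, and null "decoy" reactions that populate the enzyme
  background — with per-condition exchange rates and transcript levels
  engineered so that every planted signal is recoverable and the
  hierarchical regulation coefficient of backbone reactions equals a
  known constant;
* a machine-readable ground-truth record for recovery tests.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .tabio import (
    ExchangeMeasurement,
    ExpressionRecord,
    MetabolicModel,
    Metabolite,
    Reaction,
    write_annotations,
    write_de_table,
    write_model,
    write_rates,
)

__all__ = [
    "SynthConfig",
    "SynthData",
    "generate_de_table",
    "generate_model",
    "generate_truth",
    "generate_all",
    "write_synth",
    "PLANTED_GO_TERM",
]

PLANTED_GO_TERM = "SYN:9000"
_ROOT_BP = "SYN:0001"
_ROOT_CC = "SYN:0002"

#: cellular_component terms used for synthetic compartment annotation.
_CC_TERMS = {
    "c": "GO:0005737",  # cytoplasm
    "m": "GO:0005739",  # mitochondrion
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic data.

    Genome-scale defaults mirror the analysed organism: 4953 genes, with
    up/down fractions matching 329 up- and 251 down-regulated genes, and
    |log2 FC| effect sizes centred at 3 (eight-fold).  Exchange defaults
    mirror the measured physiology: substrate uptake 9.4 in condition A
    and 5.0 in condition B (mmol h^-1 gDW^-1), a 2.0 byproduct secretion
    in A that vanishes in B.  Backbone transcripts are scaled so the
    hierarchical regulation coefficient is ``planted_rho_h`` exactly.
    """

    seed: int = 0
    n_genes: int = 4953
    frac_up: float = 329 / 4953
    frac_down: float = 251 / 4953
    effect_mean: float = 3.0
    effect_sd: float = 1.5
    null_fc_sd: float = 0.3
    q_floor: float = 0.001
    planted_go_size: int = 12
    n_decoy_terms: int = 10
    n_decoy_reactions: int = 30
    genes_per_decoy: int = 2
    planted_rho_h: float = 0.7
    uptake_a: float = 9.4
    uptake_b: float = 5.0
    byproduct_a: float = 2.0
    smiles_alphabet: str = "CNOS()=123cn"
    smiles_len: tuple[int, int] = (8, 14)


@dataclass
class SynthData:
    """The full bundle of generated inputs plus ground truth."""

    de: list[ExpressionRecord]
    model: MetabolicModel
    annotations: dict[str, frozenset[str]]
    obo_text: str
    rates_a: ExchangeMeasurement
    rates_b: ExchangeMeasurement
    truth: dict


def _de_gene(
    rng: np.random.Generator,
    gene_id: str,
    direction: int,
    config: SynthConfig,
    go_terms: frozenset[str] = frozenset(),
) -> ExpressionRecord:
    """One genome gene: null (direction 0) or planted up/down (+1/-1)."""
    base = float(np.exp(rng.normal(4.0, 1.2)))
    if direction == 0:
        q = float(rng.uniform())
        fc = float(rng.normal(0.0, config.null_fc_sd))
    else:
        # Exponential tail in -log q, concentrated below 0.05.
        q = max(config.q_floor, 0.05 * math.exp(-rng.exponential(1.5)))
        fc = direction * max(0.5, float(rng.normal(config.effect_mean, config.effect_sd)))
    value_a = base
    value_b = base * 2.0**fc
    return ExpressionRecord(
        gene_id=gene_id,
        value_a=value_a,
        value_b=value_b,
        log2_fc=fc,
        p_value=q * float(rng.uniform()),
        q_value=q,
        significant=q < 0.05,
        go_terms=go_terms,
    )


def generate_de_table(
    config: SynthConfig,
) -> tuple[list[ExpressionRecord], dict]:
    """Genome-wide DE table with planted up/down genes.

    Each gene is independently null, up or down with probabilities
    (1 - frac_up - frac_down, frac_up, frac_down), so planted counts are
    binomial around the configured expectations.  Returns the records and
    a truth fragment listing planted gene ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    directions = rng.choice(
        [0, 1, -1],
        size=config.n_genes,
        p=[1 - config.frac_up - config.frac_down, config.frac_up, config.frac_down],
    )
    records = []
    up, down = [], []
    for i, direction in enumerate(directions):
        gid = f"G{i:05d}"
        records.append(_de_gene(rng, gid, int(direction), config))
        if direction == 1:
            up.append(gid)
        elif direction == -1:
            down.append(gid)
    truth = {"planted_up": up, "planted_down": down}
    return records, truth


def _random_smiles(rng: np.random.Generator, config: SynthConfig) -> str:
    lo, hi = config.smiles_len
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(config.smiles_alphabet), size=n))


def _scaled_gene(
    rng: np.random.Generator,
    gene_id: str,
    ratio: float,
    config: SynthConfig,
    significant: bool = True,
    go_terms: frozenset[str] = frozenset(),
) -> ExpressionRecord:
    """A model gene whose abundance scales by ``ratio`` between conditions."""
    base = float(np.exp(rng.normal(5.5, 0.8)))  # enzymes are well expressed
    q = config.q_floor if significant else float(rng.uniform(0.2, 1.0))
    return ExpressionRecord(
        gene_id=gene_id,
        value_a=base,
        value_b=base * ratio,
        log2_fc=math.log2(ratio),
        p_value=q / 2,
        q_value=q,
        significant=q < 0.05,
        go_terms=go_terms,
    )


def generate_model(
    config: SynthConfig,
) -> tuple[MetabolicModel, dict[str, frozenset[str]], list[ExpressionRecord], dict]:
    """Build the synthetic model, annotations, enzyme DE records and truth.

    Topology: EX_S -> M0 -> ... -> M5 -(transport)-> M6 -> M8 -> biomass
    in two compartments, a byproduct branch M2 -> B1 -> EX_B active only
    in condition A, a zero-flux side branch around reporter metabolite X,
    and dead-end decoy reactions carrying null genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    metabolites: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}
    annotations: dict[str, frozenset[str]] = {}
    de_records: list[ExpressionRecord] = []

    def add_met(mid: str, compartment: str, name: str | None = None) -> None:
        metabolites[mid] = Metabolite(
            id=mid,
            name=name or mid,
            smiles=_random_smiles(rng, config),
            compartment=compartment,
        )

    for i in range(6):
        add_met(f"M{i}", "c")
    for i in range(6, 9):
        add_met(f"M{i}", "m")
    add_met("B1", "c", "byproduct")
    add_met("X", "c", "reporter-x")

    gene_counter = 0

    def new_gene(prefix: str = "ENZ") -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"{prefix}{gene_counter:04d}"

    def add_reaction(
        rid: str,
        stoich: dict[str, float],
        genes: list[str],
        compartment: str,
        reversible: bool = False,
    ) -> None:
        reactions[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            reversible=reversible,
            genes=frozenset(genes),
            compartment=compartment,
        )

    # Planned steady-state fluxes for both conditions (backbone).
    ua, ub = config.uptake_a, config.uptake_b
    ba = config.byproduct_a
    flux_a: dict[str, float] = {"EX_S": -ua, "EX_B": ba}
    flux_b: dict[str, float] = {"EX_S": -ub, "EX_B": 0.0}

    backbone = [
        ("RC1", "M0", "M1", "c", ua, ub),
        ("RC2", "M1", "M2", "c", ua, ub),
        ("RB", "M2", "B1", "c", ba, 0.0),
        ("RC3", "M2", "M3", "c", ua - ba, ub),
        ("RC4", "M3", "M4", "c", ua - ba, ub),
        ("RC5", "M4", "M5", "c", ua - ba, ub),
        ("RT", "M5", "M6", "m", ua - ba, ub),
        ("RM1", "M6", "M7", "m", ua - ba, ub),
        ("RM2", "M7", "M8", "m", ua - ba, ub),
    ]
    alpha = config.planted_rho_h
    planted_rho: dict[str, float] = {}
    for rid, sub, prod, comp, ja, jb in backbone:
        n_iso = 2 if rid == "RC5" else 1
        genes = []
        if rid == "RB":
            # Disappearing byproduct flux: strongly down-regulated gene.
            gid = new_gene()
            genes.append(gid)
            de_records.append(
                _scaled_gene(rng, gid, 0.1, config, go_terms=frozenset({_CC_TERMS[comp]}))
            )
        else:
            ratio = (jb / ja) ** alpha
            for _ in range(n_iso):
                gid = new_gene()
                genes.append(gid)
                de_records.append(
                    _scaled_gene(
                        rng, gid, ratio, config,
                        go_terms=frozenset({_CC_TERMS[comp]}),
                    )
                )
            planted_rho[rid] = alpha
        add_reaction(rid, {sub: -1.0, prod: 1.0}, genes, comp)
        flux_a[rid] = ja
        flux_b[rid] = jb

    # Side branch around the reporter metabolite X.  All three reactions
    # produce X and nothing consumes it, so mass balance pins their flux
    # to zero in every condition; their strongly regulated genes make X
    # the planted top reporter metabolite.
    side = [("RX1", "M1"), ("RX2", "M2"), ("RX3", "M4")]
    reporter_genes: list[str] = []
    for rid, sub in side:
        genes = []
        for j in range(3):
            gid = new_gene()
            genes.append(gid)
            reporter_genes.append(gid)
            # Isozyme switching planted on RX1: one down among ups.
            direction = -1 if (rid == "RX1" and j == 1) else 1
            fc = direction * 3.0
            compartment_term = _CC_TERMS["m" if (rid == "RX1" and j == 1) else "c"]
            rec = _scaled_gene(
                rng, gid, 2.0**fc, config,
                go_terms=frozenset({compartment_term}),
            )
            de_records.append(rec)
        add_reaction(rid, {sub: -1.0, "X": 1.0}, genes, "c")
        flux_a[rid] = 0.0
        flux_b[rid] = 0.0

    # Dead-end decoy reactions with null genes (enzyme background).
    near_pair = None
    for d in range(config.n_decoy_reactions):
        zid = f"Z{d:02d}"
        add_met(zid, "c")
        genes = []
        for _ in range(config.genes_per_decoy):
            gid = new_gene()
            genes.append(gid)
            de_records.append(
                _scaled_gene(
                    rng, gid, float(2.0 ** rng.normal(0, config.null_fc_sd)),
                    config, significant=False,
                    go_terms=frozenset({_CC_TERMS["c"]}),
                )
            )
        add_reaction(f"D{d:02d}", {"M1": -1.0, zid: 1.0}, genes, "c")
        flux_a[f"D{d:02d}"] = 0.0
        flux_b[f"D{d:02d}"] = 0.0
    # Plant one near-duplicate SMILES pair among the decoy metabolites.
    if config.n_decoy_reactions >= 2:
        s = metabolites["Z00"].smiles or "CCO"
        mutated = list(s)
        pos = int(rng.integers(len(mutated)))
        choices = [ch for ch in config.smiles_alphabet if ch != mutated[pos]]
        mutated[pos] = choices[int(rng.integers(len(choices)))]
        metabolites["Z01"] = Metabolite(
            id="Z01", name="Z01", smiles="".join(mutated), compartment="c"
        )
        near_pair = ("Z00", "Z01")

    add_reaction("EX_S", {"M0": -1.0}, [], "e", reversible=True)
    add_reaction("EX_B", {"B1": -1.0}, [], "e", reversible=True)
    add_reaction("BIOMASS", {"M8": -1.0}, [], "m")
    flux_a["BIOMASS"] = ua - ba
    flux_b["BIOMASS"] = ub

    pathways = {
        "pw_upper": ("upper backbone", frozenset({"RC1", "RC2", "RC3"})),
        "pw_lower": ("lower backbone", frozenset({"RC4", "RC5", "RT"})),
        "pw_x1": ("side branch in", frozenset({"RX1", "RX2"})),
        "pw_x2": ("side branch out", frozenset({"RX2", "RX3"})),
    }
    # pw_x1 metabolites {M1, X, M2}, pw_x2 {X, M2, M4}: overlap 2 / min 3.

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        pathways=pathways,
        biomass_reaction="BIOMASS",
        exchanges=frozenset({"EX_S", "EX_B"}),
    )
    model.validate()

    for rec in de_records:
        annotations[rec.gene_id] = rec.go_terms

    truth = {
        "planted_reporter_metabolite": "X",
        "planted_isozyme_reaction": "RX1",
        "planted_rho": planted_rho,
        "planted_disappeared": ["RB", "EX_B"],
        "planted_pathway_pair": ["pw_x1", "pw_x2", 2 / 3],
        "planted_smiles_near_pair": list(near_pair) if near_pair else None,
        "flux_a": flux_a,
        "flux_b": flux_b,
    }
    return model, annotations, de_records, truth


def _obo_text(config: SynthConfig) -> str:
    lines = [
        "format-version: 1.2",
        "ontology: synthetic",
        "",
    ]

    def term(tid: str, name: str, parent: str | None = None) -> None:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        if parent:
            lines.append(f"is_a: {parent}")
        lines.append("")

    term(_ROOT_BP, "biological_process")
    term(_ROOT_CC, "cellular_component")
    for i in range(config.n_decoy_terms):
        term(f"SYN:{100 + i:04d}", f"decoy process {i}", _ROOT_BP)
    term(PLANTED_GO_TERM, "planted enriched process", _ROOT_BP)
    term("GO:0005737", "cytoplasm", _ROOT_CC)
    term("GO:0005739", "mitochondrion", _ROOT_CC)
    return "\n".join(lines)


def generate_all(config: SynthConfig) -> SynthData:
    """Generate the full synthetic bundle (DE, model, ontology, rates, truth)."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    genome, truth_de = generate_de_table(config)
    model, model_annot, enzyme_records, truth_model = generate_model(config)

    # Annotate genome genes: decoy BP terms at random, the planted term on
    # a subset of the planted up-regulated genes.
    annotations: dict[str, frozenset[str]] = dict(model_annot)
    decoy_terms = [f"SYN:{100 + i:04d}" for i in range(config.n_decoy_terms)]
    new_genome: list[ExpressionRecord] = []
    planted_set = truth_de["planted_up"][: config.planted_go_size]
    for rec in genome:
        terms = set(rng.choice(decoy_terms, size=int(rng.integers(0, 3)), replace=False))
        if rec.gene_id in planted_set:
            terms.add(PLANTED_GO_TERM)
        terms = frozenset(terms)
        annotations[rec.gene_id] = terms
        new_genome.append(
            ExpressionRecord(**{**rec.__dict__, "go_terms": terms})
        )

    de = new_genome + enzyme_records
    rates_a = ExchangeMeasurement(
        condition="A",
        rates={"EX_S": -config.uptake_a, "EX_B": config.byproduct_a},
    )
    rates_b = ExchangeMeasurement(
        condition="B",
        rates={"EX_S": -config.uptake_b},
        fixed_zero=frozenset({"EX_B"}),
    )
    truth = {
        **truth_de,
        **truth_model,
        "planted_go_term": PLANTED_GO_TERM,
        "planted_go_genes": list(planted_set),
        "seed": config.seed,
    }
    return SynthData(
        de=de,
        model=model,
        annotations=annotations,
        obo_text=_obo_text(config),
        rates_a=rates_a,
        rates_b=rates_b,
        truth=truth,
    )


def generate_truth(config: SynthConfig) -> dict:
    """Ground truth of a generation run (deterministic given config.seed)."""
    return generate_all(config).truth


def write_synth(data: SynthData, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle to a directory; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "de": out / "de.tsv",
        "model": out / "model.json",
        "annot": out / "annot.tsv",
        "obo": out / "ontology.obo",
        "rates_a": out / "rates_a.json",
        "rates_b": out / "rates_b.json",
        "truth": out / "truth.json",
    }
    write_de_table(data.de, paths["de"])
    write_model(data.model, paths["model"])
    write_annotations(data.annotations, paths["annot"])
    paths["obo"].write_text(data.obo_text)
    write_rates(data.rates_a, paths["rates_a"])
    write_rates(data.rates_b, paths["rates_b"])
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=1)
    return paths
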