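import pytest

from compartomics import synth, tabio
from compartomics.tabio import (
    MetabolicModel,
    Metabolite,
    Reaction,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic input bundle (genome of 500 genes)."""
    cfg = synth.SynthConfig(seed=11, n_genes=500)
    return cfg, synth.generate_all(cfg)


@pytest.fixture()
def toy_model():
    """Three-reaction linear chain with a gene-shared branch.

    EX_S -> A -> B -> biomass, plus B -> C catalysed by a gene shared
    with the A -> B step; used for hand-enumerated adjacency checks.
    """
    mets = {
        m: Metabolite(id=m, name=m, smiles=s, compartment="c")
        for m, s in [("A", "CCO"), ("B", "CC"), ("C", "OCC")]
    }
    rxns = {
        "EX_S": Reaction(id="EX_S", stoichiometry={"A": -1.0}, reversible=True),
        "R1": Reaction(
            id="R1", stoichiometry={"A": -1.0, "B": 1.0}, genes=frozenset({"g1", "g2"})
        ),
        "R2": Reaction(
            id="R2", stoichiometry={"B": -1.0, "C": 1.0}, genes=frozenset({"g2", "g3"})
        ),
        "BIO": Reaction(id="BIO", stoichiometry={"C": -1.0}),
    }
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        pathways={"p1": ("chain", frozenset({"R1", "R2"}))},
        biomass_reaction="BIO",
        exchanges=frozenset({"EX_S"}),
    )
    model.validate()
    return model


def make_record(
    gene_id,
    q=0.5,
    log2_fc=0.0,
    value_a=10.0,
    value_b=None,
    q_cutoff=0.05,
    go_terms=(),
):
    """Convenience ExpressionRecord constructor for fixtures."""
    if value_b is None:
        value_b = value_a * 2.0**log2_fc
    return tabio.ExpressionRecord(
        gene_id=gene_id,
        value_a=value_a,
        value_b=value_b,
        log2_fc=log2_fc,
        p_value=q / 2,
        q_value=q,
        significant=q < q_cutoff,
        go_terms=frozenset(go_terms),
    )
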