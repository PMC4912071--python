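import itertools
import math

import numpy as np
import pytest

from compartomics import fluxreg, pathmaps
from compartomics.fluxreg import DifferentialFluxRecord, FluxState
from compartomics.tabio import (
    ExchangeMeasurement,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from conftest import make_record


def chain_model(n=3, reversible=(), with_drain=False):
    """EX -> M0 -> ... -> Mn -> biomass (optionally a drain exchange on Mn)."""
    mets = {f"M{i}": Metabolite(id=f"M{i}", compartment="c") for i in range(n + 1)}
    rxns = {"EX": Reaction(id="EX", stoichiometry={"M0": -1.0}, reversible=True)}
    for i in range(n):
        rid = f"R{i}"
        rxns[rid] = Reaction(
            id=rid,
            stoichiometry={f"M{i}": -1.0, f"M{i+1}": 1.0},
            reversible=rid in reversible,
        )
    rxns["BIO"] = Reaction(id="BIO", stoichiometry={f"M{n}": -1.0})
    exchanges = {"EX"}
    if with_drain:
        rxns["EX2"] = Reaction(id="EX2", stoichiometry={f"M{n}": -1.0})
        exchanges.add("EX2")
    return MetabolicModel(
        metabolites=mets, reactions=rxns, pathways={},
        biomass_reaction="BIO", exchanges=frozenset(exchanges),
    )


def random_branched_model(rng, n_mets=4, n_extra=4):
    """Random acyclic network: one fixed uptake, random forward reactions,
    random sink exchanges, biomass draining the last metabolite.  Acyclicity
    plus the fixed uptake keeps the LP bounded."""
    mets = {f"M{i}": Metabolite(id=f"M{i}", compartment="c") for i in range(n_mets)}
    rxns = {"EX_IN": Reaction(id="EX_IN", stoichiometry={"M0": -1.0},
                              reversible=True)}
    exchanges = {"EX_IN"}
    # Backbone to guarantee a substrate->biomass route.
    for i in range(n_mets - 1):
        rxns[f"B{i}"] = Reaction(
            id=f"B{i}",
            stoichiometry={f"M{i}": -1.0, f"M{i+1}": float(rng.integers(1, 3))},
        )
    for j in range(n_extra):
        i = int(rng.integers(0, n_mets - 1))
        k = int(rng.integers(i + 1, n_mets))
        rxns[f"X{j}"] = Reaction(
            id=f"X{j}",
            stoichiometry={
                f"M{i}": -float(rng.integers(1, 3)),
                f"M{k}": float(rng.integers(1, 3)),
            },
        )
    # A drain exchange on a random intermediate (left free).
    mid = int(rng.integers(1, n_mets))
    rxns["EX_OUT"] = Reaction(id="EX_OUT", stoichiometry={f"M{mid}": -1.0})
    exchanges.add("EX_OUT")
    rxns["BIO"] = Reaction(id="BIO", stoichiometry={f"M{n_mets-1}": -1.0})
    return MetabolicModel(
        metabolites=mets, reactions=rxns, pathways={},
        biomass_reaction="BIO", exchanges=frozenset(exchanges),
    )


def vertex_enumeration_max(model, measurements, box=1e3):
    """Brute-force LP oracle: enumerate vertices of {Sv=0, bounds} and
    return the maximal biomass flux.  Bounds are [0, box] (or [-box, box]
    for reversible reactions), with measured rates fixed."""
    rids = list(model.reactions)
    mids = list(model.metabolites)
    n, m = len(rids), len(mids)
    S = np.zeros((m, n))
    for j, rid in enumerate(rids):
        for mid_, c in model.reactions[rid].stoichiometry.items():
            S[mids.index(mid_), j] = c
    lb = np.array(
        [-box if model.reactions[r].reversible else 0.0 for r in rids]
    )
    ub = np.full(n, box)
    for r, rate in measurements.rates.items():
        j = rids.index(r)
        lb[j] = ub[j] = rate
    for r in measurements.fixed_zero:
        j = rids.index(r)
        lb[j] = ub[j] = 0.0
    rank = np.linalg.matrix_rank(S)
    free = n - rank
    obj = rids.index(model.biomass_reaction)
    best, best_v = -np.inf, None
    for fixed_idx in itertools.combinations(range(n), free):
        rest = [j for j in range(n) if j not in fixed_idx]
        A = S[:, rest]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed_idx]):
            b = -S[:, fixed_idx] @ np.array(bounds_choice)
            sol, residual, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            v = np.zeros(n)
            v[list(fixed_idx)] = bounds_choice
            v[rest] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            if v[obj] > best:
                best, best_v = v[obj], v
    return best, best_v


class TestFbaSolve:
    def test_linear_chain_conserves_uptake(self):
        model = chain_model()
        meas = ExchangeMeasurement(condition="A", rates={"EX": -10.0})
        state = fluxreg.fba_solve(model, meas)
        assert state.objective == pytest.approx(10.0, abs=1e-8)
        for rid in ("R0", "R1", "R2", "BIO"):
            assert state[rid] == pytest.approx(10.0, abs=1e-8)

    def test_zero_uptake_zeroes_all_fluxes(self):
        model = chain_model()
        meas = ExchangeMeasurement(
            condition="A", rates={}, fixed_zero=frozenset({"EX"})
        )
        state = fluxreg.fba_solve(model, meas)
        assert all(abs(v) < 1e-9 for v in state.fluxes.values())

    def test_negative_rate_on_irreversible_reaction_rejected(self):
        model = chain_model(with_drain=True)  # EX2 is irreversible
        meas = ExchangeMeasurement(condition="A", rates={"EX2": -5.0})
        with pytest.raises(fluxreg.FBAError, match="irreversible"):
            fluxreg.fba_solve(model, meas)

    def test_infeasible_measurements_name_binding_constraints(self):
        model = chain_model(with_drain=True)
        # Demand secretion at the chain end exceeding what uptake allows.
        meas = ExchangeMeasurement(
            condition="A", rates={"EX": -1.0, "EX2": 5.0}
        )
        with pytest.raises(fluxreg.FBAError, match="EX"):
            fluxreg.fba_solve(model, meas)

    def test_soft_mode_relaxes_infeasible_equalities(self):
        model = chain_model(with_drain=True)
        meas = ExchangeMeasurement(
            condition="A", rates={"EX": -10.0, "EX2": 10.4}
        )
        with pytest.raises(fluxreg.FBAError):
            fluxreg.fba_solve(model, meas)
        state = fluxreg.fba_solve(model, meas, soft=0.05)
        # Best biomass = widest uptake (10.5) minus smallest drain (9.88).
        assert state.objective == pytest.approx(10.0 * 1.05 - 10.4 * 0.95, abs=1e-6)

    def test_unbounded_detected(self):
        # Two coupled free exchanges let biomass grow without limit.
        mets = {"A": Metabolite(id="A")}
        rxns = {
            "EX1": Reaction(id="EX1", stoichiometry={"A": -1.0}, reversible=True),
            "BIO": Reaction(id="BIO", stoichiometry={"A": -1.0}),
        }
        model = MetabolicModel(
            metabolites=mets, reactions=rxns, pathways={},
            biomass_reaction="BIO", exchanges=frozenset({"EX1"}),
        )
        with pytest.raises(fluxreg.FBAError, match="unbounded"):
            fluxreg.fba_solve(
                model, ExchangeMeasurement(condition="A", rates={})
            )

    def test_matches_vertex_enumeration_oracle_on_random_models(self):
        rng = np.random.default_rng(12)
        tested = 0
        for trial in range(12):
            model = random_branched_model(rng)
            meas = ExchangeMeasurement(
                condition="T", rates={"EX_IN": -float(rng.integers(2, 12))}
            )
            oracle_obj, oracle_v = vertex_enumeration_max(model, meas)
            if oracle_v is None:
                continue
            assert np.max(np.abs(oracle_v)) < 990  # not at the artificial box
            state = fluxreg.fba_solve(model, meas)
            assert state.objective == pytest.approx(oracle_obj, abs=1e-6)
            # Parsimonious solution must satisfy Sv=0 and never carry more
            # total flux than the best optimal vertex.
            total = sum(abs(v) for v in state.fluxes.values())
            assert total <= np.abs(oracle_v).sum() + 1e-6
            tested += 1
        assert tested >= 8

    def test_mass_balance_invariant(self):
        rng = np.random.default_rng(3)
        model = random_branched_model(rng)
        meas = ExchangeMeasurement(condition="A", rates={"EX_IN": -7.0})
        state = fluxreg.fba_solve(model, meas)
        for mid in model.metabolites:
            net = sum(
                coeff * state[rid]
                for rid, rxn in model.reactions.items()
                for m2, coeff in rxn.stoichiometry.items()
                if m2 == mid
            )
            assert abs(net) < 1e-7
        for rid, rxn in model.reactions.items():
            if not rxn.reversible:
                assert state[rid] >= -1e-8


def fs(fluxes, condition="A"):
    return FluxState(condition=condition, fluxes=fluxes, objective=0.0)


class TestDifferentialFlux:
    @pytest.mark.parametrize(
        "ja,jb,expected",
        [
            (10.0, 9.5, "constitutive"),   # 5% < 10%
            (10.0, 15.0, "up"),
            (10.0, 6.0, "down"),
            (3.0, -2.0, "reversed"),       # direction change
            (2.7, 0.0, "disappeared"),     # product absent in condition B
            (0.0, 2.7, "appeared"),
            (0.0, 0.0, "zero_both"),
        ],
    )
    def test_classification_rules(self, ja, jb, expected):
        (rec,) = fluxreg.differential_flux(fs({"r": ja}), fs({"r": jb}))
        assert rec.klass == expected

    def test_log2_ratio_defined_only_for_nonzero_pairs(self):
        (rec,) = fluxreg.differential_flux(fs({"r": 4.0}), fs({"r": 8.0}))
        assert rec.log2_ratio == pytest.approx(1.0)
        (rec,) = fluxreg.differential_flux(fs({"r": 4.0}), fs({"r": 0.0}))
        assert math.isnan(rec.log2_ratio)

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(1)
        fluxes_a = {f"r{i}": float(rng.normal(0, 5)) for i in range(30)}
        fluxes_b = {f"r{i}": float(rng.normal(0, 5)) for i in range(30)}
        fwd = {
            r.reaction_id: r.klass
            for r in fluxreg.differential_flux(fs(fluxes_a), fs(fluxes_b))
        }
        rev = {
            r.reaction_id: r.klass
            for r in fluxreg.differential_flux(fs(fluxes_b), fs(fluxes_a))
        }
        swap = {
            "up": "down", "down": "up", "appeared": "disappeared",
            "disappeared": "appeared", "constitutive": "constitutive",
            "reversed": "reversed", "zero_both": "zero_both",
        }
        for rid in fwd:
            assert rev[rid] == swap[fwd[rid]]

    def test_mismatched_reaction_sets_rejected(self):
        with pytest.raises(ValueError):
            fluxreg.differential_flux(fs({"a": 1.0}), fs({"b": 1.0}))


def expr(total_a, total_b, significant=True, klass="up"):
    return pathmaps.ReactionExpression(
        reaction_id="r", genes=frozenset({"g"}), total_a=total_a,
        total_b=total_b, rep_log2_fc=1.0, any_significant=significant,
        klass=klass,
    )


def diff(ja, jb, klass):
    ratio = math.log2(abs(jb) / abs(ja)) if ja and jb else math.nan
    return DifferentialFluxRecord(
        reaction_id="r", j_a=ja, j_b=jb, klass=klass, log2_ratio=ratio
    )


class TestMra:
    def test_expression_and_flux_doubling_is_purely_hierarchical(self):
        rec = fluxreg.mra(diff(5.0, 10.0, "up"), expr(100.0, 200.0))
        assert rec.klass == "quantified"
        assert rec.rho_h == pytest.approx(1.0)
        assert rec.rho_m == pytest.approx(0.0)

    def test_flux_halving_with_flat_expression_is_purely_metabolic_share(self):
        rec = fluxreg.mra(diff(10.0, 5.0, "down"),
                          expr(100.0, 150.0, significant=False))
        assert rec.rho_h == pytest.approx(0.0)
        assert rec.rho_m == pytest.approx(1.0)

    def test_disappeared_flux_is_purely_metabolic_regardless_of_expression(self):
        rec = fluxreg.mra(diff(2.7, 0.0, "disappeared"), expr(100.0, 500.0))
        assert rec.klass == "purely_metabolic"
        assert (rec.rho_h, rec.rho_m) == (0.0, 1.0)

    def test_quantified_coefficients_sum_to_one_exactly(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            ja, jb = rng.uniform(0.5, 20, size=2)
            ea, eb = rng.uniform(10, 1000, size=2)
            rec = fluxreg.mra(diff(ja, jb, "up"), expr(ea, eb))
            if rec.klass == "quantified":
                assert rec.rho_h + rec.rho_m == pytest.approx(1.0, abs=1e-12)

    def test_reversed_and_zero_both_not_applicable(self):
        assert fluxreg.mra(diff(3.0, -2.0, "reversed"), expr(1, 2)).klass == (
            "not_applicable"
        )
        assert fluxreg.mra(diff(0.0, 0.0, "zero_both"), expr(1, 2)).klass == (
            "not_applicable"
        )

    def test_unchanged_flux_with_changed_expression_flagged(self):
        rec = fluxreg.mra(diff(5.0, 5.0, "constitutive"), expr(100.0, 400.0))
        assert rec.klass == "not_applicable"
        assert "0" in rec.note

    def test_missing_expression_not_applicable(self):
        assert fluxreg.mra(diff(5.0, 6.0, "up"), None).klass == "not_applicable"

    def test_parameter_recovery_on_scaled_synthetic_chain(self):
        # Fluxes scaled by f, transcripts by f^alpha -> rho_h == alpha.
        model = chain_model(n=4)
        f, alpha = 0.4, 0.65
        meas_a = ExchangeMeasurement(condition="A", rates={"EX": -10.0})
        meas_b = ExchangeMeasurement(condition="B", rates={"EX": -10.0 * f})
        state_a = fluxreg.fba_solve(model, meas_a)
        state_b = fluxreg.fba_solve(model, meas_b)
        de = {}
        expressions = {}
        for i, rid in enumerate(["R0", "R1", "R2", "R3"]):
            g = f"g{i}"
            base = 100.0 * (i + 1)
            de[g] = make_record(g, q=0.001, value_a=base, value_b=base * f**alpha,
                                log2_fc=math.log2(f**alpha))
            expressions[rid] = pathmaps.summarise_reaction(
                Reaction(id=rid, stoichiometry={}, genes=frozenset({g})), de
            )
        records = fluxreg.mra_all(
            fluxreg.differential_flux(state_a, state_b), expressions
        )
        quantified = [r for r in records if r.klass == "quantified"]
        assert len(quantified) == 4
        for rec in quantified:
            assert rec.rho_h == pytest.approx(alpha, abs=1e-9)
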