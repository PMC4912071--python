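"""Flux balance analysis, differential-flux classification, and MRA.

**FBA.**  Fluxes v maximise the biomass reaction subject to steady-state
mass balance (S v = 0), irreversibility bounds (v >= 0 for irreversible
reactions) and measured exchange rates imposed as equality constraints.
Because the biomass optimum rarely pins down every internal flux, a
parsimonious secondary objective (minimise the total absolute flux with
the biomass flux fixed at its optimum) is applied by default so reported
fluxes are reproducible.

**Differential flux.**  Fluxes are compared across two conditions: a flux
differing by less than 10% is constitutive; one vanishing (appearing) in
the second condition is disappeared (appeared); sign changes are reversed.

**Metabolic Regulation Analysis.**  A flux change factorises into a
hierarchical component rho_h = Δln(e)/Δln(J) — the part explained by a
changed enzyme level e, proxied by the summed transcript abundance of all
genes mapped to the reaction — and a metabolic component rho_m = 1 - rho_h
attributed to changed metabolite concentrations, obtained by difference.
Expression changes only count when at least one member gene is significant
(q < 0.05); otherwise Δln(e) is taken as 0.  A flux that vanishes entirely
is classed purely metabolic (rho_h = 0, rho_m = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .pathmaps import ReactionExpression
from .tabio import ExchangeMeasurement, MetabolicModel

__all__ = [
    "FluxState",
    "DifferentialFluxRecord",
    "MRARecord",
    "FBAError",
    "fba_solve",
    "differential_flux",
    "mra",
    "mra_all",
]

#: Fluxes below this magnitude (mmol h^-1 gDW^-1) count as zero.
ZERO_FLUX = 1e-6
#: Relative flux difference below which a flux is constitutive.
CONSTITUTIVE_TOLERANCE = 0.10


class FBAError(RuntimeError):
    """Infeasible or unbounded flux balance problem."""


@dataclass(frozen=True)
class FluxState:
    """One condition's flux distribution (mmol h^-1 gDW^-1)."""

    condition: str
    fluxes: Mapping[str, float]
    objective: float

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass(frozen=True)
class DifferentialFluxRecord:
    reaction_id: str
    j_a: float
    j_b: float
    klass: str  # up|down|constitutive|reversed|appeared|disappeared|zero_both
    log2_ratio: float  # log2(|j_b|/|j_a|), NaN when either flux is zero


@dataclass(frozen=True)
class MRARecord:
    reaction_id: str
    delta_ln_e: float
    delta_ln_j: float
    rho_h: float
    rho_m: float
    klass: str  # quantified | purely_metabolic | not_applicable
    note: str = ""


def _bounds(
    model: MetabolicModel,
    measurements: ExchangeMeasurement,
    soft: float | None,
) -> list[tuple[float | None, float | None]]:
    bounds: list[tuple[float | None, float | None]] = []
    for rid, rxn in model.reactions.items():
        lb = None if rxn.reversible else 0.0
        ub = None
        if rid in measurements.rates:
            rate = measurements.rates[rid]
            if rate < 0 and not rxn.reversible:
                raise FBAError(
                    f"measured rate {rate} for irreversible reaction {rid!r} "
                    "requires a negative flux"
                )
            if soft is None:
                lb = ub = rate
            else:
                lo, hi = sorted((rate * (1 - soft), rate * (1 + soft)))
                lb, ub = lo, hi
        elif rid in measurements.fixed_zero:
            lb = ub = 0.0
        bounds.append((lb, ub))
    return bounds


def fba_solve(
    model: MetabolicModel,
    measurements: ExchangeMeasurement,
    parsimonious: bool = True,
    soft: float | None = None,
) -> FluxState:
    """Maximise biomass flux subject to Sv=0, bounds and measured rates.

    ``soft`` relaxes measured-rate equalities to a +/- fractional band
    (e.g. 0.05) for measurement sets that are jointly infeasible.  With
    ``parsimonious`` (default) the total absolute flux is minimised after
    fixing the biomass optimum, making the reported distribution unique in
    practice.
    """
    measurements.validate(model)
    rids = list(model.reactions)
    mids = list(model.metabolites)
    n, m = len(rids), len(mids)
    S = np.zeros((m, n))
    midx = {mid: i for i, mid in enumerate(mids)}
    for j, rid in enumerate(rids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[midx[mid], j] = coeff
    bounds = _bounds(model, measurements, soft)
    c = np.zeros(n)
    c[rids.index(model.biomass_reaction)] = -1.0  # maximise biomass

    res = linprog(c, A_eq=S, b_eq=np.zeros(m), bounds=bounds, method="highs")
    if res.status == 2:
        binding = sorted(set(measurements.rates) | set(measurements.fixed_zero))
        raise FBAError(
            f"infeasible under measured constraints {binding}"
        )
    if res.status == 3:
        raise FBAError("unbounded: biomass flux is not limited by any constraint")
    if not res.success:
        raise FBAError(f"LP solver failure: {res.message}")
    objective = -res.fun
    v = res.x

    if parsimonious:
        # Stage 2: min sum |v| with v = p - q, biomass fixed at optimum.
        A_eq = np.hstack([S, -S])
        b_eq = np.zeros(m)
        split_bounds = []
        for j, rid in enumerate(rids):
            lb, ub = bounds[j]
            if rid == model.biomass_reaction:
                lb = ub = objective
            if lb is not None and ub is not None and lb == ub:
                if lb >= 0:
                    split_bounds.append(((lb, ub), (0.0, 0.0)))
                else:
                    split_bounds.append(((0.0, 0.0), (-ub, -lb)))
            else:
                pos_ub = ub if ub is None else max(ub, 0.0)
                neg_ub = 0.0 if lb == 0.0 else (None if lb is None else max(-lb, 0.0))
                split_bounds.append(((0.0, pos_ub), (0.0, neg_ub)))
        all_bounds = [b[0] for b in split_bounds] + [b[1] for b in split_bounds]
        res2 = linprog(
            np.ones(2 * n),
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=all_bounds,
            method="highs",
        )
        if res2.success:
            v = res2.x[:n] - res2.x[n:]

    fluxes = {rid: float(v[j]) for j, rid in enumerate(rids)}
    return FluxState(
        condition=measurements.condition, fluxes=fluxes, objective=float(objective)
    )


def differential_flux(
    state_a: FluxState,
    state_b: FluxState,
    tolerance: float = CONSTITUTIVE_TOLERANCE,
    zero_tol: float = ZERO_FLUX,
) -> list[DifferentialFluxRecord]:
    """Classify each reaction's flux change between two conditions."""
    if set(state_a.fluxes) != set(state_b.fluxes):
        raise ValueError("flux states cover different reaction sets")
    records = []
    for rid in state_a.fluxes:
        ja, jb = state_a[rid], state_b[rid]
        za, zb = abs(ja) < zero_tol, abs(jb) < zero_tol
        log2_ratio = (
            math.log2(abs(jb) / abs(ja)) if not (za or zb) else math.nan
        )
        if za and zb:
            klass = "zero_both"
        elif za:
            klass = "appeared"
        elif zb:
            klass = "disappeared"
        elif (ja > 0) != (jb > 0):
            klass = "reversed"
        elif abs(jb - ja) / max(abs(ja), abs(jb)) < tolerance:
            klass = "constitutive"
        elif abs(jb) > abs(ja):
            klass = "up"
        else:
            klass = "down"
        records.append(
            DifferentialFluxRecord(
                reaction_id=rid, j_a=ja, j_b=jb, klass=klass, log2_ratio=log2_ratio
            )
        )
    return records


#: |Δln J| below which the hierarchical ratio is numerically undefined.
_LN_J_EPS = 1e-9


def mra(
    diff: DifferentialFluxRecord,
    expr: ReactionExpression | None,
) -> MRARecord:
    """Metabolic Regulation Analysis of one reaction.

    Quantified when both fluxes are nonzero with the same sign and
    |Δln J| is not ~0: rho_h = Δln(e)/Δln(J), rho_m = 1 - rho_h, with
    Δln(e) = ln(total_b/total_a) of summed member transcripts, zeroed
    when no member gene is significant.  A vanished (or newly appeared)
    flux is purely metabolic; reversed or doubly-zero fluxes, and
    reactions without usable expression totals, are not applicable.
    """
    rid = diff.reaction_id
    if diff.klass in ("disappeared", "appeared"):
        de = _delta_ln_e(expr)
        return MRARecord(
            reaction_id=rid,
            delta_ln_e=de if de is not None else math.nan,
            delta_ln_j=math.nan,
            rho_h=0.0,
            rho_m=1.0,
            klass="purely_metabolic",
            note=f"flux {diff.klass}",
        )
    if diff.klass in ("reversed", "zero_both"):
        return MRARecord(
            reaction_id=rid,
            delta_ln_e=math.nan,
            delta_ln_j=math.nan,
            rho_h=math.nan,
            rho_m=math.nan,
            klass="not_applicable",
            note=f"flux {diff.klass}",
        )
    delta_ln_e = _delta_ln_e(expr)
    if delta_ln_e is None:
        return MRARecord(
            reaction_id=rid,
            delta_ln_e=math.nan,
            delta_ln_j=math.nan,
            rho_h=math.nan,
            rho_m=math.nan,
            klass="not_applicable",
            note="no usable expression totals",
        )
    delta_ln_j = math.log(abs(diff.j_b) / abs(diff.j_a))
    if abs(delta_ln_j) < _LN_J_EPS:
        return MRARecord(
            reaction_id=rid,
            delta_ln_e=delta_ln_e,
            delta_ln_j=delta_ln_j,
            rho_h=math.nan,
            rho_m=math.nan,
            klass="not_applicable",
            note="flux unchanged (division by ~0)",
        )
    rho_h = delta_ln_e / delta_ln_j
    return MRARecord(
        reaction_id=rid,
        delta_ln_e=delta_ln_e,
        delta_ln_j=delta_ln_j,
        rho_h=rho_h,
        rho_m=1.0 - rho_h,
        klass="quantified",
    )


def _delta_ln_e(expr: ReactionExpression | None) -> float | None:
    """ln expression-total ratio; 0 when not significant; None when unusable."""
    if expr is None or expr.klass == "no_gene":
        return None
    if not expr.any_significant:
        return 0.0
    if expr.total_a <= 0 or expr.total_b <= 0:
        return None
    return math.log(expr.total_b / expr.total_a)


def mra_all(
    diff_records: Sequence[DifferentialFluxRecord],
    expressions: Mapping[str, ReactionExpression],
) -> list[MRARecord]:
    """MRA over a whole differential-flux table."""
    return [mra(d, expressions.get(d.reaction_id)) for d in diff_records]
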