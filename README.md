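# compartomics

Compartment-aware integrative analysis of two-condition RNA-seq data
against a metabolic model: bootstrap-calibrated gene-set enrichment,
reporter-metabolite scoring, pathway/molecular/metabolite–enzyme network
projections, flux balance analysis with differential-flux classification,
and metabolic regulation analysis.

## Who this is for

Microbial systems biologists comparing a reference and a perturbed
condition (say, growth on glucose vs an alternative sugar) who have a
CuffDiff-style differential-expression table, GO annotations and a
stoichiometric model, and want to answer, in one reproducible pipeline:

* which gene sets, pathways and metabolite neighbourhoods respond;
* how the response resolves across subcellular compartments, including
  isozyme switching (paralogs of one reaction regulated in opposite
  directions);
* how estimated metabolic fluxes change, and how much of each flux change
  is explained by gene expression versus metabolite levels.

## The statistics at its core

**Enrichment score.** Per-gene q-values are converted to standard-normal
deviates, Z = −Φ⁻¹(q), and summed over a gene set. The null is calibrated
empirically: random same-size sets are drawn from the analysed universe
(1000 bootstrap iterations by default) and

    S = (Z_total − mean(Z_background)) / sd(Z_background).

Under the null S ≈ N(0, 1), so S ≥ 1.64 corresponds to one-sided p = 0.05.
Reporter metabolites use the same score on the genes of every reaction a
metabolite participates in, with the background drawn from enzyme-encoding
genes only (metabolic genes are collectively more differentially expressed
than the genome, and a genome-wide background would inflate every
metabolite's score).

**Metabolic regulation analysis (MRA).** Each flux change factorises into
a hierarchical and a metabolic component,

    1 = ρ_h + ρ_m,    ρ_h = Δln(e) / Δln(J),

where J is the reaction's flux (estimated by FBA under measured exchange
rates) and e its enzyme level, proxied by the summed transcript abundance
of all genes mapped to the reaction. ρ_m is obtained by difference. A flux
that vanishes entirely between conditions is classed purely metabolic;
fluxes differing by less than 10% are constitutive.

## Worked example

Everything runs on a bundled synthetic generator whose defaults mirror a
realistic study: ~5000 genes with planted up/down-regulated fractions, a
two-compartment metabolic model with a substrate→biomass backbone,
a byproduct branch that shuts off in condition B, and a planted reporter
metabolite.

```python
from compartomics import synth, enrichment as enr, reporter, fluxreg, pathmaps

cfg = synth.SynthConfig(seed=7)
data = synth.generate_all(cfg)
de = {r.gene_id: r for r in data.de}
zmap = enr.zmap_from_records(data.de)

scores = reporter.reporter_scores(data.model, zmap, de, n_boot=1000, seed=7)
for s in sorted(scores, key=lambda s: -s.score)[:3]:
    print(f"{s.metabolite_id:>4} k={s.k} score={s.score:.2f} "
          f"up={s.n_up} down={s.n_down}")

state_a = fluxreg.fba_solve(data.model, data.rates_a)
state_b = fluxreg.fba_solve(data.model, data.rates_b)
print("biomass:", state_a.objective, state_b.objective)

diff = fluxreg.differential_flux(state_a, state_b)
for m in fluxreg.mra_all(diff, pathmaps.summarise_model(data.model, de)):
    if m.reaction_id in ("RC1", "RB"):
        print(m.reaction_id, m.klass, m.rho_h, m.rho_m)
```

prints

```
   X k=9 score=5.05 up=8 down=1
  M2 k=6 score=3.94 up=3 down=3
  M4 k=6 score=3.94 up=3 down=3
biomass: 7.4 5.0
RC1 quantified 0.7 0.30000000000000004
RB purely_metabolic 0.0 1.0
```

The planted reporter metabolite `X` tops the table (its nine neighbouring
enzyme genes are all significantly regulated, eight upward — hence the
high score and dominant direction). FBA reproduces the configured
physiology (biomass flux 7.4 on 9.4 units of uptake with 2.0 diverted to
the byproduct; 5.0 in condition B), the backbone reaction `RC1` recovers
the planted hierarchical coefficient ρ_h = 0.7 exactly, and the byproduct
reaction `RB`, whose flux vanishes in condition B, is classed purely
metabolic.

The same pipeline runs from the shell:

```sh
compartomics simulate --seed 7 --out-dir run/in
compartomics run-all --config run/config.json --out-dir run/out
```

where the config lists the input paths, thresholds and seed; `run-all`
writes one TSV/GraphML per stage plus a `manifest.json` with seeds,
thresholds and per-stage row counts.

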