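# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does not
emulate, and the known limitations.

## Gene-level statistics

Input is a two-condition differential-expression table with per-gene
abundances, a log2 fold change and a multiple-testing-corrected q-value.
Significance is always recomputed as q < 0.05 at load time; a
`significant` column in the file is ignored (disagreements are counted and
logged) so that one rule governs every downstream stage. When both
abundances are positive the log2 fold change is recomputed from them,
since the ratio of the stored abundances is the quantity every downstream
colouring and totalling step uses; the file's column is used only as a
fallback when an abundance is zero.

q-values are converted to Z-scores as Z = −Φ⁻¹(q), clamped to
q ∈ [1e-12, 1−1e-12] so Z stays finite (DE callers floor their q-values
anyway; the clamp only guards pathological 0/1 inputs). Z is
non-directional: direction is carried separately as counts of significant
up/down members (n_up, n_down) and a dominant-direction fraction, which
is the information a rendering needs for colour and brightness.

## Bootstrap-calibrated enrichment

A gene set's statistic is the sum of member Z-scores, deduplicated and
intersected with the analysed universe first. The null is estimated by
drawing random same-size subsets **without replacement** from the
universe — a gene set cannot contain a gene twice, and the exhaustive
enumeration oracle in the test suite fixes this convention — with 1000
iterations by default. The score is the standardised total,
S = (Z_total − μ_k)/σ_k. Backgrounds are computed at every distinct
observed set size k (no interpolation; at desk scale the number of
distinct sizes is small) and the per-k random streams are derived
independently from (seed, k), so results do not depend on the order in
which sets are evaluated. When σ_k = 0 (degenerate universe) the score is
reported as NaN and flagged rather than ±∞.

Ontology gene sets are the union of annotations over a term and all its
`is_a` descendants (the more specific terms): that is the direction that
lets a slim ontology's broad terms collect the signal of specialised
annotations. The ontology reader honours only `[Term]`, `id:`, `name:`,
`is_a:` and `is_obsolete:`; dangling `is_a` references are dropped with a
warning because slim subsets routinely cite absent parents, and a cyclic
closure is a hard error.

The default enrichment universe is every gene with a q-value, annotated
or not; an annotated-only universe is available (`--universe annotated`).
No multiple-testing correction is applied across sets — the score is
interpreted against the conventional one-sided 1.64 cutoff, and there is
no generally accepted correction for overlapping, hierarchically nested
gene sets.

## Reporter metabolites

A metabolite's gene set is the union of genes over every reaction whose
stoichiometry involves it, either side, deduplicated (neighbourhoods are
sets, so duplicating a reaction in the model cannot change a score). The
background universe is restricted to genes mapped to at least one
reaction. Compartment-tagged metabolite instances are scored separately
by default (the compartmentalised response is the point), with an option
to merge instances by base id. Currency metabolites (ATP, NAD(H), water…)
are **not** excluded by default — their scores are informative — but an
opt-in exclusion list is supported. Thresholds: 1.64 for "enriched", 3.0
for the focused metabolite–enzyme network, q < 0.05 for the enzyme genes
included in that network.

## Network constructions

* **Pathway overlap**: weight(a, b) = |Ma ∩ Mb| / min(|Ma|, |Mb|) over
  compartment-stripped metabolite ids (pathway databases are largely
  compartment-naïve, and stripping prevents cytosolic/mitochondrial
  instances of one compound from never matching). Edges below the
  threshold (default 0.3, a rendering choice) are dropped; pathways left
  isolated attach to a designated `Self` node so no pathway disappears
  from the picture.
* **Molecular similarity**: similarity = 1 − d/max(|s1|, |s2|) with d the
  Levenshtein distance between raw SMILES strings — deliberately a
  string-level criterion, with no canonicalisation or fingerprinting.
  Each molecule links only to its single closest partner (ties broken
  lexicographically by partner id; reciprocal closest pairs merge into
  one undirected edge); molecules whose best similarity falls below 0.4,
  or which lack a SMILES, attach to `Self`.

## Pathway-map summaries

A reaction pools all genes mapped to it. The colouring scheme reports the
member gene with the **largest-magnitude** log2 fold change, sign
preserved (a reaction whose strongest change is a down-regulation colours
down). Classification: `isozyme_switching` requires significant genes in
*both* directions; a single significant gene among constitutive paralogs
takes that gene's direction. Compartment assignment maps each gene
through all of its GO cellular_component terms, so multi-localised genes
appear in every mapped compartment view — including genes annotated to
both a membrane and an organelle, which appear in both. A compartment
view re-summarises each reaction using only genes assigned to the target
compartment, which is how an apparently isozyme-switching reaction
resolves into clean per-compartment calls.

## Flux balance analysis

Fluxes maximise the biomass reaction subject to S·v = 0, irreversibility
(v ≥ 0), and measured exchange rates imposed as **equality** constraints
(the measurements are part of the experiment, not bounds to explore); a
`--soft` mode relaxes them to ±5% bands for jointly infeasible
measurement sets. Exchange convention: an exchange reaction has
single-metabolite stoichiometry {met: −1}, positive flux exports, so
uptake rates are negative. Because the biomass optimum rarely pins down
internal fluxes, a parsimonious secondary objective — minimise Σ|v| with
the biomass flux fixed at its optimum — is applied by default, making
reported distributions reproducible across solvers. The LP is solved with
HiGHS via `scipy.optimize.linprog`. Fluxes below 1e-6 (rate units) count
as zero — the LP noise floor — and mass-balance residuals are verified to
1e-8 in the test suite.

Differential-flux classes: `constitutive` when both fluxes are nonzero,
same-signed and differ by less than 10% relative to the larger magnitude;
`reversed` when signs differ; `appeared`/`disappeared` against the
near-zero threshold; otherwise `up`/`down` by magnitude. The
classification is antisymmetric under swapping the conditions.

## Metabolic regulation analysis

For a reaction with nonzero, same-signed fluxes in both conditions,
ρ_h = Δln(e)/Δln(J) with e the summed transcript abundance over all genes
mapped to the reaction (isozymes from paralogs or multifunctional
proteins) — summing makes the estimate robust to annotation errors in
minor paralogs, whose low abundances cannot dominate the total. ρ_m is
obtained by difference from 1 = ρ_h + ρ_m; the per-metabolite elasticity
decomposition of ρ_m is out of scope. Rules:

* expression counts only when at least one member gene is significant
  (q < 0.05); otherwise Δln(e) is set to 0, so a constitutive enzyme with
  a changed flux reads as purely metabolic regulation rather than noise;
* a `disappeared` flux is purely metabolic (ρ_h = 0, ρ_m = 1) regardless
  of expression — no finite ln-ratio exists and the shutdown is driven by
  substrate/product availability. `appeared` fluxes are treated
  symmetrically, which is forced by the requirement that the analysis be
  antisymmetric under swapping the conditions;
* `reversed` and doubly-zero fluxes, reactions without usable expression
  totals, and fluxes with |Δln J| < 1e-9 (division by ~0) are
  `not_applicable`, the last with a diagnostic note.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical structure* each stage assumes,
at genome scale: ~4953 genes of which each is independently null
(q ~ Uniform(0,1), log2 FC ~ N(0, 0.3)) or planted up/down with
probabilities matching 329 up- and 251 down-regulated genes; planted
genes get q-values with an exponential tail below 0.05 (floored at 0.001,
as DE callers floor their q-values) and |log2 FC| ~ N(3, 1.5) truncated
at 0.5; abundances are reconstructed as (base, base·2^FC) with lognormal
bases. The model couples a substrate uptake of 9.4 (condition A) or 5.0
(condition B) rate units through a two-compartment backbone into biomass,
with a byproduct secretion of 2.0 in condition A only — mirroring a
respiro-fermentative reference condition and a purely respiratory
perturbed condition. Backbone transcripts are scaled by the per-reaction
flux ratio raised to the power 0.7, so the planted hierarchical
coefficient is exactly ρ_h = 0.7. A dead-end side branch (three reactions,
nine strongly regulated genes) plants the top reporter metabolite and an
isozyme-switching reaction; thirty dead-end decoy reactions with
non-significant genes populate the enzyme background; two pathway pairs
plant a 2/3 overlap edge; metabolite SMILES are random strings over a
small alphabet with one planted near-duplicate pair.

What it does **not** emulate: count-level RNA-seq noise and the
dependence structure of a real DE caller (q-values are drawn directly,
keeping the null exactly uniform); chemically valid SMILES; genome-scale
network topology, cofactor stoichiometry or realistic biomass
composition. Passing tests therefore demonstrate the correctness and
calibration of the *methods* under their stated assumptions, not the
biological accuracy of any particular genome-scale result.

## Problem sizes and determinism

Default test and acceptance runs use a 4953–5000 gene universe, 500
random sets with 1000 bootstrap iterations for null calibration, a
45-reaction synthetic model, brute-force LP oracles on ≤8-reaction
instances and exhaustive subset enumeration on ≤10-gene universes —
sizes chosen so the full suite completes in well under a minute while
every oracle remains exactly enumerable. All randomness flows from a
single integer seed through independent named substreams, so every
table, network and manifest is reproducible bit-for-bit.

## Known limitations

* FBA alternate optima are resolved by parsimony, which is a convention,
  not a biological claim; flux variability analysis is out of scope.
* The transcript proxy for enzyme level ignores translational and
  post-translational regulation; ρ_h is an estimate of genetic-level
  regulation under that proxy.
* String-level SMILES similarity is sensitive to atom ordering and
  aromatic notation; it is a deliberate, cheap clustering criterion, not
  a chemical similarity measure.
* The enrichment score's normal calibration degrades for very small sets
  (k ≤ 2) and for universes with heavy-tailed Z distributions; the
  bootstrap background absorbs most but not all of this.
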