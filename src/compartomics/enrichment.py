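"""Bootstrap-calibrated gene-set enrichment.

Per-gene differential-expression q-values are converted to standard-normal
deviates, Z = -Phi^-1(q), so that small q-values map to large positive Z.
A gene set's observed statistic is the sum of its members' Z.  The null is
calibrated empirically: random same-size gene sets are drawn (without
replacement) from the analysed universe, and the set's enrichment score is

    S = (Z_total - mean_background) / sd_background,

i.e. how many null standard deviations the observed total lies above the
random expectation.  Under the null, S is approximately standard normal,
so the conventional one-sided 5% cutoff is S >= 1.64.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .tabio import ExpressionRecord

__all__ = [
    "Q_CLAMP",
    "DEFAULT_SCORE_CUTOFF",
    "BackgroundTable",
    "EnrichmentResult",
    "q_to_z",
    "zmap_from_records",
    "go_gene_set",
    "background_stats",
    "enrichment_score",
    "enrich_all",
]

#: q-values are clamped to [Q_CLAMP, 1 - Q_CLAMP] before the normal
#: quantile transform so that Z stays finite (DE callers floor q anyway).
Q_CLAMP = 1e-12

#: One-sided standard-normal 5% cutoff used throughout.
DEFAULT_SCORE_CUTOFF = 1.64


def q_to_z(q):
    """Convert q-value(s) to Z-scores, Z = -Phi^-1(clamped q).

    Accepts a scalar or array; monotonically non-increasing in q;
    ``q_to_z(0.5) == 0``.  Raises for q outside [0, 1].
    """
    arr = np.asarray(q, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("q-values must lie in [0, 1]")
    z = -stats.norm.ppf(np.clip(arr, Q_CLAMP, 1 - Q_CLAMP))
    if np.isscalar(q) or arr.ndim == 0:
        return float(z)
    return z


def zmap_from_records(records: Iterable[ExpressionRecord]) -> dict[str, float]:
    """Per-gene Z-scores for every gene with a q-value."""
    return {r.gene_id: q_to_z(r.q_value) for r in records}


def go_gene_set(
    term_id: str,
    ontology: nx.DiGraph,
    annotations: Mapping[str, Iterable[str]],
) -> frozenset[str]:
    """Genes annotated to a term or to any of its is_a descendants.

    The ontology graph has child→parent edges, so the descendants of
    ``term_id`` (more specific terms) are exactly the nodes from which
    ``term_id`` is reachable.  Genes are deduplicated across terms.
    """
    if term_id not in ontology:
        raise KeyError(f"unknown ontology term {term_id!r}")
    terms = {term_id} | nx.ancestors(ontology, term_id)
    genes: set[str] = set()
    for gene, gene_terms in annotations.items():
        if not terms.isdisjoint(gene_terms):
            genes.add(gene)
    return frozenset(genes)


@dataclass(frozen=True)
class BackgroundTable:
    """Null mean/sd of the total Z over random gene sets, per set size."""

    stats: Mapping[int, tuple[float, float]]  # k -> (mean, sd)
    n_boot: int
    seed: int
    universe_label: str = "all_genes"

    def __getitem__(self, k: int) -> tuple[float, float]:
        return self.stats[k]

    def __contains__(self, k: int) -> bool:
        return k in self.stats


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    k: int
    total_z: float
    bg_mean: float
    bg_sd: float
    score: float  # NaN when bg_sd == 0 (undefined, flagged)
    n_up: int
    n_down: int
    flagged: bool = False

    @property
    def dominant_fraction(self) -> float:
        """Fraction of significant members regulated in the majority
        direction; NaN when the set has no significant member."""
        total = self.n_up + self.n_down
        if total == 0:
            return math.nan
        return max(self.n_up, self.n_down) / total


def _rng_for_k(seed: int, k: int) -> np.random.Generator:
    # Independent stream per set size so results do not depend on the
    # order in which sets are evaluated.
    return np.random.default_rng(np.random.SeedSequence((seed, k)))


def background_stats(
    zmap: Mapping[str, float],
    sizes: Iterable[int],
    n_boot: int,
    seed: int,
    universe: Iterable[str] | None = None,
    universe_label: str = "all_genes",
) -> BackgroundTable:
    """Bootstrap null mean and sd of total Z at each requested set size.

    For each size k, ``n_boot`` random size-k subsets are drawn without
    replacement from the universe and their total Z recorded.  The draw is
    deterministic given ``seed`` and independent per k.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if universe is None:
        universe = zmap.keys()
    z = np.array([zmap[g] for g in sorted(universe)], dtype=float)
    n = z.size
    table: dict[int, tuple[float, float]] = {}
    for k in sorted(set(int(k) for k in sizes)):
        if k < 1 or k > n:
            raise ValueError(f"set size {k} exceeds universe size {n}")
        rng = _rng_for_k(seed, k)
        if k == n:
            totals = np.full(n_boot, z.sum())
        else:
            # Random k-subsets via per-row random keys; O(n_boot * n).
            keys = rng.random((n_boot, n))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            totals = z[idx].sum(axis=1)
        table[k] = (float(totals.mean()), float(totals.std()))
    return BackgroundTable(
        stats=table, n_boot=n_boot, seed=seed, universe_label=universe_label
    )


def enrichment_score(
    member_genes: Iterable[str],
    zmap: Mapping[str, float],
    background: BackgroundTable,
    de: Mapping[str, ExpressionRecord] | None = None,
    set_id: str = "",
    name: str = "",
) -> EnrichmentResult:
    """Score one gene set against the bootstrap background.

    Members outside the Z-map domain are dropped before scoring.  When the
    background sd is zero the score is undefined and reported as NaN.
    ``n_up``/``n_down`` count significant members by fold-change sign.
    """
    members = sorted(set(member_genes) & set(zmap))
    k = len(members)
    total_z = float(sum(zmap[g] for g in members))
    bg_mean, bg_sd = background[k]
    score = (total_z - bg_mean) / bg_sd if bg_sd > 0 else math.nan
    n_up = n_down = 0
    if de is not None:
        for g in members:
            rec = de.get(g)
            if rec is not None and rec.significant:
                if rec.log2_fc > 0:
                    n_up += 1
                elif rec.log2_fc < 0:
                    n_down += 1
    return EnrichmentResult(
        set_id=set_id,
        name=name,
        k=k,
        total_z=total_z,
        bg_mean=bg_mean,
        bg_sd=bg_sd,
        score=score,
        n_up=n_up,
        n_down=n_down,
    )


def enrich_all(
    sets: Mapping[str, Iterable[str]],
    zmap: Mapping[str, float],
    de: Mapping[str, ExpressionRecord] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    significance_cutoff: float = DEFAULT_SCORE_CUTOFF,
    universe: Iterable[str] | None = None,
    universe_label: str = "all_genes",
    names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Score a collection of gene sets, sharing backgrounds by set size.

    Empty sets (after intersection with the Z-map domain) are skipped with
    a warning.  Each result is flagged when ``score >= significance_cutoff``.
    """
    universe_set = (
        set(universe) & set(zmap) if universe is not None else set(zmap)
    )
    effective: dict[str, set[str]] = {}
    for sid, genes in sets.items():
        members = set(genes) & universe_set
        if not members:
            warnings.warn(f"skipping empty gene set {sid!r}", stacklevel=2)
            continue
        effective[sid] = members
    sizes = {len(m) for m in effective.values()}
    if not sizes:
        return []
    background = background_stats(
        zmap, sizes, n_boot=n_boot, seed=seed,
        universe=universe_set, universe_label=universe_label,
    )
    results = []
    for sid, members in effective.items():
        res = enrichment_score(
            members, zmap, background, de=de, set_id=sid,
            name=(names or {}).get(sid, sid),
        )
        flagged = (not math.isnan(res.score)) and res.score >= significance_cutoff
        results.append(
            EnrichmentResult(**{**res.__dict__, "flagged": flagged})
        )
    return results
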