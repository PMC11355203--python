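"""Hypergeometric COI-enrichment testing, power surface, and generic ORA.

The gene-burden test asks, for each gene, whether the fraction of its
ClinVar records that ever carried the COI status is higher than expected
under random allocation of the universe's COI records.  With

* ``N`` — total variant records across all whitelisted genes (a variant in
  several genes counts once per gene assignment),
* ``K`` — ever-COI records among them,
* ``n`` — records in the gene, ``k`` — ever-COI records in the gene,

the p-value is the upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).
Benjamini–Hochberg adjustment is applied across the genes actually tested
(those with at least one ever-COI variant); a gene is called enriched when
its adjusted value is at or below alpha.

The power surface evaluates the same test over a grid of gene sizes n and
COI percentages, at fixed universe (N, K), answering "how large must a
gene's COI excess be before the test can see it".

`ora` reuses the identical machinery for over-representation analysis of a
query gene list against named gene sets (GMT collections).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .clinvar_io import VariantKey
from .timeline import VariantTimeline

__all__ = [
    "GeneEnrichmentResult",
    "PowerCell",
    "OraResult",
    "hypergeom_upper",
    "bh_adjust",
    "gene_enrichment",
    "power_grid",
    "ora",
]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), X ~ HG(N, K, n).

    Computed through the survival function, so it stays accurate deep in
    the tail.  Returns a value in (0, 1]; k = 0 gives exactly 1.
    """
    if not 0 <= k <= n:
        raise ValueError(f"required 0 <= k <= n, got k={k}, n={n}")
    if not n <= N:
        raise ValueError(f"required n <= N, got n={n}, N={N}")
    if not 0 <= K <= N:
        raise ValueError(f"required 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        raise ValueError(f"required k <= K, got k={k}, K={K}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    pvals = list(pvals)
    if not pvals:
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return [float(q) for q in multipletests(arr, method="fdr_bh")[1]]


@dataclass(frozen=True, slots=True)
class GeneEnrichmentResult:
    """Per-gene burden test outcome."""

    gene: str
    n: int  # variants in gene
    k: int  # ever-COI variants in gene
    p: float
    q: float
    enriched: bool


def gene_enrichment(
    timelines: Mapping[VariantKey, VariantTimeline],
    gene_index: Mapping[VariantKey, Iterable[str]] | None = None,
    alpha: float = 0.05,
) -> list[GeneEnrichmentResult]:
    """Per-gene upper-tail hypergeometric test for COI excess, with BH FDR.

    *gene_index* overrides the gene assignment stored on the timelines;
    by default each timeline's own gene set is used.  N and K span the
    whole universe; BH runs across exactly the genes with >= 1 ever-COI
    variant.  Results are sorted by ascending p.
    """
    gene_n: dict[str, int] = {}
    gene_k: dict[str, int] = {}
    N = 0
    K = 0
    for key, tl in timelines.items():
        genes = gene_index[key] if gene_index is not None else tl.genes
        for g in genes:
            gene_n[g] = gene_n.get(g, 0) + 1
            N += 1
            if tl.ever_coi:
                gene_k[g] = gene_k.get(g, 0) + 1
                K += 1
    if K == 0:
        import warnings

        warnings.warn("no ever-COI variants in universe; nothing to test")
        return []

    tested = sorted(gene_k)
    pvals = [hypergeom_upper(N, K, gene_n[g], gene_k[g]) for g in tested]
    qvals = bh_adjust(pvals)
    results = [
        GeneEnrichmentResult(
            gene=g, n=gene_n[g], k=gene_k[g], p=p, q=q,
            enriched=bool(q <= alpha),
        )
        for g, p, q in zip(tested, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.gene))
    return results


@dataclass(frozen=True, slots=True)
class PowerCell:
    """One point of the analytic power surface."""

    n: int
    pct: float
    k: int
    p: float


def power_grid(
    N: int,
    K: int,
    n_range: Sequence[int],
    pct_range: Sequence[float],
) -> list[PowerCell]:
    """Expected p-value over a (gene size, COI percentage) grid.

    For each cell the implied COI count is k = round(n * pct / 100)
    (banker's rounding), clipped to the universe's K, and the p-value is
    the upper-tail test at (N, K, n, k).
    """
    if not len(n_range) or not len(pct_range):
        raise ValueError("n_range and pct_range must be non-empty")
    cells = []
    for pct in pct_range:
        if not 0 <= pct <= 100:
            raise ValueError(f"percentage out of range: {pct}")
    for n in n_range:
        for pct in pct_range:
            k = min(round(n * pct / 100.0), n, K)
            cells.append(PowerCell(n=int(n), pct=float(pct), k=k,
                                   p=hypergeom_upper(N, K, n, k)))
    return cells


@dataclass(frozen=True, slots=True)
class OraResult:
    """Over-representation of a query gene list in one named set."""

    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    q: float


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[OraResult]:
    """Hypergeometric over-representation of *query* in each gene set.

    Sets are first intersected with the universe; BH adjustment runs
    across all tested sets.  Results sorted by ascending p.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(
            f"query genes outside universe: {sorted(stray)[:10]}"
        )
    if not collections:
        raise ValueError("no gene-set collections supplied")
    names, overlaps, set_sizes, pvals = [], [], [], []
    for name, members in collections.items():
        members = set(members) & universe
        overlap = len(members & query)
        names.append(name)
        overlaps.append(overlap)
        set_sizes.append(len(members))
        pvals.append(
            hypergeom_upper(len(universe), len(members), len(query), overlap)
            if members
            else 1.0
        )
    qvals = bh_adjust(pvals)
    results = [
        OraResult(
            set_name=name,
            overlap=ov,
            set_size=sz,
            query_size=len(query),
            universe_size=len(universe),
            p=p,
            q=q,
        )
        for name, ov, sz, p, q in zip(names, overlaps, set_sizes, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results
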