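"""Gene-level features joined to COI grouping, and group comparisons.

Genes are grouped by their conflict burden into ``no_coi`` (no variant
ever carried the COI status), ``ge1_coi`` (at least one such variant) and
``enriched`` (significant COI excess per the gene-burden test).  The
comparison battery then contrasts structural and constraint features
between groups:

* continuous features (canonical transcript length, exon count, number of
  associated disorders, LOEUF, expressed-isoform count) — unpaired
  two-sided Wilcoxon rank-sum;
* inheritance modes (AD / AR / XL / other, one count per gene-mode link)
  — chi-squared on the group x mode contingency table.

For small samples (combined n below 20) the rank-sum p-value comes from
exhaustive enumeration of group assignments, which is exact in the
presence of ties; larger samples use the tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu, rankdata

from .enrichment import GeneEnrichmentResult

__all__ = [
    "GenePropertyRow",
    "GroupComparison",
    "COI_GROUPS",
    "INHERITANCE_MODES",
    "assign_loeuf_deciles",
    "count_expressed_isoforms",
    "assign_coi_groups",
    "compare_groups",
    "property_report",
    "wilcoxon_rank_sum",
]

COI_GROUPS = ("no_coi", "ge1_coi", "enriched")
INHERITANCE_MODES = ("AD", "AR", "XL", "other")

#: TPM above which a transcript counts as expressed (strict inequality).
TPM_EXPRESSED = 5.0

#: Combined sample size below which the rank-sum test is enumerated exactly.
EXACT_WILCOXON_MAX_N = 20

CONTINUOUS_PROPERTIES = (
    "transcript_length",
    "n_exons",
    "n_diseases",
    "loeuf",
    "loeuf_decile",
    "n_expressed_isoforms",
)


@dataclass(slots=True)
class GenePropertyRow:
    """Per-gene structural/constraint/disease features with COI grouping."""

    gene: str
    transcript_length: float | None = None
    n_exons: float | None = None
    loeuf: float | None = None
    loeuf_decile: float | None = None
    n_expressed_isoforms: float | None = None
    n_diseases: float | None = None
    inheritance_modes: frozenset[str] = frozenset()
    coi_group: str = "no_coi"


def assign_loeuf_deciles(scores: Mapping[str, float]) -> dict[str, int]:
    """Rank-based LOEUF decile per gene: 0 = most constrained (lowest
    LOEUF), 9 = least.  Missing/non-finite scores are left unassigned;
    ties share the average rank and hence the same decile.
    """
    genes = [g for g, s in scores.items() if s is not None and math.isfinite(s)]
    if not genes:
        import warnings

        warnings.warn("no finite LOEUF scores; decile map is empty")
        return {}
    values = np.array([scores[g] for g in genes], dtype=float)
    ranks = rankdata(values, method="average")  # 1..n
    deciles = np.minimum(9, ((ranks - 0.5) / len(genes) * 10).astype(int))
    return {g: int(d) for g, d in zip(genes, deciles)}


def count_expressed_isoforms(
    tpm_table: pd.DataFrame,
) -> dict[str, int]:
    """Per gene, the number of transcripts with median TPM > 5 in at least
    one tissue.

    *tpm_table* is long-format with columns gene, transcript, tissue,
    median_tpm.  Genes present in the table but with no expressed
    transcript get a count of 0.
    """
    required = {"gene", "transcript", "tissue", "median_tpm"}
    missing = required - set(tpm_table.columns)
    if missing:
        raise ValueError(f"TPM table missing columns: {sorted(missing)}")
    if tpm_table.empty:
        raise ValueError("TPM table is empty")
    if (tpm_table["median_tpm"] < 0).any():
        raise ValueError("negative TPM values in table")
    peak = tpm_table.groupby(["gene", "transcript"])["median_tpm"].max()
    expressed = (peak > TPM_EXPRESSED).groupby("gene").sum()
    return {g: int(c) for g, c in expressed.items()}


def assign_coi_groups(
    genes: Iterable[str],
    enrichment_results: Sequence[GeneEnrichmentResult],
) -> dict[str, str]:
    """Map each gene to no_coi / ge1_coi / enriched from burden results."""
    tested = {r.gene: r for r in enrichment_results}
    groups = {}
    for g in genes:
        r = tested.get(g)
        if r is None:
            groups[g] = "no_coi"
        elif r.enriched:
            groups[g] = "enriched"
        else:
            groups[g] = "ge1_coi"
    return groups


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided unpaired rank-sum test; returns (statistic U_a, p-value).

    Exact enumeration of all C(n_a+n_b, n_a) group assignments when the
    combined sample is below ``EXACT_WILCOXON_MAX_N`` (valid with ties);
    otherwise scipy's tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if len(a) + len(b) < EXACT_WILCOXON_MAX_N:
        return _exact_rank_sum(a, b)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exhaustive two-sided rank-sum p over all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    n_a, n = len(a), len(pooled)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    u_obs = w_obs - n_a * (n_a + 1) / 2.0
    dev = abs(w_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n_a):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return float(u_obs), hits / total


@dataclass(frozen=True, slots=True)
class GroupComparison:
    """One group-vs-group test on one gene property."""

    property: str
    group_a: str
    group_b: str
    test: str  # "wilcoxon" | "chi_squared"
    statistic: float
    p: float
    direction: str  # "+", "-", "0" or "n/a"
    n_a: int
    n_b: int


def compare_groups(
    rows: Sequence[GenePropertyRow],
    property: str,
    group_a: str,
    group_b: str,
    multi_mode: str = "all",
) -> GroupComparison:
    """Compare one property between two COI groups.

    Continuous properties use the rank-sum test; ``inheritance_modes``
    builds a group x mode contingency table and applies the chi-squared
    test.  *multi_mode* controls genes linked to several modes: "all"
    contributes one count per mode, "dominant_if_any" collapses to AD when
    AD is among them.

    ``direction`` is the sign of median(a) - median(b) for continuous
    properties ("+" means group_a larger).
    """
    sel_a = [r for r in rows if r.coi_group == group_a]
    sel_b = [r for r in rows if r.coi_group == group_b]
    if property == "inheritance_modes":
        table = _mode_table(sel_a, sel_b, multi_mode)
        stat, p, _, _ = chi2_contingency(table, correction=False)
        return GroupComparison(
            property=property, group_a=group_a, group_b=group_b,
            test="chi_squared", statistic=float(stat), p=float(p),
            direction="n/a", n_a=len(sel_a), n_b=len(sel_b),
        )
    if property not in CONTINUOUS_PROPERTIES:
        raise ValueError(f"unknown property {property!r}")
    va = np.array(
        [getattr(r, property) for r in sel_a if getattr(r, property) is not None],
        dtype=float,
    )
    vb = np.array(
        [getattr(r, property) for r in sel_b if getattr(r, property) is not None],
        dtype=float,
    )
    if len(va) < 2 or len(vb) < 2:
        raise ValueError(
            f"insufficient data for {property}: {group_a} n={len(va)}, "
            f"{group_b} n={len(vb)}"
        )
    stat, p = wilcoxon_rank_sum(va, vb)
    diff = float(np.median(va) - np.median(vb))
    if diff == 0.0:
        # medians tie; fall back to mean-rank shift for direction only
        ranks = rankdata(np.concatenate([va, vb]))
        diff = float(ranks[: len(va)].mean() - ranks[len(va):].mean())
    direction = "+" if diff > 0 else ("-" if diff < 0 else "0")
    return GroupComparison(
        property=property, group_a=group_a, group_b=group_b,
        test="wilcoxon", statistic=stat, p=p, direction=direction,
        n_a=len(va), n_b=len(vb),
    )


def _mode_table(
    sel_a: Sequence[GenePropertyRow],
    sel_b: Sequence[GenePropertyRow],
    multi_mode: str,
) -> np.ndarray:
    if multi_mode not in ("all", "dominant_if_any"):
        raise ValueError(f"unknown multi_mode {multi_mode!r}")

    def counts(sel: Sequence[GenePropertyRow]) -> list[int]:
        c = dict.fromkeys(INHERITANCE_MODES, 0)
        for r in sel:
            modes = set(r.inheritance_modes) & set(INHERITANCE_MODES)
            if not modes:
                continue
            if multi_mode == "dominant_if_any" and "AD" in modes:
                modes = {"AD"}
            for m in modes:
                c[m] += 1
        return [c[m] for m in INHERITANCE_MODES]

    table = np.array([counts(sel_a), counts(sel_b)])
    # drop all-zero mode columns so the chi-squared df is well defined
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        raise ValueError("insufficient inheritance-mode data for chi-squared")
    return table


#: The standard battery: property and its contrasts, in report order.
REPORT_PROPERTIES = (
    "transcript_length",
    "n_exons",
    "n_diseases",
    "inheritance_modes",
    "loeuf",
    "loeuf_decile",
    "n_expressed_isoforms",
)

REPORT_CONTRASTS = (("no_coi", "ge1_coi"), ("ge1_coi", "enriched"))


def property_report(
    rows: Sequence[GenePropertyRow],
    enrichment_results: Sequence[GeneEnrichmentResult] | None = None,
    multi_mode: str = "all",
) -> list[GroupComparison]:
    """Run the full comparison battery over both group contrasts.

    When *enrichment_results* is given, coi_group on the rows is
    (re)assigned from it first.  Comparisons that lack data (e.g. a
    property entirely missing) are skipped silently only when absent for
    all genes; partial missingness is excluded pairwise inside
    :func:`compare_groups`.
    """
    if enrichment_results is not None:
        groups = assign_coi_groups([r.gene for r in rows], enrichment_results)
        for r in rows:
            r.coi_group = groups[r.gene]
    group_sizes = {g: sum(r.coi_group == g for r in rows) for g in COI_GROUPS}
    report = []
    for prop in REPORT_PROPERTIES:
        for ga, gb in REPORT_CONTRASTS:
            if group_sizes[ga] < 2 or group_sizes[gb] < 2:
                continue  # degenerate contrast: group absent from cohort
            if prop != "inheritance_modes" and all(
                getattr(r, prop) is None for r in rows
            ):
                continue
            report.append(compare_groups(rows, prop, ga, gb, multi_mode))
    return report


def rows_from_tables(
    property_table: pd.DataFrame,
    tpm_table: pd.DataFrame | None = None,
) -> list[GenePropertyRow]:
    """Build GenePropertyRow objects from the input TSV tables.

    *property_table* columns: gene, transcript_length, n_exons, loeuf,
    n_diseases, inheritance_modes (comma-separated).  LOEUF deciles and
    expressed-isoform counts are derived here.
    """
    deciles = assign_loeuf_deciles(
        {
            g: (None if pd.isna(s) else float(s))
            for g, s in zip(property_table["gene"], property_table["loeuf"])
        }
    )
    isoforms = (
        count_expressed_isoforms(tpm_table) if tpm_table is not None else {}
    )
    rows = []
    for rec in property_table.itertuples(index=False):
        modes = frozenset(
            m.strip()
            for m in str(getattr(rec, "inheritance_modes", "") or "").split(",")
            if m.strip()
        )
        rows.append(
            GenePropertyRow(
                gene=rec.gene,
                transcript_length=_opt(rec.transcript_length),
                n_exons=_opt(rec.n_exons),
                loeuf=_opt(rec.loeuf),
                loeuf_decile=deciles.get(rec.gene),
                n_expressed_isoforms=isoforms.get(rec.gene),
                n_diseases=_opt(rec.n_diseases),
                inheritance_modes=modes,
            )
        )
    return rows


def _opt(v) -> float | None:
    return None if pd.isna(v) else float(v)
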