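"""Allele-frequency and predicted-impact comparisons across classes.

Variants are grouped into P/LP, VUS, B/LB (their latest non-conflict
pooled class) and COI (ever carried the conflict status).  For each group
we summarise the gnomAD allele-frequency columns (global, popmax, popmin)
and the VEP IMPACT rating distribution, with pairwise rank-sum tests on
AF and a chi-squared test on the impact x class table.  Missing AF
(variant absent from gnomAD) is excluded pairwise by default; a switch
enables zero imputation instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .clinvar_io import VariantKey, normalize_variant_key
from .gene_props import wilcoxon_rank_sum
from .timeline import AggregatedClass, VariantTimeline, aggregate_class
from .clinvar_io import SignificanceClass

__all__ = [
    "VariantAnnotation",
    "IMPACT_LEVELS",
    "read_annotation_table",
    "variant_class_labels",
    "af_class_summary",
    "impact_distribution",
]

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
AF_COLUMNS = ("af_global", "af_popmax", "af_popmin")
CLASS_LABELS = ("PLP", "VUS", "BLB", "COI")


@dataclass(frozen=True, slots=True)
class VariantAnnotation:
    """VEP impact and gnomAD allele frequencies for one variant."""

    variant_key: VariantKey
    impact: str
    af_global: float | None = None
    af_popmax: float | None = None
    af_popmin: float | None = None

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_LEVELS:
            raise ValueError(f"unknown IMPACT level {self.impact!r}")

    def af_consistent(self) -> bool:
        """popmin <= global <= popmax (when all present)."""
        vals = (self.af_popmin, self.af_global, self.af_popmax)
        if any(v is None for v in vals):
            return True
        return 0 <= vals[0] <= vals[1] <= vals[2] <= 1


def read_annotation_table(path_or_df) -> dict[VariantKey, VariantAnnotation]:
    """Read the per-variant annotation TSV (chrom, pos, ref, alt, impact,
    af_global, af_popmax, af_popmin).

    AF-ordering violations (popmin > global etc.) are reported through a
    returned-record attribute check by the caller; ingest itself never
    silently reorders values.
    """
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, sep="\t")
    )
    annotations = {}
    for rec in df.itertuples(index=False):
        key = normalize_variant_key(str(rec.chrom), int(rec.pos), rec.ref, rec.alt)
        annotations[key] = VariantAnnotation(
            variant_key=key,
            impact=rec.impact,
            af_global=_opt(rec.af_global),
            af_popmax=_opt(rec.af_popmax),
            af_popmin=_opt(rec.af_popmin),
        )
    return annotations


def _opt(v) -> float | None:
    return None if pd.isna(v) else float(v)


def variant_class_labels(
    timelines: Mapping[VariantKey, VariantTimeline],
) -> dict[VariantKey, str]:
    """Assign each variant to PLP / VUS / BLB / COI.

    Ever-COI variants are COI; others take the pooled class of their
    latest observed state (OTHER-only variants are dropped).
    """
    labels = {}
    for key, tl in timelines.items():
        if tl.ever_coi:
            labels[key] = "COI"
            continue
        last = tl.states[-1][1]
        if last is SignificanceClass.OTHER:
            continue
        labels[key] = aggregate_class(last).value
    return labels


def af_class_summary(
    annotations: Mapping[VariantKey, VariantAnnotation],
    timelines: Mapping[VariantKey, VariantTimeline],
    impute_zero: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class AF quartiles plus pairwise rank-sum p-values.

    Returns ``(summary, pairwise)``: *summary* has one row per
    (class, AF column) with n/q25/median/q75 and an ``all_missing`` flag;
    *pairwise* has one row per (AF column, class pair) with the two-sided
    rank-sum p.
    """
    labels = variant_class_labels(timelines)
    common = set(labels) & set(annotations)
    if not common:
        raise ValueError("annotation and timeline variant keys do not overlap")

    values: dict[tuple[str, str], list[float]] = {
        (c, col): [] for c in CLASS_LABELS for col in AF_COLUMNS
    }
    for key in common:
        ann = annotations[key]
        cls = labels[key]
        for col in AF_COLUMNS:
            v = getattr(ann, col)
            if v is None:
                if impute_zero:
                    v = 0.0
                else:
                    continue
            values[(cls, col)].append(v)

    summary_rows = []
    for cls in CLASS_LABELS:
        for col in AF_COLUMNS:
            vals = np.array(values[(cls, col)], dtype=float)
            if len(vals) == 0:
                summary_rows.append(
                    dict(cls=cls, af=col, n=0, q25=np.nan, median=np.nan,
                         q75=np.nan, all_missing=True)
                )
            else:
                q25, med, q75 = np.percentile(vals, [25, 50, 75])
                summary_rows.append(
                    dict(cls=cls, af=col, n=len(vals), q25=q25, median=med,
                         q75=q75, all_missing=False)
                )
    summary = pd.DataFrame(summary_rows)

    pair_rows = []
    for col in AF_COLUMNS:
        for i, ca in enumerate(CLASS_LABELS):
            for cb in CLASS_LABELS[i + 1:]:
                va, vb = values[(ca, col)], values[(cb, col)]
                if len(va) < 2 or len(vb) < 2:
                    p = np.nan
                else:
                    _, p = wilcoxon_rank_sum(va, vb)
                pair_rows.append(dict(af=col, class_a=ca, class_b=cb, p=p))
    return summary, pd.DataFrame(pair_rows)


def impact_distribution(
    annotations: Mapping[VariantKey, VariantAnnotation],
    timelines: Mapping[VariantKey, VariantTimeline],
    stratify_by_initial: bool = False,
) -> tuple[pd.DataFrame, float, float]:
    """Impact-level proportions per class, with a chi-squared test.

    Returns ``(table, statistic, p)``.  *table* has one row per class (and,
    with *stratify_by_initial*, extra ``COI:<initial>`` rows splitting COI
    variants by their pre-conflict pooled class); proportion columns sum
    to 1 per row.  The chi-squared test runs across the four top-level
    classes only.
    """
    labels = variant_class_labels(timelines)
    common = set(labels) & set(annotations)
    if not common:
        raise ValueError("annotation and timeline variant keys do not overlap")

    def count_block(keys) -> dict[str, int]:
        c = dict.fromkeys(IMPACT_LEVELS, 0)
        for k in keys:
            c[annotations[k].impact] += 1
        return c

    groups: dict[str, list[VariantKey]] = {c: [] for c in CLASS_LABELS}
    for key in common:
        groups[labels[key]].append(key)

    rows = []
    counts_matrix = []
    for cls in CLASS_LABELS:
        c = count_block(groups[cls])
        total = sum(c.values())
        counts_matrix.append([c[i] for i in IMPACT_LEVELS])
        rows.append(
            dict(cls=cls, n=total,
                 **{i: (c[i] / total if total else np.nan) for i in IMPACT_LEVELS})
        )

    if stratify_by_initial:
        strata: dict[str, list[VariantKey]] = {}
        for key in groups["COI"]:
            tl = timelines[key]
            agg = tl.initial_aggregated
            label = f"COI:{agg.value}" if agg is not None else "COI:none"
            strata.setdefault(label, []).append(key)
        for label in sorted(strata):
            c = count_block(strata[label])
            total = sum(c.values())
            rows.append(
                dict(cls=label, n=total,
                     **{i: (c[i] / total if total else np.nan)
                        for i in IMPACT_LEVELS})
            )

    table = pd.DataFrame(rows)
    mat = np.array(counts_matrix)
    mat = mat[mat.sum(axis=1) > 0]
    if mat.size:
        mat = mat[:, mat.sum(axis=0) > 0]
    if mat.shape[0] >= 2 and mat.shape[1] >= 2:
        stat, p, _, _ = chi2_contingency(mat, correction=False)
    else:
        stat, p = np.nan, np.nan
    return table, float(stat), float(p)
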