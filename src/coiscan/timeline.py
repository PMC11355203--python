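"""Per-variant classification timelines across ClinVar releases.

A variant's timeline is its ordered sequence of ``(release_date,
SignificanceClass)`` states over a series of release snapshots.  From the
timeline we derive:

* the first release at which the variant carried the COI status;
* the *initial interpretation* — the last five-tier class assigned before
  the conflict emerged, pooled into B/LB vs VUS vs P/LP (the groups among
  which post-2018 ClinVar conflicts are defined);
* the *conflict combination* — which of the three pooled groups appear in
  the CLNSIGCONF submission breakdown (B/VUS, P/VUS, B/P or B/P/VUS);
* the *resolution* — the first post-conflict release at which the variant
  was reclassified into a five-tier class.

A variant absent from a given release is a gap, not a state: gaps are
skipped when looking for the pre-conflict interpretation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .clinvar_io import (
    ConflictBreakdown,
    ReleaseSnapshot,
    SignificanceClass,
    VariantKey,
    FIVE_TIER,
)

__all__ = [
    "AggregatedClass",
    "ConflictCombo",
    "VariantTimeline",
    "DynamicsRow",
    "aggregate_class",
    "build_timelines",
    "ascertain_initial_class",
    "classify_combo",
    "detect_resolution",
    "summarize_dynamics",
]


class AggregatedClass(str, Enum):
    """Pooled significance groups: B/LB, VUS, P/LP, other."""

    BLB = "BLB"
    VUS = "VUS"
    PLP = "PLP"
    OTHER = "OTHER"

    def __str__(self) -> str:
        return self.value


_AGGREGATE = {
    SignificanceClass.B: AggregatedClass.BLB,
    SignificanceClass.LB: AggregatedClass.BLB,
    SignificanceClass.VUS: AggregatedClass.VUS,
    SignificanceClass.LP: AggregatedClass.PLP,
    SignificanceClass.P: AggregatedClass.PLP,
    SignificanceClass.OTHER: AggregatedClass.OTHER,
}


def aggregate_class(cls: SignificanceClass) -> AggregatedClass:
    """Pool a non-COI five-tier/other class into {BLB, VUS, PLP, OTHER}."""
    if cls is SignificanceClass.COI:
        raise ValueError("COI has no aggregated class")
    return _AGGREGATE[cls]


class ConflictCombo(str, Enum):
    """Which pooled groups disagree inside a conflict."""

    B_VUS = "B_VUS"
    P_VUS = "P_VUS"
    B_P = "B_P"
    B_P_VUS = "B_P_VUS"

    def __str__(self) -> str:
        return self.value


class InvalidConflictError(ValueError):
    """A breakdown does not contain at least two disagreeing groups."""


def classify_combo(breakdown: ConflictBreakdown) -> ConflictCombo:
    """Map a submission breakdown to one of the four conflict combos.

    OTHER submissions are ignored: post-2018 conflicts are defined only
    among the B/LB, VUS and P/LP groups.
    """
    present = set()
    for cls, n in breakdown.counts.items():
        if n > 0 and cls is not SignificanceClass.OTHER:
            present.add(_AGGREGATE[cls])
    present.discard(AggregatedClass.OTHER)
    if len(present) < 2:
        raise InvalidConflictError(
            f"breakdown {dict(breakdown.counts)} has fewer than two "
            "disagreeing groups"
        )
    if present == {AggregatedClass.BLB, AggregatedClass.VUS}:
        return ConflictCombo.B_VUS
    if present == {AggregatedClass.PLP, AggregatedClass.VUS}:
        return ConflictCombo.P_VUS
    if present == {AggregatedClass.BLB, AggregatedClass.PLP}:
        return ConflictCombo.B_P
    return ConflictCombo.B_P_VUS


@dataclass(slots=True)
class VariantTimeline:
    """Ordered per-variant states with derived conflict fields."""

    variant_key: VariantKey
    genes: frozenset[str]
    states: list[tuple[_dt.date, SignificanceClass]] = field(default_factory=list)
    breakdown: ConflictBreakdown | None = None
    first_coi_date: _dt.date | None = None
    initial_class: SignificanceClass | None = None
    combo: ConflictCombo | None = None
    resolution: tuple[_dt.date, SignificanceClass] | None = None

    @property
    def ever_coi(self) -> bool:
        return self.first_coi_date is not None

    @property
    def initial_aggregated(self) -> AggregatedClass | None:
        if self.initial_class is None:
            return None
        return aggregate_class(self.initial_class)


def build_timelines(
    snapshots: Sequence[ReleaseSnapshot],
) -> dict[VariantKey, VariantTimeline]:
    """Assemble per-variant timelines from a dated series of snapshots.

    Derived fields (first COI date, initial class, combo, resolution) are
    filled in for every variant that was ever COI.  The breakdown retained
    on the timeline is the one from the variant's first COI release.
    """
    if not snapshots:
        raise ValueError("at least one release snapshot is required")
    dates = [s.release_date for s in snapshots]
    if len(set(dates)) != len(dates):
        raise ValueError("release dates must be unique")
    ordered = sorted(snapshots, key=lambda s: s.release_date)

    timelines: dict[VariantKey, VariantTimeline] = {}
    for snap in ordered:
        for key, rec in snap.records.items():
            tl = timelines.get(key)
            if tl is None:
                tl = timelines[key] = VariantTimeline(
                    variant_key=key, genes=rec.genes
                )
            else:
                tl.genes = tl.genes | rec.genes
            tl.states.append((snap.release_date, rec.significance))
            if rec.significance is SignificanceClass.COI and tl.first_coi_date is None:
                tl.first_coi_date = snap.release_date
                tl.breakdown = rec.breakdown

    for tl in timelines.values():
        if tl.first_coi_date is None:
            continue
        tl.initial_class = _initial_five_tier(tl)
        if tl.breakdown is not None:
            try:
                tl.combo = classify_combo(tl.breakdown)
            except InvalidConflictError:
                tl.combo = None
        tl.resolution = detect_resolution(tl)
    return timelines


def _initial_five_tier(tl: VariantTimeline) -> SignificanceClass | None:
    """Latest five-tier/OTHER state strictly before the first COI date."""
    last = None
    for date, cls in tl.states:
        if date >= tl.first_coi_date:
            break
        last = cls
    return last


def ascertain_initial_class(tl: VariantTimeline) -> AggregatedClass | None:
    """Pooled pre-conflict interpretation, or None if the variant's first
    observed state was already COI."""
    if tl.first_coi_date is None:
        raise ValueError("variant was never COI; initial class is undefined")
    cls = _initial_five_tier(tl)
    return None if cls is None else aggregate_class(cls)


def detect_resolution(
    tl: VariantTimeline,
) -> tuple[_dt.date, SignificanceClass] | None:
    """Earliest post-COI state that is a five-tier class, if any."""
    if tl.first_coi_date is None:
        raise ValueError("variant was never COI; resolution is undefined")
    for date, cls in tl.states:
        if date > tl.first_coi_date and cls in FIVE_TIER:
            return (date, cls)
    return None


@dataclass(frozen=True, slots=True)
class DynamicsRow:
    """Per-release record totals and COI share."""

    release_date: _dt.date
    n_total: int
    n_coi: int

    @property
    def pct_coi(self) -> float:
        return 100.0 * self.n_coi / self.n_total if self.n_total else 0.0


def summarize_dynamics(snapshots: Iterable[ReleaseSnapshot]) -> list[DynamicsRow]:
    """One row per release: total records, COI records, COI percentage."""
    rows = []
    for snap in sorted(snapshots, key=lambda s: s.release_date):
        n_coi = sum(
            1
            for r in snap.records.values()
            if r.significance is SignificanceClass.COI
        )
        rows.append(
            DynamicsRow(
                release_date=snap.release_date,
                n_total=len(snap.records),
                n_coi=n_coi,
            )
        )
    return rows
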