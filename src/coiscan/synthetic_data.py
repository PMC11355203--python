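"""Synthetic multi-release ClinVar-like cohorts with a truth ledger.

The generator emulates the statistical structure the downstream stages
assume: a dated series of release snapshots over a fixed gene universe,
a baseline rate of variants that acquire the conflicting-interpretation
(COI) status, a small set of planted COI-enriched genes with an elevated
rate, pre-conflict interpretations drawn from a VUS-dominant class mix,
CLNSIGCONF submission breakdowns matching a drawn conflict combination,
occasional resolution into a five-tier class, and gene/variant property
tables with programmed group effects (longer transcripts, more exons and
diseases, autosomal-dominant excess and more expressed isoforms in
enriched genes; allele frequencies ordered VUS < COI < B/LB).

Everything is driven by a single integer seed; a fixed seed yields
byte-identical output files.  The truth ledger records every planted
state so recovery tests can compare pipeline output against it
record-for-record.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clinvar_io import (
    CLNSIG_TERM,
    ClassificationRecord,
    ConflictBreakdown,
    ReleaseSnapshot,
    SignificanceClass,
    VariantKey,
    write_release,
)
from .timeline import ConflictCombo

__all__ = ["SyntheticConfig", "SyntheticTruth", "CohortBundle",
           "generate_cohort", "write_cohort", "monthly_dates"]

_FIVE = [SignificanceClass.P, SignificanceClass.LP, SignificanceClass.VUS,
         SignificanceClass.LB, SignificanceClass.B]
_COMBOS = [ConflictCombo.B_VUS, ConflictCombo.P_VUS, ConflictCombo.B_P,
           ConflictCombo.B_P_VUS]
_IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_TISSUES = ("adipose", "brain", "heart", "liver", "muscle")


def monthly_dates(start: _dt.date, n: int) -> list[_dt.date]:
    """*n* monthly release dates starting at *start*."""
    dates = []
    y, m = start.year, start.month
    for _ in range(n):
        dates.append(_dt.date(y, m, start.day))
        m += 1
        if m > 12:
            m, y = 1, y + 1
    return dates


@dataclass(slots=True)
class SyntheticConfig:
    """All knobs of the cohort generator.

    Defaults mirror the qualitative structure of public ClinVar data in
    clinically relevant genes: a 5.7% baseline ever-COI rate, a
    VUS-dominant (then LB) pre-conflict class mix, B/VUS as the commonest
    conflict combination, resolutions skewed towards B and LB, and
    monthly releases.
    """

    n_genes: int = 300
    variants_per_gene_mean: float = 30.0
    n_releases: int = 36
    start_date: _dt.date = _dt.date(2018, 4, 1)
    release_dates: list[_dt.date] | None = None

    baseline_coi_rate: float = 0.057
    n_enriched_genes: int = 10
    injected_coi_rate: float = 0.20

    #: P, LP, VUS, LB, B — pre-conflict / stable class probabilities.
    class_mix: tuple[float, ...] = (0.02, 0.04, 0.55, 0.27, 0.12)
    #: B_VUS, P_VUS, B_P, B_P_VUS.
    conflict_combo_mix: tuple[float, ...] = (0.55, 0.30, 0.05, 0.10)
    #: Fraction of COI variants observed with a pre-conflict state.
    prior_interpretation_frac: float = 0.9
    #: Per-release probability that an open conflict resolves.
    resolution_rate: float = 0.003
    #: P, LP, VUS, LB, B — destination mix for resolved conflicts.
    resolution_class_mix: tuple[float, ...] = (0.04, 0.06, 0.15, 0.45, 0.30)
    #: Releases over which variants enter the archive (0 = all at start).
    entry_span: int = 0

    # ---- per-class annotation models -------------------------------
    #: log-median global AF per label {PLP, VUS, BLB, COI}.
    af_log_median: dict = field(default_factory=lambda: {
        "PLP": np.log(5e-6), "VUS": np.log(2e-5),
        "COI": np.log(8e-5), "BLB": np.log(8e-4)})
    af_log_sigma: float = 1.0
    af_missing_rate: float = 0.10
    #: impact mix per stable class (rows sum to 1).
    impact_mix: dict = field(default_factory=lambda: {
        "PLP": (0.45, 0.40, 0.05, 0.10),
        "VUS": (0.06, 0.50, 0.14, 0.30),
        "BLB": (0.04, 0.30, 0.24, 0.42)})
    #: impact mix for COI variants, keyed by initial pooled class; B/LB-
    #: initial conflicts carry more high/moderate-impact alleles than
    #: plain B/LB, VUS/P-LP-initial ones skew milder.
    coi_impact_mix: dict = field(default_factory=lambda: {
        "BLB": (0.10, 0.42, 0.18, 0.30),
        "VUS": (0.04, 0.44, 0.18, 0.34),
        "PLP": (0.30, 0.40, 0.10, 0.20),
        "none": (0.04, 0.44, 0.18, 0.34)})

    # ---- gene property effects for enriched genes ------------------
    length_multiplier: float = 1.5
    exon_multiplier: float = 1.5
    disease_increment: float = 1.5
    loeuf_multiplier: float = 0.7
    isoform_increment: float = 2.0
    #: AD, AR, XL, other mode weights; second row for enriched genes.
    mode_mix: tuple[float, ...] = (0.35, 0.50, 0.10, 0.05)
    mode_mix_enriched: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)

    seed: int = 0

    def dates(self) -> list[_dt.date]:
        if self.release_dates is not None:
            return list(self.release_dates)
        return monthly_dates(self.start_date, self.n_releases)

    def validate(self) -> None:
        for name, vec in [("class_mix", self.class_mix),
                          ("conflict_combo_mix", self.conflict_combo_mix),
                          ("resolution_class_mix", self.resolution_class_mix),
                          ("mode_mix", self.mode_mix),
                          ("mode_mix_enriched", self.mode_mix_enriched)]:
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(vec)}")
        for name, mix in [("impact_mix", self.impact_mix),
                          ("coi_impact_mix", self.coi_impact_mix)]:
            for k, vec in mix.items():
                if abs(sum(vec) - 1.0) > 1e-9:
                    raise ValueError(f"{name}[{k}] must sum to 1")
        if self.n_enriched_genes and not (
            self.injected_coi_rate > self.baseline_coi_rate
        ):
            raise ValueError("injected_coi_rate must exceed baseline_coi_rate")
        if not 0 <= self.baseline_coi_rate < 1:
            raise ValueError("baseline_coi_rate must be in [0, 1)")
        if self.n_releases < 1:
            raise ValueError("need at least one release")
        if self.entry_span >= self.n_releases:
            raise ValueError("entry_span must be below n_releases")


@dataclass(slots=True)
class VariantTruth:
    """Planted state of one variant, indexed by release."""

    variant_key: VariantKey
    gene: str
    entry_index: int
    classes: list[SignificanceClass]  # one per release from entry_index
    first_coi_date: _dt.date | None
    combo: ConflictCombo | None
    resolution: tuple[_dt.date, SignificanceClass] | None


@dataclass(slots=True)
class SyntheticTruth:
    """Ground truth for a generated cohort."""

    enriched_genes: set[str]
    baseline_coi_rate: float
    injected_coi_rate: float
    variants: dict[VariantKey, VariantTruth]

    @property
    def ever_coi_keys(self) -> set[VariantKey]:
        return {k for k, v in self.variants.items()
                if v.first_coi_date is not None}


@dataclass(slots=True)
class CohortBundle:
    """Everything generate_cohort produces."""

    snapshots: list[ReleaseSnapshot]
    truth: SyntheticTruth
    gene_properties: pd.DataFrame
    tpm: pd.DataFrame
    annotations: pd.DataFrame
    whitelist: set[str]
    config: SyntheticConfig


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dates = config.dates()
    R = len(dates)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    enriched_idx = rng.choice(config.n_genes,
                              size=config.n_enriched_genes, replace=False)
    enriched = {genes[i] for i in enriched_idx}
    is_enriched_gene = np.zeros(config.n_genes, dtype=bool)
    is_enriched_gene[enriched_idx] = True

    sizes = np.maximum(rng.poisson(config.variants_per_gene_mean,
                                   config.n_genes), 1)
    n_var = int(sizes.sum())
    gene_of = np.repeat(np.arange(config.n_genes), sizes)

    # ---- per-variant draws (vectorised) ----------------------------
    rate = np.where(is_enriched_gene[gene_of],
                    config.injected_coi_rate, config.baseline_coi_rate)
    is_coi = rng.random(n_var) < rate
    entry = (rng.integers(0, config.entry_span + 1, n_var)
             if config.entry_span else np.zeros(n_var, dtype=int))
    init_cls = rng.choice(5, size=n_var, p=config.class_mix)
    has_prior = (rng.random(n_var) < config.prior_interpretation_frac) & is_coi
    has_prior &= entry < R - 1
    combo_i = rng.choice(4, size=n_var, p=config.conflict_combo_mix)
    res_offset = (rng.geometric(config.resolution_rate, n_var)
                  if config.resolution_rate > 0
                  else np.full(n_var, np.iinfo(np.int64).max))
    res_cls = rng.choice(5, size=n_var, p=config.resolution_class_mix)

    # unique coordinates: one contig stripe per gene
    contigs = [str(c) for c in range(1, 23)] + ["X"]
    gene_contig = [contigs[i % len(contigs)] for i in range(config.n_genes)]
    gene_base = 10_000 + 100_000 * np.arange(config.n_genes)
    offset = np.concatenate([np.arange(s) for s in sizes])
    pos = gene_base[gene_of] + offset
    bases = np.array(["A", "C", "G", "T"])
    ref_i = rng.integers(0, 4, n_var)
    alt_i = (ref_i + rng.integers(1, 4, n_var)) % 4

    snapshots = [ReleaseSnapshot(release_date=d) for d in dates]
    variants: dict[VariantKey, VariantTruth] = {}

    for v in range(n_var):
        g = gene_of[v]
        gname = genes[g]
        key: VariantKey = (gene_contig[g], int(pos[v]),
                           str(bases[ref_i[v]]), str(bases[alt_i[v]]))
        gset = frozenset({gname})
        e = int(entry[v])
        initial = _FIVE[init_cls[v]]

        if not is_coi[v]:
            rec = ClassificationRecord(
                variant_key=key, genes=gset,
                clnsig_raw=CLNSIG_TERM[initial], significance=initial,
                allele_id=v + 1)
            for r in range(e, R):
                snapshots[r].records[key] = rec
            variants[key] = VariantTruth(
                variant_key=key, gene=gname, entry_index=e,
                classes=[initial] * (R - e),
                first_coi_date=None, combo=None, resolution=None)
            continue

        coi_idx = e + 1 if has_prior[v] else e
        combo = _COMBOS[combo_i[v]]
        breakdown = _draw_breakdown(rng, combo)
        res_idx = coi_idx + int(res_offset[v])
        resolved = res_idx < R
        resolution_class = _FIVE[res_cls[v]]

        classes: list[SignificanceClass] = []
        coi_rec = ClassificationRecord(
            variant_key=key, genes=gset,
            clnsig_raw=CLNSIG_TERM[SignificanceClass.COI],
            significance=SignificanceClass.COI,
            allele_id=v + 1, breakdown=breakdown)
        prior_rec = (ClassificationRecord(
            variant_key=key, genes=gset,
            clnsig_raw=CLNSIG_TERM[initial], significance=initial,
            allele_id=v + 1) if has_prior[v] else None)
        res_rec = (ClassificationRecord(
            variant_key=key, genes=gset,
            clnsig_raw=CLNSIG_TERM[resolution_class],
            significance=resolution_class,
            allele_id=v + 1) if resolved else None)
        for r in range(e, R):
            if r < coi_idx:
                rec, cls = prior_rec, initial
            elif resolved and r >= res_idx:
                rec, cls = res_rec, resolution_class
            else:
                rec, cls = coi_rec, SignificanceClass.COI
            snapshots[r].records[key] = rec
            classes.append(cls)
        variants[key] = VariantTruth(
            variant_key=key, gene=gname, entry_index=e, classes=classes,
            first_coi_date=dates[coi_idx], combo=combo,
            resolution=(dates[res_idx], resolution_class) if resolved else None)

    truth = SyntheticTruth(
        enriched_genes=enriched,
        baseline_coi_rate=config.baseline_coi_rate,
        injected_coi_rate=config.injected_coi_rate,
        variants=variants)

    gene_props = _gene_property_table(rng, genes, is_enriched_gene, config)
    tpm = _tpm_table(rng, genes, is_enriched_gene, config)
    annotations = _annotation_table(
        rng, variants, has_prior, is_coi, init_cls, config,
        gene_contig, gene_of, pos, bases, ref_i, alt_i)

    return CohortBundle(
        snapshots=snapshots, truth=truth, gene_properties=gene_props,
        tpm=tpm, annotations=annotations, whitelist=set(genes),
        config=config)


def _draw_breakdown(rng: np.random.Generator,
                    combo: ConflictCombo) -> ConflictBreakdown:
    """Submission counts whose present pooled groups realise *combo*."""
    groups = {
        ConflictCombo.B_VUS: ("BLB", "VUS"),
        ConflictCombo.P_VUS: ("PLP", "VUS"),
        ConflictCombo.B_P: ("BLB", "PLP"),
        ConflictCombo.B_P_VUS: ("BLB", "PLP", "VUS"),
    }[combo]
    counts: dict[SignificanceClass, int] = {}
    for grp in groups:
        total = 1 + int(rng.poisson(1.2))
        if grp == "VUS":
            counts[SignificanceClass.VUS] = total
        elif grp == "BLB":
            b = int(rng.binomial(total, 0.35))
            if b:
                counts[SignificanceClass.B] = b
            if total - b:
                counts[SignificanceClass.LB] = total - b
        else:
            p = int(rng.binomial(total, 0.45))
            if p:
                counts[SignificanceClass.P] = p
            if total - p:
                counts[SignificanceClass.LP] = total - p
    return ConflictBreakdown(counts)


def _gene_property_table(rng, genes, is_enriched, cfg) -> pd.DataFrame:
    n = len(genes)
    length = rng.lognormal(np.log(3000.0), 0.5, n)
    exons = 1 + rng.poisson(12.0, n)
    loeuf = rng.uniform(0.05, 2.0, n)
    diseases = 1 + rng.poisson(0.8, n)
    en = is_enriched
    length[en] *= cfg.length_multiplier
    exons = exons.astype(float)
    exons[en] = np.round(exons[en] * cfg.exon_multiplier)
    loeuf[en] *= cfg.loeuf_multiplier
    diseases = diseases.astype(float)
    diseases[en] += rng.poisson(cfg.disease_increment, int(en.sum()))
    modes = []
    for i in range(n):
        mix = cfg.mode_mix_enriched if is_enriched[i] else cfg.mode_mix
        picks = {("AD", "AR", "XL", "other")[rng.choice(4, p=mix)]}
        if rng.random() < 0.2:  # a second linked mode for some genes
            picks.add(("AD", "AR", "XL", "other")[rng.choice(4, p=mix)])
        modes.append(",".join(sorted(picks)))
    return pd.DataFrame(dict(
        gene=genes,
        transcript_length=np.round(length).astype(int),
        n_exons=exons.astype(int),
        loeuf=np.round(loeuf, 4),
        n_diseases=diseases.astype(int),
        inheritance_modes=modes,
    ))


def _tpm_table(rng, genes, is_enriched, cfg) -> pd.DataFrame:
    rows = []
    for i, g in enumerate(genes):
        lam = 3.0 + (cfg.isoform_increment if is_enriched[i] else 0.0)
        n_iso = 1 + int(rng.poisson(lam))
        for t in range(n_iso):
            peak = rng.lognormal(np.log(4.0), 1.0)
            peak_tissue = int(rng.integers(0, len(_TISSUES)))
            for j, tissue in enumerate(_TISSUES):
                tpm = peak if j == peak_tissue else peak * rng.uniform(0, 0.5)
                rows.append((g, f"{g}.t{t + 1}", tissue, round(float(tpm), 3)))
    return pd.DataFrame(rows, columns=["gene", "transcript", "tissue",
                                       "median_tpm"])


def _annotation_table(rng, variants, has_prior, is_coi, init_cls, cfg,
                      gene_contig, gene_of, pos, bases, ref_i, alt_i
                      ) -> pd.DataFrame:
    n = len(is_coi)
    agg_of_init = np.array(["PLP", "PLP", "VUS", "BLB", "BLB"])
    rows = []
    for v in range(n):
        if is_coi[v]:
            label = "COI"
            init_label = agg_of_init[init_cls[v]] if has_prior[v] else "none"
            mix = cfg.coi_impact_mix[init_label]
        else:
            label = agg_of_init[init_cls[v]]
            mix = cfg.impact_mix[label]
        impact = _IMPACTS[rng.choice(4, p=mix)]
        if rng.random() < cfg.af_missing_rate:
            af = afmax = afmin = np.nan
        else:
            af = float(np.exp(cfg.af_log_median[label]
                              + cfg.af_log_sigma * rng.standard_normal()))
            afmax = min(1.0, af * float(np.exp(0.2 + abs(
                0.5 * rng.standard_normal()))))
            afmin = af * float(np.exp(-0.2 - abs(0.5 * rng.standard_normal())))
            af = min(af, 1.0)
            afmin = min(afmin, af)
        g = gene_of[v]
        rows.append((gene_contig[g], int(pos[v]), str(bases[ref_i[v]]),
                     str(bases[alt_i[v]]), impact, af, afmax, afmin))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "impact",
                                       "af_global", "af_popmax", "af_popmin"])


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> dict[str, object]:
    """Write the cohort as plain-text files; returns the path manifest.

    Layout: one VCF per release (``clinvar_<date>.vcf``), the whitelist,
    the truth ledger (TSV + JSON), and the property / TPM / annotation
    TSVs the downstream stages read.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    releases = {}
    for snap in bundle.snapshots:
        path = outdir / f"clinvar_{snap.release_date.isoformat()}.vcf"
        write_release(snap, path)
        releases[snap.release_date.isoformat()] = str(path)

    (outdir / "whitelist.txt").write_text(
        "\n".join(sorted(bundle.whitelist)) + "\n")
    bundle.gene_properties.to_csv(outdir / "gene_properties.tsv",
                                  sep="\t", index=False)
    bundle.tpm.to_csv(outdir / "isoform_tpm.tsv", sep="\t", index=False)
    bundle.annotations.to_csv(outdir / "variant_annotations.tsv",
                              sep="\t", index=False)

    dates = bundle.config.dates()
    ledger_rows = []
    for key, vt in bundle.truth.variants.items():
        res_date, res_cls = (vt.resolution if vt.resolution
                             else (None, None))
        ledger_rows.append(dict(
            chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
            gene=vt.gene,
            entry_date=dates[vt.entry_index].isoformat(),
            states=";".join(c.value for c in vt.classes),
            first_coi_date=(vt.first_coi_date.isoformat()
                            if vt.first_coi_date else ""),
            combo=vt.combo.value if vt.combo else "",
            resolution_date=res_date.isoformat() if res_date else "",
            resolution_class=res_cls.value if res_cls else "",
        ))
    pd.DataFrame(ledger_rows).to_csv(outdir / "truth_ledger.tsv",
                                     sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(dict(
        enriched_genes=sorted(bundle.truth.enriched_genes),
        baseline_coi_rate=bundle.truth.baseline_coi_rate,
        injected_coi_rate=bundle.truth.injected_coi_rate,
        n_variants=len(bundle.truth.variants),
        n_ever_coi=len(bundle.truth.ever_coi_keys),
    ), indent=2) + "\n")

    manifest = dict(
        releases=releases,
        whitelist=str(outdir / "whitelist.txt"),
        gene_properties=str(outdir / "gene_properties.tsv"),
        isoform_tpm=str(outdir / "isoform_tpm.tsv"),
        variant_annotations=str(outdir / "variant_annotations.tsv"),
    )
    import yaml

    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return manifest
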