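import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from coiscan.enrichment import gene_enrichment
from coiscan.gene_props import (
    GenePropertyRow,
    assign_loeuf_deciles,
    compare_groups,
    count_expressed_isoforms,
    property_report,
    rows_from_tables,
    wilcoxon_rank_sum,
)
from coiscan.synthetic_data import SyntheticConfig, generate_cohort
from coiscan.timeline import build_timelines


class TestLoeufDeciles:
    def test_ten_distinct_scores_one_per_decile(self):
        scores = {f"G{i}": 0.1 * (i + 1) for i in range(10)}
        deciles = assign_loeuf_deciles(scores)
        assert sorted(deciles.values()) == list(range(10))
        assert deciles["G0"] == 0  # lowest LOEUF = most constrained

    def test_ties_share_decile(self):
        scores = {"A": 1.0, "B": 1.0, "C": 2.0, "D": 3.0}
        deciles = assign_loeuf_deciles(scores)
        assert deciles["A"] == deciles["B"]

    def test_thousand_scores_balanced_counts(self):
        rng = np.random.default_rng(0)
        scores = {f"G{i}": float(s) for i, s in enumerate(rng.uniform(0, 2, 1000))}
        deciles = assign_loeuf_deciles(scores)
        counts = np.bincount(list(deciles.values()), minlength=10)
        assert (counts == 100).all()

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = {f"G{i}": float(s) for i, s in enumerate(rng.uniform(0.1, 2, 200))}
        transformed = {g: np.exp(3 * s) for g, s in scores.items()}
        assert assign_loeuf_deciles(scores) == assign_loeuf_deciles(transformed)

    def test_missing_scores_unassigned(self):
        scores = {"A": 0.5, "B": None, "C": float("nan")}
        scores.update({f"G{i}": float(i) for i in range(10)})
        deciles = assign_loeuf_deciles(scores)
        assert "B" not in deciles and "C" not in deciles and "A" in deciles

    def test_all_missing_warns_empty(self):
        with pytest.warns(UserWarning):
            assert assign_loeuf_deciles({"A": None}) == {}


class TestExpressedIsoforms:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "transcript", "tissue",
                                           "median_tpm"])

    def test_threshold_is_strict(self):
        t = self._table([("G", "t1", x, 5.0) for x in "abc"])
        assert count_expressed_isoforms(t) == {"G": 0}

    def test_one_tissue_suffices(self):
        t = self._table([("G", "t1", "a", 5.1), ("G", "t1", "b", 0.0)])
        assert count_expressed_isoforms(t) == {"G": 1}

    def test_mixed_transcripts(self):
        t = self._table([("G", "t1", "a", 6.0), ("G", "t2", "a", 5.0),
                         ("G", "t3", "a", 2.0)])
        assert count_expressed_isoforms(t) == {"G": 1}

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            count_expressed_isoforms(self._table([("G", "t1", "a", -1.0)]))


def permutation_oracle(a, b):
    """Independent exact two-sided rank-sum p by enumerating all group
    assignments and measuring the rank-sum deviation from its mean."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n = len(a), len(pooled)
    mu = n_a * (n + 1) / 2
    obs = abs(ranks[:n_a].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == 1.0

    def test_identical_large_samples_p_one(self):
        vals = list(range(30))
        _, p = wilcoxon_rank_sum(vals, vals)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_small_samples_match_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 7))
        n_b = int(rng.integers(2, 13 - n_a))
        # integer values induce ties, exercising the tie-handling path
        a = rng.integers(0, 6, n_a).astype(float)
        b = rng.integers(0, 6, n_b).astype(float)
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(permutation_oracle(a, b), abs=1e-12)

    def test_tie_free_small_sample_matches_scipy_exact(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        _, p = wilcoxon_rank_sum(a, b)
        expected = mannwhitneyu(a, b, method="exact").pvalue
        assert p == pytest.approx(float(expected), abs=1e-12)

    def test_large_sample_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 60)
        b = rng.normal(0.0, 1.0, 60)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 0.001


def _rows(values_a, values_b, prop="transcript_length"):
    rows = []
    for i, v in enumerate(values_a):
        rows.append(GenePropertyRow(gene=f"A{i}", coi_group="no_coi",
                                    **{prop: v}))
    for i, v in enumerate(values_b):
        rows.append(GenePropertyRow(gene=f"B{i}", coi_group="ge1_coi",
                                    **{prop: v}))
    return rows


class TestCompareGroups:
    def test_symmetry_swapping_groups(self):
        rng = np.random.default_rng(0)
        rows = _rows(rng.normal(10, 2, 25), rng.normal(12, 2, 25))
        ab = compare_groups(rows, "transcript_length", "no_coi", "ge1_coi")
        ba = compare_groups(rows, "transcript_length", "ge1_coi", "no_coi")
        assert ab.p == pytest.approx(ba.p)
        assert {ab.direction, ba.direction} == {"+", "-"}

    def test_balanced_contingency_table_is_null(self):
        rows = (
            [GenePropertyRow(gene=f"A{i}", coi_group="no_coi",
                             inheritance_modes=frozenset({"AD"}))
             for i in range(10)]
            + [GenePropertyRow(gene=f"B{i}", coi_group="no_coi",
                               inheritance_modes=frozenset({"AR"}))
               for i in range(10)]
            + [GenePropertyRow(gene=f"C{i}", coi_group="ge1_coi",
                               inheritance_modes=frozenset({"AD"}))
               for i in range(10)]
            + [GenePropertyRow(gene=f"D{i}", coi_group="ge1_coi",
                               inheritance_modes=frozenset({"AR"}))
               for i in range(10)]
        )
        cmp = compare_groups(rows, "inheritance_modes", "no_coi", "ge1_coi")
        assert cmp.test == "chi_squared"
        assert cmp.statistic == pytest.approx(0.0)
        assert cmp.p == pytest.approx(1.0)

    def test_insufficient_data_error(self):
        rows = _rows([1.0], [2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="insufficient"):
            compare_groups(rows, "transcript_length", "no_coi", "ge1_coi")

    def test_missing_values_excluded_pairwise(self):
        rows = _rows([1.0, 2.0, None, 3.0], [4.0, 5.0, None, 6.0])
        cmp = compare_groups(rows, "transcript_length", "no_coi", "ge1_coi")
        assert (cmp.n_a, cmp.n_b) == (3, 3)


class TestPropertyReport:
    @pytest.fixture(scope="class")
    @staticmethod
    def bundle_and_report():
        cfg = SyntheticConfig(n_genes=600, variants_per_gene_mean=80,
                              n_releases=3, n_enriched_genes=60,
                              injected_coi_rate=0.25, seed=9)
        bundle = generate_cohort(cfg)
        tls = build_timelines(bundle.snapshots)
        results = gene_enrichment(tls)
        rows = rows_from_tables(bundle.gene_properties, bundle.tpm)
        report = property_report(rows, results)
        return bundle, results, report

    def test_planted_effects_recovered(self, bundle_and_report):
        """Enriched genes were generated with longer transcripts, more
        exons/diseases and AD excess; the report finds each effect."""
        _, _, report = bundle_and_report
        by = {(c.property, c.group_a, c.group_b): c for c in report}
        for prop in ("transcript_length", "n_exons", "n_diseases"):
            cmp = by[(prop, "ge1_coi", "enriched")]
            assert cmp.p < 0.05
            assert cmp.direction == "-"  # enriched genes larger
        inh = by[("inheritance_modes", "ge1_coi", "enriched")]
        assert inh.p < 0.05
        iso = by[("n_expressed_isoforms", "ge1_coi", "enriched")]
        assert iso.p < 0.05 and iso.direction == "-"
        loe = by[("loeuf", "ge1_coi", "enriched")]
        assert loe.p < 0.05 and loe.direction == "+"  # enriched constrained

    def test_report_covers_both_contrasts(self, bundle_and_report):
        _, _, report = bundle_and_report
        contrasts = {(c.group_a, c.group_b) for c in report}
        assert contrasts == {("no_coi", "ge1_coi"), ("ge1_coi", "enriched")}

    def test_null_properties_mostly_non_significant(self):
        """With iid properties across groups, about alpha of continuous
        comparisons reach significance."""
        rng = np.random.default_rng(3)
        n_sig = n_tot = 0
        for _ in range(40):
            rows = _rows(rng.normal(0, 1, 40), rng.normal(0, 1, 40))
            cmp = compare_groups(rows, "transcript_length",
                                 "no_coi", "ge1_coi")
            n_tot += 1
            n_sig += cmp.p < 0.05
        assert n_sig / n_tot <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tot)

    def test_missing_loeuf_rows_skipped(self):
        rows = _rows([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        for i, r in enumerate(rows):
            r.loeuf = None
            r.inheritance_modes = frozenset({"AD" if i % 2 else "AR"})
        report = property_report(rows)
        assert report  # run completes
        assert all(c.property != "loeuf" for c in report)
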