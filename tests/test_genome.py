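"""PWM scanning with exact p-values and the promoter-acetylation analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from conftest import random_ppm_matrix
from corec.genome import (PromoterRecord, best_occurrence,
                          classify_promoter_change, cluster_score, count_sites,
                          define_promoters, enrichment_test, logodds_from_ppm,
                          motif_group_counts, promoter_acetylation,
                          region_score)
from corec.types import ReferenceMotif, revcomp


def sharp_pwm(seq, prob=1.0):
    """Deterministic (or near-deterministic) PWM whose consensus is ``seq``."""
    L = len(seq)
    mat = np.full((L, 4), (1 - prob) / 3)
    for i, b in enumerate(seq):
        mat[i, "ACGT".index(b)] = prob
    return logodds_from_ppm(ReferenceMotif("m", "m", mat))


class TestLogOdds:
    def test_uniform_gives_zero(self):
        pwm = logodds_from_ppm(ReferenceMotif("u", "u", np.full((5, 4), 0.25)))
        assert np.allclose(pwm.logodds, 0.0)

    def test_certain_base_no_pseudocount(self):
        mat = np.zeros((1, 4)); mat[0, 0] = 1.0
        pwm = logodds_from_ppm(ReferenceMotif("d", "d", mat), pseudocount=0.0)
        assert pwm.logodds[0, 0] == pytest.approx(2.0)

    def test_nonuniform_rows_span_zero(self, rng):
        mat = random_ppm_matrix(rng, 10)
        lo = logodds_from_ppm(ReferenceMotif("r", "r", mat)).logodds
        nonuniform = np.abs(mat - 0.25).max(axis=1) > 1e-6
        assert np.all(lo[nonuniform].max(axis=1) > 0)
        assert np.all(lo[nonuniform].min(axis=1) < 0)


class TestBestOccurrence:
    def test_consensus_tail_is_4_to_minus_L(self):
        pwm = sharp_pwm("ACGTG")
        _, pos, strand, p = best_occurrence("TT" + "ACGTG" + "TT", pwm)
        assert pos == 2 and strand == "+"
        assert p == pytest.approx(0.25 ** 5, rel=1e-9)

    def test_strand_symmetry(self, rng):
        pwm = sharp_pwm("ACGTGA", prob=0.9)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        s1, *_ = best_occurrence(seq, pwm)
        s2, *_ = best_occurrence(revcomp(seq), pwm)
        assert s1 == pytest.approx(s2)

    def test_minus_strand_hit(self):
        pwm = sharp_pwm("AACGT")
        seq = "GG" + revcomp("AACGT") + "GG"
        _, pos, strand, p = best_occurrence(seq, pwm)
        assert strand == "-" and p == pytest.approx(0.25 ** 5, rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            best_occurrence("ACG", sharp_pwm("ACGTG"))

    def test_dp_tail_equals_enumeration(self, rng):
        """Exact p-values match brute force over all 4^5 windows at every score."""
        mat = random_ppm_matrix(rng, 5)
        pwm = logodds_from_ppm(ReferenceMotif("r", "r", mat))
        scores = sorted({int(pwm.int_matrix[np.arange(5), w].sum())
                         for w in itertools.product(range(4), repeat=5)})
        all_scores = np.array([int(pwm.int_matrix[np.arange(5), list(w)].sum())
                               for w in itertools.product(range(4), repeat=5)])
        for s in scores:
            brute = np.count_nonzero(all_scores >= s) / 4 ** 5
            assert pwm.tail_p(s) == pytest.approx(brute, rel=1e-9)


class TestRegionScore:
    def test_absent_motif_scores_zero(self):
        assert region_score("T" * 50, sharp_pwm("GGGGGGGGGG")).score == 0.0

    def test_planted_consensus_scores_positive(self, rng):
        site = "ACGTACGTAG"
        seq = "".join(rng.choice(list("ACGT"), size=30)) + site + \
              "".join(rng.choice(list("ACGT"), size=30))
        rs = region_score(seq, sharp_pwm(site))
        assert rs.score >= 6.0  # -log10(4^-10) ~ 6.02

    def test_second_site_does_not_change_score(self):
        site = "ACGTACGTAG"
        one = region_score("TT" + site + "TT" * 10, sharp_pwm(site)).score
        two = region_score("TT" + site + "TT" + site + "TT" * 8, sharp_pwm(site)).score
        assert one == pytest.approx(two)

    def test_monotone_under_planting(self, rng):
        pwm = sharp_pwm("ACGTACGTAG", prob=0.9)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        before = region_score(seq, pwm).score
        planted = seq[:20] + "ACGTACGTAG" + seq[30:]
        assert region_score(planted, pwm).score >= before


class TestClusterScore:
    def test_identical_members(self):
        pwm = sharp_pwm("ACGTACGTAG")
        seq = "TT" + "ACGTACGTAG" + "TT"
        single = region_score(seq, pwm).score
        assert cluster_score(seq, [pwm, pwm]).score == pytest.approx(single)

    def test_no_hits_zero(self):
        assert cluster_score("T" * 40, [sharp_pwm("G" * 10)]).score == 0.0

    def test_max_semantics(self):
        hit, miss = sharp_pwm("ACGTACGTAG"), sharp_pwm("GGGGGGGGGG")
        seq = "TT" + "ACGTACGTAG" + "TT"
        assert cluster_score(seq, [miss, hit]).score == region_score(seq, hit).score

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_score("ACGT", [])


class TestCountSites:
    def test_no_sites(self):
        assert count_sites("T" * 60, sharp_pwm("G" * 8)) == 0

    def test_two_disjoint_sites(self):
        site = "ACGTACGTAC"
        seq = "TT" + site + "TTTT" + site + "TT"
        assert count_sites(seq, sharp_pwm(site)) == 2

    def test_short_motif_cannot_clear_p_floor(self):
        # a deterministic 8-mer's best attainable p is 4^-8 ~ 1.5e-5 > 1e-5
        assert count_sites("TT" + "ACGTACGT" + "TT", sharp_pwm("ACGTACGT")) == 0

    def test_overlapping_hits_counted_once(self):
        # poly-A sequence contains many overlapping windows of the poly-A motif
        pwm = sharp_pwm("A" * 10)
        assert count_sites("A" * 14, pwm) == 1
        assert count_sites("A" * 20, pwm) == 2


class TestPromoters:
    def tss(self, rows):
        return pd.DataFrame(rows, columns=["gene", "contig", "tss", "strand"])

    def test_plus_strand_window(self):
        (p,) = define_promoters(self.tss([("g", "chr1", 10_000, "+")]))
        assert (p.start, p.end) == (9_500, 10_100)

    def test_minus_strand_window(self):
        (p,) = define_promoters(self.tss([("g", "chr1", 10_000, "-")]))
        assert (p.start, p.end) == (9_900, 10_500)

    def test_clipping_warns(self, caplog):
        with caplog.at_level("WARNING"):
            (p,) = define_promoters(self.tss([("g", "chr1", 200, "+")]))
        assert (p.start, p.end) == (0, 300)
        assert any("clipped" in r.message for r in caplog.records)

    def test_first_tss_per_gene(self):
        ps = define_promoters(self.tss([("g", "chr1", 1000, "+"), ("g", "chr1", 9000, "+")]))
        assert len(ps) == 1 and ps[0].start == 500

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            define_promoters(self.tss([("g", "chr1", 1000, ".")]))


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


class TestPromoterAcetylation:
    def prom(self, start=1000, end=1600):
        return PromoterRecord("g", "chr1", start, end, "+")

    def test_max_overlapping_peak(self):
        peaks = bed([("chr1", 900, 1100, "p1", 3.0), ("chr1", 1500, 1700, "p2", 7.0)])
        (p,) = promoter_acetylation([self.prom()], peaks, bed([]))
        assert p.acetylation == 7.0

    def test_atac_only_scores_zero(self):
        atac = bed([("chr1", 1100, 1200, "a", 1.0)])
        (p,) = promoter_acetylation([self.prom()], bed([]), atac)
        assert p.acetylation == 0.0

    def test_neither_excluded(self):
        (p,) = promoter_acetylation([self.prom()], bed([]), bed([]))
        assert p.acetylation is None

    def test_overlap_engine_matches_all_pairs_oracle(self, rng):
        proms = [PromoterRecord(f"g{i}", "chr1", int(s), int(s) + 600, "+")
                 for i, s in enumerate(rng.integers(0, 50_000, size=30))]
        peaks = bed([("chr1", int(s), int(s) + int(w), f"p{i}", float(v))
                     for i, (s, w, v) in enumerate(zip(
                         rng.integers(0, 50_000, size=40),
                         rng.integers(50, 2000, size=40),
                         rng.uniform(1, 10, size=40)))])
        got = promoter_acetylation([PromoterRecord(p.gene, p.contig, p.start, p.end, "+")
                                    for p in proms], peaks, bed([]))
        for p in got:
            overlapping = [r.score for _, r in peaks.iterrows()
                           if r.start < p.end and p.start < r.end]
            expected = max(overlapping) if overlapping else None
            assert p.acetylation == expected


class TestPromoterChange:
    def db(self, rows):
        return pd.DataFrame(rows, columns=["contig", "start", "end", "log2fc", "fdr"])

    def prom(self):
        return PromoterRecord("g", "chr1", 1000, 1600, "+")

    def test_induced(self):
        (p,) = classify_promoter_change([self.prom()], self.db([("chr1", 900, 1100, 2.0, 0.001)]))
        assert p.change_class == "induced"

    def test_unchanged(self):
        (p,) = classify_promoter_change([self.prom()], self.db([("chr1", 900, 1100, 0.05, 0.9)]))
        assert p.change_class == "unchanged"

    def test_multi_peak_rule_induced_wins(self):
        db = self.db([("chr1", 900, 1100, 0.05, 0.9), ("chr1", 1400, 1700, 2.0, 0.001)])
        (p,) = classify_promoter_change([self.prom()], db)
        assert p.change_class == "induced"

    def test_intermediate_fc_unclassified(self):
        (p,) = classify_promoter_change([self.prom()], self.db([("chr1", 900, 1100, 0.8, 0.2)]))
        assert p.change_class == "unclassified"


class TestMotifGroupCounts:
    def test_no_hits(self):
        clusters = {"C1": [sharp_pwm("GGGGGGGG")]}
        assert motif_group_counts("T" * 40, clusters) == (0, 0)

    def test_homotypic_hits(self):
        site = "ACGTACGTAC"
        seq = "TT" + site + "TT"
        clusters = {"C1": [sharp_pwm(site), sharp_pwm(site), sharp_pwm(site)]}
        assert motif_group_counts(seq, clusters) == (3, 1)

    def test_heterotypic_distinct_clusters(self, rng):
        sites = ["ACGTACGTAC", "GGATCCGGAT", "TTGACATTGC", "CCCGTTAACC", "AGAGAGGGAG"]
        seq = "TT".join(sites)
        clusters = {f"C{i}": [sharp_pwm(s)] for i, s in enumerate(sites)}
        total, distinct = motif_group_counts(seq, clusters)
        assert distinct == 5 and total == 5


class TestEnrichmentTest:
    def test_identical_groups_nonsignificant(self):
        p = enrichment_test([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_extreme_separation_exact(self):
        # most extreme of C(6,3) = 20 orderings, doubled for two sides
        assert enrichment_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, size=12)
        assert enrichment_test(a, b) == pytest.approx(enrichment_test(b, a))

    def test_exact_matches_permutation_oracle(self, rng):
        a = [1.0, 4.0, 6.0]
        b = [2.0, 3.0, 9.0, 11.0]
        pooled = a + b
        n = len(a)
        obs_u = mannwhitneyu(a, b, alternative="two-sided", method="exact").statistic
        # exhaustive permutation of group labels
        us = []
        for comb in itertools.combinations(range(len(pooled)), n):
            ga = [pooled[i] for i in comb]
            gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
            u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
                1 for x in ga for y in gb if x == y)
            us.append(u)
        us = np.array(us)
        mu = n * (len(pooled) - n) / 2
        exact_p = np.mean(np.abs(us - mu) >= abs(obs_u - mu) - 1e-12)
        assert enrichment_test(a, b) == pytest.approx(exact_p, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([], [1.0])
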