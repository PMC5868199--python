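"""ChIP peak filtering, TSS mapping, ranking, overlap, occupancy tests."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trnkit.chip import (
    OverlapSummary,
    PeakTable,
    differential_occupancy,
    distance_to_nearest_tss,
    filter_peaks,
    map_peaks_to_genes,
    module_chip_concordance,
    occupancy_correlation,
    qualitative_overlap,
)
from trnkit.priors import GeneAnnotation

SAMPLES = ("m1", "m2", "w1", "w2")
GROUPS = {"m1": "mutant", "m2": "mutant", "w1": "wildtype", "w2": "wildtype"}


def peaks_from(rows):
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit", "fdr", *SAMPLES]
    )
    return PeakTable(frame=frame, sample_columns=SAMPLES, groups=GROUPS)


class TestFilterPeaks:
    CASES = [
        (("c1", 0, 100, 50, 0.005, 12, 3, 11, 0), True),   # two samples >= 10
        (("c1", 0, 100, 50, 0.005, 12, 9, 9, 9), False),   # only one sample
        (("c1", 0, 100, 50, 0.02, 50, 50, 50, 50), False), # FDR rule, strict <
    ]

    @pytest.mark.parametrize("row,kept", CASES)
    def test_retention_rules(self, row, kept):
        out = filter_peaks(peaks_from([row]))
        assert (len(out) == 1) == kept

    def test_summit_must_lie_inside_interval(self):
        with pytest.raises(ValueError):
            peaks_from([("c1", 0, 100, 100, 0.001, 10, 10, 10, 10)])


class TestDistances:
    GENES = [
        GeneAnnotation("gA", "c1", "+", (10_000, 13_500)),
        GeneAnnotation("gB", "c2", "-", (50_000,)),
    ]

    def test_summit_at_tss(self):
        pk = peaks_from([("c1", 9_900, 10_100, 10_000, 0.001, 10, 10, 10, 10)])
        assert distance_to_nearest_tss(pk, self.GENES).iloc[0] == 0

    def test_minimum_over_tss(self):
        pk = peaks_from([("c1", 11_500, 12_500, 12_000, 0.001, 10, 10, 10, 10)])
        assert distance_to_nearest_tss(pk, self.GENES).iloc[0] == 1_500

    def test_chromosome_without_genes_is_missing(self):
        pk = peaks_from([("c9", 0, 100, 50, 0.001, 10, 10, 10, 10)])
        assert np.isnan(distance_to_nearest_tss(pk, self.GENES).iloc[0])


class TestPeakGeneMap:
    def test_boundary_inclusive(self):
        genes = [GeneAnnotation("g", "c1", "+", (50_000,))]
        pk = peaks_from(
            [("c1", 59_900, 60_100, 60_000, 0.001, 10, 10, 10, 10),
             ("c1", 60_000, 60_200, 60_001, 0.001, 10, 10, 10, 10)]
        )
        pm = map_peaks_to_genes(pk, genes, window_bp=10_000)
        assert pm.gene_stats.loc["g", "n_peaks"] == 1  # exactly-at-window kept

    def test_peak_counts_for_both_equidistant_genes(self):
        genes = [
            GeneAnnotation("gL", "c1", "+", (10_000,)),
            GeneAnnotation("gR", "c1", "+", (20_000,)),
        ]
        pk = peaks_from([("c1", 14_900, 15_100, 15_000, 0.001, 10, 10, 10, 10)])
        pm = map_peaks_to_genes(pk, genes, window_bp=10_000)
        assert pm.gene_stats["n_peaks"].tolist() == [1, 1]

    def test_top_target_rule_on_skewed_counts(self):
        genes = [
            GeneAnnotation(f"g{i}", "c1", "+", (i * 100_000,)) for i in range(100)
        ]
        rows = [
            ("c1", 99 * 100_000 - 50, 99 * 100_000 + 50, 99 * 100_000, 0.001,
             10, 10, 10, 10)
        ] * 10
        pm = map_peaks_to_genes(peaks_from(rows), genes, window_bp=10_000)
        assert pm.mean_count == pytest.approx(0.1)
        assert pm.sd_count == pytest.approx(np.sqrt(0.99), abs=1e-6)
        assert pm.top_targets() == {"g99"}

    def test_matches_bruteforce_and_window_monotone(self, rng):
        genes = [
            GeneAnnotation(
                f"g{i}", f"c{i % 3}", "+",
                tuple(sorted(rng.integers(0, 300_000, rng.integers(1, 3)))),
            )
            for i in range(40)
        ]
        rows = [
            (f"c{int(rng.integers(3))}", int(s), int(s) + 200, int(s) + 100,
             0.001, 10, 10, 10, 10)
            for s in rng.integers(0, 300_000, 300)
        ]
        pk = peaks_from(rows)
        pm = map_peaks_to_genes(pk, genes, window_bp=10_000)
        brute = {g.gene_id: 0 for g in genes}
        for r in pk.frame.itertuples():
            for g in genes:
                if g.chrom == r.chrom and any(
                    abs(r.summit - t) <= 10_000 for t in g.tss_positions
                ):
                    brute[g.gene_id] += 1
        assert dict(pm.gene_stats["n_peaks"]) == brute
        wide = map_peaks_to_genes(pk, genes, window_bp=30_000)
        assert (wide.gene_stats["n_peaks"] >= pm.gene_stats["n_peaks"]).all()

    def test_invariant_to_gene_order_and_zero_tss_genes(self, rng):
        genes = [
            GeneAnnotation(f"g{i}", "c1", "+", (int(p),))
            for i, p in enumerate(rng.integers(0, 500_000, 30))
        ]
        rows = [
            ("c1", int(s), int(s) + 100, int(s) + 50, 0.001, 10, 10, 10, 10)
            for s in rng.integers(0, 500_000, 100)
        ]
        pk = peaks_from(rows)
        base = map_peaks_to_genes(pk, genes)
        shuffled = map_peaks_to_genes(pk, genes[::-1])
        padded = map_peaks_to_genes(
            pk, genes + [GeneAnnotation("empty", "c1", "+", ())]
        )
        assert base.top_targets() == shuffled.top_targets() == padded.top_targets()


class TestQualitativeOverlap:
    def _pk(self, intervals):
        return peaks_from(
            [(c, s, e, s, 0.001, 10, 10, 10, 10) for c, s, e in intervals]
        )

    def test_identical_sets_all_shared(self):
        a = self._pk([("c1", 0, 100), ("c1", 200, 300)])
        out = qualitative_overlap(a, a)
        assert out == OverlapSummary(2, 0, 2, 0)

    def test_disjoint_sets(self):
        a = self._pk([("c1", 0, 100)])
        b = self._pk([("c1", 200, 300)])
        assert qualitative_overlap(a, b) == OverlapSummary(0, 1, 0, 1)

    def test_one_spanning_peak_counts_asymmetrically(self):
        a = self._pk([("c1", 0, 1000)])
        b = self._pk([("c1", 100, 200), ("c1", 700, 800)])
        out = qualitative_overlap(a, b)
        assert out.a_shared == 1 and out.b_shared == 2

    def test_matches_bruteforce(self, rng):
        def rand(n):
            return self._pk(
                [
                    (f"c{int(rng.integers(2))}", int(s), int(s) + int(rng.integers(50, 400)))
                    for s in rng.integers(0, 20_000, n)
                ]
            )

        a, b = rand(150), rand(120)
        out = qualitative_overlap(a, b)
        brute_a = sum(
            any(
                ra.chrom == rb.chrom and ra.start < rb.end and rb.start < ra.end
                for rb in b.frame.itertuples()
            )
            for ra in a.frame.itertuples()
        )
        assert out.a_shared == brute_a


class TestOccupancyCorrelation:
    def test_identity_and_negation(self, rng):
        x = rng.normal(size=100)
        assert occupancy_correlation(x, x) == pytest.approx(1.0)
        assert occupancy_correlation(x, -x) == pytest.approx(-1.0)

    def test_independent_signals_near_zero(self, rng):
        r = occupancy_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_restriction_mask(self, rng):
        x = rng.normal(size=50)
        y = np.concatenate([x[:25], rng.normal(size=25)])
        mask = np.arange(50) < 25
        assert occupancy_correlation(x, y, restrict=mask) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            occupancy_correlation(np.ones(10), np.arange(10.0))


class TestConcordance:
    def test_hand_table(self):
        # module of 10, 8 with peaks; 90 non-module genes, 10 with peaks
        genes = [f"g{i}" for i in range(100)]
        gene_stats = pd.DataFrame(
            {"n_peaks": [1] * 8 + [0] * 2 + [1] * 10 + [0] * 80},
            index=pd.Index(genes, name="gene"),
        )
        gene_stats["rank"] = 1
        gene_stats["top_target"] = False
        from trnkit.chip import PeakGeneMap

        pm = PeakGeneMap(gene_stats, pd.Series(dtype=float), 10_000, 0.18, 0.4)
        a, orat, p = module_chip_concordance(set(genes[:10]), pm)
        assert (a, orat) == (8, 32.0)
        exact = sum(
            comb(18, j) * comb(82, 10 - j) for j in range(8, 11)
        ) / comb(100, 10)
        assert p == pytest.approx(exact, rel=1e-10)

    def test_null_p_uniformity(self, rng):
        """Under independence the exact tail P is calibrated.

        The test statistic is discrete, so the plain tail P is conservative
        by construction; the randomized tail u = P(X > a) + U * P(X = a) is
        exactly uniform under the null and is what the KS test checks.
        """
        from trnkit.chip import PeakGeneMap

        genes = [f"g{i}" for i in range(1000)]
        us = []
        for _ in range(200):
            positive = set(rng.choice(genes, size=150, replace=False))
            gene_stats = pd.DataFrame(
                {"n_peaks": [int(g in positive) for g in genes]},
                index=pd.Index(genes, name="gene"),
            )
            gene_stats["rank"] = 1
            gene_stats["top_target"] = False
            pm = PeakGeneMap(gene_stats, pd.Series(dtype=float), 10_000, 0.15, 0.36)
            module = set(rng.choice(genes, size=100, replace=False))
            a, _, p = module_chip_concordance(module, pm)
            p_next = stats.hypergeom.sf(a, 1000, 150, 100)
            us.append(p_next + rng.random() * (p - p_next))
        assert stats.kstest(us, "uniform").pvalue > 0.01


class TestDifferentialOccupancy:
    def test_identical_groups_null(self, rng):
        half = rng.negative_binomial(20, 0.2, size=(30, 2))
        frame = pd.DataFrame(
            np.hstack([half, half]), columns=SAMPLES
        )
        frame.insert(0, "fdr", 0.001)
        frame.insert(0, "summit", 50)
        frame.insert(0, "end", 100)
        frame.insert(0, "start", 0)
        frame.insert(0, "chrom", "c1")
        pk = PeakTable(frame, SAMPLES, GROUPS)
        out = differential_occupancy(pk, "mutant")
        assert np.allclose(out["log2_fc"], 0)
        assert (out["pvalue"] > 0.999).all()

    def test_twofold_loss_detected_in_direction(self, rng):
        # half the peaks lose occupancy in the mutant, half are stable
        mu = rng.uniform(50, 200, size=200)
        mut_mu = mu.copy()
        mut_mu[:100] /= 2
        k = 1 / 0.05
        wt = rng.negative_binomial(k, k / (k + mu[:, None]), size=(200, 2))
        mut = rng.negative_binomial(k, k / (k + mut_mu[:, None]), size=(200, 2))
        frame = pd.DataFrame(np.hstack([mut, wt]), columns=SAMPLES)
        for col, val in [("fdr", 0.001), ("summit", 50), ("end", 100),
                         ("start", 0), ("chrom", "c1")]:
            frame.insert(0, col, val)
        pk = PeakTable(frame, SAMPLES, GROUPS)
        out = differential_occupancy(pk, "mutant")
        lost = np.median(out["log2_fc"].iloc[:100])
        stable = np.median(out["log2_fc"].iloc[100:])
        assert lost < -0.3
        assert stable - lost > 0.7
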