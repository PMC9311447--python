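"""Evaluation procedures: PR sweeps, destranding, R², Ward clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisgbs import evalbench
from bisgbs.bsalign import OB, OT, AlignmentRecord
from bisgbs.denovo import ReferenceCluster
from bisgbs.evalbench import (both_strand_filter, cluster_truth_stats,
                              destrand_cpg, methylation_r2, pr_curve,
                              ward_clusters)
from bisgbs.methylation import CytosineRecord
from bisgbs.variants import VariantRecord

Q = chr(37 + 33)


def _vr(contig, pos, ref, alt, qual=50.0, gts=None):
    return VariantRecord(contig, pos, ref, [alt] if isinstance(alt, str) else alt,
                         qual, gts or {})


def _aln(cluster, start, length, strand):
    return AlignmentRecord("r", "S1", cluster, start, f"{length}M", 40, strand,
                           1, "A" * length, Q * length)


class TestClusterTruthStats:
    def test_perfect_reconstruction(self):
        loci = ["ACGT" * 30, "TTGCA" * 20]
        clusters = [ReferenceCluster(f"c{i}", "NNNN" + s + "NNNN", 1, 1)
                    for i, s in enumerate(loci)]
        st_ = cluster_truth_stats(clusters, loci)
        assert st_.fraction_uniquely_matched == 1.0
        assert st_.mean_mismatches == 0.0

    def test_duplicate_locus_not_unique(self):
        s = "ACGT" * 30
        clusters = [ReferenceCluster("c0", "NNNN" + s + "NNNN", 1, 1)]
        st_ = cluster_truth_stats(clusters, [s, s])
        assert st_.fraction_uniquely_matched == 0.0

    def test_empty_clusters(self):
        st_ = cluster_truth_stats([], ["ACGT"])
        assert st_.n_clusters == 0 and st_.fraction_uniquely_matched == 0.0

    def test_near_match_counts_mismatches(self):
        s = "ACGT" * 30
        s2 = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        clusters = [ReferenceCluster("c0", "NNNN" + s2 + "NNNN", 1, 1)]
        st_ = cluster_truth_stats(clusters, [s, "TTGCA" * 24])
        assert st_.fraction_uniquely_matched == 1.0
        assert st_.mean_mismatches == pytest.approx(1.0)


def brute_force_pr(calls, baseline, squash, q):
    """All-pairs matcher over decomposed (contig,pos,alt[,genotypes])."""
    def decomp(records):
        out = []
        for r in records:
            for k, alt in enumerate(r.alts, 1):
                gts = {}
                for s, (gt, _, _) in r.genotypes.items():
                    if gt == "./.":
                        continue
                    a, b = sorted(int(x) for x in gt.split("/"))
                    if {a, b} - {0, k}:
                        continue
                    gts[s] = {0: "0/0", 1: "0/1", 2: "1/1"}[(a == k) + (b == k)]
                out.append((r.cluster, r.position, alt, r.qual, gts))
        return out

    calls_d = [c for c in decomp(calls) if c[3] >= q]
    base_d = decomp(baseline)
    tp = 0
    used = set()
    fp = 0
    for c in calls_d:
        hit = None
        for j, b in enumerate(base_d):
            if j in used or (b[0], b[1], b[2]) != (c[0], c[1], c[2]):
                continue
            if squash or all(c[4][s] == b[4][s] for s in set(c[4]) & set(b[4])):
                hit = j
                break
        if hit is None:
            fp += 1
        else:
            tp += 1
            used.add(hit)
    fn = len(base_d) - tp
    prec = tp / (tp + fp) if tp + fp else 1.0
    sens = tp / (tp + fn) if tp + fn else 1.0
    return prec, sens


class TestPrCurve:
    def test_precision_arithmetic(self):
        base = [_vr("c", i, "A", "G") for i in range(1, 13)]
        calls = [_vr("c", i, "A", "G") for i in range(1, 10)]  # 9 TP
        calls += [_vr("c", 100, "A", "G")]                     # 1 FP
        (q, prec, sens), = pr_curve(calls, base, qual_grid=[0.0])
        assert prec == pytest.approx(0.9)
        assert sens == pytest.approx(9 / 12)

    def test_squash_ploidy_ignores_genotype(self):
        base = [_vr("c", 1, "A", "G", gts={"S1": ("1/1", 99, 30)})]
        calls = [_vr("c", 1, "A", "G", gts={"S1": ("0/1", 99, 30)})]
        (_, p_strict, s_strict), = pr_curve(calls, base, qual_grid=[0.0])
        (_, p_squash, s_squash), = pr_curve(calls, base, squash_ploidy=True,
                                            qual_grid=[0.0])
        assert (p_strict, s_strict) == (0.0, 0.0)
        assert (p_squash, s_squash) == (1.0, 1.0)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([], [])

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        base = [_vr("c", int(i), "A", "G") for i in rng.choice(500, 40, False)]
        calls = [_vr("c", int(i), "A", "G", qual=float(rng.integers(1, 100)))
                 for i in rng.choice(500, 60, False)]
        rows = pr_curve(calls, base)
        sens = [r[2] for r in rows]
        assert sens == sorted(sens, reverse=True)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.booleans())
    def test_equals_brute_force(self, seed, squash):
        rng = np.random.default_rng(seed)
        bases = "ACGT"

        def rand_records(n):
            out = []
            positions = rng.choice(np.arange(1, 60), size=n, replace=False)
            for pos in positions:
                ref, alt = rng.choice(list(bases), 2, replace=False)
                gt = str(rng.choice(["0/1", "1/1"]))
                out.append(_vr("c", int(pos), str(ref), str(alt),
                               qual=float(rng.integers(0, 60)),
                               gts={"S1": (gt, 99.0, 30)}))
            return out

        calls, base = rand_records(int(rng.integers(1, 15))), rand_records(
            int(rng.integers(1, 15)))
        for q in (0.0, 20.0, 45.0):
            (_, prec, sens), = pr_curve(calls, base, squash_ploidy=squash,
                                        qual_grid=[q])
            b_prec, b_sens = brute_force_pr(calls, base, squash, q)
            assert prec == pytest.approx(b_prec)
            assert sens == pytest.approx(b_sens)


class TestBothStrandFilter:
    def test_single_strand_removed(self):
        base = [_vr("c1", 5, "C", "T")]
        alns = [_aln("c1", 1, 10, OT)] * 5
        assert both_strand_filter(base, alns) == []

    def test_both_strands_kept(self):
        base = [_vr("c1", 5, "C", "T")]
        alns = [_aln("c1", 1, 10, OT), _aln("c1", 3, 10, OB)]
        assert both_strand_filter(base, alns) == base

    def test_no_alignments_empty(self):
        assert both_strand_filter([_vr("c1", 5, "C", "T")], []) == []


def _cx(cluster, pos, strand, m, u, ctx="CG"):
    return CytosineRecord(cluster, pos, strand, m, u, ctx, "CGN")


class TestDestrand:
    def test_sum_rule(self):
        out = destrand_cpg([_cx("c", 10, "+", 3, 1), _cx("c", 11, "-", 2, 2)])
        (r,) = out
        assert (r.position, r.count_methylated, r.count_unmethylated) == (10, 5, 3)

    def test_plus_only_unchanged(self):
        (r,) = destrand_cpg([_cx("c", 10, "+", 3, 1)])
        assert (r.position, r.count_methylated) == (10, 3)

    def test_minus_only_moves_to_plus_coordinate(self):
        (r,) = destrand_cpg([_cx("c", 11, "-", 2, 2)])
        assert r.position == 10

    def test_non_cg_rejected(self):
        with pytest.raises(ValueError):
            destrand_cpg([_cx("c", 10, "+", 1, 1, ctx="CHH")])


class TestMethylationR2:
    def test_identical_sets(self):
        a = [_cx("c", i, "+", i, 20 - i) for i in range(1, 15)]
        assert methylation_r2(a, a, min_cov=10) == pytest.approx(1.0)

    def test_perfect_negative_fit(self):
        a = [_cx("c", 1, "+", 0, 20), _cx("c", 2, "+", 10, 10),
             _cx("c", 3, "+", 20, 0)]
        b = [_cx("c", 1, "+", 20, 0), _cx("c", 2, "+", 10, 10),
             _cx("c", 3, "+", 0, 20)]
        assert methylation_r2(a, b, min_cov=10) == pytest.approx(1.0)

    def test_low_coverage_excluded(self):
        a = [_cx("c", i, "+", i, 15 - i) for i in range(1, 12)]
        b = [_cx("c", i, "+", i, 15 - i) for i in range(1, 12)]
        b[0] = _cx("c", 1, "+", 2, 3)  # coverage 5 < 10: dropped from the fit
        r2 = methylation_r2(a, b, min_cov=10)
        assert r2 == pytest.approx(1.0)

    def test_too_few_sites_error(self):
        a = [_cx("c", 1, "+", 5, 10)]
        with pytest.raises(ValueError):
            methylation_r2(a, a, min_cov=10)


class TestWard:
    def test_identical_samples_merge_at_zero(self):
        x = np.vstack([np.linspace(0, 1, 30)] * 2 + [np.linspace(1, 0, 30)])
        z, labels, newick = ward_clusters(x, ["a", "b", "c"],
                                          distance="euclidean")
        assert z[0, 2] == pytest.approx(0.0)
        assert newick.endswith(";") and "a" in newick

    def test_two_populations_partition(self):
        rng = np.random.default_rng(0)
        pop1 = rng.normal(0, 0.05, size=(4, 40)) + np.linspace(0, 1, 40)
        pop2 = rng.normal(0, 0.05, size=(4, 40)) + np.linspace(1, 0, 40)
        x = np.vstack([pop1, pop2])
        labels = [f"p1_{i}" for i in range(4)] + [f"p2_{i}" for i in range(4)]
        z, _, _ = ward_clusters(x, labels, distance="correlation")
        g1, g2 = evalbench.cut_two(z, labels)
        assert {frozenset(g1), frozenset(g2)} == {
            frozenset(labels[:4]), frozenset(labels[4:])}

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            ward_clusters(np.ones((1, 5)), ["a"])

    def test_constant_row_correlation_error(self):
        with pytest.raises(ValueError):
            ward_clusters(np.vstack([np.ones(5), np.arange(5)]), ["a", "b"])
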