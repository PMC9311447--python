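"""De novo reconstruction: encodings, dedup, pairing, merge, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisgbs.demux import CRICK, WATSON
from bisgbs.denovo import (assemble_or_join, binary_encode,
                           cluster_identity, dedup_consensus, global_identity,
                           pair_watson_crick, reconstruct_consensus,
                           three_letter_encode)
from bisgbs.simdata import revcomp

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestEncodings:
    def test_three_letter_watson(self):
        assert three_letter_encode("ACGGAT", WATSON) == "ATGGAT"

    def test_three_letter_crick(self):
        assert three_letter_encode("ACGGAT", CRICK) == "ACAAAT"

    def test_identity_on_conversion_free_sequence(self):
        assert three_letter_encode("TTTT", WATSON) == "TTTT"
        assert three_letter_encode("TTTT", CRICK) == "TTTT"

    def test_binary(self):
        assert binary_encode("ACGGAT") == "ATAAAT"
        assert binary_encode("") == ""
        assert binary_encode("NACGT") == "NATAT"

    @settings(max_examples=40, deadline=None)
    @given(dna)
    def test_binary_commutes_with_three_letter(self, s):
        assert binary_encode(three_letter_encode(s, WATSON)) == binary_encode(s)
        assert binary_encode(three_letter_encode(s, CRICK)) == binary_encode(s)


class TestAssembleOrJoin:
    def test_full_overlap_recovers_insert(self):
        # read-through mates of an 80-bp molecule: assembly must exclude
        # both custom-adapter tails
        insert = ("ACGTTGCA" * 40)[:80]
        tail1 = "GCGTACGTAG" + "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
        tail2 = "CTATCGATCG" + "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
        r1 = (insert + tail1)[:120]
        r2 = (revcomp(insert) + tail2)[:120]
        assert assemble_or_join(r1, r2) == insert

    def test_no_overlap_joined_with_spacer(self):
        a = ("ACGT" * 40)[:150]
        b = ("TTGCAGGA" * 40)[:150]
        joined = assemble_or_join(a, revcomp(b))
        assert joined == a + "N" * 8 + b
        assert len(joined) == 308

    def test_exact_reverse_complement_collapses(self):
        s = ("ACGGATTC" * 10)[:64]
        assert assemble_or_join(s, revcomp(s)) == s

    def test_partial_overlap(self):
        rng = np.random.default_rng(4)
        mol = "".join(rng.choice(list("ACGT"), size=260))
        r1, r2 = mol[:150], revcomp(mol[-150:])
        assert assemble_or_join(r1, r2) == mol


class TestDedupConsensus:
    def test_majority_consensus_restores_methylated_column(self):
        # 12 Watson copies of true ACGGAT; 7 retained the methylated C
        seqs = ["ACGGAT"] * 7 + ["ATGGAT"] * 5
        clusters = dedup_consensus(seqs, WATSON, min_depth=10)
        assert len(clusters) == 1
        assert clusters[0].depth == 12
        assert clusters[0].consensus == "ACGGAT"
        assert clusters[0].encoded_key == "ATGGAT"

    def test_majority_t_when_conversion_dominates(self):
        seqs = ["ACGGAT"] * 4 + ["ATGGAT"] * 8
        (c,) = dedup_consensus(seqs, WATSON, min_depth=10)
        assert c.consensus == "ATGGAT"

    def test_tie_column_becomes_n(self):
        seqs = ["ACGGAT"] * 6 + ["ATGGAT"] * 6
        (c,) = dedup_consensus(seqs, WATSON, min_depth=10)
        assert c.consensus == "ANGGAT"

    def test_min_depth_bound(self):
        assert dedup_consensus(["ACGT"] * 5, WATSON, min_depth=10) == []

    def test_max_depth_bound(self):
        assert dedup_consensus(["ACGT"] * 11, WATSON, min_depth=1, max_depth=10) == []

    def test_invariant_key_matches_consensus(self):
        (c,) = dedup_consensus(["ACGGAT"] * 12, WATSON, min_depth=1)
        assert three_letter_encode(c.consensus, WATSON) == c.encoded_key


class TestPairing:
    def _cluster(self, seqs, strand, **kw):
        return dedup_consensus(seqs, strand, min_depth=1, **kw)

    def test_watson_crick_pair_by_binary_key(self):
        w = self._cluster(["ATGGAT"] * 12, WATSON)      # from ACGGAT
        c = self._cluster(["ACAAAT"] * 12, CRICK)       # ACGGAT, bottom converted
        pairs, leftovers = pair_watson_crick(w, c)
        assert len(pairs) == 1 and not leftovers

    def test_unpaired_watson(self):
        w = self._cluster(["ATGGAT"] * 12, WATSON)
        pairs, leftovers = pair_watson_crick(w, [])
        assert not pairs and leftovers == w

    def test_depth_tie_rule(self):
        w = (self._cluster(["ATGGAT"] * 12, WATSON)
             + self._cluster(["ACGGAT"] * 3, WATSON))   # same binary key
        c = self._cluster(["ACAAAT"] * 5, CRICK)
        pairs, leftovers = pair_watson_crick(w, c)
        assert len(pairs) == 1
        assert pairs[0][0].depth == 12  # highest-depth Watson paired first


class TestReconstruct:
    def test_conversion_merge(self):
        assert reconstruct_consensus("ATGGAT", "ACAAAT") == "ACGGAT"

    def test_methylation_independent(self):
        assert reconstruct_consensus("ACGGAT", "ACAAAT") == "ACGGAT"

    def test_inconsistent_column_becomes_n(self):
        assert reconstruct_consensus("AAGGAT", "ACAAAT") == "ANGGAT"

    def test_n_defers_to_partner(self):
        assert reconstruct_consensus("ANGGAT", "ACAAAT") == "ACGGAT"

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            reconstruct_consensus("ACGT", "ACG")

    @settings(max_examples=60, deadline=None)
    @given(dna, st.floats(0, 1))
    def test_roundtrip_any_methylation_pattern(self, s, p_meth):
        """Converting both strands and merging restores the original."""
        rng = np.random.default_rng(abs(hash((s, round(p_meth, 3)))) % 2**31)
        meth = rng.random(len(s)) < p_meth
        watson = "".join("T" if b == "C" and not m else b
                         for b, m in zip(s, meth))
        crick = "".join("A" if b == "G" and not m else b
                        for b, m in zip(s, meth))
        assert reconstruct_consensus(watson, crick) == s


class TestClusterIdentity:
    def test_identical_sequences_merge(self):
        out = cluster_identity([("ACGTACGTACGT", 10, 10), ("ACGTACGTACGT", 5, 5)])
        assert len(out) == 1 and out[0].members == 2
        assert out[0].sequence == "NNNN" + "ACGTACGTACGT" + "NNNN"

    def test_threshold_semantics(self):
        a = "ACGTACGTACGTACGTACGT"            # 20 bp
        b = a[:10] + "T" + a[11:]             # 95% identical
        assert len(cluster_identity([(a, 9, 9), (b, 1, 1)], identity=0.99)) == 2
        assert len(cluster_identity([(a, 9, 9), (b, 1, 1)], identity=0.95)) == 1

    def test_empty(self):
        assert cluster_identity([]) == []

    def test_padding_and_ids(self):
        out = cluster_identity([("ACGT" * 10, 3, 3), ("TTGGCCAA" * 5, 9, 9)])
        assert [c.id for c in out] == ["cluster_00000", "cluster_00001"]
        assert out[0].watson_depth == 9  # descending-depth processing order
        assert all(c.sequence.startswith("NNNN") and c.sequence.endswith("NNNN")
                   for c in out)


class TestGlobalIdentity:
    def test_exact(self):
        assert global_identity("ACGT", "ACGT") == 1.0

    def test_n_never_matches(self):
        assert global_identity("ANGT", "ANGT") == 0.75

    def test_gap_columns_count(self):
        assert global_identity("ACGTACGT", "ACGACGT") < 1.0


class TestOracleEquivalence:
    def test_reconstruction_matches_truth(self, small_products):
        """Error-free library: cluster set equals the true molecule set."""
        truth = sorted(l.molecule for l in small_products.lib.truth.loci)
        rec = sorted(c.core for c in small_products.clusters)
        # SNP consensus may legitimately pick the population-major allele;
        # allow at most one substitution per locus with a segregating SNP
        assert len(rec) == len(truth)
        n_exact = sum(t in rec for t in truth)
        assert n_exact >= len(truth) - 6  # <= one divergence per SNP site

    def test_monotonicity_in_min_depth_and_identity(self, small_products):
        """Cluster count falls with min depth, rises with identity."""
        from bisgbs.denovo import build_reference
        watson = small_products.strand_pool(WATSON)
        crick = small_products.strand_pool(CRICK)
        counts_depth = [len(build_reference(watson, crick, min_depth=d)[0])
                        for d in (10, 50, 100)]
        assert counts_depth == sorted(counts_depth, reverse=True)
        counts_ident = [len(build_reference(watson, crick, identity=i)[0])
                        for i in (0.95, 0.99)]
        assert counts_ident == sorted(counts_ident)
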