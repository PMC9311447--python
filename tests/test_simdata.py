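"""Simulator: digestion, size selection, truth drawing and read anatomy."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisgbs import simdata
from bisgbs.simdata import MSPI, NSII, SimConfig, digest, select_loci

GENOME = "TTCCGGTTATGCATTTCCGGTT"


class TestDigest:
    def test_dual_digest_boundaries(self):
        frags = digest(GENOME, (MSPI, NSII))
        assert [f.sequence for f in frags] == ["TTC", "CGGTTATGCA", "TTTC", "CGGTT"]
        # boundaries after 1-based positions 3, 13, 17
        assert [f.end for f in frags[:-1]] == [3, 13, 17]
        assert [(f.left_enzyme, f.right_enzyme) for f in frags] == [
            ("genome_end", "MspI"), ("MspI", "NsiI"), ("NsiI", "MspI"),
            ("MspI", "genome_end")]

    def test_no_sites_single_fragment(self):
        frags = digest("ATATATATAT", (MSPI, NSII))
        assert len(frags) == 1 and frags[0].sequence == "ATATATATAT"

    def test_mspi_only_tiling(self):
        frags = digest("CCGGCCGG", [MSPI])
        assert [f.sequence for f in frags] == ["C", "CGGC", "CGG"]
        assert "".join(f.sequence for f in frags) == "CCGGCCGG"

    def test_bad_genome_rejected(self):
        with pytest.raises(ValueError):
            digest("ACGX", (MSPI, NSII))

    def test_bad_iupac_in_recognition_rejected(self):
        with pytest.raises(ValueError):
            simdata.Enzyme("bad", "CCQG", 1)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_tiling_property(self, genome):
        frags = digest(genome, (MSPI, NSII))
        assert "".join(f.sequence for f in frags) == genome


class TestSelectLoci:
    def test_dual_cut_size_selection(self):
        loci = select_loci(digest(GENOME, (MSPI, NSII)), (4, 50), require_dual=True)
        assert [l.sequence for l in loci] == ["CGGTTATGCA", "TTTC"]

    def test_no_dual_requirement_keeps_all(self):
        loci = select_loci(digest(GENOME, (MSPI, NSII)), (1, 100), require_dual=False)
        assert len(loci) == 4

    def test_size_window(self):
        frags = digest(GENOME, (MSPI, NSII))  # lengths 3, 10, 4, 5
        assert len(select_loci(frags, (11, 100), require_dual=False)) == 0
        assert len(select_loci(frags, (10, 100), require_dual=False)) == 1

    def test_locus_starts_with_left_remnant(self):
        for loc in select_loci(digest(GENOME, (MSPI, NSII)), (4, 50)):
            remnant = simdata.ENZYMES_BY_NAME[loc.left_enzyme].remnant
            assert loc.sequence.startswith(remnant)
            assert loc.molecule.startswith(remnant)

    def test_molecule_ends_with_revcomp_of_right_remnant(self):
        for loc in select_loci(digest(GENOME, (MSPI, NSII)), (4, 50)):
            remnant = simdata.ENZYMES_BY_NAME[loc.right_enzyme].remnant
            assert loc.molecule.endswith(simdata.revcomp(remnant))


class TestTruth:
    def _loci(self):
        cfg = SimConfig(genome_length=60_000, n_loci=10, n_samples=2, seed=5)
        lib = simdata.simulate_library(cfg)
        return lib, cfg

    def test_zero_heterozygosity_means_no_alt_alleles(self):
        lib, _ = self._loci()
        assert all(not v for v in
                   (lib.truth.sample_genotypes[s] for s in lib.truth.sample_genotypes))

    def test_fixed_cg_level(self):
        cfg = SimConfig(genome_length=60_000, n_loci=5, n_samples=1,
                        meth_cg=1.0, seed=5)
        lib = simdata.simulate_library(cfg)
        for loc in lib.truth.loci:
            ctx = simdata.methylation_contexts(loc.molecule)
            top_prot, bot_prot = loc.protection_masks()
            for key, context in ctx.items():
                if context == "CG":
                    assert lib.truth.methylation["S1"][loc.id][key] == 1.0

    def test_snp_offsets_inside_locus_and_outside_remnants(self):
        cfg = SimConfig(genome_length=250_000, n_loci=30, n_samples=2,
                        n_snps=20, seed=9)
        lib = simdata.simulate_library(cfg)
        mol = {l.id: l.molecule for l in lib.truth.loci}
        for s, per_locus in lib.truth.sample_genotypes.items():
            for loc_id, snps in per_locus.items():
                for pos, ref, alt, gt in snps:
                    assert 0 <= pos < len(mol[loc_id])
                    assert mol[loc_id][pos] == ref
                    assert pos >= 4 and pos < len(mol[loc_id]) - 4

    def test_seeded_determinism_bytes(self):
        cfg = SimConfig(genome_length=60_000, n_loci=8, n_samples=2,
                        coverage=5, seed=13, pcr_duplicate_rate=0.2,
                        error_rate=0.002)
        a = simdata.simulate_library(cfg)
        b = simdata.simulate_library(cfg)
        assert [(p.id, p.seq1, p.seq2, p.qual1, p.qual2) for p in a.pairs] == \
               [(p.id, p.seq1, p.seq2, p.qual1, p.qual2) for p in b.pairs]


class TestReads:
    def test_read_anatomy(self):
        cfg = SimConfig(genome_length=60_000, n_loci=5, n_samples=1,
                        coverage=4, seed=3)
        lib = simdata.simulate_library(cfg)
        bc = simdata.default_barcodes(1)[0]
        loci = {l.id: l for l in lib.truth.loci}
        for p in lib.pairs:
            _, sample, strand, loc_id = lib.read_truth[p.id]
            loc = loci[loc_id]
            cn1 = "T" if strand == "Watson" else "C"
            assert p.seq1[3:9] == bc[1]          # barcode after 3-nt UMI
            assert p.seq1[9] == cn1              # control nucleotide
            assert len(p.seq1) == cfg.read_length
            assert len(p.qual1) == len(p.seq1)

    def test_full_conversion_no_c_in_watson_insert(self):
        cfg = SimConfig(genome_length=60_000, n_loci=5, n_samples=1, coverage=6,
                        meth_cg=0.0, meth_chg=0.0, meth_chh=0.0, seed=3)
        lib = simdata.simulate_library(cfg)
        loci = {l.id: l for l in lib.truth.loci}
        for p in lib.pairs:
            _, _, strand, loc_id = lib.read_truth[p.id]
            if strand != "Watson":
                continue
            loc = loci[loc_id]
            top_prot, _ = loc.protection_masks()
            insert = p.seq1[10:10 + len(loc.molecule)]
            for i, b in enumerate(insert):
                if loc.molecule[i] == "C" and not top_prot[i]:
                    assert b == "T"

    def test_no_duplicates_unique_pairs(self):
        cfg = SimConfig(genome_length=60_000, n_loci=5, n_samples=1,
                        coverage=10, pcr_duplicate_rate=0.0, seed=3)
        lib = simdata.simulate_library(cfg)
        triples = {(p.seq1, p.seq2) for p in lib.pairs}
        assert len(triples) == len(lib.pairs)
        assert len(set(lib.truth.clone_labels.values())) == len(lib.pairs)

    def test_read_through_reaches_adapter(self):
        # insert shorter than the read: the 3' end must contain the
        # reverse-complemented opposite custom adapter then the Illumina adapter
        cfg = SimConfig(genome_length=60_000, n_loci=5, n_samples=1,
                        coverage=2, read_length=250, seed=3)
        lib = simdata.simulate_library(cfg)
        loci = {l.id: l for l in lib.truth.loci}
        found = 0
        for p in lib.pairs:
            _, _, strand, loc_id = lib.read_truth[p.id]
            L = len(loci[loc_id].molecule)
            if strand == "Watson" and 10 + L + 10 + 20 < cfg.read_length:
                tail = p.seq1[10 + L:]
                assert tail[10:].startswith(simdata.ILLUMINA_ADAPTER[:20])
                found += 1
        assert found > 0

    def test_barcode_shortage_rejected(self):
        cfg = SimConfig(genome_length=60_000, n_loci=3, n_samples=3,
                        barcodes=simdata.default_barcodes(2), seed=1)
        lib_loci = simdata.select_loci(
            simdata.digest("T" * 10 + "CCGG" + "A" * 200, (MSPI, NSII)), (1, 300),
            require_dual=False)
        truth = simdata.simulate_truth(lib_loci, cfg)
        with pytest.raises(ValueError, match="barcode count"):
            simdata.simulate_reads(truth, cfg)


def test_write_library_outputs(tmp_path):
    cfg = SimConfig(genome_length=60_000, n_loci=4, n_samples=2, coverage=3, seed=2)
    lib = simdata.simulate_library(cfg)
    paths = simdata.write_library(lib, str(tmp_path))
    import gzip
    with gzip.open(paths["r1"], "rt") as f:
        lines = f.readlines()
    assert len(lines) == 4 * len(lib.pairs)
    with open(paths["loci"]) as f:
        assert sum(1 for l in f if l.startswith(">")) == len(lib.truth.loci)
    with open(paths["clones"]) as f:
        assert len(f.readlines()) == len(lib.pairs) + 1
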