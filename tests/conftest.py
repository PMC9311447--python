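"""Shared fixtures: simulated libraries and derived pipeline products."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from bisgbs import bsalign, demux, denovo, simdata, trimmer
from bisgbs.demux import CRICK, WATSON


@dataclass
class PipelineProducts:
    """A simulated library taken through demux and both reference branches."""

    lib: simdata.SimulatedLibrary
    binned: dict
    demux_stats: demux.DemuxStats
    clone_stats: demux.CloneStats
    clusters: list
    denovo_stats: dict
    reference: dict[str, str]        # de novo clusters
    truth_reference: dict[str, str]  # padded true molecules (reference branch)

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _ in self.binned})

    def strand_pool(self, strand: str):
        return [p for (s, st), ps in self.binned.items() if st == strand for p in ps]


def run_through_denovo(cfg: simdata.SimConfig, rescue_mode: str = "any_single_mismatch",
                       **denovo_kwargs) -> PipelineProducts:
    lib = simdata.simulate_library(cfg)
    pairs, clone_stats = demux.remove_clones(lib.pairs, cfg.umi_length)
    table = [demux.BarcodeSpec(*b) for b in
             (cfg.barcodes or simdata.default_barcodes(cfg.n_samples,
                                                       cfg.barcode_length))]
    expanded = demux.expand_barcodes(table[: cfg.n_samples])
    binned, dstats = demux.demultiplex(pairs, expanded, cfg.enzyme_pair(),
                                       rescue_mode=rescue_mode)
    watson = [p for (s, st), ps in binned.items() if st == WATSON for p in ps]
    crick = [p for (s, st), ps in binned.items() if st == CRICK for p in ps]
    clusters, dn_stats = denovo.build_reference(watson, crick, **denovo_kwargs)
    return PipelineProducts(
        lib=lib, binned=binned, demux_stats=dstats, clone_stats=clone_stats,
        clusters=clusters, denovo_stats=dn_stats,
        reference={c.id: c.sequence for c in clusters},
        truth_reference={l.id: "NNNN" + l.molecule + "NNNN" for l in lib.truth.loci},
    )


def align_all(products: PipelineProducts, reference: dict[str, str],
              **align_kwargs) -> list[bsalign.AlignmentRecord]:
    index = bsalign.build_index(reference)
    records = []
    for sample in products.samples:
        tw, _ = trimmer.trim_all(products.binned.get((sample, WATSON), []))
        tc, _ = trimmer.trim_all(products.binned.get((sample, CRICK), []))
        m1, m2 = trimmer.merge_directional(tw, tc)
        recs, _ = bsalign.align_library(
            m1, m2, index, sample_of={r.id: sample for r in m1}, **align_kwargs)
        records.extend(recs)
    records.sort(key=lambda r: (r.cluster, r.start, r.read_id, r.mate))
    return records


@pytest.fixture(scope="session")
def small_products() -> PipelineProducts:
    """~30 loci, 2 samples, 20x/strand, a few SNPs; enough for most checks."""
    cfg = simdata.SimConfig(genome_length=250_000, n_loci=30, n_samples=2,
                            coverage=40, read_length=200, n_snps=6, seed=13)
    return run_through_denovo(cfg)


@pytest.fixture(scope="session")
def small_alignments(small_products) -> list[bsalign.AlignmentRecord]:
    """Alignments of the small library against its own de novo reference."""
    return align_all(small_products, small_products.reference)


@pytest.fixture(scope="session")
def small_truth_alignments(small_products) -> list[bsalign.AlignmentRecord]:
    """Reference-branch alignments against the padded true molecules."""
    return align_all(small_products, small_products.truth_reference)
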