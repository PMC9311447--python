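"""Double masking and diploid SNP calling on bisulfite alignments.

Bisulfite conversion mimics C->T (top strand) and G->A (bottom strand)
variants.  Double masking removes this confound before variant calling by
rewriting every conversion-ambiguous read state to the reference base: on
original-top (OT) reads, a C or T over a reference C becomes C; on
original-bottom (OB) reads, a G or A over a reference G becomes G.  Real
variant evidence at cytosine positions therefore only survives on the
opposite strand, which is exactly the information conversion cannot touch.
Masked alignments feed a per-site independent diploid maximum-likelihood
caller with a symmetric base-error model and no population prior.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from .bsalign import OB, OT, AlignmentRecord

__all__ = [
    "VariantRecord",
    "CallerParams",
    "double_mask",
    "call_variants",
    "filter_snps",
    "write_vcf",
    "read_vcf",
]

QUAL_CAP = 3000.0


@dataclass
class VariantRecord:
    cluster: str
    position: int                 # 1-based
    ref: str
    alts: list[str]
    qual: float
    # sample -> (genotype "0/0"... or "./.", GQ, depth)
    genotypes: dict[str, tuple[str, float, int]] = field(default_factory=dict)

    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 and a != self.ref
                                          for a in self.alts)


@dataclass
class CallerParams:
    min_coverage: int = 0
    min_base_quality: int = 1
    min_mapping_quality: int = 10
    max_alts: int = 3


def double_mask(record: AlignmentRecord, reference: dict[str, str]) -> AlignmentRecord:
    """Rewrite conversion-ambiguous read bases to the reference base.

    Qualities are kept: masking changes base identity only, preserving depth
    for site quality.
    """
    if record.bisulfite_strand not in (OT, OB):
        raise ValueError("alignment record lacks a bisulfite strand tag")
    ref = reference[record.cluster]
    s0 = record.start - 1
    seq = list(record.seq)
    n = min(len(seq), len(ref) - s0)
    if record.bisulfite_strand == OT:
        target, confound = "C", "CT"
    else:
        target, confound = "G", "GA"
    for i in range(n):
        if ref[s0 + i] == target and seq[i] in confound:
            seq[i] = target
    return replace(record, seq="".join(seq))


def _genotype_pairs(n_alleles: int):
    return [(i, j) for i in range(n_alleles) for j in range(i, n_alleles)]


def _drop_conversion_ambiguous(per_sample: dict, refbase: str) -> dict:
    """Site-level removal of conversion-ambiguous strand evidence.

    Reference-base masking (``double_mask``) rewrites OT C/T states at
    reference C (and OB G/A at reference G) to the reference base, which is
    correct only while no second allele of the C/T pair segregates at the
    site.  Whenever the site's candidate alleles (reference plus observed
    bases) contain *both* C and T, an OT read showing C or T cannot tell a
    true C allele (possibly converted) from a true T allele, so those
    observations carry no genotype information and are dropped; the same
    holds for OB reads showing G or A when both G and A are candidates.
    The surviving opposite-strand evidence is exactly what conversion
    cannot touch: without this step a homozygous alternate T at a reference
    C would be pulled toward a heterozygous call by its own masked reads,
    and an alternate C (which converts on the top strand) would surface as
    a spurious T allele.
    """
    alleles = {refbase} | {b for obs in per_sample.values() for b, _, _ in obs}
    drop_ot = "C" in alleles and "T" in alleles
    drop_ob = "G" in alleles and "A" in alleles
    if not (drop_ot or drop_ob):
        return per_sample
    out = {}
    for s, obs in per_sample.items():
        kept = [o for o in obs
                if not (drop_ot and o[2] == OT and o[0] in "CT")
                and not (drop_ob and o[2] == OB and o[0] in "GA")]
        out[s] = kept
    return out


def _site_likelihoods(obs: list[tuple[str, int, str]], alleles: list[str]) -> np.ndarray:
    """log10 likelihood of each diploid genotype given (base, qual) observations."""
    pairs = _genotype_pairs(len(alleles))
    ll = np.zeros(len(pairs))
    for base, qual, _strand in obs:
        eps = 10 ** (-qual / 10)
        p_match = 1 - eps
        p_mis = eps / 3
        per_allele = [p_match if base == a else p_mis for a in alleles]
        for k, (i, j) in enumerate(pairs):
            ll[k] += math.log10(0.5 * per_allele[i] + 0.5 * per_allele[j])
    return ll


def call_variants(alignments: list[AlignmentRecord], reference: dict[str, str],
                  params: CallerParams | None = None) -> list[VariantRecord]:
    """Per-site independent diploid ML calling across all samples.

    Observations failing base/mapping-quality thresholds are excluded.  Per
    sample the maximum-likelihood diploid genotype over the site's alleles
    is reported with GQ = phred difference between the best and second-best
    genotype; site QUAL is the phred-scaled probability (uniform genotype
    prior) that every sample is homozygous reference.  Only sites with at
    least one non-reference allele in a called genotype are emitted.
    """
    params = params or CallerParams()
    samples = sorted({r.sample for r in alignments})
    if any(not r.sample for r in alignments):
        raise ValueError("alignment record without a sample read group")

    ref_arrs = {n: np.frombuffer(s.encode(), dtype=np.uint8)
                for n, s in reference.items()}
    usable = [r for r in alignments if r.mapq >= params.min_mapping_quality]

    # pass 1: vectorized mismatch discovery -> candidate sites per cluster
    nonref_by_cluster: dict[str, set[int]] = defaultdict(set)
    for r in usable:
        ra = ref_arrs[r.cluster]
        s0 = r.start - 1
        read = np.frombuffer(r.seq.encode(), dtype=np.uint8)[: len(ra) - s0]
        seg = ra[s0:s0 + len(read)]
        mism = np.nonzero((read != seg) & (read != ord("N")) & (seg != ord("N")))[0]
        if mism.size:
            quals = np.frombuffer(r.qual.encode(), dtype=np.uint8)[mism] - 33
            for i in mism[quals >= params.min_base_quality]:
                nonref_by_cluster[r.cluster].add(s0 + int(i))
    sites_by_cluster = {c: np.array(sorted(p), dtype=np.int64)
                        for c, p in nonref_by_cluster.items()}

    # pass 2: pile up every usable observation at the candidate sites
    pile: dict[tuple[str, int], dict[str, list[tuple[str, int, str]]]] = defaultdict(
        lambda: defaultdict(list))
    nonref: set[tuple[str, int]] = set()
    for r in usable:
        sites = sites_by_cluster.get(r.cluster)
        if sites is None:
            continue
        ra = ref_arrs[r.cluster]
        s0 = r.start - 1
        n = min(len(r.seq), len(ra) - s0)
        lo, hi = np.searchsorted(sites, (s0, s0 + n))
        for p in sites[lo:hi]:
            i = int(p) - s0
            base = r.seq[i]
            if base == "N" or reference[r.cluster][int(p)] == "N":
                continue
            qual = ord(r.qual[i]) - 33
            if qual < params.min_base_quality:
                continue
            pile[(r.cluster, int(p))][r.sample].append((base, qual, r.bisulfite_strand))
            if base != reference[r.cluster][int(p)]:
                nonref.add((r.cluster, int(p)))

    out: list[VariantRecord] = []
    for cluster, pos in sorted(nonref):
        per_sample = pile[(cluster, pos)]
        refbase = reference[cluster][pos]
        per_sample = _drop_conversion_ambiguous(per_sample, refbase)
        alt_counts: dict[str, int] = defaultdict(int)
        for obs in per_sample.values():
            for base, _, _ in obs:
                if base != refbase:
                    alt_counts[base] += 1
        if not alt_counts:
            continue
        alts = sorted(alt_counts, key=lambda b: (-alt_counts[b], b))[: params.max_alts]
        alleles = [refbase] + alts
        pairs = _genotype_pairs(len(alleles))
        gt_of = {k: f"{i}/{j}" for k, (i, j) in enumerate(pairs)}

        qual = 0.0
        genotypes: dict[str, tuple[str, float, int]] = {}
        any_nonref_call = False
        for s in samples:
            obs = per_sample.get(s, [])
            depth = len(obs)
            if depth == 0 or depth < params.min_coverage:
                genotypes[s] = ("./.", 0.0, depth)
                continue
            ll = _site_likelihoods(obs, alleles)
            order = np.argsort(ll)[::-1]
            best, second = int(order[0]), int(order[1]) if len(order) > 1 else int(order[0])
            gq = 10.0 * (ll[best] - ll[second]) if len(order) > 1 else 0.0
            genotypes[s] = (gt_of[best], round(float(gq), 2), depth)
            if gt_of[best] != "0/0":
                any_nonref_call = True
            # P(0/0 | data) under a uniform genotype prior
            norm = ll - ll.max()
            post00 = 10 ** norm[0] / np.sum(10 ** norm)
            post00 = min(max(post00, 1e-300), 1.0)
            qual += -10.0 * math.log10(post00)
        qual = min(qual, QUAL_CAP)
        if qual > 0 and any_nonref_call:
            out.append(VariantRecord(cluster, pos + 1, refbase, alts,
                                     round(qual, 2), genotypes))
    return out


def filter_snps(records: list[VariantRecord]) -> list[VariantRecord]:
    """Keep only single-nucleotide substitutions."""
    return [r for r in records if r.is_snp()]


def write_vcf(records: list[VariantRecord], samples: list[str],
              reference: dict[str, str], path: str) -> None:
    """Write a multi-sample VCF 4.2 with GT:GQ:DP genotype fields."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for name, seq in reference.items():
        header.contigs.add(name, length=len(seq))
    for s in samples:
        header.add_sample(s)
    prev = None
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for r in sorted(records, key=lambda r: (r.cluster, r.position)):
            if prev is not None and (r.cluster, r.position) < prev:
                raise ValueError("records must be sorted")
            prev = (r.cluster, r.position)
            rec = vcf.new_record(contig=r.cluster, start=r.position - 1,
                                 alleles=tuple([r.ref] + r.alts))
            rec.qual = r.qual
            for s in samples:
                gt, gq, dp = r.genotypes.get(s, ("./.", 0.0, 0))
                if gt == "./.":
                    rec.samples[s]["GT"] = (None, None)
                else:
                    a, b = gt.split("/")
                    rec.samples[s]["GT"] = (int(a), int(b))
                rec.samples[s]["GQ"] = int(round(gq))
                rec.samples[s]["DP"] = int(dp)
            vcf.write(rec)


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a VCF into VariantRecords (GT/GQ/DP aware; other fields ignored)."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            genotypes = {}
            for s in rec.samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    gt_s = "./."
                else:
                    gt_s = "/".join(str(a) for a in sorted(gt))
                gq = rec.samples[s].get("GQ") or 0.0
                dp = rec.samples[s].get("DP") or 0
                genotypes[s] = (gt_s, float(gq), int(dp))
            out.append(VariantRecord(rec.contig, rec.pos, rec.ref,
                                     list(rec.alts or []),
                                     float(rec.qual or 0.0), genotypes))
    return out
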