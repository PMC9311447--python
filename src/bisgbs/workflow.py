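"""Pipeline orchestration: demultiplex -> trim -> reference -> align ->
methylation -> variants -> report, with a de novo and a reference branch.

Configuration is a flat key=value text file (see ``PipelineConfig.from_file``);
every stage writes its outputs into the run directory and a completed stage
is skipped on rerun unless forced, so stages can be re-executed and reused
independently.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from dataclasses import dataclass, field, fields

from Bio import SeqIO

from . import bsalign, demux, denovo, methylation, trimmer, variants
from .demux import CRICK, WATSON
from .simdata import ENZYMES_BY_NAME, ILLUMINA_ADAPTER, ReadPair

__all__ = ["PipelineConfig", "PipelineResult", "run", "report", "ConfigError"]

log = logging.getLogger("bisgbs")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    mode: str = "denovo"                  # denovo | reference
    r1: str = ""
    r2: str = ""
    barcodes: str = ""
    reference: str = ""                   # FASTA, reference mode only
    enzymes: str = "MspI,NsiI"
    outdir: str = "bisgbs_out"
    umi_length: int = 3
    mismatches_r1: int = 0
    mismatches_r2: int = 0
    rescue: str = "any_single_mismatch"   # or ct_only
    adapter: str = ILLUMINA_ADAPTER
    min_len: int = 20
    hard_trim: int = 10
    min_depth: int = 10
    max_depth: int = 10000
    identity: float = 0.99
    min_score_frac: float = 0.6
    nondirectional: bool = False
    min_base_quality: int = 1
    min_mapping_quality: int = 10
    min_coverage: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        values: dict[str, str] = {}
        with open(path) as f:
            for line in f:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"expected key=value, got {line!r}")
                k, v = line.split("=", 1)
                values[k.strip()] = v.strip()
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for k, v in values.items():
            if k not in known:
                raise ConfigError(f"unknown config key {k!r}")
            typ = known[k]
            if typ == "int":
                kwargs[k] = int(v)
            elif typ == "float":
                kwargs[k] = float(v)
            elif typ == "bool":
                kwargs[k] = v.lower() in ("1", "true", "yes")
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def validate(self) -> None:
        if self.mode == "legacy":
            raise ConfigError("legacy mode is not supported; "
                              "use mode=denovo or mode=reference")
        if self.mode not in ("denovo", "reference"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for path, name in ((self.r1, "r1"), (self.r2, "r2"),
                           (self.barcodes, "barcodes")):
            if not path or not os.path.exists(path):
                raise ConfigError(f"missing input {name}: {path!r}")
        if self.mode == "reference" and not os.path.exists(self.reference):
            raise ConfigError(f"missing reference FASTA: {self.reference!r}")
        names = self.enzymes.split(",")
        if len(names) != 2 or any(n not in ENZYMES_BY_NAME for n in names):
            raise ConfigError(f"enzymes must be two known names, got {self.enzymes!r}")

    def enzyme_pair(self):
        a, b = self.enzymes.split(",")
        return ENZYMES_BY_NAME[a], ENZYMES_BY_NAME[b]


@dataclass
class PipelineResult:
    outdir: str
    reference: dict[str, str] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)


def _read_fastq_pairs(r1_path: str, r2_path: str) -> list[ReadPair]:
    pairs = []
    with _open(r1_path) as f1, _open(r2_path) as f2:
        it1 = SeqIO.QualityIO.FastqGeneralIterator(f1)
        it2 = SeqIO.QualityIO.FastqGeneralIterator(f2)
        for (h1, s1, q1), (h2, s2, q2) in zip(it1, it2):
            rid = h1.split()[0]
            if rid != h2.split()[0]:
                raise ValueError(f"mate id mismatch: {h1!r} vs {h2!r}")
            pairs.append(ReadPair(rid, s1.upper(), s2.upper(), q1, q2))
    return pairs


def _open(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _write_fastq_pairs(pairs: list[ReadPair], r1_path: str, r2_path: str) -> None:
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.id}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}\n{p.seq2}\n+\n{p.qual2}\n")


def run(config: PipelineConfig, force: bool = False) -> PipelineResult:
    """Execute the configured branch end to end; returns outputs and stats."""
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    stats: dict = {"mode": config.mode}
    enzymes = config.enzyme_pair()

    # --- clone removal + demultiplexing --------------------------------
    log.info("[demux] reading %s / %s", config.r1, config.r2)
    pairs = _read_fastq_pairs(config.r1, config.r2)
    deduped, clone_stats = demux.remove_clones(pairs, config.umi_length)
    table = demux.read_barcode_file(config.barcodes)
    expanded = demux.expand_barcodes(table)
    binned, dstats = demux.demultiplex(
        deduped, expanded, enzymes,
        mismatches_r1=config.mismatches_r1, mismatches_r2=config.mismatches_r2,
        rescue_mode=config.rescue)
    stats["clone_removal"] = {
        "input_pairs": clone_stats.input_pairs,
        "clones_removed": clone_stats.clones_removed,
        "clone_fraction": clone_stats.clone_fraction,
        "retained": clone_stats.retained,
    }
    stats["demultiplexing"] = {
        "input_pairs": dstats.input_pairs,
        "ambiguous_barcode_drops": dstats.ambiguous_barcode_drops,
        "low_quality_drops": dstats.low_quality_drops,
        "ambiguous_radtag_drops": dstats.ambiguous_radtag_drops,
        "retained_per_sample": dstats.retained_per_sample,
        "observed_unexpected_barcodes": {
            f"{k1}/{k2}": n for (k1, k2), n
            in dstats.observed_unexpected_barcodes.most_common(20)},
    }
    demux_dir = os.path.join(outdir, "demultiplexed")
    os.makedirs(demux_dir, exist_ok=True)
    for (sample, strand), ps in binned.items():
        _write_fastq_pairs(ps, os.path.join(demux_dir, f"{sample}.{strand}.R1.fastq.gz"),
                           os.path.join(demux_dir, f"{sample}.{strand}.R2.fastq.gz"))

    # --- reference: de novo reconstruction or provided FASTA -----------
    ref_path = os.path.join(outdir, "reference.fasta")
    if config.mode == "reference":
        reference = {rec.id: str(rec.seq).upper()
                     for rec in SeqIO.parse(config.reference, "fasta")}
        stats["reference"] = {"source": config.reference, "n_sequences": len(reference)}
    elif os.path.exists(ref_path) and not force:
        log.info("[denovo] reusing %s", ref_path)
        reference = {rec.id: str(rec.seq).upper()
                     for rec in SeqIO.parse(ref_path, "fasta")}
        stats["reference"] = {"source": ref_path, "n_sequences": len(reference)}
    else:
        watson = [p for (s, st), ps in binned.items() if st == WATSON for p in ps]
        crick = [p for (s, st), ps in binned.items() if st == CRICK for p in ps]
        clusters, dn_stats = denovo.build_reference(
            watson, crick, min_depth=config.min_depth,
            max_depth=config.max_depth, identity=config.identity)
        reference = {c.id: c.sequence for c in clusters}
        with open(ref_path, "w") as f:
            for c in clusters:
                f.write(f">{c.id}\n{c.sequence}\n")
        with open(os.path.join(outdir, "clusters.tsv"), "w") as f:
            f.write("id\tlength\twatson_depth\tcrick_depth\tmembers\n")
            for c in clusters:
                f.write(f"{c.id}\t{len(c.sequence)}\t{c.watson_depth}"
                        f"\t{c.crick_depth}\t{c.members}\n")
        stats["denovo"] = dn_stats
    if not reference:
        raise RuntimeError("empty reference; nothing to align to")

    # --- trimming + directional merge ----------------------------------
    trimmed: dict[tuple[str, str], list[ReadPair]] = {}
    trim_totals = {"input_pairs": 0, "pairs_with_adapter": 0,
                   "dropped_short": 0, "retained": 0}
    for key, ps in binned.items():
        t, tstats = trimmer.trim_all(ps, adapter=config.adapter,
                                     hard_trim=config.hard_trim,
                                     min_len=config.min_len)
        trimmed[key] = t
        for k in trim_totals:
            trim_totals[k] += getattr(tstats, k)
    stats["trimming"] = trim_totals

    # --- alignment ------------------------------------------------------
    index = bsalign.build_index(reference)
    all_records: list[bsalign.AlignmentRecord] = []
    align_totals = {"input_pairs": 0, "unique": 0, "ambiguous": 0, "unaligned": 0}
    samples = sorted({s for s, _ in trimmed})
    for sample in samples:
        m1, m2 = trimmer.merge_directional(
            trimmed.get((sample, WATSON), []), trimmed.get((sample, CRICK), []))
        recs, astats = bsalign.align_library(
            m1, m2, index, sample_of={r.id: sample for r in m1},
            min_score_frac=config.min_score_frac,
            nondirectional=config.nondirectional)
        all_records.extend(recs)
        for k in align_totals:
            align_totals[k] += getattr(astats, k)
    all_records.sort(key=lambda r: (r.cluster, r.start, r.read_id, r.mate))
    stats["alignment"] = dict(align_totals)
    stats["alignment"]["mapping_rate"] = (
        align_totals["unique"] / align_totals["input_pairs"]
        if align_totals["input_pairs"] else 0.0)
    bsalign.write_alignments(all_records, reference,
                             os.path.join(outdir, "alignments.sam"))

    # --- methylation ----------------------------------------------------
    meth_stats = {}
    for sample in samples:
        recs = [r for r in all_records if r.sample == sample]
        cx = methylation.call_methylation(recs, reference)
        methylation.write_cx_report(
            cx, os.path.join(outdir, f"{sample}.CX_report.txt"))
        per_ctx: dict[str, list[float]] = {"CG": [0, 0], "CHG": [0, 0], "CHH": [0, 0]}
        for r in cx:
            per_ctx[r.context][0] += r.count_methylated
            per_ctx[r.context][1] += r.count_unmethylated
        meth_stats[sample] = {
            ctx: (m / (m + u) if m + u else 0.0) for ctx, (m, u) in per_ctx.items()}
        mb = methylation.mbias(recs, reference)
        mb.to_csv(os.path.join(outdir, f"{sample}.mbias.tsv"), sep="\t", index=False)
    stats["methylation_percent"] = meth_stats

    # --- variants -------------------------------------------------------
    masked = [variants.double_mask(r, reference) for r in all_records]
    params = variants.CallerParams(min_coverage=config.min_coverage,
                                   min_base_quality=config.min_base_quality,
                                   min_mapping_quality=config.min_mapping_quality)
    vrecs = variants.filter_snps(variants.call_variants(masked, reference, params))
    variants.write_vcf(vrecs, samples, reference,
                       os.path.join(outdir, "variants.vcf"))
    stats["variants"] = {"n_snps": len(vrecs)}

    report(stats, outdir)
    return PipelineResult(outdir=outdir, reference=reference, stats=stats)


def report(stats: dict, outdir: str) -> str:
    """Write the consolidated run report (JSON + plain-text summary)."""
    path = os.path.join(outdir, "report.json")
    with open(path, "w") as f:
        json.dump(stats, f, indent=2, default=str)
    lines = ["run report", "=" * 40]
    for section, payload in stats.items():
        lines.append(f"[{section}]")
        if isinstance(payload, dict):
            for k, v in payload.items():
                lines.append(f"  {k}: {v}")
        else:
            lines.append(f"  {payload}")
    with open(os.path.join(outdir, "report.txt"), "w") as f:
        f.write("\n".join(lines) + "\n")
    return path
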