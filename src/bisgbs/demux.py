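"""UMI clone removal, barcode expansion, demultiplexing and strand annotation.

A directional double-digest bisulfite library tags every read pair with a
3-nt UMI, a per-sample barcode pair and a single control nucleotide (CN)
whose bisulfite fate identifies the strand of origin: Watson pairs read T at
the CN of R1 and C at the CN of R2, Crick pairs the reverse.  Demultiplexing
therefore expands each sample's barcode pair into a Watson key and a Crick
key (barcode + CN) and assigns pairs by exact-prefix match, then validates
the restriction-enzyme overhang remnant that must follow the key, rescuing a
single mismatch (a bisulfite-converted overhang base) by replacing it with
the expected base.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .simdata import Enzyme, ReadPair

__all__ = [
    "BarcodeSpec",
    "ExpandedBarcode",
    "DemuxStats",
    "RescueResult",
    "remove_clones",
    "expand_barcodes",
    "quality_pass",
    "rescue_overhang",
    "demultiplex",
    "read_barcode_file",
]

WATSON = "Watson"
CRICK = "Crick"


@dataclass(frozen=True)
class BarcodeSpec:
    sample: str
    bc1: str
    bc2: str


@dataclass(frozen=True)
class ExpandedBarcode:
    sample: str
    strand_class: str  # WATSON or CRICK
    key1: str          # bc1 + control nucleotide expected in R1
    key2: str          # bc2 + control nucleotide expected in R2


@dataclass
class CloneStats:
    input_pairs: int = 0
    clones_removed: int = 0
    too_short_dropped: int = 0
    retained: int = 0

    @property
    def clone_fraction(self) -> float:
        return self.clones_removed / self.input_pairs if self.input_pairs else 0.0


@dataclass
class DemuxStats:
    input_pairs: int = 0
    ambiguous_barcode_drops: int = 0
    low_quality_drops: int = 0
    ambiguous_radtag_drops: int = 0
    retained_per_sample: dict[str, int] = field(default_factory=dict)
    observed_unexpected_barcodes: Counter = field(default_factory=Counter)

    @property
    def retained(self) -> int:
        return sum(self.retained_per_sample.values())


class RescueResult(Enum):
    ACCEPT_EXACT = "ACCEPT_EXACT"
    ACCEPT_REPLACED = "ACCEPT_REPLACED"
    REJECT = "REJECT"


def read_barcode_file(path: str) -> list[BarcodeSpec]:
    """Read a TSV barcode table with header sample/barcode_R1/barcode_R2."""
    specs = []
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample", "barcode_R1", "barcode_R2"]:
            raise ValueError("barcode file must have header sample/barcode_R1/barcode_R2")
        for line in f:
            if line.strip():
                sample, bc1, bc2 = line.rstrip("\n").split("\t")[:3]
                specs.append(BarcodeSpec(sample, bc1.upper(), bc2.upper()))
    return specs


def remove_clones(pairs: list[ReadPair], umi_length: int = 3) -> tuple[list[ReadPair], CloneStats]:
    """Drop PCR clones: pairs identical in both UMIs and both sequences.

    The first pair of each clone family is retained; UMIs (first
    ``umi_length`` bases and qualities of each mate) are stripped from the
    retained reads.
    """
    stats = CloneStats(input_pairs=len(pairs))
    seen: set[tuple[str, str]] = set()
    out: list[ReadPair] = []
    for p in pairs:
        if len(p.seq1) < umi_length or len(p.seq2) < umi_length:
            stats.too_short_dropped += 1
            continue
        key = (p.seq1, p.seq2)  # includes both UMIs and both fragments
        if key in seen:
            stats.clones_removed += 1
            continue
        seen.add(key)
        out.append(ReadPair(p.id, p.seq1[umi_length:], p.seq2[umi_length:],
                            p.qual1[umi_length:], p.qual2[umi_length:]))
    stats.retained = len(out)
    return out, stats


def expand_barcodes(table: list[BarcodeSpec]) -> list[ExpandedBarcode]:
    """Append the Watson (T/C) and Crick (C/T) control nucleotides to each pair."""
    if len({(b.bc1, b.bc2) for b in table}) != len(table):
        raise ValueError("duplicate (bc1, bc2) combination in barcode table")
    out = []
    for b in table:
        out.append(ExpandedBarcode(b.sample, WATSON, b.bc1 + "T", b.bc2 + "C"))
        out.append(ExpandedBarcode(b.sample, CRICK, b.bc1 + "C", b.bc2 + "T"))
    return out


def quality_pass(qual: str, threshold: float = 10, window_fraction: float = 0.15) -> bool:
    """Sliding-window raw-quality filter.

    Fails iff any window of length ceil(window_fraction * read length)
    (step 1) has mean phred below ``threshold``.
    """
    if not qual:
        raise ValueError("empty quality string")
    phred = [ord(c) - 33 for c in qual]
    w = max(1, math.ceil(window_fraction * len(phred)))
    s = sum(phred[:w])
    if s / w < threshold:
        return False
    for i in range(w, len(phred)):
        s += phred[i] - phred[i - w]
        if s / w < threshold:
            return False
    return True


def rescue_overhang(observed: str, expected: str,
                    mode: str = "any_single_mismatch") -> tuple[RescueResult, str]:
    """Validate a restriction overhang remnant, rescuing one mismatch.

    Returns the decision and the resulting sequence.  In the default
    ``any_single_mismatch`` mode the mismatching base is replaced with the
    expected base.  In ``ct_only`` mode only a bisulfite-explainable
    mismatch (expected C read as T, or expected G read as A) is rescuable
    and the observed base is kept: replacing a converted T with C would
    relabel an unmethylated overhang cytosine as methylated, so this mode
    approves the overhang without rewriting it.
    """
    if len(observed) != len(expected):
        return RescueResult.REJECT, observed
    mism = [i for i, (o, e) in enumerate(zip(observed, expected)) if o != e]
    if not mism:
        return RescueResult.ACCEPT_EXACT, observed
    if len(mism) > 1:
        return RescueResult.REJECT, observed
    i = mism[0]
    if mode == "ct_only":
        ok = (expected[i] == "C" and observed[i] == "T") or \
             (expected[i] == "G" and observed[i] == "A")
        if not ok:
            return RescueResult.REJECT, observed
        return RescueResult.ACCEPT_REPLACED, observed
    if mode != "any_single_mismatch":
        raise ValueError(f"unknown rescue mode {mode!r}")
    return RescueResult.ACCEPT_REPLACED, observed[:i] + expected[i] + observed[i + 1:]


def _match_key(seq: str, key: str, max_mismatch: int) -> bool:
    if len(seq) < len(key):
        return False
    if max_mismatch == 0:
        return seq.startswith(key)
    return sum(a != b for a, b in zip(seq, key)) <= max_mismatch


def demultiplex(
    pairs: list[ReadPair],
    expanded: list[ExpandedBarcode],
    enzymes: tuple[Enzyme, Enzyme],
    mismatches_r1: int = 0,
    mismatches_r2: int = 0,
    rescue_mode: str = "any_single_mismatch",
    quality_threshold: float = 10,
    quality_window_fraction: float = 0.15,
) -> tuple[dict[tuple[str, str], list[ReadPair]], DemuxStats]:
    """Assign clone-removed pairs to (sample, strand class) bins.

    A pair is assigned iff exactly one expanded barcode matches both mate
    prefixes at the allowed mismatch level; the following overhang must then
    match one enzyme remnant per mate (either enzyme order, since fragment
    orientation is unknown), with single-mismatch rescue.  Assigned reads
    have barcode + control nucleotide stripped and the overhang retained.
    """
    stats = DemuxStats(input_pairs=len(pairs))
    stats.retained_per_sample = {e.sample: 0 for e in expanded}
    out: dict[tuple[str, str], list[ReadPair]] = {
        (e.sample, e.strand_class): [] for e in expanded
    }
    rem_a, rem_b = enzymes[0].remnant, enzymes[1].remnant
    key_lengths = sorted({(len(e.key1), len(e.key2)) for e in expanded})

    for p in pairs:
        hits = [e for e in expanded
                if _match_key(p.seq1, e.key1, mismatches_r1)
                and _match_key(p.seq2, e.key2, mismatches_r2)]
        if len(hits) != 1:
            if not hits and key_lengths:
                l1, l2 = key_lengths[0]
                stats.observed_unexpected_barcodes[(p.seq1[:l1], p.seq2[:l2])] += 1
            stats.ambiguous_barcode_drops += 1
            continue
        hit = hits[0]
        s1, s2 = p.seq1[len(hit.key1):], p.seq2[len(hit.key2):]
        q1, q2 = p.qual1[len(hit.key1):], p.qual2[len(hit.key2):]
        if not (quality_pass(q1, quality_threshold, quality_window_fraction)
                and quality_pass(q2, quality_threshold, quality_window_fraction)):
            stats.low_quality_drops += 1
            continue
        fixed = _overhang_check(s1, s2, rem_a, rem_b, rescue_mode)
        if fixed is None:
            stats.ambiguous_radtag_drops += 1
            continue
        s1, s2 = fixed
        out[(hit.sample, hit.strand_class)].append(
            ReadPair(f"{p.id}|{hit.sample}|{hit.strand_class}", s1, s2, q1, q2))
        stats.retained_per_sample[hit.sample] += 1
    return out, stats


def _overhang_check(s1: str, s2: str, rem_a: str, rem_b: str,
                    mode: str) -> tuple[str, str] | None:
    """Try both enzyme orders; return overhang-corrected mates or None.

    When both orders are acceptable (e.g. a converted MspI "TGG" start is
    also a valid exact start for a T-remnant enzyme), the order needing
    fewer rescue replacements wins.
    """
    best = None
    for e1, e2 in ((rem_a, rem_b), (rem_b, rem_a)):
        r1, fixed1 = rescue_overhang(s1[:len(e1)], e1, mode)
        r2, fixed2 = rescue_overhang(s2[:len(e2)], e2, mode)
        if r1 == RescueResult.REJECT or r2 == RescueResult.REJECT:
            continue
        n_repl = ((r1 == RescueResult.ACCEPT_REPLACED)
                  + (r2 == RescueResult.ACCEPT_REPLACED))
        cand = (n_repl, fixed1 + s1[len(e1):], fixed2 + s2[len(e2):])
        if best is None or cand[0] < best[0]:
            best = cand
    return None if best is None else (best[1], best[2])
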