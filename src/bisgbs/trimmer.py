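"""3' adapter trimming, first-base removal and directional re-merge.

Reads longer than their DNA fragment run through the fragment end into the
custom adapter (UMI + barcode + CN, reverse-complemented) and then into the
standard Illumina adapter.  Trimming locates the Illumina adapter at the 3'
end, truncates there, removes the filled-in first base from the 5' end of
every read, hard-trims a further 10 bp from the 3' end of adapter-containing
reads (the read-through copy of the custom adapter) and drops pairs with a
mate shorter than 20 bp.  Finally Watson and Crick read sets are merged into
a conventional directional library: mate1 = Watson R1 + Crick R2, mate2 =
Watson R2 + Crick R1, so that mate1 always carries top-strand sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .demux import CRICK, WATSON
from .simdata import ILLUMINA_ADAPTER, ReadPair

__all__ = ["TrimStats", "find_adapter", "trim_pair", "trim_all", "merge_directional"]

DROP = None


@dataclass
class TrimStats:
    input_pairs: int = 0
    pairs_with_adapter: int = 0
    dropped_short: int = 0
    retained: int = 0


def find_adapter(seq: str, adapter: str = ILLUMINA_ADAPTER,
                 min_overlap: int = 3, max_mismatch_frac: float = 0.1) -> int | None:
    """0-based position where the adapter starts in ``seq``, or None.

    The adapter may occur internally (full occurrence, leftmost wins) or as
    a partial overlap at the read's 3' end (longest suffix of the read
    matching a prefix of the adapter).  Both allow up to
    ``max_mismatch_frac`` mismatches per overlap; partial overlaps shorter
    than ``min_overlap`` are ignored.
    """
    n = len(seq)
    # fast path: exact internal occurrence
    i = seq.find(adapter)
    if i != -1:
        return i
    # seeded internal search with mismatches
    k = min(8, len(adapter))
    seed = adapter[:k]
    i = seq.find(seed)
    while i != -1:
        ov = min(len(adapter), n - i)
        if ov >= min_overlap:
            allowed = int(max_mismatch_frac * ov)
            if _mismatches(seq[i:i + ov], adapter[:ov], allowed) <= allowed:
                return i
        i = seq.find(seed, i + 1)
    # suffix overlaps (adapter prefix at the very end of the read)
    for ov in range(min(n, len(adapter)) - 1, min_overlap - 1, -1):
        allowed = int(max_mismatch_frac * ov)
        if _mismatches(seq[n - ov:], adapter[:ov], allowed) <= allowed:
            return n - ov
    return None


def _mismatches(a: str, b: str, cap: int) -> int:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > cap:
                break
    return mism


def trim_pair(pair: ReadPair, adapter: str = ILLUMINA_ADAPTER,
              min_overlap: int = 3, hard_trim: int = 10,
              min_len: int = 20,
              max_mismatch_frac: float = 0.1) -> ReadPair | None:
    """Trim one pair; returns None (DROP) if either mate ends below min_len."""
    mates = []
    for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
        cut = find_adapter(seq, adapter, min_overlap, max_mismatch_frac)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]
        seq, qual = seq[1:], qual[1:]  # filled-in first base
        if cut is not None and hard_trim:
            seq, qual = seq[:max(0, len(seq) - hard_trim)], qual[:max(0, len(qual) - hard_trim)]
        if len(seq) < min_len:
            return DROP
        mates.append((seq, qual))
    (s1, q1), (s2, q2) = mates
    return ReadPair(pair.id, s1, s2, q1, q2)


def trim_all(pairs: list[ReadPair], **kwargs) -> tuple[list[ReadPair], TrimStats]:
    stats = TrimStats(input_pairs=len(pairs))
    out = []
    for p in pairs:
        if find_adapter(p.seq1, kwargs.get("adapter", ILLUMINA_ADAPTER),
                        kwargs.get("min_overlap", 3),
                        kwargs.get("max_mismatch_frac", 0.1)) is not None:
            stats.pairs_with_adapter += 1
        t = trim_pair(p, **kwargs)
        if t is DROP:
            stats.dropped_short += 1
        else:
            out.append(t)
    stats.retained = len(out)
    return out, stats


@dataclass
class DirectionalRead:
    id: str
    seq: str
    qual: str
    strand_class: str  # WATSON or CRICK


def merge_directional(
    watson_pairs: list[ReadPair], crick_pairs: list[ReadPair]
) -> tuple[list[DirectionalRead], list[DirectionalRead]]:
    """Combine Watson R1 with Crick R2 (mate1) and Watson R2 with Crick R1 (mate2).

    After the swap mate1 always reads 5'->3' along the top strand of the
    molecule (C->T converted for Watson pairs, G->A converted for Crick
    pairs) and mate2 the bottom, which is the layout a directional bisulfite
    aligner expects.  Pairing of ids is preserved.
    """
    mate1, mate2 = [], []
    for p in watson_pairs:
        mate1.append(DirectionalRead(p.id, p.seq1, p.qual1, WATSON))
        mate2.append(DirectionalRead(p.id, p.seq2, p.qual2, WATSON))
    for p in crick_pairs:
        mate1.append(DirectionalRead(p.id, p.seq2, p.qual2, CRICK))
        mate2.append(DirectionalRead(p.id, p.seq1, p.qual1, CRICK))
    ids1 = [r.id for r in mate1]
    ids2 = [r.id for r in mate2]
    if len(set(ids1)) != len(ids1) or set(ids1) != set(ids2):
        raise ValueError("unpaired or duplicate read ids after directional merge")
    return mate1, mate2
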