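"""Directional three-letter bisulfite alignment to a cluster reference.

Reads cannot be aligned in the raw alphabet because bisulfite conversion is
asymmetric and methylation-dependent.  Both the reference and the reads are
therefore collapsed into three-letter space — C->T for the original-top (OT)
orientation, G->A for original-bottom (OB) — which makes alignment scores
independent of the conversion state.  After directional merging, mate1
always carries top-strand sequence read left-to-right, so only two
orientations need to be tried per pair: OT (mate1 C->T forward against the
C->T reference) and OB (mate1 G->A forward against the G->A reference);
mate2 is aligned reverse-complemented in the same space.  A nondirectional
mode additionally tries the two complementary-strand orientations.

Verification is gapless seed-and-extend (match +1, mismatch -1): candidate
placements come from exact k-mer seeds, every candidate is scored over the
full read, the unique best-scoring cluster wins (MAPQ 40), ties are
ambiguous and below-threshold pairs unaligned.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .simdata import revcomp
from .trimmer import DirectionalRead

__all__ = [
    "AlignmentRecord",
    "BisulfiteIndex",
    "build_index",
    "align_pair",
    "align_library",
    "write_alignments",
    "read_alignments",
    "AMBIGUOUS",
    "UNALIGNED",
]

AMBIGUOUS = "AMBIGUOUS"
UNALIGNED = "UNALIGNED"

OT = "OT"   # read informative for top-strand cytosines (tag CT)
OB = "OB"   # read informative for bottom-strand cytosines (tag GA)

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")


@dataclass
class AlignmentRecord:
    read_id: str
    sample: str
    cluster: str
    start: int              # 1-based on the padded cluster
    cigar: str
    mapq: int
    bisulfite_strand: str   # OT or OB
    mate: int               # 1 or 2
    seq: str                # original letters, reference orientation
    qual: str

    @property
    def end(self) -> int:
        """1-based inclusive end (gapless records consume len(seq))."""
        return self.start + len(self.seq) - 1


class BisulfiteIndex:
    """Two converted copies of the reference plus exact k-mer seed tables."""

    def __init__(self, reference: dict[str, str], k: int = 16):
        if not reference:
            raise ValueError("empty reference")
        if len(set(reference)) != len(reference):
            raise ValueError("duplicate cluster ids")
        self.k = k
        self.names = list(reference)
        self.raw = dict(reference)
        self.ct = {n: s.upper().translate(_CT) for n, s in reference.items()}
        self.ga = {n: s.upper().translate(_GA) for n, s in reference.items()}
        self.ct_arr = {n: np.frombuffer(s.encode(), dtype=np.uint8)
                       for n, s in self.ct.items()}
        self.ga_arr = {n: np.frombuffer(s.encode(), dtype=np.uint8)
                       for n, s in self.ga.items()}
        self.ct_seeds = self._seed_table(self.ct)
        self.ga_seeds = self._seed_table(self.ga)

    def _seed_table(self, seqs: dict[str, str]) -> dict[str, list[tuple[str, int]]]:
        table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        k = self.k
        for name, s in seqs.items():
            for i in range(len(s) - k + 1):
                kmer = s[i:i + k]
                if "N" not in kmer:  # N positions never seed
                    table[kmer].append((name, i))
        return dict(table)


def build_index(reference: dict[str, str], k: int = 16) -> BisulfiteIndex:
    """Construct the converted references and seed tables."""
    return BisulfiteIndex(reference, k)


def _candidates(conv_read: str, seeds: dict, k: int,
                n_probes: int = 4) -> set[tuple[str, int]]:
    """Candidate (cluster, 0-based read-start) placements from seed hits."""
    out: set[tuple[str, int]] = set()
    n = len(conv_read)
    if n < k:
        return out
    offsets = {int(round(f * (n - k))) for f in
               np.linspace(0, 1, min(n_probes, n - k + 1))}
    for off in offsets:
        for name, pos in seeds.get(conv_read[off:off + k], ()):
            out.add((name, pos - off))  # may be negative: junk head clipped later
    return out


def _score(conv_read: str, ref_arr: np.ndarray, start: int) -> int:
    """Gapless score (match +1, mismatch -1) of a placement.

    Bases overhanging either reference end (read-through junk on reads
    longer than their cluster) are counted as mismatches.
    """
    n = len(conv_read)
    lo = max(0, start)
    hi = min(len(ref_arr), start + n)
    if hi <= lo:
        return -n
    seg = ref_arr[lo:hi]
    read = np.frombuffer(conv_read[lo - start:hi - start].encode(), dtype=np.uint8)
    matches = int((seg == read).sum())
    return 2 * matches - n


def _best_placements(conv_read: str, index: BisulfiteIndex, space: str
                     ) -> dict[str, tuple[int, int]]:
    """Best (score, start) per cluster for one converted read."""
    seeds = index.ct_seeds if space == "CT" else index.ga_seeds
    arrs = index.ct_arr if space == "CT" else index.ga_arr
    best: dict[str, tuple[int, int]] = {}
    for name, start in _candidates(conv_read, seeds, index.k):
        sc = _score(conv_read, arrs[name], start)
        if name not in best or sc > best[name][0]:
            best[name] = (sc, start)
    return best


def align_pair(mate1: DirectionalRead, mate2: DirectionalRead,
               index: BisulfiteIndex, min_score_frac: float = 0.6,
               sample: str = "", nondirectional: bool = False):
    """Align one directional pair; returns a record pair, AMBIGUOUS or UNALIGNED.

    OT hypothesis: mate1 C->T forward, revcomp(mate2) C->T forward, both on
    the C->T reference.  OB: the G->A mirror.  Both mates must place on the
    same cluster; the unique best total score wins.
    """
    hypotheses = [
        (OT, mate1.seq.translate(_CT), revcomp(mate2.seq).translate(_CT), "CT"),
        (OB, mate1.seq.translate(_GA), revcomp(mate2.seq).translate(_GA), "GA"),
    ]
    if nondirectional:
        hypotheses += [
            (OB, revcomp(mate1.seq).translate(_GA), mate2.seq.translate(_GA), "GA"),
            (OT, revcomp(mate1.seq).translate(_CT), mate2.seq.translate(_CT), "CT"),
        ]
    results = []  # (total score, strand, cluster, s1, s2, flip)
    for h_i, (strand, c1, c2, space) in enumerate(hypotheses):
        p1 = _best_placements(c1, index, space)
        p2 = _best_placements(c2, index, space)
        for cluster in set(p1) & set(p2):
            sc1, s1 = p1[cluster]
            sc2, s2 = p2[cluster]
            results.append((sc1 + sc2, strand, cluster, s1, s2, h_i >= 2))
    if not results:
        return UNALIGNED
    results.sort(key=lambda r: -r[0])
    min_score = min_score_frac * (len(mate1.seq) + len(mate2.seq))
    if results[0][0] < min_score:
        return UNALIGNED
    top = [r for r in results if r[0] == results[0][0]]
    if len({(r[2], r[3], r[4]) for r in top}) > 1:
        return AMBIGUOUS
    # ties that agree on cluster and coordinates (e.g. a read without any
    # conversion-informative position scores equally in OT and OB space)
    # resolve to the first hypothesis
    _, strand, cluster, s1, s2, flipped = results[0]
    seq1, qual1 = mate1.seq, mate1.qual
    seq2, qual2 = revcomp(mate2.seq), mate2.qual[::-1]
    if flipped:
        seq1, qual1 = revcomp(mate1.seq), mate1.qual[::-1]
        seq2, qual2 = mate2.seq, mate2.qual
    ref_len = len(index.raw[cluster])
    fc1, fc2 = max(0, -s1), max(0, -s2)
    seq1, qual1, s1 = seq1[fc1:ref_len - s1], qual1[fc1:ref_len - s1], s1 + fc1
    seq2, qual2, s2 = seq2[fc2:ref_len - s2], qual2[fc2:ref_len - s2], s2 + fc2
    rec1 = AlignmentRecord(mate1.id, sample, cluster, s1 + 1, f"{len(seq1)}M",
                           40, strand, 1, seq1, qual1)
    rec2 = AlignmentRecord(mate2.id, sample, cluster, s2 + 1, f"{len(seq2)}M",
                           40, strand, 2, seq2, qual2)
    return rec1, rec2


@dataclass
class AlignStats:
    input_pairs: int = 0
    unique: int = 0
    ambiguous: int = 0
    unaligned: int = 0

    @property
    def mapping_rate(self) -> float:
        return self.unique / self.input_pairs if self.input_pairs else 0.0


def align_library(mate1s: list[DirectionalRead], mate2s: list[DirectionalRead],
                  index: BisulfiteIndex, sample_of: dict[str, str] | None = None,
                  min_score_frac: float = 0.6, nondirectional: bool = False
                  ) -> tuple[list[AlignmentRecord], AlignStats]:
    """Align all pairs; records are returned coordinate-sorted."""
    stats = AlignStats(input_pairs=len(mate1s))
    records: list[AlignmentRecord] = []
    for m1, m2 in zip(mate1s, mate2s):
        sample = (sample_of or {}).get(m1.id, _sample_from_id(m1.id))
        res = align_pair(m1, m2, index, min_score_frac, sample, nondirectional)
        if res == UNALIGNED:
            stats.unaligned += 1
        elif res == AMBIGUOUS:
            stats.ambiguous += 1
        else:
            stats.unique += 1
            records.extend(res)
    records.sort(key=lambda r: (r.cluster, r.start, r.read_id, r.mate))
    return records, stats


def _sample_from_id(read_id: str) -> str:
    """Demultiplexed read ids carry '|sample|strand' suffixes."""
    parts = read_id.split("|")
    return parts[1] if len(parts) >= 3 else "sample"


def write_alignments(records: list[AlignmentRecord], reference: dict[str, str],
                     path: str) -> None:
    """Write coordinate-sorted records as SAM with @SQ, @RG and XG tags."""
    import pysam

    prev = None
    for r in records:
        key = (r.cluster, r.start)
        if prev is not None and prev[0] == key[0] and key[1] < prev[1]:
            raise ValueError("records must be coordinate-sorted")
        prev = key
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in reference.items()],
        "RG": [{"ID": s, "SM": s} for s in sorted({r.sample for r in records})],
    }
    names = {n: i for i, n in enumerate(reference)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id.split("|")[0]
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(r.qual)
            a.reference_id = names[r.cluster]
            a.reference_start = r.start - 1
            a.cigarstring = r.cigar
            a.mapping_quality = r.mapq
            a.flag = (0x1 | 0x2 | (0x40 if r.mate == 1 else 0x80)
                      | (0x10 if (r.bisulfite_strand == OB) == (r.mate == 1) else 0))
            a.set_tag("RG", r.sample)
            a.set_tag("XG", "CT" if r.bisulfite_strand == OT else "GA")
            out.write(a)


def read_alignments(path: str) -> list[AlignmentRecord]:
    """Read SAM produced by write_alignments back into records."""
    import pysam

    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as f:
        for a in f:
            records.append(AlignmentRecord(
                read_id=a.query_name,
                sample=a.get_tag("RG") if a.has_tag("RG") else "sample",
                cluster=a.reference_name,
                start=a.reference_start + 1,
                cigar=a.cigarstring,
                mapq=a.mapping_quality,
                bisulfite_strand=OT if a.get_tag("XG") == "CT" else OB,
                mate=1 if a.is_read1 else 2,
                seq=a.query_sequence,
                qual=pysam.qualities_to_qualitystring(a.query_qualities),
            ))
    return records
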