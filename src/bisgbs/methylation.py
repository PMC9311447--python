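"""Per-cytosine methylation calling from strand-tagged alignments.

An original-top (OT) read reports the methylation state of top-strand
cytosines: a C over a reference C was protected (methylated), a T was
converted (unmethylated).  An original-bottom (OB) read symmetrically
reports bottom-strand cytosines, which sit at reference G positions in top
coordinates (read G = methylated, A = unmethylated).  Where the two mates of
a pair overlap, each reference position is counted from mate1 only, so
overlapping calls are never scored twice.  Context (CG / CHG / CHH) and the
trinucleotide are taken from the reference; positions whose context window
runs into N (cluster padding or join spacers) fall through to CHH with an
N-containing trinucleotide and are flagged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bsalign import OB, OT, AlignmentRecord
from .simdata import revcomp

__all__ = [
    "CytosineRecord",
    "call_methylation",
    "write_cx_report",
    "read_cx_report",
    "mbias",
]


@dataclass
class CytosineRecord:
    cluster: str
    position: int          # 1-based
    strand: str            # '+' or '-'
    count_methylated: int
    count_unmethylated: int
    context: str           # CG, CHG, CHH
    trinucleotide: str
    flagged: bool = False  # context window contained N

    @property
    def proportion(self) -> float:
        n = self.count_methylated + self.count_unmethylated
        return self.count_methylated / n if n else float("nan")

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated


def _context_tables(ref: str):
    """Per-position context/trinucleotide for + strand Cs and - strand Cs (ref G)."""
    n = len(ref)
    plus, minus = {}, {}
    for i, b in enumerate(ref):
        if b == "C":
            tri = ref[i:i + 3].ljust(3, "N")
            nxt, nxt2 = tri[1], tri[2]
            if nxt == "G":
                ctx = "CG"
            elif nxt2 == "G":
                ctx = "CHG"
            else:
                ctx = "CHH"
            plus[i] = (ctx, tri, "N" in tri)
        elif b == "G":
            win = ref[max(0, i - 2):i + 1].rjust(3, "N")
            tri = revcomp(win)
            prv, prv2 = win[1], win[0]
            if prv == "C":
                ctx = "CG"
            elif prv2 == "C":
                ctx = "CHG"
            else:
                ctx = "CHH"
            minus[i] = (ctx, tri, "N" in tri)
    return plus, minus


def call_methylation(alignments: list[AlignmentRecord], reference: dict[str, str],
                     sample: str | None = None,
                     min_base_quality: int = 0) -> list[CytosineRecord]:
    """Count methylated/unmethylated calls at every covered cytosine.

    ``alignments`` must be records of one sample (or pass ``sample`` to
    filter).  Records are paired by read id; overlapping reference positions
    of a proper pair are taken from mate1.
    """
    for r in alignments:
        if r.cluster not in reference:
            raise KeyError(f"alignment references {r.cluster!r} absent from reference")
    if sample is not None:
        alignments = [r for r in alignments if r.sample == sample]

    ctx_cache = {name: _context_tables(seq) for name, seq in reference.items()}
    meth: dict[str, np.ndarray] = {}
    unmeth: dict[str, np.ndarray] = {}
    for name, seq in reference.items():
        meth[name] = np.zeros((2, len(seq)), dtype=np.int64)   # row 0 '+', 1 '-'
        unmeth[name] = np.zeros((2, len(seq)), dtype=np.int64)

    by_pair: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in alignments:
        by_pair[r.read_id].append(r)

    for recs in by_pair.values():
        recs.sort(key=lambda r: r.mate)
        mate1_span = None
        for r in recs:
            s0 = r.start - 1
            exclude = None
            if r.mate == 1:
                mate1_span = (r.cluster, s0, s0 + len(r.seq))
            elif mate1_span is not None and mate1_span[0] == r.cluster:
                exclude = (mate1_span[1], mate1_span[2])
            _count_record(r, reference[r.cluster], meth[r.cluster],
                          unmeth[r.cluster], exclude, min_base_quality)

    out: list[CytosineRecord] = []
    for name in reference:
        plus, minus = ctx_cache[name]
        for row, strand, table in ((0, "+", plus), (1, "-", minus)):
            covered = np.nonzero(meth[name][row] + unmeth[name][row])[0]
            for i in covered:
                ctx, tri, flagged = table[int(i)]
                out.append(CytosineRecord(name, int(i) + 1, strand,
                                          int(meth[name][row, i]),
                                          int(unmeth[name][row, i]),
                                          ctx, tri, flagged))
    out.sort(key=lambda r: (r.cluster, r.position, r.strand))
    return out


def _count_record(r: AlignmentRecord, ref: str, meth: np.ndarray,
                  unmeth: np.ndarray, exclude: tuple[int, int] | None,
                  min_base_quality: int) -> None:
    s0 = r.start - 1
    ref_seg = np.frombuffer(ref[s0:s0 + len(r.seq)].encode(), dtype=np.uint8)
    read = np.frombuffer(r.seq.encode(), dtype=np.uint8)
    if len(ref_seg) < len(read):  # clipped at cluster end; ignore overhang
        read = read[:len(ref_seg)]
    mask = np.ones(len(read), dtype=bool)
    if exclude is not None:
        pos = np.arange(s0, s0 + len(read))
        mask &= (pos < exclude[0]) | (pos >= exclude[1])
    if min_base_quality > 0:
        quals = np.frombuffer(r.qual[:len(read)].encode(), dtype=np.uint8) - 33
        mask &= quals >= min_base_quality
    if r.bisulfite_strand == OT:
        at = mask & (ref_seg == ord("C"))
        row = 0
        m_base, u_base = ord("C"), ord("T")
    else:
        at = mask & (ref_seg == ord("G"))
        row = 1
        m_base, u_base = ord("G"), ord("A")
    idx = np.nonzero(at)[0]
    if idx.size == 0:
        return
    bases = read[idx]
    np.add.at(meth[row], s0 + idx[bases == m_base], 1)
    np.add.at(unmeth[row], s0 + idx[bases == u_base], 1)


def write_cx_report(records: list[CytosineRecord], path: str) -> None:
    """Write records as a per-cytosine TSV report (CX column layout)."""
    prev = None
    with open(path, "w") as f:
        for r in records:
            key = (r.cluster, r.position)
            if prev is not None and key < prev:
                raise ValueError("records must be sorted by cluster, position")
            prev = key
            f.write(f"{r.cluster}\t{r.position}\t{r.strand}\t{r.count_methylated}"
                    f"\t{r.count_unmethylated}\t{r.context}\t{r.trinucleotide}\n")


def read_cx_report(path: str) -> list[CytosineRecord]:
    out = []
    with open(path) as f:
        for line in f:
            c, p, s, m, u, ctx, tri = line.rstrip("\n").split("\t")
            out.append(CytosineRecord(c, int(p), s, int(m), int(u), ctx, tri,
                                      flagged="N" in tri))
    return out


def mbias(alignments: list[AlignmentRecord], reference: dict[str, str]) -> pd.DataFrame:
    """Methylation fraction per read cycle, split by mate and context.

    Cycle is the 1-based position in sequencing orientation: mate1 records
    are stored as sequenced; mate2 records were reverse-complemented during
    alignment, so their cycles count from the record's 3' end.
    """
    ctx_cache = {name: _context_tables(seq) for name, seq in reference.items()}
    counts: dict[tuple[int, str, int], list[int]] = defaultdict(lambda: [0, 0])
    for r in alignments:
        ref = reference[r.cluster]
        s0 = r.start - 1
        plus, minus = ctx_cache[r.cluster]
        n = min(len(r.seq), len(ref) - s0)
        for off in range(n):
            refbase = ref[s0 + off]
            base = r.seq[off]
            if r.bisulfite_strand == OT and refbase == "C":
                table, is_m, is_u = plus, base == "C", base == "T"
            elif r.bisulfite_strand == OB and refbase == "G":
                table, is_m, is_u = minus, base == "G", base == "A"
            else:
                continue
            if not (is_m or is_u):
                continue
            ctx = table[s0 + off][0]
            cycle = off + 1 if r.mate == 1 else len(r.seq) - off
            cell = counts[(r.mate, ctx, cycle)]
            cell[0] += is_m
            cell[1] += is_u
    rows = [
        {"mate": mate, "context": ctx, "cycle": cyc,
         "methylated": m, "unmethylated": u,
         "fraction": m / (m + u)}
        for (mate, ctx, cyc), (m, u) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["mate", "context", "cycle",
                                       "methylated", "unmethylated", "fraction"])
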