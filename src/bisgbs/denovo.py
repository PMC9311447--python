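"""De novo reconstruction of unconverted reference loci from bisulfite reads.

Bisulfite conversion destroys sequence identity within a strand class (an
unmethylated C reads as T on Watson, as A in top coordinates on Crick), so
reconstruction proceeds through progressively coarser encodings:

1. read-pair assembly (overlap consensus, excluding 3' read-through) or
   joining with an N spacer;
2. *three-letter* deduplication per strand class — Watson reads compared
   after C->T, Crick (top-oriented) after G->A — grouping all reads of one
   locus-strand regardless of methylation state, with a per-column majority
   consensus over the original letters and min/max depth bounds;
3. *binary* pairing — collapsing C->T and G->A simultaneously makes the
   Watson and Crick representations of one locus identical, which pairs the
   two strand clusters of each locus;
4. per-column merge of the Watson/Crick partner consensi back into the
   unconverted reference sequence (a Watson T opposite a Crick C was a
   converted C; a Watson G opposite a Crick A was a converted G on the
   bottom strand);
5. greedy centroid clustering by global identity, and N-padding of the
   final clusters for the aligner.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .demux import CRICK, WATSON
from .simdata import ReadPair, revcomp

__all__ = [
    "StrandCluster",
    "ReferenceCluster",
    "assemble_or_join",
    "three_letter_encode",
    "binary_encode",
    "dedup_consensus",
    "pair_watson_crick",
    "reconstruct_consensus",
    "cluster_identity",
    "build_reference",
    "global_identity",
]

JOIN_SPACER = "N" * 8

_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")
_BINARY = str.maketrans("CG", "TA")


@dataclass
class StrandCluster:
    encoded_key: str
    consensus: str
    depth: int
    strand_class: str


@dataclass
class ReferenceCluster:
    id: str
    sequence: str          # padded: NNNN + consensus + NNNN
    watson_depth: int
    crick_depth: int
    members: int = 1

    @property
    def core(self) -> str:
        """Cluster sequence with the 4-N padding stripped."""
        return self.sequence[4:-4]


def assemble_or_join(r1: str, r2: str, min_overlap: int = 10,
                     max_mismatch_frac: float = 0.1) -> str:
    """Merge a read pair into one insert sequence.

    r2 is reverse-complemented and slid against r1 over all insert lengths;
    the placement with the fewest mismatches over an overlap of at least
    ``min_overlap`` (ties: longest overlap, then shortest insert) wins, and
    the consensus over the insert excludes read-through tails.  Without an
    acceptable overlap the reads are joined with an 8-N spacer.

    Candidate placements are seeded from exact 16-mer matches, so a pair
    whose overlap contains no error-free seed word falls through to joining.
    """
    r2rc = revcomp(r2)
    n1, n2 = len(r1), len(r2rc)
    k = min(16, n1, n2)
    candidates: set[int] = set()
    # probe k-mers of r2rc at staggered offsets against r1 (and vice versa);
    # a hit of r2rc offset j at r1 position i implies insert length
    # L = (i - j) + n2, since r2rc spans insert coordinates [L - n2, L)
    for j in range(0, n2 - k + 1, 8):
        seed = r2rc[j:j + k]
        i = r1.find(seed)
        while i != -1:
            if i - j + n2 > 0:
                candidates.add(i - j + n2)
            i = r1.find(seed, i + 1)
    for i in range(0, n1 - k + 1, 8):
        seed = r1[i:i + k]
        j = r2rc.find(seed)
        while j != -1:
            if i - j + n2 > 0:
                candidates.add(i - j + n2)
            j = r2rc.find(seed, j + 1)
    best = None  # (mismatches/overlap, -overlap, L)
    for L in sorted(candidates):
        lo, hi = max(0, L - n2), min(n1, L)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        a = r1[lo:hi]
        b = r2rc[lo - (L - n2): hi - (L - n2)]
        mism = sum(x != y for x, y in zip(a, b))
        if mism <= max_mismatch_frac * overlap:
            cand = (mism / overlap, -overlap, L)
            if best is None or cand < best:
                best = cand
    if best is None:
        return r1 + JOIN_SPACER + r2rc
    L = best[2]
    lo = max(0, L - n2)
    # r1 authoritative over the overlap; left flank from r1, right from r2rc
    return r1[:min(n1, L)] + r2rc[min(n1, L) - (L - n2):]


def three_letter_encode(seq: str, strand_class: str) -> str:
    """Collapse the conversion-confounded letter: Watson C->T, Crick G->A."""
    if strand_class == WATSON:
        return seq.translate(_CT)
    if strand_class == CRICK:
        return seq.translate(_GA)
    raise ValueError(f"unknown strand class {strand_class!r}")


def binary_encode(seq: str) -> str:
    """Collapse C->T and G->A simultaneously (alphabet {A, T, N})."""
    return seq.translate(_BINARY)


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_IDX_BASE = "ACGTN"


def _majority_consensus(seqs: list[str]) -> str:
    """Per-column majority over original letters; ties and N-majorities -> N."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    out = []
    codes = [ord(c) for c in "ACGT"]
    counts = np.stack([(arr == c).sum(axis=0) for c in codes])  # 4 x L
    best = counts.argmax(axis=0)
    bestc = counts.max(axis=0)
    n_ties = (counts == bestc).sum(axis=0)
    for j in range(arr.shape[1]):
        if bestc[j] == 0 or n_ties[j] > 1:
            out.append("N")
        else:
            out.append("ACGT"[best[j]])
    return "".join(out)


def dedup_consensus(sequences: list[str], strand_class: str,
                    min_depth: int = 10, max_depth: int = 10000) -> list[StrandCluster]:
    """Dereplicate same-length sequences by identical three-letter encoding.

    Per group the consensus is the per-column majority over the original
    letters (ties become N); groups outside [min_depth, max_depth] are
    discarded.  Output is sorted by descending depth, then key.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for s in sequences:
        groups[three_letter_encode(s, strand_class)].append(s)
    clusters = []
    for key, members in groups.items():
        if not min_depth <= len(members) <= max_depth:
            continue
        clusters.append(StrandCluster(key, _majority_consensus(members),
                                      len(members), strand_class))
    clusters.sort(key=lambda c: (-c.depth, c.encoded_key))
    return clusters


def pair_watson_crick(
    watson_clusters: list[StrandCluster], crick_clusters: list[StrandCluster]
) -> tuple[list[tuple[StrandCluster, StrandCluster]], list[StrandCluster]]:
    """Pair strand clusters whose binary encodings agree.

    Crick consensi must already be in top-strand orientation.  The binary
    key is computed from the three-letter encoded key (equivalently from
    the consensus, but immune to the N a per-column majority tie leaves at
    a conversion-confounded column).  When several clusters share a binary
    key they are paired greedily by descending depth; leftovers are
    returned unpaired.
    """
    w_by_key: dict[str, list[StrandCluster]] = defaultdict(list)
    c_by_key: dict[str, list[StrandCluster]] = defaultdict(list)
    for c in watson_clusters:
        w_by_key[binary_encode(c.encoded_key)].append(c)
    for c in crick_clusters:
        c_by_key[binary_encode(c.encoded_key)].append(c)
    pairs, leftovers = [], []
    for key in sorted(set(w_by_key) | set(c_by_key)):
        ws = sorted(w_by_key.get(key, []), key=lambda c: -c.depth)
        cs = sorted(c_by_key.get(key, []), key=lambda c: -c.depth)
        for w, c in zip(ws, cs):
            pairs.append((w, c))
        leftovers.extend(ws[len(cs):])
        leftovers.extend(cs[len(ws):])
    return pairs, leftovers


_MERGE = {}
for _a in "ACGTN":
    for _b in "ACGTN":
        if _a == _b:
            _MERGE[(_a, _b)] = _a
        elif (_a, _b) == ("T", "C"):
            _MERGE[(_a, _b)] = "C"     # Watson converted C, Crick kept it
        elif (_a, _b) == ("G", "A"):
            _MERGE[(_a, _b)] = "G"     # bottom-strand converted C (top G)
        elif _a == "N":
            _MERGE[(_a, _b)] = _b
        elif _b == "N":
            _MERGE[(_a, _b)] = _a
        else:
            _MERGE[(_a, _b)] = "N"


def reconstruct_consensus(watson_seq: str, crick_top_seq: str) -> str:
    """Merge paired Watson/Crick consensi into the unconverted sequence.

    Equal letters stand; Watson T against Crick C restores a C, Watson G
    against Crick A restores a G; an N defers to the partner; any other
    disagreement is conversion-inconsistent and becomes N.
    """
    if len(watson_seq) != len(crick_top_seq):
        raise ValueError("paired consensi must have equal length")
    return "".join(_MERGE[(a, b)] for a, b in zip(watson_seq, crick_top_seq))


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -1


def global_identity(a: str, b: str) -> float:
    """Global pairwise identity: matches / alignment columns; N never matches."""
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        exact = sum(x == y and x != "N" for x, y in zip(a, b))
        if exact == len(a):
            return 1.0
    aln = _aligner.align(a, b)[0]
    idx = aln.indices  # 2 x columns, -1 in gap columns
    cols = idx.shape[1]
    matches = 0
    for j in range(cols):
        i1, i2 = idx[0, j], idx[1, j]
        if i1 >= 0 and i2 >= 0 and a[i1] == b[i2] and a[i1] != "N":
            matches += 1
    return matches / cols if cols else 0.0


@dataclass
class _Consensus:
    sequence: str
    watson_depth: int
    crick_depth: int


def cluster_identity(consensi: list[_Consensus] | list[tuple[str, int, int]],
                     identity: float = 0.99) -> list[ReferenceCluster]:
    """Greedy centroid clustering of reconstructed consensi.

    Sequences are processed in descending total depth; each joins the first
    centroid with global identity >= ``identity`` or founds a new one.
    Centroids are emitted N-padded with deterministic ids in processing
    order.
    """
    items = [c if isinstance(c, _Consensus) else _Consensus(*c) for c in consensi]
    items.sort(key=lambda c: (-(c.watson_depth + c.crick_depth), c.sequence))
    centroids: list[ReferenceCluster] = []
    cores: list[str] = []
    for it in items:
        placed = False
        for k, core in enumerate(cores):
            if abs(len(core) - len(it.sequence)) > (1 - identity) * max(len(core), len(it.sequence)) + 1:
                continue
            if global_identity(core, it.sequence) >= identity:
                centroids[k].members += 1
                centroids[k].watson_depth += it.watson_depth
                centroids[k].crick_depth += it.crick_depth
                placed = True
                break
        if not placed:
            cores.append(it.sequence)
            centroids.append(ReferenceCluster(
                id=f"cluster_{len(centroids):05d}",
                sequence="NNNN" + it.sequence + "NNNN",
                watson_depth=it.watson_depth,
                crick_depth=it.crick_depth,
            ))
    return centroids


def build_reference(
    watson_pairs: list[ReadPair],
    crick_pairs: list[ReadPair],
    min_depth: int = 10,
    max_depth: int = 10000,
    identity: float = 0.99,
    min_overlap: int = 10,
    keep_unpaired: bool = False,
) -> tuple[list[ReferenceCluster], dict]:
    """Full de novo branch: assembly -> dedup -> pairing -> merge -> clustering.

    Inputs are untrimmed, demultiplexed pairs (barcode/CN stripped, overhang
    retained) of each strand class, pooled over samples.
    """
    watson_seqs = [assemble_or_join(p.seq1, p.seq2, min_overlap) for p in watson_pairs]
    # Crick pairs: R1 reads the bottom strand; assembled sequence is
    # bottom-oriented, so flip to top-strand orientation before encoding.
    crick_seqs = [revcomp(assemble_or_join(p.seq1, p.seq2, min_overlap))
                  for p in crick_pairs]
    w_clusters = dedup_consensus(watson_seqs, WATSON, min_depth, max_depth)
    c_clusters = dedup_consensus(crick_seqs, CRICK, min_depth, max_depth)
    pairs, leftovers = pair_watson_crick(w_clusters, c_clusters)
    consensi = [_Consensus(reconstruct_consensus(w.consensus, c.consensus),
                           w.depth, c.depth) for w, c in pairs]
    if keep_unpaired:
        for lc in leftovers:
            seq = three_letter_encode(lc.consensus, lc.strand_class)
            masked = "".join("N" if (lc.strand_class == WATSON and b == "T")
                             or (lc.strand_class == CRICK and b == "A") else b
                             for b in seq)
            w = lc.depth if lc.strand_class == WATSON else 0
            consensi.append(_Consensus(masked, w, lc.depth - w))
    clusters = cluster_identity(consensi, identity)
    stats = {
        "watson_reads": len(watson_seqs),
        "crick_reads": len(crick_seqs),
        "watson_strand_clusters": len(w_clusters),
        "crick_strand_clusters": len(c_clusters),
        "paired": len(pairs),
        "unpaired": len(leftovers),
        "clusters": len(clusters),
        "members_absorbed": sum(c.members for c in clusters),
    }
    return clusters, stats
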