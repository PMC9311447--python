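"""Evaluation procedures: cluster truth assessment, precision-sensitivity
sweeps, both-strand filtering, CpG destranding, coverage-filtered methylation
correlation, and Ward clustering of samples.

These mirror the standard benchmarking workflow for reduced-representation
bisulfite pipelines: reconstructed reference clusters are compared against
the loci they should represent; SNP calls are matched against a baseline set
by position and alternate allele (optionally ignoring genotype, the
"squash-ploidy" mode used when the baseline lacks heterozygous calls);
methylation proportions are compared by ordinary least squares after a
minimum-coverage filter and optional destranding of CpG dinucleotides.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .bsalign import OT, AlignmentRecord
from .denovo import ReferenceCluster, global_identity
from .methylation import CytosineRecord
from .simdata import Locus
from .variants import VariantRecord

__all__ = [
    "cluster_truth_stats",
    "pr_curve",
    "both_strand_filter",
    "destrand_cpg",
    "methylation_r2",
    "ward_clusters",
]


@dataclass
class ClusterTruthStats:
    n_clusters: int
    fraction_uniquely_matched: float
    mean_mismatches: float


def cluster_truth_stats(clusters: list[ReferenceCluster],
                        loci: list[Locus] | list[str],
                        min_identity: float = 0.9) -> ClusterTruthStats:
    """Match each cluster (padding stripped) against the true locus set.

    A cluster is uniquely matched when exactly one locus achieves its best
    identity (>= ``min_identity``); the mean mismatch count over uniquely
    matched clusters measures reconstruction accuracy.
    """
    seqs = [l.molecule if isinstance(l, Locus) else l for l in loci]
    if not clusters:
        return ClusterTruthStats(0, 0.0, 0.0)
    by_seq: dict[str, int] = defaultdict(int)
    for s in seqs:
        by_seq[s] += 1
    n_unique = 0
    mismatches = []
    for c in clusters:
        core = c.core
        if by_seq.get(core, 0) == 1:       # exact, unique
            n_unique += 1
            mismatches.append(0)
            continue
        if by_seq.get(core, 0) > 1:        # exact but multiple identical loci
            continue
        idents = [(global_identity(core, s), s) for s in seqs]
        best = max(i for i, _ in idents) if idents else 0.0
        hits = [s for i, s in idents if i == best]
        if best >= min_identity and len(hits) == 1:
            n_unique += 1
            s = hits[0]
            if len(s) == len(core):
                mismatches.append(sum(a != b for a, b in zip(core, s)))
            else:
                mismatches.append(round((1 - best) * max(len(s), len(core))))
    return ClusterTruthStats(
        n_clusters=len(clusters),
        fraction_uniquely_matched=n_unique / len(clusters),
        mean_mismatches=float(np.mean(mismatches)) if mismatches else 0.0,
    )


def _decompose(records: list[VariantRecord]):
    """(contig, pos, alt, genotype-wrt-that-alt) tuples, multiallelics split."""
    out = []
    for r in records:
        for k, alt in enumerate(r.alts, start=1):
            gts = {}
            for s, (gt, _, _) in r.genotypes.items():
                if gt == "./.":
                    continue
                a, b = (int(x) for x in gt.split("/"))
                dosage = (a == k) + (b == k)
                if dosage == 0 and (a not in (0, k) or b not in (0, k)):
                    continue  # genotype involves a different alt
                gts[s] = {0: "0/0", 1: "0/1", 2: "1/1"}[dosage]
            out.append((r.cluster, r.position, alt, r.qual, gts))
    return out


def pr_curve(calls: list[VariantRecord], baseline: list[VariantRecord],
             squash_ploidy: bool = False,
             qual_grid: list[float] | None = None):
    """Precision and sensitivity of SNP calls against a baseline, by QUAL.

    A true positive is a call matching a baseline record at the same contig,
    position and alternate allele; unless ``squash_ploidy``, the genotype of
    every genotyped sample must also match.  Sensitivity = TP / baseline
    records; precision = TP / calls at or above the threshold.
    """
    if not baseline:
        raise ValueError("empty baseline")
    if qual_grid is None:
        qual_grid = sorted({0.0} | {c.qual for c in calls})
    base_keys = {}
    for contig, pos, alt, _q, gts in _decompose(baseline):
        base_keys[(contig, pos, alt)] = gts
    call_items = _decompose(calls)
    rows = []
    for q in qual_grid:
        tp = fp = 0
        matched: set[tuple] = set()
        for contig, pos, alt, qual, gts in call_items:
            if qual < q:
                continue
            key = (contig, pos, alt)
            if key in base_keys and key not in matched:
                if squash_ploidy or _genotypes_agree(gts, base_keys[key]):
                    tp += 1
                    matched.add(key)
                    continue
            fp += 1
        fn = len(base_keys) - len(matched)
        precision = tp / (tp + fp) if tp + fp else 1.0
        sensitivity = tp / (tp + fn) if tp + fn else 1.0
        rows.append((q, precision, sensitivity))
    return rows


def _genotypes_agree(call_gts: dict[str, str], base_gts: dict[str, str]) -> bool:
    shared = set(call_gts) & set(base_gts)
    return all(call_gts[s] == base_gts[s] for s in shared)


def covered_positions(alignments: list[AlignmentRecord]) -> set[tuple[str, int]]:
    """(contig, 1-based position) pairs covered by at least one alignment."""
    out: set[tuple[str, int]] = set()
    for r in alignments:
        out.update((r.cluster, p) for p in range(r.start, r.end + 1))
    return out


def restrict_to_covered(baseline: list[VariantRecord],
                        alignments: list[AlignmentRecord]) -> list[VariantRecord]:
    """Drop baseline records at positions the call set's alignments never cover."""
    cov = covered_positions(alignments)
    return [r for r in baseline if (r.cluster, r.position) in cov]


def both_strand_filter(baseline: list[VariantRecord],
                       alignments: list[AlignmentRecord]) -> list[VariantRecord]:
    """Keep baseline positions with at least one OT and one OB observation."""
    ot: set[tuple[str, int]] = set()
    ob: set[tuple[str, int]] = set()
    for r in alignments:
        target = ot if r.bisulfite_strand == OT else ob
        target.update((r.cluster, p) for p in range(r.start, r.end + 1))
    keep = ot & ob
    return [r for r in baseline if (r.cluster, r.position) in keep]


def destrand_cpg(records: list[CytosineRecord]) -> list[CytosineRecord]:
    """Merge the two cytosines of each CpG dinucleotide into one record.

    The + strand C at position p and the - strand C at p+1 are combined with
    summed counts at coordinate p.  Only CG-context records are accepted.
    """
    for r in records:
        if r.context != "CG":
            raise ValueError("destranding applies to CG-context records only")
    plus = {(r.cluster, r.position): r for r in records if r.strand == "+"}
    minus = {(r.cluster, r.position): r for r in records if r.strand == "-"}
    out = []
    used_minus: set[tuple[str, int]] = set()
    for (cluster, pos), r in sorted(plus.items()):
        m = minus.get((cluster, pos + 1))
        if m is not None:
            used_minus.add((cluster, pos + 1))
            out.append(CytosineRecord(cluster, pos, "+",
                                      r.count_methylated + m.count_methylated,
                                      r.count_unmethylated + m.count_unmethylated,
                                      "CG", r.trinucleotide))
        else:
            out.append(CytosineRecord(cluster, pos, "+", r.count_methylated,
                                      r.count_unmethylated, "CG", r.trinucleotide))
    for (cluster, pos), m in sorted(minus.items()):
        if (cluster, pos) not in used_minus:
            out.append(CytosineRecord(cluster, pos - 1, "+", m.count_methylated,
                                      m.count_unmethylated, "CG", m.trinucleotide))
    out.sort(key=lambda r: (r.cluster, r.position))
    return out


def methylation_r2(set_a: list[CytosineRecord], set_b: list[CytosineRecord],
                   min_cov: int = 10) -> float:
    """R-squared of the least-squares fit of b's proportions on a's.

    Restricted to sites present in both sets with coverage >= ``min_cov``
    in both.  Raises on fewer than two usable shared sites.
    """
    a_by = {(r.cluster, r.position, r.strand): r for r in set_a}
    xs, ys = [], []
    for r in set_b:
        partner = a_by.get((r.cluster, r.position, r.strand))
        if partner is None:
            continue
        if partner.coverage < min_cov or r.coverage < min_cov:
            continue
        xs.append(partner.proportion)
        ys.append(r.proportion)
    if len(xs) < 2:
        raise ValueError("fewer than 2 shared sites meeting the coverage filter")
    if np.std(xs) == 0 or np.std(ys) == 0:
        return 1.0 if np.allclose(xs, xs[0]) and np.allclose(ys, ys[0]) else 0.0
    fit = sp_stats.linregress(xs, ys)
    return float(fit.rvalue ** 2)


def aggregate_by_group(per_sample: dict[str, list[CytosineRecord]],
                       groups: dict[str, str]) -> dict[str, list[CytosineRecord]]:
    """Pool per-sample counts into group (accession) level records.

    Methylated and unmethylated counts are summed over the group's samples,
    so the pooled proportion is the coverage-weighted mean.
    """
    pooled: dict[str, dict[tuple, list]] = defaultdict(dict)
    for sample, records in per_sample.items():
        g = groups[sample]
        for r in records:
            key = (r.cluster, r.position, r.strand)
            cell = pooled[g].setdefault(key, [0, 0, r.context, r.trinucleotide])
            cell[0] += r.count_methylated
            cell[1] += r.count_unmethylated
    out = {}
    for g, cells in pooled.items():
        out[g] = [CytosineRecord(c, p, s, m, u, ctx, tri)
                  for (c, p, s), (m, u, ctx, tri) in sorted(cells.items())]
    return out


def ward_clusters(matrix: np.ndarray, labels: list[str],
                  distance: str = "correlation"):
    """Ward agglomerative clustering of samples.

    ``matrix`` is samples x features (methylation proportions or genotype
    dosages).  Correlation distance is 1 - Pearson; euclidean is the
    alternative.  Returns (scipy linkage matrix, labels, newick string).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if distance == "correlation":
        if np.any(np.std(matrix, axis=1) == 0):
            raise ValueError("constant sample rows have undefined correlation distance")
        d = pdist(matrix, metric="correlation")
    elif distance == "euclidean":
        d = pdist(matrix, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    z = hierarchy.linkage(d, method="ward")
    return z, labels, _to_newick(z, labels)


def _to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return walk(tree) + ";"


def cut_two(z: np.ndarray, labels: list[str]) -> tuple[set[str], set[str]]:
    """Membership of the two top-level branches of a linkage tree."""
    assign = hierarchy.fcluster(z, t=2, criterion="maxclust")
    g1 = {l for l, a in zip(labels, assign) if a == 1}
    g2 = {l for l, a in zip(labels, assign) if a == 2}
    return g1, g2
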