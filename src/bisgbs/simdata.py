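"""Synthetic double-digest bisulfite library generator with exact ground truth.

Emulates the full read anatomy of a dual-enzyme, directional,
reduced-representation bisulfite library: a 3-nt unique molecular identifier
(UMI), per-sample barcodes, a single control nucleotide (CN) whose
converted/unconverted state labels the strand of origin, the restriction
enzyme overhang remnant, the bisulfite-converted insert, and 3' read-through
into the opposite custom adapter followed by the standard Illumina adapter.

The generator also performs the in silico digestion recommended for study
design: digesting a genome with a pair of restriction enzymes, selecting
dual-cut fragments within a size window, and reporting the expected
complexity reduction.

End chemistry model
-------------------
Fragment boundaries are placed at the top-strand cut position of each
recognition site, so digest() fragments tile the genome exactly.  The
*sequenced molecule* of a locus additionally models end repair: at the right
end the duplex is extended (5' overhang fill-in) or trimmed (3' overhang
removal) to the bottom-strand cut position.  Fill-in uses 5-methyl-dCTP, so
filled bases never convert; the simulator tracks a per-strand protection
mask and reports those positions as fully methylated ground truth.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Enzyme",
    "Fragment",
    "Locus",
    "TruthSet",
    "SimConfig",
    "SimulatedLibrary",
    "MSPI",
    "NSII",
    "ENZYMES",
    "ILLUMINA_ADAPTER",
    "revcomp",
    "digest",
    "select_loci",
    "simulate_truth",
    "simulate_reads",
    "simulate_library",
    "default_barcodes",
    "write_library",
]

_COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHV", "TGCANYRMKSWVHDB")

# Read-through sequence of the standard Illumina TruSeq adapter as it appears
# at the 3' end of both mates, and the full adapter the simulator sequences
# into (index + flow-cell binding part) so that short inserts never run out
# of adapter before the end of the read.
ILLUMINA_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
FULL_ADAPTER_READTHROUGH = ILLUMINA_ADAPTER + "CATCACGATCTCGTATGCCGTCTTCTGCTTGTAAAACGACGGCCAGTGAAT"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme collapsed to its cut coordinates inside the motif.

    ``cut_offset_top`` is the 0-based position of the top-strand cut within
    the recognition motif; ``cut_offset_bottom`` the bottom-strand cut in top
    coordinates (defaults to ``len(recognition) - cut_offset_top``, exact for
    palindromic sites).  The 5' remnant — the bases a read is expected to
    start with at an end cut by this enzyme — is ``recognition[cut_offset_top:]``.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int = -1

    def __post_init__(self):
        rec = self.recognition.upper()
        if not rec or any(b not in _IUPAC for b in rec):
            raise ValueError(f"unknown IUPAC code in recognition {self.recognition!r}")
        object.__setattr__(self, "recognition", rec)
        if not 0 <= self.cut_offset_top <= len(rec):
            raise ValueError("cut_offset_top outside the recognition motif")
        if self.cut_offset_bottom < 0:
            object.__setattr__(self, "cut_offset_bottom", len(rec) - self.cut_offset_top)
        if not 0 <= self.cut_offset_bottom <= len(rec):
            raise ValueError("cut_offset_bottom outside the recognition motif")

    @property
    def remnant(self) -> str:
        """Expected 5' bases of a read starting at an end cut by this enzyme."""
        return self.recognition[self.cut_offset_top:]

    def sites(self, genome: str) -> list[int]:
        """0-based start positions of the recognition motif in ``genome``."""
        rec = self.recognition
        if all(b in "ACGT" for b in rec):
            hits, i = [], genome.find(rec)
            while i != -1:
                hits.append(i)
                i = genome.find(rec, i + 1)
            return hits
        # degenerate motif: scan with per-position alternatives
        alts = [_IUPAC[b] for b in rec]
        k = len(rec)
        return [
            i for i in range(len(genome) - k + 1)
            if all(genome[i + j] in alts[j] for j in range(k))
        ]


MSPI = Enzyme("MspI", "CCGG", 1)
NSII = Enzyme("NsiI", "ATGCAT", 5)
ENZYMES = {"MspI": MSPI, "NsiI": NSII}

GENOME_END = "genome_end"


@dataclass
class Fragment:
    """One digest fragment; boundaries sit at top-strand cut positions."""

    sequence: str
    left_enzyme: str   # enzyme name or "genome_end"
    right_enzyme: str
    start: int         # 0-based genome start
    end: int           # exclusive
    # signed right-end adjustment to the bottom-strand cut: >0 bases to
    # append (5' overhang fill-in), <0 bases to trim (3' overhang removal)
    right_shift: int = 0
    right_fill: str = ""


@dataclass
class Locus:
    """A size-selected fragment retained as a sequencing target."""

    id: str
    sequence: str      # raw top-cut fragment (unconverted top strand)
    left_enzyme: str
    right_enzyme: str
    genome_coord: tuple[str, int, int]  # contig, 1-based start, inclusive end
    right_shift: int = 0
    right_fill: str = ""

    @property
    def molecule(self) -> str:
        """Blunt double-stranded molecule actually ligated and sequenced."""
        if self.right_shift >= 0:
            return self.sequence + self.right_fill
        return self.sequence[: self.right_shift]

    def protection_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(top, bottom) boolean masks of 5mC-protected fill-in positions.

        Top protection blocks C->T conversion on Watson reads, bottom
        protection blocks the G->A appearance of bottom-strand conversion.
        """
        mol = self.molecule
        top = np.zeros(len(mol), dtype=bool)
        bottom = np.zeros(len(mol), dtype=bool)
        if self.right_shift > 0:
            top[len(mol) - self.right_shift:] = True
        enz = ENZYMES_BY_NAME.get(self.left_enzyme)
        if enz is not None and enz.cut_offset_bottom > enz.cut_offset_top:
            n = enz.cut_offset_bottom - enz.cut_offset_top
            bottom[:min(n, len(mol))] = True
        return top, bottom


# populated below default_barcodes; kept as a module-level registry so Locus
# can resolve enzyme names without carrying Enzyme objects around
ENZYMES_BY_NAME: dict[str, Enzyme] = dict(ENZYMES)


def register_enzyme(enzyme: Enzyme) -> None:
    ENZYMES_BY_NAME[enzyme.name] = enzyme


def digest(genome: str, enzymes: tuple[Enzyme, Enzyme] | list[Enzyme]) -> list[Fragment]:
    """Digest ``genome`` with two enzymes; fragments tile the genome exactly.

    Each internal boundary is a top-strand cut of one of the enzymes.  The
    right-end fill/trim needed to reach the bottom-strand cut is recorded on
    each fragment for downstream molecule construction.
    """
    genome = genome.upper()
    if any(b not in "ACGT" for b in genome):
        raise ValueError("genome must be over A/C/G/T")
    cuts: list[tuple[int, Enzyme, int]] = []  # (top cut pos, enzyme, motif start)
    for enz in enzymes:
        for p in enz.sites(genome):
            cuts.append((p + enz.cut_offset_top, enz, p))
    cuts.sort(key=lambda t: t[0])
    # drop duplicate cut coordinates (overlapping sites), keep first enzyme
    dedup: list[tuple[int, Enzyme, int]] = []
    for c in cuts:
        if not dedup or c[0] != dedup[-1][0]:
            if 0 < c[0] < len(genome):
                dedup.append(c)
    frags: list[Fragment] = []
    prev = 0
    prev_enz = GENOME_END
    for cut, enz, motif_start in dedup:
        shift, fill = _right_end_adjust(genome, enz, motif_start)
        frags.append(Fragment(genome[prev:cut], prev_enz, enz.name, prev, cut,
                              right_shift=shift, right_fill=fill))
        prev, prev_enz = cut, enz.name
    frags.append(Fragment(genome[prev:], prev_enz, GENOME_END, prev, len(genome)))
    return frags


def _right_end_adjust(genome: str, enz: Enzyme, motif_start: int) -> tuple[int, str]:
    shift = enz.cut_offset_bottom - enz.cut_offset_top
    if shift > 0:
        cut = motif_start + enz.cut_offset_top
        return shift, genome[cut:cut + shift]
    return shift, ""


def select_loci(
    fragments: list[Fragment],
    size_range: tuple[int, int],
    require_dual: bool = True,
    contig: str = "genome",
) -> list[Locus]:
    """Size-select fragments into loci; optionally require two distinct enzymes."""
    lo, hi = size_range
    loci = []
    for f in fragments:
        if not lo <= len(f.sequence) <= hi:
            continue
        if require_dual:
            if GENOME_END in (f.left_enzyme, f.right_enzyme):
                continue
            if f.left_enzyme == f.right_enzyme:
                continue
        loci.append(Locus(
            id=f"locus_{len(loci):05d}",
            sequence=f.sequence,
            left_enzyme=f.left_enzyme,
            right_enzyme=f.right_enzyme,
            genome_coord=(contig, f.start + 1, f.end),
            right_shift=f.right_shift,
            right_fill=f.right_fill,
        ))
    return loci


# ---------------------------------------------------------------------------
# configuration and truth


@dataclass
class SimConfig:
    """Study conditions of a simulated library.

    Defaults describe a typical dual-digest (MspI + NsiI) plant library
    sequenced 150 bp paired-end: ~30x per strand per sample per locus,
    complete conversion, context-specific methylation (CG ~ Beta(2,2),
    CHG 0.3, CHH 0.05).
    """

    genome_length: int = 1_800_000
    gc_content: float = 0.40
    enzymes: tuple[str, str] = ("MspI", "NsiI")
    size_range: tuple[int, int] = (120, 350)
    n_loci: int | None = 200
    n_samples: int = 4
    barcodes: list[tuple[str, str, str]] | None = None  # (sample, bc1, bc2)
    barcode_length: int = 6
    umi_length: int = 3
    read_length: int = 150
    coverage: int = 60              # read pairs per locus per sample (both strands)
    watson_fraction: float = 0.5    # probability a molecule is Watson
    conversion_efficiency: float = 1.0
    error_rate: float = 0.0
    pcr_duplicate_rate: float = 0.0
    heterozygosity: float = 0.0     # per-bp SNP rate per sample
    n_snps: int | None = None       # alternative: fixed number of SNP sites
    meth_cg: tuple[float, float] | float = (2.0, 2.0)  # Beta params or fixed level
    meth_chg: tuple[float, float] | float = 0.3
    meth_chh: tuple[float, float] | float = 0.05
    base_quality: int = 37
    seed: int = 0

    def enzyme_pair(self) -> tuple[Enzyme, Enzyme]:
        try:
            return ENZYMES_BY_NAME[self.enzymes[0]], ENZYMES_BY_NAME[self.enzymes[1]]
        except KeyError as e:
            raise ValueError(f"unknown enzyme {e.args[0]!r}") from None


@dataclass
class TruthSet:
    """Exact ground truth of a simulated library."""

    loci: list[Locus]
    # sample -> locus id -> list of (0-based molecule offset, ref, alt, genotype)
    sample_genotypes: dict[str, dict[str, list[tuple[int, str, str, str]]]]
    # sample -> locus id -> (0-based molecule offset, strand '+'/'-') -> p(methylated)
    methylation: dict[str, dict[str, dict[tuple[int, str], float]]]
    clone_labels: dict[str, str] = field(default_factory=dict)  # read id -> molecule id


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str


@dataclass
class SimulatedLibrary:
    config: SimConfig
    truth: TruthSet
    pairs: list[ReadPair]
    # read id -> (molecule id, sample, strand class, locus id)
    read_truth: dict[str, tuple[str, str, str, str]]


def default_barcodes(n: int, length: int = 6, seed: int = 101) -> list[tuple[str, str, str]]:
    """Deterministic barcode table with pairwise Hamming distance >= 3."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    while len(chosen) < 2 * n:
        cand = "".join(rng.choice(list("ACGT"), size=length))
        if all(sum(a != b for a, b in zip(cand, c)) >= 3 for c in chosen):
            chosen.append(cand)
    return [(f"S{i + 1}", chosen[2 * i], chosen[2 * i + 1]) for i in range(n)]


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def methylation_contexts(molecule: str) -> dict[tuple[int, str], str]:
    """Context (CG/CHG/CHH) of every cytosine on both strands of a molecule.

    Keys are (0-based position, strand); '-' strand cytosines appear as G on
    the given top-strand sequence.  Contexts at molecule edges with missing
    neighbours fall through to CHH, mirroring an N-containing trinucleotide.
    """
    out: dict[tuple[int, str], str] = {}
    n = len(molecule)
    for i, b in enumerate(molecule):
        if b == "C":
            nxt = molecule[i + 1] if i + 1 < n else "N"
            nxt2 = molecule[i + 2] if i + 2 < n else "N"
            out[(i, "+")] = "CG" if nxt == "G" else ("CHG" if nxt2 == "G" else "CHH")
        elif b == "G":
            prv = molecule[i - 1] if i >= 1 else "N"
            prv2 = molecule[i - 2] if i >= 2 else "N"
            out[(i, "-")] = "CG" if prv == "C" else ("CHG" if prv2 == "C" else "CHH")
    return out


def _draw_level(rng: np.random.Generator, model: tuple[float, float] | float) -> float:
    if isinstance(model, tuple):
        return float(rng.beta(*model))
    return float(model)


def simulate_truth(loci: list[Locus], config: SimConfig) -> TruthSet:
    """Draw per-sample SNP genotypes and per-cytosine methylation levels."""
    if not loci:
        raise ValueError("loci must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = [bc[0] for bc in (config.barcodes or default_barcodes(config.n_samples,
                                                                    config.barcode_length))]
    samples = samples[: config.n_samples]

    genotypes: dict[str, dict[str, list[tuple[int, str, str, str]]]] = {s: {} for s in samples}
    methylation: dict[str, dict[str, dict[tuple[int, str], float]]] = {s: {} for s in samples}

    # candidate SNP positions: outside both end motifs
    candidates: list[tuple[str, int]] = []
    mol_by_id: dict[str, str] = {}
    guard: dict[str, int] = {}
    for loc in loci:
        mol = loc.molecule
        mol_by_id[loc.id] = mol
        left = ENZYMES_BY_NAME.get(loc.left_enzyme)
        right = ENZYMES_BY_NAME.get(loc.right_enzyme)
        g_l = len(left.recognition) if left else 0
        g_r = len(right.recognition) if right else 0
        guard[loc.id] = g_l
        for i in range(g_l, max(g_l, len(mol) - g_r)):
            candidates.append((loc.id, i))

    if config.n_snps is not None:
        n_sites = min(config.n_snps, len(candidates))
    else:
        n_sites = rng.binomial(len(candidates), min(1.0, config.heterozygosity))
    site_idx = sorted(rng.choice(len(candidates), size=n_sites, replace=False)) if n_sites else []
    snp_sites = [candidates[i] for i in site_idx]

    bases = "ACGT"
    for loc_id, pos in snp_sites:
        ref = mol_by_id[loc_id][pos]
        alt = rng.choice([b for b in bases if b != ref])
        for s in samples:
            gt = rng.choice(["0/0", "0/1", "1/1"], p=[0.4, 0.4, 0.2])
            if gt != "0/0":
                genotypes[s].setdefault(loc_id, []).append((pos, ref, str(alt), str(gt)))

    for loc in loci:
        mol = mol_by_id[loc.id]
        top_prot, bot_prot = loc.protection_masks()
        ctx = methylation_contexts(mol)
        for s in samples:
            per_site: dict[tuple[int, str], float] = {}
            for (pos, strand), context in ctx.items():
                protected = top_prot[pos] if strand == "+" else bot_prot[pos]
                if protected:
                    per_site[(pos, strand)] = 1.0
                elif context == "CG":
                    per_site[(pos, strand)] = _draw_level(rng, config.meth_cg)
                elif context == "CHG":
                    per_site[(pos, strand)] = _draw_level(rng, config.meth_chg)
                else:
                    per_site[(pos, strand)] = _draw_level(rng, config.meth_chh)
            methylation[s][loc.id] = per_site
    return TruthSet(loci=loci, sample_genotypes=genotypes, methylation=methylation)


# ---------------------------------------------------------------------------
# read generation


def _apply_snps(mol: str, snps: list[tuple[int, str, str, str]],
                rng: np.random.Generator) -> str:
    """Pick one haplotype of a diploid molecule."""
    if not snps:
        return mol
    seq = list(mol)
    for pos, ref, alt, gt in snps:
        if gt == "1/1" or (gt == "0/1" and rng.random() < 0.5):
            seq[pos] = alt
    return "".join(seq)


def simulate_reads(truth: TruthSet, config: SimConfig) -> SimulatedLibrary:
    """Generate R1/R2 reads with UMIs, barcodes, CN, remnants and read-through.

    Watson molecules yield R1 = converted top strand from the left end and
    R2 = its complement from the right end; Crick molecules the reverse.
    Unmethylated cytosines convert independently with the configured
    efficiency; PCR duplicates replicate sequence and UMI; sequencing errors
    are applied last, independently per copy.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    barcodes = config.barcodes or default_barcodes(config.n_samples, config.barcode_length)
    barcodes = barcodes[: config.n_samples]
    if len(barcodes) < config.n_samples:
        raise ValueError("barcode count < n_samples")

    pairs: list[ReadPair] = []
    read_truth: dict[str, tuple[str, str, str, str]] = {}
    clone_labels: dict[str, str] = {}
    qual_char = chr(config.base_quality + 33)
    L = config.read_length
    serial = 0
    mol_serial = 0

    for loc in truth.loci:
        mol = loc.molecule
        top_prot, bot_prot = loc.protection_masks()
        for sample, bc1, bc2 in barcodes:
            meth = truth.methylation[sample][loc.id]
            snps = truth.sample_genotypes[sample].get(loc.id, [])
            for _ in range(config.coverage):
                mol_serial += 1
                mol_id = f"mol_{mol_serial:08d}"
                hap = _apply_snps(mol, snps, rng)
                watson = rng.random() < config.watson_fraction
                conv = _convert(hap, meth, top_prot, bot_prot, watson, rng,
                                config.conversion_efficiency)
                umi1 = "".join(rng.choice(list("ACGT"), size=config.umi_length))
                umi2 = "".join(rng.choice(list("ACGT"), size=config.umi_length))
                if watson:
                    cn1, cn2 = "T", "C"
                    core1, core2 = conv, revcomp(conv)
                    strand = "Watson"
                else:
                    cn1, cn2 = "C", "T"
                    core1, core2 = revcomp(conv), conv
                    strand = "Crick"
                r1 = (umi1 + bc1 + cn1 + core1 + revcomp(cn2) + revcomp(bc2)
                      + revcomp(umi2) + FULL_ADAPTER_READTHROUGH)[:L]
                r2 = (umi2 + bc2 + cn2 + core2 + revcomp(cn1) + revcomp(bc1)
                      + revcomp(umi1) + FULL_ADAPTER_READTHROUGH)[:L]
                r1 = r1.ljust(L, "A") if len(r1) < L else r1
                r2 = r2.ljust(L, "A") if len(r2) < L else r2
                n_copies = 1 + (rng.poisson(config.pcr_duplicate_rate)
                                if config.pcr_duplicate_rate > 0 else 0)
                for _copy in range(n_copies):
                    serial += 1
                    rid = f"sim_{serial:08d}"
                    e1 = _errors(r1, config.error_rate, rng)
                    e2 = _errors(r2, config.error_rate, rng)
                    pairs.append(ReadPair(rid, e1, e2, qual_char * len(e1), qual_char * len(e2)))
                    read_truth[rid] = (mol_id, sample, strand, loc.id)
                    clone_labels[rid] = mol_id

    truth = replace(truth, clone_labels=clone_labels)
    return SimulatedLibrary(config=config, truth=truth, pairs=pairs, read_truth=read_truth)


def _convert(hap: str, meth: dict[tuple[int, str], float],
             top_prot: np.ndarray, bot_prot: np.ndarray,
             watson: bool, rng: np.random.Generator, efficiency: float) -> str:
    """Bisulfite-convert one molecule (top-strand coordinates)."""
    seq = list(hap)
    if watson:
        for i, b in enumerate(seq):
            if b != "C" or (i < len(top_prot) and top_prot[i]):
                continue
            p = meth.get((i, "+"), 0.0)
            methylated = rng.random() < p
            if not methylated and rng.random() < efficiency:
                seq[i] = "T"
    else:
        for i, b in enumerate(seq):
            if b != "G" or (i < len(bot_prot) and bot_prot[i]):
                continue
            p = meth.get((i, "-"), 0.0)
            methylated = rng.random() < p
            if not methylated and rng.random() < efficiency:
                seq[i] = "A"
    return "".join(seq)


def _errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for i in rng.choice(len(seq), size=n_err, replace=False):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def simulate_library(config: SimConfig) -> SimulatedLibrary:
    """End-to-end: random genome -> digest -> size selection -> truth -> reads."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    enz = config.enzyme_pair()
    genome = _random_genome(rng, config.genome_length, config.gc_content)
    frags = digest(genome, enz)
    loci = select_loci(frags, config.size_range, require_dual=True)
    if config.n_loci is not None:
        loci = loci[: config.n_loci]
    for i, loc in enumerate(loci):  # stable ids after subsetting
        loc.id = f"locus_{i:05d}"
    truth = simulate_truth(loci, config)
    return simulate_reads(truth, config)


# ---------------------------------------------------------------------------
# file output


def write_library(lib: SimulatedLibrary, outdir: str) -> dict[str, str]:
    """Write R1/R2 gzip FASTQ, loci FASTA and truth TSV tables."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "r1": os.path.join(outdir, "reads_R1.fastq.gz"),
        "r2": os.path.join(outdir, "reads_R2.fastq.gz"),
        "loci": os.path.join(outdir, "loci.fasta"),
        "snps": os.path.join(outdir, "snps.tsv"),
        "meth": os.path.join(outdir, "meth.tsv"),
        "clones": os.path.join(outdir, "clones.tsv"),
        "barcodes": os.path.join(outdir, "barcodes.tsv"),
    }
    with gzip.open(paths["r1"], "wt") as f1, gzip.open(paths["r2"], "wt") as f2:
        for p in lib.pairs:
            f1.write(f"@{p.id}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}\n{p.seq2}\n+\n{p.qual2}\n")
    with open(paths["loci"], "w") as f:
        for loc in lib.truth.loci:
            f.write(f">{loc.id}\n{loc.molecule}\n")
    with open(paths["snps"], "w") as f:
        f.write("sample\tlocus\tpos_1based\tref\talt\tgenotype\n")
        for s, per_locus in lib.truth.sample_genotypes.items():
            for loc_id, snps in per_locus.items():
                for pos, ref, alt, gt in snps:
                    f.write(f"{s}\t{loc_id}\t{pos + 1}\t{ref}\t{alt}\t{gt}\n")
    with open(paths["meth"], "w") as f:
        f.write("sample\tlocus\tpos_1based\tstrand\tcontext\tp_meth\n")
        for s, per_locus in lib.truth.methylation.items():
            for loc_id, sites in per_locus.items():
                mol = next(l.molecule for l in lib.truth.loci if l.id == loc_id)
                ctx = methylation_contexts(mol)
                for (pos, strand), p in sorted(sites.items()):
                    f.write(f"{s}\t{loc_id}\t{pos + 1}\t{strand}\t{ctx[(pos, strand)]}\t{p:.6g}\n")
    with open(paths["clones"], "w") as f:
        f.write("read_id\tmolecule_id\tsample\tstrand\tlocus\n")
        for rid, (mol_id, sample, strand, loc_id) in lib.read_truth.items():
            f.write(f"{rid}\t{mol_id}\t{sample}\t{strand}\t{loc_id}\n")
    barcodes = lib.config.barcodes or default_barcodes(lib.config.n_samples,
                                                       lib.config.barcode_length)
    with open(paths["barcodes"], "w") as f:
        f.write("sample\tbarcode_R1\tbarcode_R2\n")
        for s, b1, b2 in barcodes[: lib.config.n_samples]:
            f.write(f"{s}\t{b1}\t{b2}\n")
    return paths
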