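"""Genomic coordinate model, GTF/BED/FASTA I/O, peak merging and annotation.

All internal coordinates are 0-based half-open on the forward strand; GTF
input (1-based closed) is converted on read, BED6 is the native exchange
dialect.  Strand-oriented windows (promoter, TTS, scan windows) are computed
in gene/peak orientation and mapped back to forward-strand intervals.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree
from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Peak",
    "GeneIndex",
    "read_gtf",
    "read_bed",
    "write_bed",
    "write_peak_table",
    "read_peak_table",
    "merge_peaks",
    "annotate_peak",
    "annotate_peaks",
    "extract_fasta_windows",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "TTS_UPSTREAM",
    "TTS_DOWNSTREAM",
    "CATEGORY_PRIORITY",
]

# Promoter-TSS window: 1000 bp upstream through 100 bp downstream of the TSS,
# both bounds inclusive, in gene orientation.  The TTS window mirrors it.
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100
TTS_UPSTREAM = 100
TTS_DOWNSTREAM = 1000

#: annotation categories, highest priority first
CATEGORY_PRIORITY = ("promoter-TSS", "TTS", "exon", "intron", "intergenic")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Stranded half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """Gene with strand-aware TSS/TTS and exon structure.

    ``tss`` is the position of the 5' end in strand orientation: on '+' it
    equals ``interval.start``, on '-' it equals ``interval.end - 1``.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def tts(self) -> int:
        if self.strand == "-":
            return self.interval.start
        return self.interval.end - 1

    def promoter_window(self) -> tuple[int, int]:
        """Inclusive genomic [lo, hi] of the promoter-TSS window."""
        return oriented_window(
            self.tss, self.strand, PROMOTER_UPSTREAM, PROMOTER_DOWNSTREAM
        )

    def tts_window(self) -> tuple[int, int]:
        return oriented_window(self.tts, self.strand, TTS_UPSTREAM, TTS_DOWNSTREAM)


def oriented_window(pos: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Inclusive genomic bounds of [pos - upstream, pos + downstream] taken in
    strand orientation (upstream = 5'-ward of pos)."""
    if strand == "-":
        return pos - downstream, pos + upstream
    return pos - upstream, pos + downstream


@dataclass
class Peak:
    """A transcription-initiation peak with annotation state."""

    peak_id: str
    interval: GenomicInterval
    center: int = -1
    score: int = 0
    category: str | None = None
    nearest_gene: str | None = None
    distance_to_tss: int | None = None
    stability: str = "unknown"

    def __post_init__(self):
        if self.center < 0:
            self.center = (self.interval.start + self.interval.end) // 2
        if not (self.interval.start <= self.center < self.interval.end):
            raise ValueError(
                f"peak {self.peak_id}: center {self.center} outside interval"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from a GTF file (1-based closed coordinates).

    ``gene`` features define the gene interval; ``exon`` features are attached
    by gene_id.  Genes without an explicit ``gene`` line take the span of
    their exons.  Output is sorted by (chrom, start, gene_id).
    """
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "exon", "transcript"):
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            attributes = _parse_gtf_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno} missing gene_id attribute")
            if feature == "gene":
                spans[gene_id] = iv
            elif feature == "exon":
                exons.setdefault(gene_id, []).append(iv)

    genes = []
    for gene_id in set(spans) | set(exons):
        ex = sorted(exons.get(gene_id, []), key=lambda e: e.start)
        if gene_id in spans:
            iv = spans[gene_id]
        else:
            iv = GenomicInterval(
                ex[0].chrom, ex[0].start, max(e.end for e in ex), ex[0].strand
            )
        genes.append(GeneModel(gene_id, iv, ex))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def read_bed(path) -> list[Peak]:
    """Read peaks from BED6 (0-based half-open; strand in column 6)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected BED6")
            chrom, start, end, name, score, strand = fields[:6]
            peaks.append(
                Peak(
                    peak_id=name,
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    score=int(score),
                )
            )
    return peaks


def write_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.peak_id}\t{p.score}\t{p.strand}\n"
            )


_TABLE_COLUMNS = (
    "peak_id", "chrom", "start", "end", "strand", "center",
    "category", "nearest_gene", "distance_to_tss", "stability",
)


def write_peak_table(peaks: list[Peak], path) -> None:
    """Write the annotated-peak side table (TSV)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.peak_id, p.chrom, str(p.interval.start),
                        str(p.interval.end), p.strand, str(p.center),
                        p.category or "NA", p.nearest_gene or "NA",
                        "NA" if p.distance_to_tss is None else str(p.distance_to_tss),
                        p.stability,
                    ]
                )
                + "\n"
            )


def read_peak_table(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            peaks.append(
                Peak(
                    peak_id=f[idx["peak_id"]],
                    interval=GenomicInterval(
                        f[idx["chrom"]], int(f[idx["start"]]),
                        int(f[idx["end"]]), f[idx["strand"]],
                    ),
                    center=int(f[idx["center"]]),
                    category=None if f[idx["category"]] == "NA" else f[idx["category"]],
                    nearest_gene=None if f[idx["nearest_gene"]] == "NA" else f[idx["nearest_gene"]],
                    distance_to_tss=None if f[idx["distance_to_tss"]] == "NA"
                    else int(f[idx["distance_to_tss"]]),
                    stability=f[idx["stability"]],
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# peak merging
# ---------------------------------------------------------------------------

def merge_peaks(per_sample_peaks: list[list[Peak]], id_prefix: str = "peak") -> list[Peak]:
    """Condense peaks that directly overlap (>= 1 bp, same strand) into one
    peak spanning their union.

    csRNA-seq is strand-resolved, so '+' and '-' peaks never merge; abutting
    half-open intervals do not overlap and stay separate.  Idempotent and
    independent of input order.  Merged peaks are renamed ``<prefix>_NNNNN``
    in (chrom, start, strand) order with center at the interval midpoint.
    """
    flat = [p for sample in per_sample_peaks for p in sample]
    flat.sort(key=lambda p: (p.chrom, p.strand, p.interval.start, p.interval.end))
    merged: list[tuple[str, str, int, int]] = []
    for p in flat:
        if merged:
            chrom, strand, start, end = merged[-1]
            if chrom == p.chrom and strand == p.strand and p.interval.start < end:
                merged[-1] = (chrom, strand, start, max(end, p.interval.end))
                continue
        merged.append((p.chrom, p.strand, p.interval.start, p.interval.end))
    merged.sort(key=lambda t: (t[0], t[2], t[3], t[1]))
    width = max(5, len(str(len(merged))))
    return [
        Peak(f"{id_prefix}_{i:0{width}d}", GenomicInterval(chrom, start, end, strand))
        for i, (chrom, strand, start, end) in enumerate(merged)
    ]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval and TSS indexes over a gene set, for peak annotation."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        self._tss: dict[str, tuple[list[int], list[str]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g)
        for chrom, glist in by_chrom.items():
            tree = IntervalTree()
            for g in glist:
                plo, phi = g.promoter_window()
                tlo, thi = g.tts_window()
                lo = min(g.interval.start, plo, tlo)
                hi = max(g.interval.end, phi + 1, thi + 1)
                tree.addi(lo, hi, g)
            self._trees[chrom] = tree
            # TSS sorted with gene_id tie-break for deterministic nearest calls
            pairs = sorted((g.tss, g.gene_id) for g in glist)
            self._tss[chrom] = ([p[0] for p in pairs], [p[1] for p in pairs])

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda g: g.gene_id)

    def nearest_gene(self, chrom: str, pos: int) -> GeneModel | None:
        """Gene minimizing |distance to TSS|; ties broken by gene_id."""
        if chrom not in self._tss:
            return None
        positions, ids = self._tss[chrom]
        i = bisect.bisect_left(positions, pos)
        best: tuple[int, str] | None = None
        for j in range(max(0, i - 2), min(len(positions), i + 2)):
            cand = (abs(positions[j] - pos), ids[j])
            if best is None or cand < best:
                best = cand
        # among equal |distance|, pick lexicographically smallest gene_id
        if best is None:
            return None
        dist = best[0]
        tied = [ids[j] for j in range(len(positions)) if abs(positions[j] - pos) == dist]
        return self.genes[min(tied)]


def _category_for_gene(center: int, gene: GeneModel) -> str | None:
    plo, phi = gene.promoter_window()
    if plo <= center <= phi:
        return "promoter-TSS"
    tlo, thi = gene.tts_window()
    if tlo <= center <= thi:
        return "TTS"
    if gene.interval.start <= center < gene.interval.end:
        for exon in gene.exons:
            if exon.start <= center < exon.end:
                return "exon"
        return "intron"
    return None


def annotate_peak(peak: Peak, index: GeneIndex) -> Peak:
    """Assign annotation category, nearest gene and signed TSS distance.

    Category is decided from the peak *center* with priority
    promoter-TSS > TTS > exon > intron > intergenic across all genes whose
    (window-extended) span covers the center.  ``distance_to_tss`` is signed
    in the nearest gene's orientation (negative = upstream of its TSS).
    """
    center = peak.center
    best_rank = len(CATEGORY_PRIORITY) - 1
    for gene in index.overlapping(peak.chrom, center):
        cat = _category_for_gene(center, gene)
        if cat is not None:
            best_rank = min(best_rank, CATEGORY_PRIORITY.index(cat))
    category = CATEGORY_PRIORITY[best_rank]

    nearest = index.nearest_gene(peak.chrom, center)
    if nearest is None:
        return replace_annotation(peak, "intergenic", None, None)
    d = center - nearest.tss
    if nearest.strand == "-":
        d = -d
    return replace_annotation(peak, category, nearest.gene_id, d)


def replace_annotation(peak: Peak, category, nearest_gene, distance) -> Peak:
    peak = replace(peak)
    peak.category = category
    peak.nearest_gene = nearest_gene
    peak.distance_to_tss = distance
    return peak


def annotate_peaks(peaks: list[Peak], genes: list[GeneModel]) -> list[Peak]:
    index = GeneIndex(genes)
    return [annotate_peak(p, index) for p in peaks]


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def scan_window_bounds(center: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Forward-strand half-open bounds of the peak scan window.

    '+' peak: [center - upstream, center + downstream); '-' peak: the mirror
    image around the center, later reverse-complemented.
    """
    if strand == "-":
        return center - downstream + 1, center + upstream + 1
    return center - upstream, center + downstream


def extract_fasta_windows(
    peaks: list[Peak],
    genome,
    upstream: int = 150,
    downstream: int = 50,
) -> dict[str, str]:
    """Extract the strand-oriented sequence window around each peak center.

    ``genome`` is a pyfaidx.Fasta or a path to an indexed FASTA.  Windows are
    clipped at contig edges; '-'-strand windows are reverse-complemented so
    that all returned sequences read 5'->3' in peak orientation, uppercase.
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    out: dict[str, str] = {}
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"peak {p.peak_id}: unknown contig {p.chrom!r}")
        contig = genome[p.chrom]
        lo, hi = scan_window_bounds(p.center, p.strand, upstream, downstream)
        lo = max(lo, 0)
        hi = min(hi, len(contig))
        seq = str(contig[lo:hi]).upper()
        if p.strand == "-":
            seq = reverse_complement(seq)
        out[p.peak_id] = seq
    return out
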