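"""Genome sequences, gene annotation, and TA-dinucleotide target sites.

TA-targeting transposons (TcBuster, Sleeping beauty and other Tc1/mariner or
hAT family elements) insert exclusively at 5'-TA-3' dinucleotides, so the set
of TA positions in a genome is the universe of possible insertion sites.  This
module loads a genome (FASTA) and its gene annotation (GFF3), indexes every TA
site, and defines the strand-aware "effective region" of each gene — the
5'-most 90% of the gene span — inside which insertions are counted when
scoring essentiality (insertions in the 3'-terminal 10% are tolerated even in
essential genes and are excluded).

Coordinates are 1-based inclusive throughout; a TA site is identified by the
coordinate of its T on the forward strand.  TA is its own reverse complement,
so one site serves both insertion orientations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GeneAnnotation",
    "TASiteIndex",
    "EffectiveRegion",
    "load_genome",
    "load_annotation",
    "index_ta_sites",
    "effective_region",
    "ta_counts_per_gene",
    "write_ta_index_tsv",
    "write_ta_index_bed",
]

_ALPHABET = frozenset("ACGTN")


@dataclass
class GenomeSequence:
    """A set of named chromosome sequences over the alphabet A,C,G,T,N."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """Return the sequence of [start, end], 1-based inclusive."""
        return self.chromosomes[chromosome][start - 1 : end]


@dataclass
class GeneAnnotation:
    """A gene with 1-based inclusive span and exon structure.

    Introns are the gaps between consecutive exon intervals.  Genes without
    explicit exon records are treated as single-exon.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exon_intervals:
            self.exon_intervals = [(self.start, self.end)]
        self.exon_intervals = sorted(self.exon_intervals)
        prev_end = None
        for s, e in self.exon_intervals:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon interval reversed")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene span "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def intron_intervals(self) -> list[tuple[int, int]]:
        introns = []
        for (s1, e1), (s2, e2) in zip(self.exon_intervals, self.exon_intervals[1:]):
            introns.append((e1 + 1, s2 - 1))
        return introns


@dataclass
class TASiteIndex:
    """Sorted 1-based T coordinates of every TA dinucleotide, per chromosome."""

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"TA positions for {name!r} not strictly increasing")
            self.positions[name] = pos

    @property
    def total(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def contains(self, chromosome: str, position: int) -> bool:
        pos = self.positions.get(chromosome)
        if pos is None or len(pos) == 0:
            return False
        i = np.searchsorted(pos, position)
        return i < len(pos) and pos[i] == position

    def count_in(self, chromosome: str, start: int, end: int) -> int:
        """Number of TA sites whose T lies in [start, end] (inclusive)."""
        pos = self.positions.get(chromosome)
        if pos is None or start > end:
            return 0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return int(hi - lo)

    def sites_in(self, chromosome: str, start: int, end: int) -> np.ndarray:
        pos = self.positions.get(chromosome)
        if pos is None or start > end:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return pos[lo:hi]


@dataclass
class EffectiveRegion:
    """The 5'-most (1 - excluded_fraction) of a gene, in genomic coordinates."""

    gene_id: str
    intervals: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)


def load_genome(fasta_path: str) -> GenomeSequence:
    """Load a multi-record FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; RNA (U) and non-ACGTN characters are rejected;
    duplicate record ids are an error.
    """
    with open(fasta_path) as handle:
        first = handle.readline()
        if not first.startswith(">"):
            raise ValueError(f"{fasta_path}: line 1 is not a FASTA header")
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(fasta_path, "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate FASTA record id {record.id!r}")
        seq = str(record.seq).upper()
        if "U" in seq:
            raise ValueError(f"record {record.id!r} contains U (RNA not accepted)")
        chromosomes[record.id] = seq
    return GenomeSequence(chromosomes)


def load_annotation(gff_path: str, genome: GenomeSequence) -> list[GeneAnnotation]:
    """Load gene/exon features from GFF3 into :class:`GeneAnnotation` records.

    Exons are attached to their gene through Parent relationships (possibly
    via an mRNA level).  Genes are returned sorted by (chromosome, start).
    """
    import gffutils

    db = gffutils.create_db(
        gff_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        if feat.seqid not in genome.chromosomes:
            raise ValueError(f"gene {gene_id}: unknown seqid {feat.seqid!r}")
        if feat.end > len(genome.chromosomes[feat.seqid]):
            raise ValueError(f"gene {gene_id}: span exceeds chromosome bounds")
        exons = []
        for child in db.children(feat, featuretype="exon"):
            if child.start < feat.start or child.end > feat.end:
                raise ValueError(
                    f"gene {gene_id}: exon ({child.start},{child.end}) outside "
                    f"gene span ({feat.start},{feat.end})"
                )
            exons.append((child.start, child.end))
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                exon_intervals=exons,
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def index_ta_sites(genome: GenomeSequence) -> TASiteIndex:
    """Index every TA dinucleotide; overlapping occurrences all count.

    N bases never form TA sites.  The returned positions are 1-based
    coordinates of the T on the forward strand.
    """
    positions: dict[str, np.ndarray] = {}
    for name, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if len(arr) < 2:
            positions[name] = np.empty(0, dtype=np.int64)
            continue
        mask = (arr[:-1] == ord("T")) & (arr[1:] == ord("A"))
        positions[name] = (np.flatnonzero(mask) + 1).astype(np.int64)
    return TASiteIndex(positions)


def effective_region(
    gene: GeneAnnotation, excluded_fraction: float = 0.10
) -> EffectiveRegion:
    """The 5'-most (1 - excluded_fraction) of the gene's genomic span.

    For a + strand gene spanning [s, e] the region is [s, s + floor((1-f)L) - 1];
    for a - strand gene it is [e - floor((1-f)L) + 1, e].  The region is
    computed on the genomic span (not spliced length); introns in this yeast
    are rare enough that the distinction is negligible.
    """
    if not (0.0 <= excluded_fraction < 1.0):
        raise ValueError("excluded_fraction must be in [0, 1)")
    L = gene.length
    eff_len = int(math.floor((1.0 - excluded_fraction) * L + 1e-9))
    if eff_len <= 0:
        return EffectiveRegion(gene.gene_id, [])
    if gene.strand == "+":
        interval = (gene.start, gene.start + eff_len - 1)
    else:
        interval = (gene.end - eff_len + 1, gene.end)
    return EffectiveRegion(gene.gene_id, [interval])


def ta_counts_per_gene(
    index: TASiteIndex,
    genes: list[GeneAnnotation],
    region: str = "full",
    excluded_fraction: float = 0.10,
) -> dict[str, int]:
    """TA-site counts per gene, over the full span or the effective region.

    Site membership is by the position of the T: a TA whose T is the last base
    of the region counts as inside even though its A lies one base beyond.
    """
    if region not in ("full", "effective"):
        raise ValueError("region must be 'full' or 'effective'")
    counts: dict[str, int] = {}
    for gene in genes:
        if region == "full":
            counts[gene.gene_id] = index.count_in(gene.chromosome, gene.start, gene.end)
        else:
            eff = effective_region(gene, excluded_fraction)
            counts[gene.gene_id] = sum(
                index.count_in(gene.chromosome, s, e) for s, e in eff.intervals
            )
    return counts


def write_ta_index_tsv(index: TASiteIndex, path: str) -> None:
    with open(path, "w") as out:
        out.write("chromosome\tposition\n")
        for name in index.positions:
            for p in index.positions[name]:
                out.write(f"{name}\t{p}\n")


def write_ta_index_bed(index: TASiteIndex, path: str) -> None:
    """BED export: 0-based half-open intervals covering each TA dinucleotide."""
    with open(path, "w") as out:
        for name in index.positions:
            for p in index.positions[name]:
                out.write(f"{name}\t{p - 1}\t{p + 1}\tTA\n")
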