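"""Per-gene insertion statistics and genome-wide insertional-bias diagnostics.

The central per-gene quantity is the Gene Insertion Index

    GII = (unique effective insertions) * K / (TA sites in the gene),

with K = 72, the genome-wide average number of TA sites per gene; dividing by
the gene's own TA count removes the target-site availability effect, and the
constant K restores an interpretable scale ("insertions an average-sized gene
would have seen").  Insertions in the 3'-terminal 10% of a gene are excluded
from the numerator — terminal insertions rarely abolish function, so even
essential genes tolerate them.  Read density (summed junction-read counts /
TA count) is the secondary feature; read counts per site are too noisy to
carry the classification on their own.

Diagnostics cover where insertions land (exon / intron / intergenic), how they
distribute along gene bodies (25-segment profile with flanking bins), the
nucleotide context around target TAs (logo matrix), library saturation and
overlap, and the choice of TA count over gene length as normalizer (R²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import (
    GeneAnnotation,
    GenomeSequence,
    TASiteIndex,
    effective_region,
)
from .junctions import InsertionLibrary, revcomp

__all__ = [
    "GeneInsertionStats",
    "SegmentProfile",
    "compute_gene_stats",
    "gene_stats_frame",
    "region_fractions",
    "segment_profile",
    "logo_matrix",
    "saturation_curve",
    "venn_overlap",
    "normalization_r2",
    "density_per_kb",
]

DEFAULT_CONSTANT_K = 72  # genome-wide average TA sites per gene


@dataclass
class GeneInsertionStats:
    gene_id: str
    length: int
    ta_full: int
    ta_effective: int
    insertions_full: int
    insertions_effective: int
    reads_effective: int
    gii: float
    read_density: float
    defined: bool  # False when ta_full == 0 (GII/read density undefined)


@dataclass
class SegmentProfile:
    orf_bins: np.ndarray  # n_bins counts along the gene body, 5'->3'
    upstream_bins: np.ndarray  # flanking intergenic counts, nearest bin first
    downstream_bins: np.ndarray
    n_far: int  # intergenic sites beyond the flank window


def _position_counts_by_chrom(library: InsertionLibrary, stranded: bool):
    """{chrom: (sorted site positions, read counts)}.

    With stranded=True a position hit in both orientations appears twice
    (two distinct sites); collapsed, it appears once with summed reads.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    if stranded:
        for (chrom, pos, _orient), n in library.position_counts(True).items():
            per_chrom.setdefault(chrom, []).append((pos, n))
    else:
        for (chrom, pos), n in library.position_counts(False).items():
            per_chrom.setdefault(chrom, []).append((pos, n))
    out = {}
    for chrom, entries in per_chrom.items():
        entries.sort()
        pos = np.array([p for p, _ in entries], dtype=np.int64)
        cnt = np.array([n for _, n in entries], dtype=np.int64)
        out[chrom] = (pos, cnt)
    return out


def _interval_sums(pos: np.ndarray, cnt: np.ndarray, start: int, end: int):
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="right")
    return int(hi - lo), int(cnt[lo:hi].sum())


def compute_gene_stats(
    library: InsertionLibrary,
    genes: list[GeneAnnotation],
    ta_index: TASiteIndex,
    constant_K: float = DEFAULT_CONSTANT_K,
    excluded_fraction: float = 0.10,
    collapse_orientation: bool = True,
    exclude_reads_3prime: bool = True,
) -> list[GeneInsertionStats]:
    """Per-gene TA counts, effective insertion/read counts, GII and read density.

    Insertions are counted as unique sites — by default orientation-collapsed,
    since a TA hit in both orientations is one disrupted position — within the
    5' effective region; the GII denominator is the full-gene TA count.  Genes
    with no TA sites are flagged undefined and excluded from classification
    downstream.  Read density mirrors the insertion numerator's 3' exclusion
    unless ``exclude_reads_3prime`` is disabled.
    """
    by_chrom = _position_counts_by_chrom(library, stranded=not collapse_orientation)
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    out: list[GeneInsertionStats] = []
    for gene in genes:
        pos, cnt = by_chrom.get(gene.chromosome, empty)
        ta_full = ta_index.count_in(gene.chromosome, gene.start, gene.end)
        eff = effective_region(gene, excluded_fraction)
        ta_eff = sum(ta_index.count_in(gene.chromosome, s, e) for s, e in eff.intervals)
        ins_full, reads_full = _interval_sums(pos, cnt, gene.start, gene.end)
        ins_eff = reads_eff = 0
        for s, e in eff.intervals:
            n, r = _interval_sums(pos, cnt, s, e)
            ins_eff += n
            reads_eff += r
        reads_used = reads_eff if exclude_reads_3prime else reads_full
        if ta_full > 0:
            gii = ins_eff * constant_K / ta_full
            density = reads_used / ta_full
            defined = True
        else:
            gii = float("nan")
            density = float("nan")
            defined = False
        out.append(
            GeneInsertionStats(
                gene_id=gene.gene_id,
                length=gene.length,
                ta_full=ta_full,
                ta_effective=ta_eff,
                insertions_full=ins_full,
                insertions_effective=ins_eff,
                reads_effective=reads_used,
                gii=gii,
                read_density=density,
                defined=defined,
            )
        )
    return out


def gene_stats_frame(stats: list[GeneInsertionStats]) -> pd.DataFrame:
    """Tabular per-gene stats (the per-gene feature table written to TSV)."""
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in stats],
            "length": [s.length for s in stats],
            "ta_full": [s.ta_full for s in stats],
            "ta_effective": [s.ta_effective for s in stats],
            "insertions_full": [s.insertions_full for s in stats],
            "insertions_effective": [s.insertions_effective for s in stats],
            "reads_effective": [s.reads_effective for s in stats],
            "gii": [s.gii for s in stats],
            "read_density": [s.read_density for s in stats],
        }
    )


# ---------------------------------------------------------------------------
# Genome-wide diagnostics
# ---------------------------------------------------------------------------


def _locate_gene(genes_by_chrom, chrom, position):
    """Return the gene covering position, else None (genes non-overlapping)."""
    entry = genes_by_chrom.get(chrom)
    if entry is None:
        return None
    starts, gene_list = entry
    i = int(np.searchsorted(starts, position, side="right")) - 1
    if i >= 0 and gene_list[i].start <= position <= gene_list[i].end:
        return gene_list[i]
    return None


def _genes_by_chrom(genes):
    by: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by.setdefault(g.chromosome, []).append(g)
    return {
        c: (np.array([g.start for g in gl], dtype=np.int64), gl)
        for c, gl in ((c, sorted(gl, key=lambda g: g.start)) for c, gl in by.items())
    }


def region_fractions(
    library: InsertionLibrary, genes: list[GeneAnnotation]
) -> dict[str, float]:
    """Fractions of unique insertion sites in exon / intron / intergenic DNA."""
    by_chrom = _genes_by_chrom(genes)
    counts = {"exon": 0, "intron": 0, "igr": 0}
    for chrom, pos, _orient in library.positions(stranded=True):
        gene = _locate_gene(by_chrom, chrom, pos)
        if gene is None:
            counts["igr"] += 1
        elif any(s <= pos <= e for s, e in gene.exon_intervals):
            counts["exon"] += 1
        else:
            counts["intron"] += 1
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}


def segment_profile(
    library: InsertionLibrary,
    genes: list[GeneAnnotation],
    n_bins: int = 25,
    flank_bp: int = 1000,
    flank_bin_bp: int = 100,
) -> SegmentProfile:
    """Positional insertion profile along gene bodies and their flanks.

    A site at gene-relative offset d (1-based from the 5' end, in gene
    orientation) of a length-L gene falls in body bin ceil(d*n_bins/L).
    Intergenic sites are assigned to the nearer gene end (exact ties go to the
    gene 5'-ward in genomic coordinates), classified upstream/downstream in
    that gene's orientation, and binned by distance in ``flank_bin_bp`` steps
    out to ``flank_bp``; farther sites are tallied separately.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not genes:
        raise ValueError("need at least one gene")
    by_chrom = _genes_by_chrom(genes)
    n_flank_bins = flank_bp // flank_bin_bp
    orf = np.zeros(n_bins, dtype=np.int64)
    up = np.zeros(n_flank_bins, dtype=np.int64)
    down = np.zeros(n_flank_bins, dtype=np.int64)
    n_far = 0
    for chrom, pos, _orient in library.positions(stranded=True):
        gene = _locate_gene(by_chrom, chrom, pos)
        if gene is not None:
            d = pos - gene.start + 1 if gene.strand == "+" else gene.end - pos + 1
            b = -(-d * n_bins // gene.length)  # ceil
            orf[min(max(b, 1), n_bins) - 1] += 1
            continue
        entry = by_chrom.get(chrom)
        if entry is None:
            n_far += 1
            continue
        starts, gene_list = entry
        i = int(np.searchsorted(starts, pos, side="right"))
        left = gene_list[i - 1] if i >= 1 else None
        right = gene_list[i] if i < len(gene_list) else None
        d_left = pos - left.end if left is not None else None
        d_right = right.start - pos if right is not None else None
        if left is None and right is None:
            n_far += 1
            continue
        if right is None or (left is not None and d_left <= d_right):
            gene, dist, side = left, d_left, "right_of_gene"
        else:
            gene, dist, side = right, d_right, "left_of_gene"
        if dist > flank_bp:
            n_far += 1
            continue
        # upstream = 5' side of the gene in its own orientation
        if (side == "left_of_gene") == (gene.strand == "+"):
            up[min((dist - 1) // flank_bin_bp, n_flank_bins - 1)] += 1
        else:
            down[min((dist - 1) // flank_bin_bp, n_flank_bins - 1)] += 1
    return SegmentProfile(orf, up, down, n_far)


def logo_matrix(
    library: InsertionLibrary,
    genome: GenomeSequence,
    flank_k: int = 6,
    include_center: bool = True,
) -> pd.DataFrame:
    """Nucleotide frequencies at positions flanking the target TA.

    Rows are flank positions -k..-1 and +1..+k (plus the central 'T','A'
    slots when ``include_center``); columns are A,C,G,T frequencies across
    unique insertion sites.  Reverse-orientation sites contribute the reverse
    complement of their genomic context, so the matrix reads in insertion
    orientation.  Sites whose flanks run off a chromosome end are skipped.
    """
    window = 2 * flank_k + 2
    counts = np.zeros((window, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    used = 0
    for chrom, pos, orient in sorted(library.positions(stranded=True)):
        seq = genome.chromosomes.get(chrom)
        if seq is None:
            continue
        lo = pos - 1 - flank_k  # 0-based window start
        hi = pos + 1 + flank_k  # 0-based exclusive end
        if lo < 0 or hi > len(seq):
            continue
        context = seq[lo:hi]
        if orient == "reverse":
            context = revcomp(context)
        if any(b not in base_idx for b in context):
            continue
        for j, b in enumerate(context):
            counts[j, base_idx[b]] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable insertion sites for logo matrix")
    freqs = counts / used
    labels = [str(-i) for i in range(flank_k, 0, -1)] + ["T", "A"] + [
        f"+{i}" for i in range(1, flank_k + 1)
    ]
    df = pd.DataFrame(freqs, index=labels, columns=list("ACGT"))
    df.index.name = "position"
    if not include_center:
        df = df.drop(index=["T", "A"])
    return df


def saturation_curve(
    libraries: list[InsertionLibrary],
    n_orders: int | None = None,
    seed: int | None = None,
    stranded: bool = True,
):
    """Cumulative unique-site counts as libraries are pooled in order.

    With ``n_orders`` the pooling order is shuffled that many times and the
    per-step mean and standard deviation are returned instead.
    """
    if not libraries:
        raise ValueError("need at least one library")

    def one_order(libs):
        seen: set = set()
        out = []
        for lib in libs:
            seen |= lib.positions(stranded=stranded)
            out.append(len(seen))
        return out

    if n_orders is None:
        return np.array(one_order(libraries), dtype=np.int64)
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_orders):
        order = rng.permutation(len(libraries))
        curves.append(one_order([libraries[i] for i in order]))
    curves = np.array(curves, dtype=np.float64)
    return curves.mean(axis=0), curves.std(axis=0)


def venn_overlap(
    lib_a: InsertionLibrary, lib_b: InsertionLibrary, stranded: bool = True
) -> tuple[int, int, int]:
    """(only A, shared, only B) unique-site counts."""
    a = lib_a.positions(stranded=stranded)
    b = lib_b.positions(stranded=stranded)
    return len(a - b), len(a & b), len(b - a)


def normalization_r2(stats: list[GeneInsertionStats]) -> tuple[float, float]:
    """Squared Pearson correlations justifying TA-count normalization.

    Returns (R² of TA count vs full-gene insertions, R² of gene length vs
    full-gene insertions) across genes; NaN when a variable has no variance.
    """
    if len(stats) < 3:
        raise ValueError("need at least 3 genes")
    ta = np.array([s.ta_full for s in stats], dtype=float)
    length = np.array([s.length for s in stats], dtype=float)
    ins = np.array([s.insertions_full for s in stats], dtype=float)

    def r2(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(sps.pearsonr(x, y).statistic ** 2)

    return r2(ta, ins), r2(length, ins)


def density_per_kb(library: InsertionLibrary, genome: GenomeSequence) -> float:
    """Unique insertion sites per kilobase of genome."""
    return library.n_unique / (genome.total_length / 1000.0)
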