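"""Synthetic genomes, insertion libraries and junction reads with known truth.

The generator emulates the statistical structure the analysis assumes so each
pipeline stage can be tested against ground truth: a multi-chromosome genome
with non-overlapping ORFs covering ~80% of the sequence, TA target sites from
the base composition, insertion libraries with intergenic enrichment (the
nucleosome-free-region effect), transposase sequence-context bias around the
TA, suppression of insertions inside essential genes' 5' 90% (their 3' edge
tolerates insertions), over-dispersed per-site read counts, and junction
reads composed of transposon terminus + genomic fragment + adapter.

Everything is deterministic given the configuration seed; each operation
derives its RNG from ``seed + fixed offset`` so stages are individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import TrainingSet
from .genome import GeneAnnotation, GenomeSequence, TASiteIndex, effective_region, index_ta_sites
from .junctions import InsertionLibrary, JunctionReadSpec, revcomp

__all__ = [
    "SimulationConfig",
    "TrainingFeatureConfig",
    "SyntheticTruth",
    "simulate_genome",
    "assign_labels",
    "simulate_insertions",
    "simulate_junction_reads",
    "simulate_training_features",
    "write_fasta",
    "write_gff3",
    "write_truth_tsv",
]

_GENOME_SEED_OFFSET = 11
_LABEL_SEED_OFFSET = 23
_INSERTION_SEED_OFFSET = 37
_FEATURE_SEED_OFFSET = 53


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic Tn-seq experiment.

    Defaults describe a desk-scale genome (2 Mb, 2,000 genes, 40,000
    insertions) with the biases the original libraries showed: ~20%
    intergenic sequence receiving >40% of insertions, ~22% of genes
    essential, near-total suppression of insertions in essential gene bodies
    with a tolerated 3'-terminal 10%, and heavily dispersed read counts.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    gc_content: float = 0.41
    n_genes: int = 2000
    gene_length_mean: float = 800.0  # lognormal body, genomic span
    gene_length_sigma: float = 0.35
    gene_length_min: int = 150
    gene_length_max: int = 5000
    igr_fraction: float = 0.20
    intron_fraction: float = 0.02  # genes given a single short intron
    fraction_essential: float = 0.22
    n_insertions: int = 40_000
    igr_enrichment: float = 3.2
    sequence_bias: dict[int, dict[str, float]] = field(default_factory=dict)
    essential_body_suppression: float = 0.02
    edge_tolerance_fraction: float = 0.10
    read_count_mu: float = 0.7  # lognormal parameters for per-site reads
    read_count_sigma: float = 1.2

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must match n_chromosomes")
        for frac in (self.gc_content, self.igr_fraction, self.fraction_essential,
                     self.essential_body_suppression, self.edge_tolerance_fraction,
                     self.intron_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.igr_enrichment <= 0:
            raise ValueError("igr_enrichment must be positive")
        for d in self.sequence_bias.values():
            if any(w <= 0 for w in d.values()):
                raise ValueError("sequence bias weights must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated library, for recovery tests."""

    labels: dict[str, str]  # gene_id -> essential | non_essential
    site_positions: dict[str, np.ndarray]  # per-chromosome TA positions
    weights_forward: dict[str, np.ndarray]  # selection weight per TA site
    weights_reverse: dict[str, np.ndarray]
    realized: list[tuple[str, int, str]]  # drawn (chrom, position, orientation)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneAnnotation]]:
    """Random genome with non-overlapping genes hitting the IGR target.

    Genes are placed sequentially with intergenic gaps; per chromosome the
    coding budget is (1 - igr_fraction) of its length, so the realized IGR
    fraction matches the target up to integer rounding.  Strands are random;
    a small fraction of genes receives one short intron.
    """
    rng = np.random.default_rng(config.seed + _GENOME_SEED_OFFSET)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    total_len = sum(config.chromosome_lengths)
    genes: list[GeneAnnotation] = []
    chromosomes: dict[str, str] = {}
    gene_no = 0
    # apportion genes to chromosomes by length
    quotas = [
        int(round(config.n_genes * L / total_len)) for L in config.chromosome_lengths
    ]
    quotas[-1] = config.n_genes - sum(quotas[:-1])
    for name, L, n_genes in zip(chrom_names, config.chromosome_lengths, quotas):
        chromosomes[name] = _random_sequence(rng, L, config.gc_content)
        if n_genes == 0:
            continue
        coding_budget = int(round((1 - config.igr_fraction) * L))
        raw = rng.lognormal(
            np.log(config.gene_length_mean) - config.gene_length_sigma**2 / 2,
            config.gene_length_sigma,
            n_genes,
        )
        lengths = np.clip(
            np.round(raw * coding_budget / raw.sum()).astype(int),
            config.gene_length_min,
            config.gene_length_max,
        )
        # nudge the longest genes so the coding total hits the budget
        excess = int(lengths.sum()) - coding_budget
        order = np.argsort(lengths)[::-1]
        i = 0
        while excess != 0 and i < len(order) * 4:
            j = order[i % len(order)]
            step = -1 if excess > 0 else 1
            new = lengths[j] + step
            if config.gene_length_min <= new <= config.gene_length_max:
                lengths[j] = new
                excess += step
            i += 1
        igr_budget = L - int(lengths.sum())
        if igr_budget < n_genes + 1:
            raise ValueError(
                f"infeasible packing on {name}: genes exceed chromosome length"
            )
        gaps = rng.dirichlet(np.ones(n_genes + 1)) * igr_budget
        gaps = np.maximum(1, np.round(gaps).astype(int))
        gaps[-1] = igr_budget - int(gaps[:-1].sum())
        if gaps[-1] < 0:  # rounding overshoot: shave the largest gaps
            deficit = -int(gaps[-1])
            gaps[-1] = 0
            big = np.argsort(gaps[:-1])[::-1]
            k = 0
            while deficit > 0:
                j = big[k % len(big)]
                if gaps[j] > 1:
                    gaps[j] -= 1
                    deficit -= 1
                k += 1
        cursor = 0
        for gi in range(n_genes):
            cursor += int(gaps[gi])
            start = cursor + 1
            end = cursor + int(lengths[gi])
            cursor = end
            gene_no += 1
            gene_id = f"g{gene_no:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            exons: list[tuple[int, int]] = []
            span = end - start + 1
            if rng.random() < config.intron_fraction and span >= 300:
                intron_len = int(rng.integers(40, 101))
                mid = start + span // 2
                exons = [(start, mid - 1), (mid + intron_len, end)]
            genes.append(GeneAnnotation(gene_id, name, start, end, strand, exons))
    return GenomeSequence(chromosomes), genes


def assign_labels(
    genes: list[GeneAnnotation], fraction_essential: float, seed: int
) -> dict[str, str]:
    """Mark floor(fraction * n) randomly chosen genes essential."""
    rng = np.random.default_rng(seed + _LABEL_SEED_OFFSET)
    n_ess = int(np.floor(fraction_essential * len(genes)))
    ess_idx = set(rng.choice(len(genes), size=n_ess, replace=False).tolist())
    return {
        g.gene_id: ("essential" if i in ess_idx else "non_essential")
        for i, g in enumerate(genes)
    }


# ---------------------------------------------------------------------------
# Insertions
# ---------------------------------------------------------------------------


def _context_base(seq: str, t_pos: int, offset: int, orientation: str) -> str | None:
    """Base at logo offset (-k..-1, +1..+k) around the TA, insertion-oriented."""
    idx_t = t_pos - 1  # 0-based T
    idx_a = t_pos  # 0-based A
    if orientation == "forward":
        idx = idx_t + offset if offset < 0 else idx_a + offset
        if 0 <= idx < len(seq):
            return seq[idx]
        return None
    # reverse: walk the minus strand; complement the forward base
    idx = idx_a - offset if offset < 0 else idx_t - offset
    if 0 <= idx < len(seq):
        return revcomp(seq[idx])
    return None


def simulate_insertions(
    genome: GenomeSequence,
    genes: list[GeneAnnotation],
    labels: dict[str, str],
    config: SimulationConfig,
    ta_index: TASiteIndex | None = None,
    label: str = "simulated",
) -> tuple[InsertionLibrary, SyntheticTruth]:
    """Draw insertion sites proportional to per-site, per-orientation weights.

    weight = 1
           x igr_enrichment           if the TA lies outside every gene span
           x sequence-context bias    product over configured flank offsets
           x essential_body_suppression  if inside an essential gene's 5'
                                          (1 - edge_tolerance) region

    ``n_insertions`` (site, orientation) pairs are drawn without replacement
    (Gumbel top-k, exact weighted sampling), so a site is hit at most once per
    orientation; multiplicity is expressed through lognormal read counts.
    """
    rng = np.random.default_rng(config.seed + _INSERTION_SEED_OFFSET)
    if ta_index is None:
        ta_index = index_ta_sites(genome)
    weights_f: dict[str, np.ndarray] = {}
    weights_r: dict[str, np.ndarray] = {}
    all_keys: list[tuple[str, int, str]] = []
    all_weights: list[np.ndarray] = []
    genes_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(ta_index.positions):
        pos = ta_index.positions[chrom]
        seq = genome.chromosomes[chrom]
        base = np.ones(len(pos), dtype=float)
        in_gene = np.zeros(len(pos), dtype=bool)
        for g in genes_by_chrom.get(chrom, []):
            lo = np.searchsorted(pos, g.start, side="left")
            hi = np.searchsorted(pos, g.end, side="right")
            in_gene[lo:hi] = True
            if labels.get(g.gene_id) == "essential":
                eff = effective_region(g, config.edge_tolerance_fraction)
                for s, e in eff.intervals:
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e, side="right")
                    base[lo:hi] *= config.essential_body_suppression
        base[~in_gene] *= config.igr_enrichment
        wf = base.copy()
        wr = base.copy()
        if config.sequence_bias:
            for i, t in enumerate(pos):
                for offset, table in config.sequence_bias.items():
                    bf = _context_base(seq, int(t), offset, "forward")
                    if bf is not None and bf in table:
                        wf[i] *= table[bf]
                    br = _context_base(seq, int(t), offset, "reverse")
                    if br is not None and br in table:
                        wr[i] *= table[br]
        weights_f[chrom] = wf
        weights_r[chrom] = wr
        for orient, w in (("forward", wf), ("reverse", wr)):
            all_keys.extend((chrom, int(t), orient) for t in pos)
            all_weights.append(w)
    w = np.concatenate(all_weights) if all_weights else np.empty(0)
    positive = np.flatnonzero(w > 0)
    if config.n_insertions > len(positive):
        raise ValueError(
            f"n_insertions={config.n_insertions} exceeds the "
            f"{len(positive)} selectable (site, orientation) slots"
        )
    # Gumbel top-k == weighted sampling without replacement
    gumbel = rng.gumbel(size=len(positive))
    keys_sorted = np.log(w[positive]) + gumbel
    chosen = positive[np.argpartition(-keys_sorted, config.n_insertions - 1)[: config.n_insertions]]
    chosen.sort()
    counts = np.maximum(
        1, np.round(rng.lognormal(config.read_count_mu, config.read_count_sigma,
                                  size=len(chosen)))
    ).astype(int)
    library = InsertionLibrary(label=label)
    realized = []
    for idx, count in zip(chosen, counts):
        chrom, t, orient = all_keys[idx]
        library.add(chrom, t, orient, int(count))
        realized.append((chrom, t, orient))
    truth = SyntheticTruth(
        labels=dict(labels),
        site_positions={c: ta_index.positions[c] for c in sorted(ta_index.positions)},
        weights_forward=weights_f,
        weights_reverse=weights_r,
        realized=realized,
    )
    return library, truth


# ---------------------------------------------------------------------------
# Junction reads
# ---------------------------------------------------------------------------


def simulate_junction_reads(
    library: InsertionLibrary,
    genome: GenomeSequence,
    spec: JunctionReadSpec,
    read_length: int = 75,
    seed: int = 0,
    error_rate: float = 0.0,
    fragment_len_range: tuple[int, int] = (30, 50),
) -> list[tuple[str, str]]:
    """Emit (id, sequence) junction reads: terminus + genomic fragment + adapter.

    For a forward insertion at T coordinate t the fragment starts at t+2 and
    runs 3'-ward on the forward strand; for a reverse insertion it starts at
    t-1 and runs 5'-ward (reported as the minus-strand sequence).  One read is
    emitted per unit of read_count; reads are truncated to ``read_length``;
    optional uniform substitution errors are applied to the whole read.
    Fragments are clipped at chromosome ends (reads whose fragment vanishes
    are skipped).
    """
    if read_length < len(spec.transposon_terminus):
        raise ValueError("read_length shorter than the transposon terminus")
    rng = np.random.default_rng(seed)
    lo, hi = fragment_len_range
    reads: list[tuple[str, str]] = []
    for site in library.sites():
        seq = genome.chromosomes[site.chromosome]
        for k in range(site.read_count):
            frag_len = int(rng.integers(lo, hi + 1))
            if site.orientation == "forward":
                start0 = site.position + 1  # 0-based index of base after the A
                frag = seq[start0 : start0 + frag_len]
            else:
                end0 = site.position - 1  # 0-based exclusive end (base before T)
                frag = revcomp(seq[max(0, end0 - frag_len) : end0])
            # fragments clipped empty at a chromosome edge still yield a
            # (junk) read, discarded downstream by the length filter
            read = (spec.transposon_terminus + frag + spec.adapter_tail)[:read_length]
            if error_rate > 0:
                arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
                hit = rng.random(len(arr)) < error_rate
                if hit.any():
                    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
                    lut = {ord(b): i for i, b in enumerate("ACGT")}
                    idx = np.array([lut.get(int(v), 0) for v in arr[hit]])
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    arr[hit] = bases[(idx + shift) % 4]
                    read = arr.tobytes().decode("ascii")
            reads.append(
                (f"{site.chromosome}:{site.position}:{site.orientation}:{k}", read)
            )
    return reads


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as out:
        for read_id, seq in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Training features
# ---------------------------------------------------------------------------


@dataclass
class TrainingFeatureConfig:
    """Mixture model behind the labelled training features.

    Essential genes draw GII from a half-normal hugging zero; non-essential
    genes from a normal with mode ~3.5 (the separation the real ortholog
    labels showed).  Read density is a weakly informative second feature.
    """

    n_essential: int = 161
    n_non_essential: int = 171
    essential_gii_scale: float = 0.7
    non_essential_gii_mean: float = 3.5
    non_essential_gii_sd: float = 1.3
    essential_density_scale: float = 3.0
    non_essential_density_mean: float = 6.0
    non_essential_density_sd: float = 5.0


def simulate_training_features(
    config: TrainingFeatureConfig, seed: int = 0
) -> TrainingSet:
    """Labelled (gii, read_density) samples from the two-component mixture."""
    rng = np.random.default_rng(seed + _FEATURE_SEED_OFFSET)
    ess_gii = np.abs(rng.normal(0.0, config.essential_gii_scale, config.n_essential))
    ess_rd = np.abs(rng.normal(0.0, config.essential_density_scale, config.n_essential))
    # folded normals: nonnegative, and identical to the essential component
    # when the parameters coincide (negligible folding at mode ~3.5)
    non_gii = np.abs(
        rng.normal(config.non_essential_gii_mean, config.non_essential_gii_sd,
                   config.n_non_essential)
    )
    non_rd = np.abs(
        rng.normal(config.non_essential_density_mean, config.non_essential_density_sd,
                   config.n_non_essential)
    )
    gene_ids = [f"ess{i:04d}" for i in range(config.n_essential)] + [
        f"non{i:04d}" for i in range(config.n_non_essential)
    ]
    features = np.column_stack(
        [np.concatenate([ess_gii, non_gii]), np.concatenate([ess_rd, non_rd])]
    )
    y = np.concatenate(
        [np.zeros(config.n_essential, dtype=int), np.ones(config.n_non_essential, dtype=int)]
    )
    return TrainingSet(gene_ids, features, y)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_fasta(genome: GenomeSequence, path: str, width: int = 80) -> None:
    with open(path, "w") as out:
        for name in genome.chromosomes:
            out.write(f">{name}\n")
            seq = genome.chromosomes[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_gff3(genes: list[GeneAnnotation], genome: GenomeSequence, path: str) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for name, length in genome.lengths.items():
            out.write(f"##sequence-region {name} 1 {length}\n")
        for g in genes:
            out.write(
                f"{g.chromosome}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exon_intervals, start=1):
                out.write(
                    f"{g.chromosome}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def write_truth_tsv(truth: SyntheticTruth, path: str) -> None:
    with open(path, "w") as out:
        out.write("gene_id\tlabel\n")
        for gene_id in sorted(truth.labels):
            out.write(f"{gene_id}\t{truth.labels[gene_id]}\n")
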