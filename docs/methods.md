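# Methods

## The problem

Transposon insertion sequencing (Tn-seq) locates every transposon insertion in
a pooled mutant library by sequencing transposon–genome junctions. For
TA-targeting transposons (TcBuster, Sleeping beauty), the genome's TA
dinucleotides are the complete universe of possible insertion sites, so an
observed *absence* of insertions in a gene — relative to how many TA sites it
offers — is evidence the gene is essential under the assayed growth
condition. This package implements the full analysis: junction reads →
insertion sites → per-gene features → logistic essentiality classification →
cross-condition screens, plus a synthetic-data generator that provides ground
truth for every stage.

## Pipeline model and conventions

**Coordinates.** 1-based inclusive everywhere internally; BED exports are
0-based half-open at the writer. A TA site is identified by the forward-strand
coordinate of its T; because TA is its own reverse complement, one site serves
both insertion orientations.

**Junction reads.** A read is modelled as transposon terminus + genomic
fragment + adapter tail. Trimming has three passes: (1) the terminus must be
a read prefix, matched with at most ceil(mismatch_rate × terminus length)
mismatches (default rate 0.05); reads without it are discarded; (2) a
nonspecific-amplification guard strips a second terminus occurrence (the new
prefix under the same mismatch rule, and any exact internal copy — nothing
downstream ever contains the full terminus); (3) the adapter is removed as
the *shortest* fragment suffix matching a prefix of the adapter under the
same per-length mismatch budget, with a 4-nt minimum overlap. Up to 3
residual adapter nucleotides can survive pass 3; the mapper's 3-mismatch
allowance absorbs them. Finally fragments shorter than 16 nt are discarded
and longer than 50 nt truncated.

**Mapping.** Fragments are aligned ungapped against both strands at every
offset; a fragment is kept only when exactly one location attains the minimum
mismatch count and that count is ≤ 3. Equally good locations — including a
palindromic fragment matching both strands at one locus — make it
multi-mapped and discarded. The implementation uses an exact 16-mer seed
index for the zero-mismatch case and a vectorized full scan otherwise; both
paths return exactly the brute-force answer (the exact index enumerates *all*
zero-mismatch loci, which decides minimum and uniqueness whenever an exact
hit exists). Pre-mapped SAM is accepted so any external aligner can
substitute the native mapper.

**Site calling.** The fragment's 5' (junction-proximal) end must abut a TA:
for a plus-strand alignment starting at s the expected T coordinate is s − 2,
for a minus-strand alignment ending at e it is e + 1. End repair can shift
the junction, so the nearest indexed TA within 2 bp wins, ties breaking to
the 5' side in insertion orientation; alignments with no TA in the window are
dropped. Duplicate (chromosome, position, orientation) calls collapse into
one site with a read count.

**Gene features.** For each gene,

    GII = insertions_effective × K / TA_full        (K = 72)
    read_density = reads_effective / TA_full

where *effective* counts cover only the 5'-most 90% of the gene span
(floor(0.9·L), computed on the genomic span; introns in this genome are rare
and short) — insertions in the 3'-terminal 10% rarely abolish function, so
they are excluded from the numerator. K = 72 is the genome-wide average TA
count per gene in the original study; it is a display scale only and cancels
out of the classification after standardization. Insertion counting is
orientation-collapsed by default (a TA hit in both orientations is one
disrupted position); read density applies the same 3' exclusion as the
insertion numerator (both choices configurable). Genes with zero TA sites
have undefined features and are excluded downstream.

**Classification.** Features are standardized with the labelled training
set's means and standard deviations, and the same transform is applied
genome-wide — the only standardization defined at fit time. An
L2-regularized logistic regression (C = 10, lbfgs; the optimizer is
irrelevant at convergence) maps (x1, x2) to the non-essentiality probability
NEP = σ(b1·x1 + b2·x2 + b0). Training reports held-out accuracy over ten
70/30 stratified splits (seeded seed, seed+1, …) and refits on all data. The
model fitted on the original glucose libraries — b1 = 5.737, b2 = 0.082,
b0 = 2.098 — ships as a named built-in; its standardization parameters were
never released, so scoring raw features with it requires supplying a labelled
set to standardize against.

Categories: NEP < 0.03 putatively essential; 0.03 ≤ NEP < 0.5 ambig1;
0.5 ≤ NEP ≤ 0.9 ambig2; NEP > 0.9 putatively non-essential. The published
rules fix the outer boundaries ("less than 0.03", "NEP > 0.9"); placing the
interior boundaries 0.03, 0.5 and 0.9 in ambig1/ambig2/ambig2 is this
package's documented convention. Genes with fewer than 15 TA sites (full-gene
count, configurable) and the transposon's marker gene are excluded with
reasons; categories plus exclusions always partition the gene universe.

**Condition comparison.** Two classifications over the same gene universe are
joined; genes excluded on either side are dropped and listed. The screen
keeps genes with NEP_a > 0.9 (confidently dispensable under condition A) and
NEP_b < 0.5 (needed under condition B), sorted by NEP_b ascending. Both
cutoffs are parameters.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
not the biology producing it:

- **Genome**: i.i.d. nucleotides at 41% GC (the host genome's composition)
  across two chromosomes (2 Mb default); 2,000 non-overlapping genes packed
  with intergenic gaps so ~20% of the sequence is intergenic (the study
  genome's 19.8%); random strands; 2% of genes carry one short intron.
- **Insertions**: each (TA site, orientation) gets weight
  1 × igr_enrichment (3.2, calibrated so ~45% of insertions land in the 20%
  intergenic fraction, the nucleosome-free-region effect) × sequence-context
  bias (per-offset nucleotide multipliers, evaluated in insertion
  orientation) × essential-body suppression (0.02 inside an essential gene's
  5' 90%; the 3' 10% tolerates insertions). n_insertions pairs are drawn
  without replacement by Gumbel top-k (exact weighted sampling), matching the
  "unique insertions" accounting; read counts are lognormal (μ=0.7, σ=1.2),
  heavily dispersed because observed per-site read counts carry little
  fitness signal.
- **Junction reads**: terminus + fragment (30–50 nt, uniform) + adapter,
  truncated to the read length, with optional uniform substitution errors.
  Reads whose fragment is clipped empty at a chromosome end are still
  emitted (and die at the trimming length filter), so emitted reads always
  equal the summed read counts.
- **Training features**: essential genes draw GII from |N(0, 0.7)| and
  non-essential from a folded N(3.5, 1.3) — the separation the real ortholog
  labels showed (essential mode ≈ 0, non-essential mode ≈ 3.5), reproducing
  the published ~96% held-out accuracy (mean 0.97 over 20 seeds here); read
  density (|N(0,3)| vs folded N(6,5)) is deliberately weakly informative,
  mirroring its small published coefficient. Folded normals make the two
  components *exactly* identical when their parameters coincide, which pins
  the chance-level behaviour in tests.

Determinism: every operation derives its RNG from config.seed plus a fixed
per-operation offset, so identical configs reproduce byte-identical outputs
stage by stage.

What the generator does **not** emulate: nucleosome positioning (intergenic
enrichment is a single multiplicative factor), PCR/sequencing artifacts
beyond uniform substitutions, growth competition within pools, paired-end
structure, or real gene structure (no codons, few introns). Passing tests
therefore demonstrate the *analysis* is correct under the stated statistical
assumptions, not that those assumptions hold for any particular real library.

## Numerical choices

- Effective-length rounding: floor(0.9·L) with a 1e-9 guard against float
  droop; a TA whose T is the region's last base counts as inside.
- NEP uses `scipy.special.expit` (numerically saturating); tests pin it to a
  high-precision symbolic evaluation to 1e-12.
- Thresholds must be strictly increasing inside (0, 1); violating inputs are
  rejected, not reordered.
- Segment profile: bin = ceil(d·25/L); intergenic sites go to the nearer
  gene end, exact ties to the lower-coordinate gene.
- The ≥15-TA filter uses full-gene TA counts (the effective-region count is
  also computed and available).

## Problem sizes

Desk-scale defaults were chosen so the full pipeline — 2 Mb genome, 2,000
genes, 40,000 insertions, ~50,000 junction reads — runs in well under a
minute, and the complete analysis and test suite in a few minutes, while
keeping every per-gene quantity at realistic magnitudes (≈20 insertions/kb,
≈70 TA sites per average gene). The bundled study under `analysis/` uses a
1 Mb genome with ten 12,000-insertion pools per condition for the same
reason.

## Known limitations

- The native mapper's mismatch-tolerant path scans every offset; it is meant
  for desk-scale genomes (SAM input covers production-scale mapping).
- Effective regions are genomic-span based; a long 3'-terminal intron would
  misplace the excluded 10% (irrelevant in this nearly intron-free genome).
- The published model ships without standardization parameters (not
  released), so applying it to new data requires a labelled set — a property
  of the published artifact, not of this implementation.
- With a highly saturated synthetic library the essential/non-essential
  separation is stronger than in the real data, so pipeline-level
  classification accuracy here exceeds the published ~96%; the
  feature-level generator is the calibrated surrogate for that number.
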