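"""Generate the synthetic Tn-seq study: genome, labels, insertion pools, reads.

Writes to scratch/study/: the genome (FASTA) and annotation (GFF3), true
essentiality labels, ten glucose-condition insertion pools (five TcBuster-like,
five Sleeping-beauty-like, each with its own target-context bias), ten
methanol-condition pools in which 30 extra genes are required, junction reads
for one pool, and the list of switched genes.  A small summary lands in
results/study_summary.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import (
    BASE_SEED,
    N_METHANOL_SWITCHED,
    N_POOLS_PER_TRANSPOSON,
    POOL_INSERTIONS,
    RESULTS,
    SB_BIAS,
    SCRATCH,
    TCB_BIAS,
    base_config,
)

from tnseq_essentials.genome import index_ta_sites
from tnseq_essentials.junctions import JunctionReadSpec, write_sites_tsv
from tnseq_essentials.simulate import (
    assign_labels,
    simulate_genome,
    simulate_insertions,
    simulate_junction_reads,
    write_fasta,
    write_fastq,
    write_gff3,
    write_truth_tsv,
)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    config = base_config()
    genome, genes = simulate_genome(config)
    ta_index = index_ta_sites(genome)
    labels = assign_labels(genes, config.fraction_essential, BASE_SEED)
    write_fasta(genome, str(SCRATCH / "genome.fa"))
    write_gff3(genes, genome, str(SCRATCH / "annotation.gff3"))
    with open(SCRATCH / "labels_glucose.tsv", "w") as out:
        out.write("gene_id\tlabel\n")
        for gid in sorted(labels):
            out.write(f"{gid}\t{labels[gid]}\n")

    # methanol condition: some non-essential genes become required
    rng = np.random.default_rng(BASE_SEED + 99)
    non_ess = sorted(g for g, l in labels.items() if l == "non_essential")
    switched = sorted(rng.choice(non_ess, N_METHANOL_SWITCHED, replace=False))
    labels_m = {g: ("essential" if g in switched else labels[g]) for g in labels}
    (SCRATCH / "methanol_switched.txt").write_text("\n".join(switched) + "\n")

    pools = {}
    for condition, cond_labels, seed_base in (
        ("glucose", labels, 1000),
        ("methanol", labels_m, 2000),
    ):
        for t, bias in (("tcb", TCB_BIAS), ("sb", SB_BIAS)):
            for i in range(N_POOLS_PER_TRANSPOSON):
                name = f"{t}{i + 1}"
                cfg = base_config(
                    seed=BASE_SEED + seed_base + (0 if t == "tcb" else 500) + i,
                    sequence_bias=bias,
                )
                lib, truth = simulate_insertions(
                    genome, genes, cond_labels, cfg, ta_index=ta_index, label=name
                )
                write_sites_tsv(lib, str(SCRATCH / f"sites_{condition}_{name}.tsv"))
                pools[f"{condition}_{name}"] = lib.n_unique

    # junction reads for one pool, for the read-processing stage
    from tnseq_essentials.junctions import read_sites_tsv

    pool1 = read_sites_tsv(str(SCRATCH / "sites_glucose_tcb1.tsv"), ta_index)
    reads = simulate_junction_reads(
        pool1, genome, JunctionReadSpec(), seed=BASE_SEED
    )
    write_fastq(reads, str(SCRATCH / "reads_glucose_tcb1.fastq"))
    write_truth_tsv(truth, str(SCRATCH / "truth_labels_methanol.tsv"))

    summary = {
        "genome_bp": genome.total_length,
        "n_genes": len(genes),
        "ta_sites": ta_index.total,
        "n_essential": sum(1 for l in labels.values() if l == "essential"),
        "methanol_switched": len(switched),
        "pool_insertions": POOL_INSERTIONS,
        "pool_unique_sites": pools,
        "reads_pool_tcb1": len(reads),
    }
    (RESULTS / "study_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"genome {genome.total_length} bp, {len(genes)} genes, "
        f"{ta_index.total} TA sites; {len(pools)} pools written; "
        f"{len(reads)} junction reads for pool tcb1"
    )


if __name__ == "__main__":
    main()
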