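"""Shared configuration for the synthetic Tn-seq study driven by analysis/.

One genome, two transposon types with their own target-context biases
(TcBuster-like and Sleeping-beauty-like), ten insertion pools per growth
condition.  Large generated inputs (FASTA/FASTQ/site tables) go under
scratch/study/; the numbered scripts write their result tables under
results/.
"""

from pathlib import Path

from tnseq_essentials.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

BASE_SEED = 42

# TcBuster-like peripheral preference: T at -5/+6, A at -6/+5
TCB_BIAS = {-5: {"T": 2.5}, +6: {"T": 2.5}, -6: {"A": 2.5}, +5: {"A": 2.5}}
# Sleeping-beauty-like: A at -3, T at +3
SB_BIAS = {-3: {"A": 3.0}, +3: {"T": 3.0}}

N_POOLS_PER_TRANSPOSON = 5
POOL_INSERTIONS = 12_000
N_METHANOL_SWITCHED = 30  # non-essential genes that become methanol-essential


def base_config(seed: int = BASE_SEED, **overrides) -> SimulationConfig:
    defaults = dict(
        seed=seed,
        n_chromosomes=2,
        chromosome_lengths=(600_000, 400_000),
        n_genes=1000,
        n_insertions=POOL_INSERTIONS,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def pool_names() -> list[str]:
    tcb = [f"tcb{i + 1}" for i in range(N_POOLS_PER_TRANSPOSON)]
    sb = [f"sb{i + 1}" for i in range(N_POOLS_PER_TRANSPOSON)]
    return tcb + sb
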