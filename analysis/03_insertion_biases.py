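"""Insertional-bias diagnostics of the merged glucose library.

Where do insertions land (exon/intron/intergenic), how do they distribute
along gene bodies (25-segment profile), which nucleotide contexts do the two
transposons prefer (logo matrices), and does TA count beat gene length as the
normalization covariate (R^2)?  Tables go to results/, figures to
results/figures/.
"""

import json
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, SCRATCH, pool_names

from tnseq_essentials.genome import index_ta_sites, load_annotation, load_genome
from tnseq_essentials.junctions import merge_libraries, read_sites_tsv
from tnseq_essentials.stats import (
    compute_gene_stats,
    density_per_kb,
    gene_stats_frame,
    logo_matrix,
    normalization_r2,
    region_fractions,
    segment_profile,
)


def main() -> None:
    figdir = RESULTS / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome(str(SCRATCH / "genome.fa"))
    genes = load_annotation(str(SCRATCH / "annotation.gff3"), genome)
    ta_index = index_ta_sites(genome)
    merged = read_sites_tsv(str(SCRATCH / "sites_glucose_merged.tsv"), ta_index)

    fractions = region_fractions(merged, genes)
    profile = segment_profile(merged, genes)
    stats = compute_gene_stats(merged, genes, ta_index)
    gene_stats_frame(stats).to_csv(RESULTS / "gene_stats_glucose.tsv", sep="\t",
                                   index=False, float_format="%.4f")
    r2_ta, r2_len = normalization_r2(stats)

    # per-transposon logo matrices from the first pool of each type
    logos = {}
    for t in ("tcb", "sb"):
        libs = [
            read_sites_tsv(str(SCRATCH / f"sites_glucose_{p}.tsv"), ta_index)
            for p in pool_names() if p.startswith(t)
        ]
        logo = logo_matrix(merge_libraries(libs), genome, flank_k=6)
        logo.to_csv(RESULTS / f"logo_{t}.tsv", sep="\t", float_format="%.4f")
        logos[t] = logo

    # figures: segment profile and stacked logo bars
    fig, axes = plt.subplots(1, 3, figsize=(11, 3), width_ratios=[1, 2, 1])
    axes[0].bar(range(len(profile.upstream_bins)),
                profile.upstream_bins[::-1], color="tab:gray")
    axes[0].set_title("upstream IGR")
    axes[1].bar(range(1, 26), profile.orf_bins, color="tab:blue")
    axes[1].set_title("ORF (25 segments, 5'->3')")
    axes[2].bar(range(len(profile.downstream_bins)),
                profile.downstream_bins, color="tab:gray")
    axes[2].set_title("downstream IGR")
    fig.tight_layout()
    fig.savefig(figdir / "segment_profile.png", dpi=150)

    fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
    for ax, (t, logo) in zip(axes, logos.items()):
        bottom = np.zeros(len(logo))
        for base, color in zip("ACGT", ("tab:green", "tab:blue", "tab:orange", "tab:red")):
            ax.bar(logo.index, logo[base], bottom=bottom, label=base, color=color)
            bottom += logo[base].to_numpy()
        ax.set_ylabel(f"{t} freq")
    axes[0].legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / "logo_matrices.png", dpi=150)
    plt.close("all")

    summary = {
        "region_fractions": {k: round(v, 4) for k, v in fractions.items()},
        "density_per_kb": round(density_per_kb(merged, genome), 2),
        "r2_ta_vs_insertions": round(r2_ta, 4),
        "r2_length_vs_insertions": round(r2_len, 4),
        "orf_bins": profile.orf_bins.tolist(),
        "tcb_top_biases": {
            "-5_T": round(float(logos["tcb"].loc["-5", "T"]), 3),
            "-6_A": round(float(logos["tcb"].loc["-6", "A"]), 3),
        },
        "sb_top_biases": {
            "-3_A": round(float(logos["sb"].loc["-3", "A"]), 3),
            "+3_T": round(float(logos["sb"].loc["+3", "T"]), 3),
        },
    }
    (RESULTS / "bias_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"region fractions: exon {fractions['exon']:.1%}, intron "
        f"{fractions['intron']:.2%}, IGR {fractions['igr']:.1%}\n"
        f"density {summary['density_per_kb']} insertions/kb; "
        f"R2 TA vs insertions {r2_ta:.2f}, length vs insertions {r2_len:.2f}\n"
        f"TcB-like logo: T@-5 {summary['tcb_top_biases']['-5_T']}, "
        f"A@-6 {summary['tcb_top_biases']['-6_A']}; "
        f"SB-like: A@-3 {summary['sb_top_biases']['-3_A']}, "
        f"T@+3 {summary['sb_top_biases']['+3_T']}"
    )


if __name__ == "__main__":
    main()
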