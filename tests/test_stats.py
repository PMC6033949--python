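import numpy as np
import pytest

from tnseq_essentials.genome import GeneAnnotation, GenomeSequence, index_ta_sites
from tnseq_essentials.junctions import InsertionLibrary
from tnseq_essentials.stats import (
    compute_gene_stats,
    density_per_kb,
    gene_stats_frame,
    logo_matrix,
    normalization_r2,
    region_fractions,
    saturation_curve,
    segment_profile,
    venn_overlap,
)

from conftest import make_ta_chromosome


def lib_of(keys):
    lib = InsertionLibrary("t")
    for k in keys:
        lib.add(*k)
    return lib


class TestGeneInsertionIndex:
    def test_constant_cancels_at_average_ta_count(self):
        # 72 TA sites, 10 effective insertions -> GII = 10
        chrom = make_ta_chromosome(4 * 72, [1 + 4 * k for k in range(72)])
        genome = GenomeSequence({"c": chrom})
        idx = index_ta_sites(genome)
        gene = GeneAnnotation("g", "c", 1, 4 * 72, "+")
        lib = lib_of([("c", 1 + 4 * k, "forward") for k in range(10)])
        (s,) = compute_gene_stats(lib, [gene], idx)
        assert s.ta_full == 72
        assert s.gii == pytest.approx(10.0)

    def test_half_average_ta_doubles_index(self):
        # 36 TA sites, 9 effective insertions -> GII = 9 * 72 / 36 = 18
        chrom = make_ta_chromosome(4 * 36, [1 + 4 * k for k in range(36)])
        genome = GenomeSequence({"c": chrom})
        idx = index_ta_sites(genome)
        gene = GeneAnnotation("g", "c", 1, 4 * 36, "+")
        lib = lib_of([("c", 1 + 4 * k, "forward") for k in range(9)])
        (s,) = compute_gene_stats(lib, [gene], idx)
        assert s.gii == pytest.approx(18.0)

    def test_three_prime_ten_percent_excluded(self):
        # gene 1..1000 (+), 36 TA sites, insertions at 50/500/950;
        # 950 lies in the 3' 10% -> 2 effective -> GII = 2 * 72 / 36 = 4
        ta = [50, 500, 950] + [100 + 4 * k for k in range(33)]
        chrom = make_ta_chromosome(1000, ta)
        genome = GenomeSequence({"c": chrom})
        idx = index_ta_sites(genome)
        gene = GeneAnnotation("g", "c", 1, 1000, "+")
        lib = lib_of([("c", p, "forward") for p in (50, 500, 950)])
        (s,) = compute_gene_stats(lib, [gene], idx)
        assert s.ta_full == 36
        assert s.insertions_effective == 2
        assert s.gii == pytest.approx(4.0)

    def test_gii_invariant_to_read_counts(self):
        chrom = make_ta_chromosome(4 * 20, [1 + 4 * k for k in range(20)])
        genome = GenomeSequence({"c": chrom})
        idx = index_ta_sites(genome)
        gene = GeneAnnotation("g", "c", 1, 4 * 20, "+")
        low = lib_of([("c", 1, "forward"), ("c", 5, "forward")])
        high = InsertionLibrary("t")
        high.add("c", 1, "forward", 500)
        high.add("c", 5, "forward", 9)
        (s1,) = compute_gene_stats(low, [gene], idx)
        (s2,) = compute_gene_stats(high, [gene], idx)
        assert s1.gii == s2.gii
        assert s2.read_density > s1.read_density

    def test_orientation_collapse_counts_disrupted_positions(self):
        chrom = make_ta_chromosome(4 * 20, [1 + 4 * k for k in range(20)])
        genome = GenomeSequence({"c": chrom})
        idx = index_ta_sites(genome)
        gene = GeneAnnotation("g", "c", 1, 4 * 20, "+")
        both = lib_of([("c", 1, "forward"), ("c", 1, "reverse")])
        (s,) = compute_gene_stats(both, [gene], idx)
        assert s.insertions_effective == 1  # one disrupted TA position
        (s2,) = compute_gene_stats(both, [gene], idx, collapse_orientation=False)
        assert s2.insertions_effective == 2

    def test_zero_ta_gene_flagged_undefined(self):
        genome = GenomeSequence({"c": "G" * 100})
        idx = index_ta_sites(genome)
        gene = GeneAnnotation("g", "c", 1, 100, "+")
        (s,) = compute_gene_stats(InsertionLibrary(), [gene], idx)
        assert not s.defined and np.isnan(s.gii)

    def test_frame_columns(self, small_sim):
        stats = compute_gene_stats(
            small_sim["library"], small_sim["genes"], small_sim["ta_index"]
        )
        df = gene_stats_frame(stats)
        assert len(df) == len(small_sim["genes"])
        assert {"gene_id", "ta_full", "insertions_effective", "gii", "read_density"} <= set(
            df.columns
        )


class TestRegionFractions:
    def test_igr_and_exon_split(self):
        genome_genes = [GeneAnnotation("g", "c", 11, 90, "+")]
        lib = lib_of([("c", 5, "forward"), ("c", 50, "forward")])
        fr = region_fractions(lib, genome_genes)
        assert fr == {"exon": 0.5, "intron": 0.0, "igr": 0.5}

    def test_intron_assignment(self):
        gene = GeneAnnotation("g", "c", 11, 90, "+", [(11, 40), (61, 90)])
        lib = lib_of([("c", 50, "forward")])
        assert region_fractions(lib, [gene])["intron"] == 1.0

    def test_all_intergenic(self):
        gene = GeneAnnotation("g", "c", 50, 60, "+")
        lib = lib_of([("c", 5, "forward"), ("c", 70, "reverse")])
        assert region_fractions(lib, [gene])["igr"] == 1.0

    def test_fractions_sum_to_one(self, small_sim):
        fr = region_fractions(small_sim["library"], small_sim["genes"])
        assert sum(fr.values()) == pytest.approx(1.0)


class TestSegmentProfile:
    def make(self, sites, genes):
        return segment_profile(lib_of(sites), genes)

    def test_boundary_bins(self):
        gene = GeneAnnotation("g", "c", 1, 250, "+")
        prof = self.make(
            [("c", 1, "forward"), ("c", 125, "forward"), ("c", 250, "forward")], [gene]
        )
        assert prof.orf_bins[0] == 1  # offset 1 -> bin 1
        assert prof.orf_bins[12] == 1  # offset 125 -> ceil(12.5) = bin 13
        assert prof.orf_bins[24] == 1  # offset 250 -> bin 25

    def test_minus_strand_offsets_reverse(self):
        gene = GeneAnnotation("g", "c", 1, 250, "-")
        prof = self.make([("c", 250, "forward")], [gene])
        assert prof.orf_bins[0] == 1  # genomic end = 5' end on minus strand

    def test_orf_bins_sum_to_orf_insertions(self, small_sim):
        prof = segment_profile(small_sim["library"], small_sim["genes"])
        fr = region_fractions(small_sim["library"], small_sim["genes"])
        n_sites = len(small_sim["library"].positions())
        in_orf = round((fr["exon"] + fr["intron"]) * n_sites)
        assert prof.orf_bins.sum() == in_orf

    def test_igr_site_goes_to_nearer_gene_flank(self):
        g1 = GeneAnnotation("a", "c", 1, 100, "+")
        g2 = GeneAnnotation("b", "c", 201, 300, "+")
        # site at 110: 10 bp right of g1 (downstream of + gene)
        prof = self.make([("c", 110, "forward")], [g1, g2])
        assert prof.downstream_bins[0] == 1
        # site at 195: 6 bp left of g2 (upstream of + gene)
        prof = self.make([("c", 195, "forward")], [g1, g2])
        assert prof.upstream_bins[0] == 1

    def test_equidistant_tie_breaks_to_lower_coordinate_gene(self):
        g1 = GeneAnnotation("a", "c", 1, 100, "+")
        g2 = GeneAnnotation("b", "c", 201, 300, "+")
        prof = self.make([("c", 150, "forward")], [g1, g2])  # 50 bp from both
        assert prof.downstream_bins.sum() == 1 and prof.upstream_bins.sum() == 0


class TestLogoMatrix:
    def test_constructed_context(self):
        # context "AT[TA]TA": A at -2 with frequency 1.0
        genome = GenomeSequence({"c": "GGATTATAGG"})
        lib = lib_of([("c", 5, "forward")])
        logo = logo_matrix(lib, genome, flank_k=2)
        assert logo.loc["-2", "A"] == 1.0
        assert logo.loc["-1", "T"] == 1.0
        assert logo.loc["T", "T"] == 1.0 and logo.loc["A", "A"] == 1.0

    def test_single_site_is_one_hot(self):
        genome = GenomeSequence({"c": "GGATTATAGG"})
        logo = logo_matrix(lib_of([("c", 5, "forward")]), genome, flank_k=2)
        assert ((logo == 0) | (logo == 1)).all().all()
        assert (logo.sum(axis=1) == 1.0).all()

    def test_reverse_site_contributes_reverse_complement(self):
        genome = GenomeSequence({"c": "GGCTTAGAGG"})  # TA at 5
        fwd = logo_matrix(lib_of([("c", 5, "forward")]), genome, flank_k=2)
        rev = logo_matrix(lib_of([("c", 5, "reverse")]), genome, flank_k=2)
        # forward +1,+2 = "GA"; reverse -1,-2 read the complement of that
        assert fwd.loc["+1", "G"] == 1.0 and rev.loc["-1", "C"] == 1.0
        assert fwd.loc["-1", "T"] == 1.0 and rev.loc["+1", "A"] == 1.0

    def test_rows_sum_to_one_and_center_pure(self, small_sim):
        logo = logo_matrix(small_sim["library"], small_sim["genome"])
        assert np.allclose(logo.sum(axis=1), 1.0, atol=1e-9)
        assert logo.loc["T", "T"] == 1.0 and logo.loc["A", "A"] == 1.0

    def test_no_usable_sites_rejected(self):
        genome = GenomeSequence({"c": "TAGG"})  # TA at 1, flanks run off edge
        with pytest.raises(ValueError, match="no usable"):
            logo_matrix(lib_of([("c", 1, "forward")]), genome, flank_k=3)


class TestSaturationAndVenn:
    def test_cumulative_counts(self):
        libs = [
            lib_of([("c", 1, "forward"), ("c", 2, "forward")]),
            lib_of([("c", 2, "forward"), ("c", 3, "forward")]),
            lib_of([("c", 3, "forward")]),
        ]
        assert saturation_curve(libs).tolist() == [2, 3, 3]

    def test_identical_libraries_flat_after_first(self):
        lib = lib_of([("c", i, "forward") for i in range(1, 6)])
        assert saturation_curve([lib] * 4).tolist() == [5, 5, 5, 5]

    def test_disjoint_libraries_grow_linearly(self):
        libs = [lib_of([("c", 10 * k + i, "forward") for i in range(3)]) for k in range(4)]
        assert saturation_curve(libs).tolist() == [3, 6, 9, 12]

    def test_monotone_for_random_orderings(self, small_sim):
        lib = small_sim["library"]
        keys = sorted(lib.keys())
        chunks = [keys[i::5] for i in range(5)]
        libs = []
        for chunk in chunks:
            l = InsertionLibrary()
            for k in chunk:
                l.add(*k)
            libs.append(l)
        mean, sd = saturation_curve(libs, n_orders=10, seed=3)
        assert np.all(np.diff(mean) >= 0)
        assert mean[-1] == lib.n_unique

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [2, 3, 4], (1, 2, 1)),
            ([1, 2, 3], [1, 2, 3], (0, 3, 0)),
            ([1, 2], [5, 6, 7], (2, 0, 3)),
        ],
    )
    def test_venn_partitions_union(self, a, b, expected):
        la = lib_of([("c", i, "forward") for i in a])
        lb = lib_of([("c", i, "forward") for i in b])
        assert venn_overlap(la, lb) == expected


class TestNormalizationR2:
    def stats_for(self, ta, ins, length=None):
        from tnseq_essentials.stats import GeneInsertionStats

        length = length or [10 * t for t in ta]
        return [
            GeneInsertionStats(f"g{i}", length[i], ta[i], ta[i], ins[i], ins[i],
                               ins[i], 0.0, 0.0, True)
            for i in range(len(ta))
        ]

    def test_proportional_gives_unit_r2(self):
        ta = [10, 20, 30, 40]
        r2_ta, r2_len = normalization_r2(self.stats_for(ta, [2 * t for t in ta]))
        assert r2_ta == pytest.approx(1.0)
        assert r2_len == pytest.approx(1.0)

    def test_permuted_insertions_give_near_zero_r2(self):
        rng = np.random.default_rng(0)
        ta = list(range(10, 1010))
        ins = [2 * t for t in ta]
        rng.shuffle(ins)
        r2_ta, _ = normalization_r2(self.stats_for(ta, ins))
        assert r2_ta < 0.02

    def test_constant_insertions_flagged_undefined(self):
        r2_ta, r2_len = normalization_r2(self.stats_for([10, 20, 30], [5, 5, 5]))
        assert np.isnan(r2_ta) and np.isnan(r2_len)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            normalization_r2(self.stats_for([10, 20], [1, 2]))


class TestDensity:
    def test_sites_per_kb(self):
        genome = GenomeSequence({"c": "G" * 1000})
        lib = lib_of([("c", i, "forward") for i in range(1, 11)])
        assert density_per_kb(lib, genome) == pytest.approx(10.0)

    def test_empty_library(self):
        genome = GenomeSequence({"c": "G" * 1000})
        assert density_per_kb(InsertionLibrary(), genome) == 0.0

    def test_doubling_genome_halves_density(self):
        lib = lib_of([("c", i, "forward") for i in range(1, 11)])
        g1 = GenomeSequence({"c": "G" * 1000})
        g2 = GenomeSequence({"c": "G" * 1000, "c2": "G" * 1000})
        assert density_per_kb(lib, g1) == 2 * density_per_kb(lib, g2)
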