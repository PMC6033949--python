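import numpy as np
import pytest

from tnseq_essentials.genome import GenomeSequence, index_ta_sites
from tnseq_essentials.junctions import (
    Alignment,
    GenomeMapper,
    InsertionLibrary,
    JunctionReadSpec,
    call_insertion_sites,
    map_fragments,
    merge_libraries,
    read_alignments_sam,
    read_sites_tsv,
    revcomp,
    trim_records,
    write_sites_tsv,
)

from conftest import make_ta_chromosome

TERM = "AATATCTCGACAAAGG"
ADAPT = "ATACCACGAC"
SPEC = JunctionReadSpec()


def trim_one(seq, spec=SPEC):
    out = list(trim_records([("r", seq)], spec))
    return out[0][1] if out else None


class TestTrimming:
    def test_exact_composition(self):
        frag = "ACGTACGTACGTACGTAA"
        assert trim_one(TERM + frag + ADAPT) == frag

    def test_read_without_terminus_discarded(self):
        assert trim_one("GGGG" + TERM + "ACGTACGTACGTACGTAA") is None

    def test_short_fragment_discarded(self):
        assert trim_one(TERM + "ACGTACGTAC" + ADAPT) is None  # 10 < 16

    def test_terminus_mismatch_within_budget_tolerated(self):
        mutated = "C" + TERM[1:]  # 1 mismatch <= ceil(0.05 * 16)
        frag = "ACGTACGTACGTACGTAA"
        assert trim_one(mutated + frag + ADAPT) == frag

    def test_second_terminus_occurrence_stripped(self):
        frag = "ACGTACGTACGTACGTAA"
        assert trim_one(TERM + TERM + frag + ADAPT) == frag

    def test_output_never_contains_full_terminus(self):
        frag1, frag2 = "ACGTACGTACGTACGTAA", "TTGCATGCATGCATGCAT"
        out = trim_one(TERM + frag1 + TERM + frag2 + ADAPT)
        assert out is not None and TERM not in out
        assert out == frag2

    def test_partial_adapter_at_truncated_read_end(self):
        frag = "ACGTACGTACGTACGTAA"
        read = (TERM + frag + ADAPT)[: len(TERM) + len(frag) + 6]
        assert trim_one(read) == frag

    def test_truncation_to_max_fragment_len(self):
        frag = "ACGT" * 20  # 80 nt
        out = trim_one(TERM + frag)  # no adapter present
        assert out == frag[: SPEC.max_fragment_len]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            JunctionReadSpec(mismatch_rate=0.7)
        with pytest.raises(ValueError):
            JunctionReadSpec(transposon_terminus="")


def brute_force_locations(frag, genome, max_mm):
    """Exhaustive (position, strand) scan; keeps all minimum-mismatch loci."""
    locs = []
    for chrom, seq in genome.chromosomes.items():
        for target, strand in ((frag, "+"), (revcomp(frag), "-")):
            L = len(target)
            for p in range(len(seq) - L + 1):
                mm = sum(1 for a, b in zip(seq[p : p + L], target) if a != b)
                if mm <= max_mm:
                    locs.append((chrom, p, strand, mm))
    if not locs:
        return []
    best = min(m for *_, m in locs)
    return sorted(t for t in locs if t[3] == best)


class TestMapping:
    def test_unique_exact_fragment_found(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 500))
        genome = GenomeSequence({"c": seq})
        frag = seq[100:130]
        res = map_fragments([("f", frag)], genome)
        assert len(res.alignments) == 1
        aln = res.alignments[0]
        assert (aln.chromosome, aln.start, aln.strand, aln.mismatches) == ("c", 101, "+", 0)

    def test_duplicated_fragment_dropped_as_multimapped(self):
        rng = np.random.default_rng(1)
        core = "".join(rng.choice(list("ACGT"), 30))
        seq = "".join(rng.choice(list("ACGT"), 200)) + core + "".join(
            rng.choice(list("ACGT"), 200)
        ) + core
        genome = GenomeSequence({"c": seq})
        res = map_fragments([("f", core)], genome)
        assert res.alignments == []
        assert res.dropped == {"f": "multi_mapped"}

    def test_unmappable_fragment_dropped(self):
        genome = GenomeSequence({"c": "G" * 300})
        res = map_fragments([("f", "ACGTACGTACGTACGTACGT")], genome)
        assert res.dropped == {"f": "unmapped"}

    def test_reverse_strand_coordinates(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 400))
        genome = GenomeSequence({"c": seq})
        frag = revcomp(seq[200:230])
        res = map_fragments([("f", frag)], genome)
        assert len(res.alignments) == 1
        aln = res.alignments[0]
        assert (aln.start, aln.strand) == (201, "-")

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_brute_force_on_random_genomes(self, seed):
        """Native mapper vs exhaustive scan on random 2-kb genomes, including
        planted repeats (multi-map discards) and mutated fragments."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        # plant an exact repeat to exercise multi-mapping
        seq = seq[:1500] + seq[200:240] + seq[1540:]
        genome = GenomeSequence({"c": seq})
        mapper = GenomeMapper(genome)
        fragments = []
        for i in range(8):
            start = int(rng.integers(0, 1950))
            L = int(rng.integers(18, 45))
            frag = seq[start : start + L]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            n_mut = int(rng.integers(0, 5))  # up to 4 > max_mismatches
            frag = list(frag)
            for _ in range(n_mut):
                j = int(rng.integers(0, len(frag)))
                frag[j] = "ACGT"[int(rng.integers(0, 4))]
            fragments.append((f"f{i}", "".join(frag)))
        fragments.append(("rand", "".join(rng.choice(list("ACGT"), 25))))
        res = map_fragments(fragments, genome, max_mismatches=3, mapper=mapper)
        by_id = {a.fragment_id: a for a in res.alignments}
        for frag_id, frag in fragments:
            expected = brute_force_locations(frag, genome, max_mm=3)
            if len(expected) == 1:
                chrom, p0, strand, mm = expected[0]
                aln = by_id[frag_id]
                assert (aln.chromosome, aln.start, aln.strand, aln.mismatches) == (
                    chrom, p0 + 1, strand, mm,
                )
            elif len(expected) == 0:
                assert res.dropped[frag_id] == "unmapped"
            else:
                assert res.dropped[frag_id] == "multi_mapped"

    def test_verbatim_fragments_at_unique_loci_recovered_exactly(self):
        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("ACGT"), 5000))
        genome = GenomeSequence({"c": seq})
        mapper = GenomeMapper(genome)
        frags = []
        for i in range(40):
            start = int(rng.integers(0, 4950))
            frags.append((f"f{i}", seq[start : start + 30], start + 1))
        res = map_fragments([(i, s) for i, s, _ in frags], genome, mapper=mapper)
        starts = {a.fragment_id: a.start for a in res.alignments}
        for frag_id, frag, true_start in frags:
            if frag_id in starts:  # unique locus
                assert starts[frag_id] == true_start


class TestSiteCalling:
    def test_plus_strand_alignment_after_ta(self):
        # TA at 10; fragment begins at 12 on + strand
        chrom = make_ta_chromosome(40, [10])
        idx = index_ta_sites(GenomeSequence({"c": chrom}))
        aln = Alignment("f", "c", 12, "+", 0, 20)
        lib = call_insertion_sites([aln], idx)
        assert list(lib.keys()) == [("c", 10, "forward")]

    def test_minus_strand_alignment_before_ta(self):
        # TA at 30; minus-strand fragment covers [10, 29]; junction at 29 end
        chrom = make_ta_chromosome(40, [30])
        idx = index_ta_sites(GenomeSequence({"c": chrom}))
        aln = Alignment("f", "c", 10, "-", 0, 20)
        lib = call_insertion_sites([aln], idx)
        assert list(lib.keys()) == [("c", 30, "reverse")]

    def test_snap_window_and_no_ta_dropped(self):
        chrom = make_ta_chromosome(40, [10])
        idx = index_ta_sites(GenomeSequence({"c": chrom}))
        # expected T at 12-2=10 exact; at start 14 expected 12, snaps 2 to 10
        snapped = call_insertion_sites([Alignment("f", "c", 14, "+", 0, 20)], idx)
        assert list(snapped.keys()) == [("c", 10, "forward")]
        # start 20 -> expected 18, beyond the window: dropped
        dropped = call_insertion_sites([Alignment("f", "c", 20, "+", 0, 15)], idx)
        assert len(dropped) == 0

    def test_duplicates_collapse_to_read_count(self):
        chrom = make_ta_chromosome(40, [10])
        idx = index_ta_sites(GenomeSequence({"c": chrom}))
        alns = [Alignment(f"f{i}", "c", 12, "+", 0, 20) for i in range(3)]
        lib = call_insertion_sites(alns, idx)
        assert lib.read_count(("c", 10, "forward")) == 3


class TestLibraryAlgebra:
    def lib(self, keys, label=""):
        out = InsertionLibrary(label=label)
        for k in keys:
            out.add(*k)
        return out

    def test_merge_unions_and_sums(self):
        a = self.lib([("c1", 10, "forward"), ("c1", 20, "forward")])
        b = self.lib([("c1", 20, "forward"), ("c1", 30, "reverse")])
        m = merge_libraries([a, b])
        assert m.n_unique == 3
        assert m.read_count(("c1", 20, "forward")) == 2

    def test_self_merge_keeps_keys_doubles_counts(self):
        a = self.lib([("c1", 10, "forward"), ("c2", 5, "reverse")])
        m = merge_libraries([a, a])
        assert m.positions() == a.positions()
        assert m.total_reads == 2 * a.total_reads

    def test_merge_associative_commutative_on_keys(self):
        libs = [
            self.lib([("c1", i, "forward") for i in range(1, 10, k)])
            for k in (1, 2, 3)
        ]
        m1 = merge_libraries([merge_libraries(libs[:2]), libs[2]])
        m2 = merge_libraries([libs[0], merge_libraries(libs[2:0:-1])])
        assert m1.positions() == m2.positions()
        assert m1.position_counts() == m2.position_counts()

    def test_merge_validates_against_ta_index(self):
        idx = index_ta_sites(GenomeSequence({"c1": make_ta_chromosome(20, [10])}))
        bad = self.lib([("c1", 3, "forward")])
        with pytest.raises(ValueError, match="not at TA"):
            merge_libraries([bad], ta_index=idx)


class TestSitesIO:
    def test_round_trip_identity(self, tmp_path):
        lib = InsertionLibrary("x")
        lib.add("c1", 10, "forward", 3)
        lib.add("c2", 5, "reverse", 1)
        path = tmp_path / "sites.tsv"
        write_sites_tsv(lib, str(path))
        assert read_sites_tsv(str(path)) == lib

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("chromosome\tposition\torientation\tread_count\n")
        assert read_sites_tsv(str(path)).n_unique == 0

    def test_non_ta_position_rejected(self, tmp_path):
        idx = index_ta_sites(GenomeSequence({"c1": make_ta_chromosome(20, [10])}))
        path = tmp_path / "sites.tsv"
        path.write_text(
            "chromosome\tposition\torientation\tread_count\nc1\t7\tforward\t1\n"
        )
        with pytest.raises(ValueError, match="not at TA"):
            read_sites_tsv(str(path), idx)


class TestSAMInput:
    def test_minimal_sam_parsed(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:c1\tLN:1000\n"
            "f1\t0\tc1\t101\t42\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:1\n"
            "f2\t16\tc1\t51\t42\t20M\t*\t0\t0\t" + "C" * 20 + "\t*\tNM:i:0\n"
            "f3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "G" * 20 + "\t*\n"
        )
        alns = read_alignments_sam(str(sam))
        assert len(alns) == 2
        assert (alns[0].chromosome, alns[0].start, alns[0].strand, alns[0].mismatches) == (
            "c1", 101, "+", 1,
        )
        assert (alns[1].start, alns[1].strand) == (51, "-")
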