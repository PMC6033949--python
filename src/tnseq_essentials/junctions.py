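"""Transposon–genome junction reads to unique insertion-site libraries.

A junction read begins with the transposon terminus (the end of the terminal
inverted repeat carried into the sequencing library), continues into adjacent
genomic DNA, and may end in adapter sequence.  Processing is:

1. trim — strip the terminus prefix (tolerating mismatches), guard against a
   second terminus copy from nonspecific amplification, strip the adapter
   suffix, then length-filter/truncate the genomic fragment;
2. map — align each fragment ungapped against both genome strands and keep it
   only when a single location attains the minimum mismatch count (multi-mapped
   and unmapped fragments are dropped with reason codes);
3. call sites — the junction-proximal (5') end of the aligned fragment must
   abut a TA dinucleotide; the insertion site is that TA's T coordinate, with
   the alignment strand as insertion orientation.

Trimming and mapping are implemented natively so the whole pipeline runs from
Python without external aligner binaries; pre-mapped SAM is also accepted so
any aligner can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .genome import GenomeSequence, TASiteIndex

__all__ = [
    "JunctionReadSpec",
    "InsertionSite",
    "InsertionLibrary",
    "Alignment",
    "MappingResult",
    "GenomeMapper",
    "trim_junction_reads",
    "trim_records",
    "map_fragments",
    "call_insertion_sites",
    "merge_libraries",
    "read_sites_tsv",
    "write_sites_tsv",
    "write_sites_bed",
    "read_alignments_sam",
    "revcomp",
]

# TcBuster terminus and sequencing-adapter tail used by the original libraries.
DEFAULT_TERMINUS = "AATATCTCGACAAAGG"
DEFAULT_ADAPTER = "ATACCACGAC"

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class JunctionReadSpec:
    """What a junction read looks like and how strictly to trim it."""

    transposon_terminus: str = DEFAULT_TERMINUS
    adapter_tail: str = DEFAULT_ADAPTER
    mismatch_rate: float = 0.05
    min_fragment_len: int = 16
    max_fragment_len: int = 50

    def __post_init__(self) -> None:
        if not self.transposon_terminus:
            raise ValueError("transposon_terminus must be non-empty")
        if not (0.0 <= self.mismatch_rate < 0.5):
            raise ValueError("mismatch_rate must be in [0, 0.5)")
        if self.min_fragment_len > self.max_fragment_len:
            raise ValueError("min_fragment_len > max_fragment_len")


@dataclass(frozen=True)
class InsertionSite:
    chromosome: str
    position: int  # 1-based coordinate of the TA's T
    orientation: str  # "forward" | "reverse"
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chromosome, self.position, self.orientation)


class InsertionLibrary:
    """A named set of unique insertion sites keyed by (chrom, position, orientation)."""

    def __init__(self, label: str = "", sites: dict | None = None):
        self.label = label
        self._sites: dict[tuple[str, int, str], int] = dict(sites or {})

    def add(self, chromosome: str, position: int, orientation: str, read_count: int = 1):
        if read_count < 1:
            raise ValueError("read_count must be >= 1")
        key = (chromosome, int(position), orientation)
        self._sites[key] = self._sites.get(key, 0) + read_count

    @property
    def n_unique(self) -> int:
        return len(self._sites)

    @property
    def total_reads(self) -> int:
        return sum(self._sites.values())

    def keys(self):
        return self._sites.keys()

    def read_count(self, key: tuple[str, int, str]) -> int:
        return self._sites[key]

    def sites(self):
        for (chrom, pos, orient), count in sorted(self._sites.items()):
            yield InsertionSite(chrom, pos, orient, count)

    def positions(self, stranded: bool = True) -> set:
        """Site keys; with stranded=False orientations are collapsed."""
        if stranded:
            return set(self._sites)
        return {(c, p) for c, p, _ in self._sites}

    def position_counts(self, stranded: bool = True) -> dict:
        """Read counts aggregated by key (optionally orientation-collapsed)."""
        if stranded:
            return dict(self._sites)
        out: dict[tuple[str, int], int] = {}
        for (c, p, _), n in self._sites.items():
            out[(c, p)] = out.get((c, p), 0) + n
        return out

    def validate(self, ta_index: TASiteIndex) -> None:
        bad = [k for k in self._sites if not ta_index.contains(k[0], k[1])]
        if bad:
            raise ValueError(f"{len(bad)} site(s) not at TA positions: {bad[:10]}")

    def __len__(self) -> int:
        return self.n_unique

    def __eq__(self, other) -> bool:
        return isinstance(other, InsertionLibrary) and self._sites == other._sites


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def _strip_terminus(seq: str, terminus: str, allowed_mm: int) -> str | None:
    lt = len(terminus)
    if len(seq) < lt or not _hamming_leq(seq[:lt], terminus, allowed_mm):
        return None
    return seq[lt:]


def _strip_adapter(seq: str, adapter: str, rate: float, min_overlap: int = 4) -> str:
    """Remove the shortest fragment suffix matching a prefix of the adapter.

    Suffix lengths from min_overlap up to the adapter length are tried
    shortest-first, each with its own mismatch budget ceil(rate * L); up to
    min_overlap-1 residual adapter bases may survive, which the downstream
    mismatch-tolerant mapping absorbs.
    """
    la = len(adapter)
    for L in range(min_overlap, min(la, len(seq)) + 1):
        if _hamming_leq(seq[-L:], adapter[:L], math.ceil(rate * L)):
            return seq[:-L]
    return seq


def trim_records(records, spec: JunctionReadSpec):
    """Trim (id, sequence) read records; yields (id, genomic fragment).

    Reads lacking the terminus prefix are discarded entirely; a second
    terminus occurrence (nonspecific amplification) is stripped; the adapter
    suffix is removed; fragments shorter than min_fragment_len are discarded
    and longer ones truncated to max_fragment_len.
    """
    terminus = spec.transposon_terminus.upper()
    adapter = spec.adapter_tail.upper()
    allowed = math.ceil(spec.mismatch_rate * len(terminus))
    for read_id, seq in records:
        seq = seq.upper()
        frag = _strip_terminus(seq, terminus, allowed)
        if frag is None:
            continue
        # nonspecific-amplification guard: drop through any later terminus copy
        # (mismatch-tolerant at the new prefix, exact-match anywhere inside)
        again = _strip_terminus(frag, terminus, allowed)
        if again is not None:
            frag = again
        idx = frag.find(terminus)
        while idx != -1:
            frag = frag[idx + len(terminus):]
            idx = frag.find(terminus)
        if adapter:
            frag = _strip_adapter(frag, adapter, spec.mismatch_rate)
        if len(frag) < spec.min_fragment_len:
            continue
        yield read_id, frag[: spec.max_fragment_len]


def trim_junction_reads(fastq_path: str, spec: JunctionReadSpec) -> list[tuple[str, str]]:
    """Trim a FASTQ file of junction reads to genomic fragments."""
    try:
        records = ((r.id, str(r.seq)) for r in SeqIO.parse(fastq_path, "fastq"))
        return list(trim_records(records, spec))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {fastq_path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    fragment_id: str
    chromosome: str
    start: int  # 1-based leftmost coordinate on the forward strand
    strand: str  # "+" | "-"
    mismatches: int
    length: int


@dataclass
class MappingResult:
    alignments: list[Alignment]
    dropped: dict[str, str] = field(default_factory=dict)  # id -> reason


_ENC = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _ENC[ord(base)] = i


class GenomeMapper:
    """Exact-seed + exhaustive-fallback ungapped mapper.

    An exact 16-mer index finds all zero-mismatch occurrences; fragments
    without an exact hit fall back to a vectorized full scan of every offset
    on both strands.  Results are identical to brute force: when an exact hit
    exists the minimum mismatch count is 0 and uniqueness is decided by the
    number of exact hits; otherwise the full scan decides.
    """

    K = 16

    def __init__(self, genome: GenomeSequence):
        self.genome = genome
        self._arrays: dict[str, np.ndarray] = {}
        self._kmer_codes: dict[str, np.ndarray] = {}
        self._kmer_pos: dict[str, np.ndarray] = {}
        for name, seq in genome.chromosomes.items():
            arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            self._arrays[name] = arr
            n = len(arr) - self.K + 1
            if n <= 0:
                self._kmer_codes[name] = np.empty(0, dtype=np.int64)
                self._kmer_pos[name] = np.empty(0, dtype=np.int64)
                continue
            codes = np.zeros(n, dtype=np.int64)
            valid = np.ones(n, dtype=bool)
            for j in range(self.K):
                b = arr[j : n + j]
                valid &= b != 255
                codes = codes * 4 + np.where(b == 255, 0, b)
            pos = np.flatnonzero(valid)
            codes = codes[pos]
            order = np.argsort(codes, kind="stable")
            self._kmer_codes[name] = codes[order]
            self._kmer_pos[name] = pos[order]

    @staticmethod
    def _encode(seq: str) -> np.ndarray | None:
        arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if np.any(arr == 255):
            return None
        return arr

    def _exact_hits(self, frag: str) -> list[tuple[str, int]]:
        """All 0-based start positions of frag on the forward strand."""
        L = len(frag)
        hits: list[tuple[str, int]] = []
        if L >= self.K:
            code_arr = self._encode(frag[: self.K])
            if code_arr is None:
                return []
            code = 0
            for b in code_arr:
                code = code * 4 + int(b)
            for name, seq in self.genome.chromosomes.items():
                codes, pos = self._kmer_codes[name], self._kmer_pos[name]
                lo = np.searchsorted(codes, code, side="left")
                hi = np.searchsorted(codes, code, side="right")
                for p in pos[lo:hi]:
                    p = int(p)
                    if seq[p : p + L] == frag:
                        hits.append((name, p))
        else:
            for name, seq in self.genome.chromosomes.items():
                i = seq.find(frag)
                while i != -1:
                    hits.append((name, i))
                    i = seq.find(frag, i + 1)
        return hits

    def _scan_hits(self, frag: str, max_mm: int) -> list[tuple[str, int, int]]:
        """All (chrom, 0-based start, mismatches<=max_mm) via full scan."""
        enc = _ENC[np.frombuffer(frag.encode("ascii"), dtype=np.uint8)]
        L = len(frag)
        out: list[tuple[str, int, int]] = []
        for name, arr in self._arrays.items():
            n = len(arr) - L + 1
            if n <= 0:
                continue
            mism = np.zeros(n, dtype=np.int32)
            for j in range(L):
                mism += arr[j : n + j] != enc[j]
            for p in np.flatnonzero(mism <= max_mm):
                out.append((name, int(p), int(mism[p])))
        return out

    def locate(self, frag: str, max_mismatches: int) -> list[tuple[str, int, str, int]]:
        """All alignment locations (chrom, 0-based start, strand, mismatches)
        attaining the minimum mismatch count, provided it is <= max_mismatches."""
        rc = revcomp(frag)
        exact = [(c, p, "+") for c, p in self._exact_hits(frag)]
        exact += [(c, p, "-") for c, p in self._exact_hits(rc)]
        if exact:
            return [(c, p, s, 0) for c, p, s in exact]
        if max_mismatches == 0:
            return []
        cands = [(c, p, "+", m) for c, p, m in self._scan_hits(frag, max_mismatches)]
        cands += [(c, p, "-", m) for c, p, m in self._scan_hits(rc, max_mismatches)]
        if not cands:
            return []
        best = min(m for _, _, _, m in cands)
        return [t for t in cands if t[3] == best]


def map_fragments(
    fragments: list[tuple[str, str]],
    genome: GenomeSequence,
    max_mismatches: int = 3,
    mapper: GenomeMapper | None = None,
) -> MappingResult:
    """Uniquely map genomic fragments, discarding multi-mapped ones.

    A fragment is retained only when exactly one (chromosome, start, strand)
    location attains the minimum mismatch count and that count does not exceed
    ``max_mismatches``.  Identical fragment sequences are located once and the
    result reused.
    """
    if mapper is None:
        mapper = GenomeMapper(genome)
    cache: dict[str, list[tuple[str, int, str, int]]] = {}
    alignments: list[Alignment] = []
    dropped: dict[str, str] = {}
    for frag_id, seq in fragments:
        seq = seq.upper()
        locs = cache.get(seq)
        if locs is None:
            locs = mapper.locate(seq, max_mismatches)
            cache[seq] = locs
        if not locs:
            dropped[frag_id] = "unmapped"
        elif len(locs) > 1:
            dropped[frag_id] = "multi_mapped"
        else:
            chrom, p0, strand, mm = locs[0]
            alignments.append(
                Alignment(frag_id, chrom, p0 + 1, strand, mm, len(seq))
            )
    return MappingResult(alignments, dropped)


# ---------------------------------------------------------------------------
# Site calling and library algebra
# ---------------------------------------------------------------------------


def call_insertion_sites(
    alignments: list[Alignment],
    ta_index: TASiteIndex,
    snap_window: int = 2,
    label: str = "",
) -> InsertionLibrary:
    """Snap alignment junctions to TA sites and collapse duplicates.

    For a + strand alignment starting at s, the fragment begins immediately 3'
    of the TA, so the expected T coordinate is s - 2; for a - strand alignment
    ending at e it is e + 1.  The nearest indexed TA within ``snap_window``
    bases of the expected coordinate wins (end-repair can shift the junction);
    exact-distance ties break toward the 5' side in insertion orientation.
    Alignments with no TA in the window are dropped.
    """
    lib = InsertionLibrary(label=label)
    for aln in alignments:
        if aln.strand == "+":
            expected = aln.start - 2
            orientation = "forward"
            five_prime_sign = -1  # 5'-ward in insertion orientation = lower coord
        else:
            expected = aln.start + aln.length  # e + 1
            orientation = "reverse"
            five_prime_sign = +1
        found = None
        for dist in range(snap_window + 1):
            shifts = [0] if dist == 0 else [five_prime_sign * dist, -five_prime_sign * dist]
            for shift in shifts:
                t = expected + shift
                if ta_index.contains(aln.chromosome, t):
                    found = t
                    break
            if found is not None:
                break
        if found is not None:
            lib.add(aln.chromosome, found, orientation)
    return lib


def merge_libraries(
    libraries: list[InsertionLibrary],
    label: str = "merged",
    ta_index: TASiteIndex | None = None,
) -> InsertionLibrary:
    """Union by (chromosome, position, orientation); read counts are summed."""
    if not libraries:
        raise ValueError("need at least one library")
    merged = InsertionLibrary(label=label)
    for lib in libraries:
        for key in lib.keys():
            merged.add(*key, read_count=lib.read_count(key))
    if ta_index is not None:
        merged.validate(ta_index)
    return merged


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_HEADER = "chromosome\tposition\torientation\tread_count"


def write_sites_tsv(library: InsertionLibrary, path: str) -> None:
    with open(path, "w") as out:
        out.write(_TSV_HEADER + "\n")
        for site in library.sites():
            out.write(
                f"{site.chromosome}\t{site.position}\t{site.orientation}\t{site.read_count}\n"
            )


def read_sites_tsv(
    path: str, ta_index: TASiteIndex | None = None, label: str = ""
) -> InsertionLibrary:
    lib = InsertionLibrary(label=label or path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header.split("\t") != _TSV_HEADER.split("\t"):
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, pos, orient, count = fields
            lib.add(chrom, int(pos), orient, int(count))
    if ta_index is not None:
        lib.validate(ta_index)
    return lib


def write_sites_bed(library: InsertionLibrary, path: str) -> None:
    """BED export (0-based half-open over the TA dinucleotide, strand column)."""
    with open(path, "w") as out:
        for site in library.sites():
            strand = "+" if site.orientation == "forward" else "-"
            out.write(
                f"{site.chromosome}\t{site.position - 1}\t{site.position + 1}\t"
                f"insertion\t{site.read_count}\t{strand}\n"
            )


def read_alignments_sam(path: str) -> list[Alignment]:
    """Read pre-mapped alignments from SAM (any aligner can substitute the
    native mapper).  Secondary/supplementary and unmapped records are skipped;
    the NM tag supplies the mismatch count when present."""
    import pysam

    alignments: list[Alignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alignments.append(
                Alignment(
                    fragment_id=rec.query_name,
                    chromosome=rec.reference_name,
                    start=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(mm),
                    length=rec.query_length or len(rec.query_sequence or ""),
                )
            )
    return alignments
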