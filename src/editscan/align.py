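"""Read placement and hyper-editing rescue.

Standard aligners drop reads whose A-to-I edit clusters produce too many
mismatches.  Those reads are recovered here the way hyper-editing pipelines
do: collapse the A/G distinction by rewriting every A as G in both the read
and the reference, align in the reduced three-letter alphabet, then verify
the original read against the original genome at the recovered locus.  A
read is accepted as hyper-edited only when its mismatches are dominated by
the edit-consistent change (A→G on the transcript strand; T→C on the
genomic plus strand for minus-strand transcripts).

The primary pass is a deliberately small ungapped k-mer seed aligner — a
desk-scale stand-in for a production spliced aligner, adequate for the
synthetic genomes this package ships with.  Real alignments in SAM/BAM can
be ingested instead and bypass it entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .models import GenomeRef, open_maybe_gzip, revcomp


class AlphabetError(ValueError):
    pass


def transform_a_to_g(sequence: str) -> str:
    """Rewrite every A as G (the pseudo-genome / pseudo-read transform)."""
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise AlphabetError(f"non-ACGTN symbols {sorted(bad)}")
    return sequence.replace("A", "G")


def transform_t_to_c(sequence: str) -> str:
    """Rewrite every T as C — the plus-strand image of A→G on the minus
    strand; used to rescue reads whose edits appear as T→C mismatches."""
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise AlphabetError(f"non-ACGTN symbols {sorted(bad)}")
    return sequence.replace("T", "C")


@dataclass
class AlignParams:
    """Primary-pass and rescue thresholds.

    Rescue acceptance: at least ``rescue_min_ag_sites`` edit-consistent
    mismatches, making up at least ``rescue_min_ag_fraction`` of all
    mismatches, with at most ``rescue_max_other_mismatches`` others.
    """

    max_mismatches: int = 4
    seed_kmer: int = 20
    rescue_min_ag_sites: int = 3
    rescue_min_ag_fraction: float = 0.6
    rescue_max_other_mismatches: int = 2

    def __post_init__(self):
        if self.seed_kmer < 8:
            raise ValueError("seed_kmer must be at least 8")
        if min(
            self.max_mismatches,
            self.rescue_min_ag_sites,
            self.rescue_max_other_mismatches,
        ) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.rescue_min_ag_fraction <= 1.0:
            raise ValueError("rescue_min_ag_fraction must lie in [0,1]")


@dataclass
class AlignedRead:
    """One placed read, stored in genome-forward orientation.

    ``blocks`` are half-open genomic intervals in read order whose total
    length equals the read length (multi-block only for spliced truth
    alignments).  ``mismatches`` lists (genomic position, ref base, read
    base) against the ORIGINAL genome — for rescued reads too, never
    against the pseudo-genome.
    """

    qname: str
    contig: str
    start: int
    seq: str
    blocks: tuple[tuple[int, int], ...]
    transcript_strand: str  # strand of the transcript the fragment came from
    mate: int  # 1 or 2
    rescued: bool = False
    orientation: str = "+"  # alignment orientation of the stored read
    mismatches: tuple[tuple[int, str, str], ...] = ()
    n_edit_consistent: int = 0

    def positions(self):
        for s, e in self.blocks:
            yield from range(s, e)

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class FastqRead:
    name: str
    seq: str
    mate: int


def read_fastq_pair(fastq1: str | Path, fastq2: str | Path) -> list[FastqRead]:
    out: list[FastqRead] = []
    for path, mate in ((fastq1, 1), (fastq2, 2)):
        with open_maybe_gzip(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                name = header[1:].split()[0]
                if name.endswith(("/1", "/2")):
                    name = name[:-2]
                out.append(FastqRead(name=name, seq=seq, mate=mate))
    return out


class KmerIndex:
    """Exact k-mer → positions index over a set of contigs."""

    def __init__(self, contigs: dict[str, str], k: int):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in contigs.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((name, i))
        self.contigs = contigs

    def candidates(self, seq: str) -> set[tuple[str, int]]:
        """Candidate (contig, start) placements from non-overlapping seeds."""
        k = self.k
        cands: set[tuple[str, int]] = set()
        offsets = list(range(0, max(len(seq) - k, 0) + 1, k))
        if offsets and offsets[-1] != len(seq) - k:
            offsets.append(len(seq) - k)
        for off in offsets:
            for contig, pos in self.index.get(seq[off : off + k], ()):
                start = pos - off
                if start >= 0 and start + len(seq) <= len(self.contigs[contig]):
                    cands.add((contig, start))
        return cands


def _count_mismatches(read: str, ref: str, limit: int) -> int | None:
    """Hamming distance, early-exit above ``limit`` (returns None)."""
    n = 0
    for a, b in zip(read, ref):
        if a != b:
            n += 1
            if n > limit:
                return None
    return n


def _mismatch_list(read: str, ref: str, start: int) -> tuple[tuple[int, str, str], ...]:
    return tuple(
        (start + i, r, q) for i, (q, r) in enumerate(zip(read, ref)) if q != r
    )


def _best_placements(
    seq: str, index: KmerIndex, max_mm: int
) -> tuple[list[tuple[str, int, int]], bool]:
    """All minimal-mismatch placements of ``seq``; second value marks ties
    at distinct loci."""
    best: list[tuple[str, int, int]] = []
    best_mm = max_mm + 1
    for contig, start in index.candidates(seq):
        ref = index.contigs[contig][start : start + len(seq)]
        mm = _count_mismatches(seq, ref, max_mm)
        if mm is None:
            continue
        if mm < best_mm:
            best = [(contig, start, mm)]
            best_mm = mm
        elif mm == best_mm:
            best.append((contig, start, mm))
    return best, len(best) > 1


@dataclass
class AlignmentResult:
    aligned: list[AlignedRead]
    unaligned: list[FastqRead]
    ambiguous: int = 0


def _transcript_strand(mate: int, orientation: str) -> str:
    # F2R1: read 2 carries the transcript-strand sequence
    if mate == 2:
        return orientation
    return "+" if orientation == "-" else "-"


def toy_align(
    reads: Sequence[FastqRead],
    genome: GenomeRef,
    params: AlignParams,
    index: KmerIndex | None = None,
) -> AlignmentResult:
    """Ungapped primary-pass alignment.

    A read maps iff a unique minimal-mismatch ungapped placement with at
    most ``max_mismatches`` exists (either orientation); equally good
    placements at different loci discard the read from both pools.
    """
    if index is None:
        index = KmerIndex(genome.contigs, params.seed_kmer)
    aligned: list[AlignedRead] = []
    unaligned: list[FastqRead] = []
    ambiguous = 0
    for read in reads:
        placements: list[tuple[str, int, int, str, str]] = []
        best_mm = params.max_mismatches + 1
        for orient, oseq in (("+", read.seq), ("-", revcomp(read.seq))):
            found, _ = _best_placements(oseq, index, params.max_mismatches)
            for contig, start, mm in found:
                placements.append((contig, start, mm, orient, oseq))
        if not placements:
            unaligned.append(read)
            continue
        best_mm = min(p[2] for p in placements)
        best = [p for p in placements if p[2] == best_mm]
        loci = {(p[0], p[1]) for p in best}
        if len(loci) > 1:
            ambiguous += 1
            continue
        contig, start, mm, orient, oseq = best[0]
        ref = genome.contigs[contig][start : start + len(oseq)]
        aligned.append(
            AlignedRead(
                qname=read.name,
                contig=contig,
                start=start,
                seq=oseq,
                blocks=((start, start + len(oseq)),),
                transcript_strand=_transcript_strand(read.mate, orient),
                mate=read.mate,
                orientation=orient,
                mismatches=_mismatch_list(oseq, ref, start),
            )
        )
    return AlignmentResult(aligned=aligned, unaligned=unaligned, ambiguous=ambiguous)


@dataclass
class RescueResult:
    rescued: list[AlignedRead]
    n_attempted: int = 0
    n_unrescued: int = 0


class PseudoGenomes:
    """A→G and T→C transformed references with their k-mer indexes.

    Two transforms are needed so both mates of a stranded F2R1 library are
    rescuable: edits on a plus-strand transcript read as A→G against the
    forward genome, edits on a minus-strand transcript read as T→C.
    """

    def __init__(self, genome: GenomeRef, k: int):
        self.genome = genome
        ag = {n: transform_a_to_g(s) for n, s in genome.contigs.items()}
        tc = {n: transform_t_to_c(s) for n, s in genome.contigs.items()}
        self.index_ag = KmerIndex(ag, k)
        self.index_tc = KmerIndex(tc, k)


def hyper_rescue(
    unaligned: Sequence[FastqRead],
    genome: GenomeRef,
    params: AlignParams,
    pseudo: PseudoGenomes | None = None,
) -> RescueResult:
    """Recover hyper-edited reads from the unaligned pool.

    Each read is transformed and aligned against the matching transformed
    reference in both orientations; a unique best placement is then verified
    against the original genome and accepted under the AlignParams rescue
    thresholds.  The transcript strand follows from which transform
    succeeded: A→G placements come from plus-strand transcripts, T→C from
    minus-strand ones.
    """
    if pseudo is None:
        pseudo = PseudoGenomes(genome, params.seed_kmer)
    rescued: list[AlignedRead] = []
    n_unrescued = 0
    for read in unaligned:
        fwd = read.seq
        rev = revcomp(read.seq)
        routes = (
            (transform_a_to_g(fwd), pseudo.index_ag, "+", "AG", fwd),
            (transform_a_to_g(rev), pseudo.index_ag, "-", "AG", rev),
            (transform_t_to_c(fwd), pseudo.index_tc, "+", "TC", fwd),
            (transform_t_to_c(rev), pseudo.index_tc, "-", "TC", rev),
        )
        placements: list[tuple[int, str, int, str, str, str]] = []
        for tseq, index, orient, route, oseq in routes:
            found, _ = _best_placements(tseq, index, params.max_mismatches)
            for contig, start, mm in found:
                placements.append((mm, contig, start, orient, route, oseq))
        if not placements:
            n_unrescued += 1
            continue
        best_mm = min(p[0] for p in placements)
        best = [p for p in placements if p[0] == best_mm]
        loci = {(p[1], p[2]) for p in best}
        if len(loci) > 1:
            n_unrescued += 1
            continue
        mm, contig, start, orient, route, oseq = best[0]
        ref = genome.contigs[contig][start : start + len(oseq)]
        mismatches = _mismatch_list(oseq, ref, start)
        if route == "AG":
            consistent = [m for m in mismatches if m[1] == "A" and m[2] == "G"]
            tstrand = "+"
        else:
            consistent = [m for m in mismatches if m[1] == "T" and m[2] == "C"]
            tstrand = "-"
        n_cons = len(consistent)
        n_other = len(mismatches) - n_cons
        frac = n_cons / len(mismatches) if mismatches else 0.0
        if (
            n_cons >= params.rescue_min_ag_sites
            and frac >= params.rescue_min_ag_fraction
            and n_other <= params.rescue_max_other_mismatches
        ):
            rescued.append(
                AlignedRead(
                    qname=read.name,
                    contig=contig,
                    start=start,
                    seq=oseq,
                    blocks=((start, start + len(oseq)),),
                    transcript_strand=tstrand,
                    mate=read.mate,
                    rescued=True,
                    orientation=orient,
                    mismatches=mismatches,
                    n_edit_consistent=n_cons,
                )
            )
        else:
            n_unrescued += 1
    return RescueResult(
        rescued=rescued, n_attempted=len(unaligned), n_unrescued=n_unrescued
    )


# ---------------------------------------------------------------------------
# SAM I/O (pysam)
# ---------------------------------------------------------------------------


def write_sam(
    reads: Iterable[AlignedRead], genome: GenomeRef, path: str | Path
) -> None:
    """Write placements as SAM.  Rescued reads carry ``XE`` (edit-consistent
    mismatch count) and ``XH:A:Y``; every read carries ``XS`` (transcript
    strand)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": genome.length(name)} for name in genome.names()
        ],
    }
    tid = {name: i for i, name in enumerate(genome.names())}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.qname
            a.query_sequence = r.seq
            a.reference_id = tid[r.contig]
            a.reference_start = r.start
            a.mapping_quality = 255
            cigar = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))  # N
                cigar.append((0, e - s))  # M
                prev_end = e
            a.cigartuples = cigar
            flag = 0x1 | 0x2
            flag |= 0x40 if r.mate == 1 else 0x80
            if r.orientation == "-":
                flag |= 0x10
            a.flag = flag
            a.set_tag("XS", r.transcript_strand)
            if r.rescued:
                a.set_tag("XE", r.n_edit_consistent)
                a.set_tag("XH", "Y")
            out.write(a)


def read_sam(
    path: str | Path, genome: GenomeRef, min_baseq: int = 20
) -> tuple[list[AlignedRead], list[FastqRead]]:
    """Ingest SAM/BAM into AlignedReads plus the unmapped pool.

    Transcript strand is taken from the XS tag when present, otherwise
    derived from the F2R1 flag convention.  Mismatches are recomputed
    against the supplied genome.  Bases below ``min_baseq`` (when qualities
    are present) are masked to N so the pileup ignores them.
    """
    import pysam

    aligned: list[AlignedRead] = []
    unmapped: list[FastqRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = 1 if rec.is_read1 or not rec.is_paired else 2
            if rec.is_unmapped:
                seq = rec.query_sequence or ""
                if rec.is_reverse:
                    seq = revcomp(seq)
                unmapped.append(FastqRead(name=rec.query_name, seq=seq, mate=mate))
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            quals = rec.query_qualities
            if quals is not None and min_baseq > 0:
                seq = "".join(
                    b if q >= min_baseq else "N" for b, q in zip(seq, quals)
                )
            blocks: list[tuple[int, int]] = []
            qpos = 0
            rpos = rec.reference_start
            kept_seq: list[str] = []
            for op, length in rec.cigartuples or ():
                if op == 0 or op == 7 or op == 8:  # M/=/X
                    blocks.append((rpos, rpos + length))
                    kept_seq.append(seq[qpos : qpos + length])
                    qpos += length
                    rpos += length
                elif op == 3:  # N
                    rpos += length
                elif op in (1, 4):  # I/S consume query
                    qpos += length
                elif op == 2:  # D consumes reference
                    rpos += length
            seq = "".join(kept_seq)
            contig = rec.reference_name
            if rec.reference_end is not None and rec.reference_end > genome.length(contig):
                raise ValueError(
                    f"read {rec.query_name} extends beyond contig {contig}"
                )
            orientation = "-" if rec.is_reverse else "+"
            if rec.has_tag("XS"):
                tstrand = rec.get_tag("XS")
            else:
                tstrand = _transcript_strand(mate, orientation)
            mismatches = []
            off = 0
            for s, e in blocks:
                ref = genome.fetch(contig, s, e)
                for i, (q, rb) in enumerate(zip(seq[off : off + e - s], ref)):
                    if q != rb and q != "N":
                        mismatches.append((s + i, rb, q))
                off += e - s
            aligned.append(
                AlignedRead(
                    qname=rec.query_name,
                    contig=contig,
                    start=rec.reference_start,
                    seq=seq,
                    blocks=tuple(blocks),
                    transcript_strand=tstrand,
                    mate=mate,
                    rescued=bool(rec.has_tag("XH")),
                    orientation=orientation,
                    mismatches=tuple(mismatches),
                    n_edit_consistent=int(rec.get_tag("XE")) if rec.has_tag("XE") else 0,
                )
            )
    return aligned, unmapped
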