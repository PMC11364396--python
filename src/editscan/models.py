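"""Genomic data containers: reference genome, gene models and repeat intervals.

Coordinates are 0-based half-open internally.  Emitted files use their
standard conventions (GTF/SAM 1-based inclusive, BED 0-based half-open).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.Seq import Seq
from pyfaidx import Fasta

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


class GenomeRef:
    """Named contig sequences held in memory.

    Desk-scale genomes are small (tens of kb), so sequences are plain
    uppercase strings; :meth:`from_fasta` goes through pyfaidx for
    arbitrary FASTA input.
    """

    def __init__(self, contigs: dict[str, str]):
        for name, seq in contigs.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name}: non-ACGTN symbols {sorted(bad)}")
        self.contigs = dict(contigs)

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def base_composition(self) -> dict[str, float]:
        """Genome-wide base frequencies over A/C/G/T (N excluded)."""
        counts = {b: 0 for b in "ACGT"}
        for seq in self.contigs.values():
            for b in "ACGT":
                counts[b] += seq.count(b)
        total = sum(counts.values())
        return {b: c / total for b, c in counts.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeRef":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene with 5'UTR / CDS / intron / 3'UTR structure.

    All intervals are genomic (plus-strand) 0-based half-open, sorted by
    start.  ``strand`` is the transcript strand; for minus-strand genes the
    5'UTR therefore sits at the genomic right end.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...]
    utr3: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    # ---- coordinate maps -------------------------------------------------

    def transcript_positions(self) -> np.ndarray:
        """Genomic position of each mature-transcript base, 5'→3'."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.exons])
        return pos[::-1] if self.strand == "-" else pos

    def premrna_positions(self) -> np.ndarray:
        """Genomic position of each pre-mRNA base, 5'→3'."""
        pos = np.arange(self.start, self.end)
        return pos[::-1] if self.strand == "-" else pos

    def transcript_sequence(self, genome: GenomeRef) -> str:
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def premrna_sequence(self, genome: GenomeRef) -> str:
        seq = genome.fetch(self.contig, self.start, self.end)
        return revcomp(seq) if self.strand == "-" else seq

    def coding_sequence(self, genome: GenomeRef) -> str:
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_positions(self) -> np.ndarray:
        """Genomic position of each coding base, in coding order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds])
        return pos[::-1] if self.strand == "-" else pos

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class RepeatInterval:
    contig: str
    start: int
    end: int
    repeat_class: str  # SINE / LINE / LTR / Simple_repeat ...

    def __len__(self) -> int:
        return self.end - self.start


class RepeatTrack:
    """Repeat-class intervals, BED6-backed (name column = repeat class)."""

    def __init__(self, intervals: Iterable[RepeatInterval]):
        self.intervals = sorted(intervals, key=lambda r: (r.contig, r.start, r.end))

    def __iter__(self) -> Iterator[RepeatInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, contig: str, pos: int) -> list[RepeatInterval]:
        return [r for r in self.intervals if r.contig == contig and r.start <= pos < r.end]

    @classmethod
    def from_bed(cls, path: str | Path) -> "RepeatTrack":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                ivs.append(RepeatInterval(f[0], int(f[1]), int(f[2]), f[3]))
        return cls(ivs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.intervals:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.repeat_class}\t0\t+\n")


# ---- GTF I/O -------------------------------------------------------------


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write single-transcript gene models as GTF (1-based inclusive)."""

    def row(gene, feature, s, e):
        attrs = (
            f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
        )
        return (
            f"{gene.contig}\teditscan\t{feature}\t{s + 1}\t{e}\t.\t"
            f"{gene.strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        for g in genes:
            fh.write(row(g, "gene", g.start, g.end))
            fh.write(row(g, "transcript", g.start, g.end))
            for s, e in g.exons:
                fh.write(row(g, "exon", s, e))
            for s, e in g.cds:
                fh.write(row(g, "CDS", s, e))
            for s, e in g.utr5:
                fh.write(row(g, "five_prime_utr", s, e))
            for s, e in g.utr3:
                fh.write(row(g, "three_prime_utr", s, e))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GTF via gffutils (multi-isoform GTFs are
    collapsed to the transcript with the longest CDS per gene)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        best = None
        for t in db.children(g, featuretype="transcript"):
            cds = [(c.start - 1, c.end) for c in db.children(t, featuretype="CDS")]
            cds_len = sum(e - s for s, e in cds)
            if best is None or cds_len > best[0]:
                best = (cds_len, t)
        if best is None:
            continue
        t = best[1]

        def ivs(ftype):
            return tuple(
                sorted((f.start - 1, f.end) for f in db.children(t, featuretype=ftype))
            )

        genes.append(
            GeneModel(
                gene_id=g.id,
                contig=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=ivs("exon"),
                cds=ivs("CDS"),
                utr5=ivs("five_prime_utr"),
                utr3=ivs("three_prime_utr"),
            )
        )
    return genes


def open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
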