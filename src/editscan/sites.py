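"""Strand-aware per-site base counting and high-confidence edit filtering.

Counts are accumulated in transcript-strand orientation: a minus-strand
transcript's edits, which read as T→C mismatches on the genomic plus
strand, are counted as A→G events on the minus strand (the browser-track
convention for genes encoded on the minus strand).  The editing rate at a
site is the fraction of edited (G) reads over informative (A+G) reads on
the event strand; bases other than A/G — sequencing errors and N-masked
bases — are excluded from the denominator and reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignedRead
from .models import GenomeRef

BASE2IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
IDX_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N
BASE_ORDER = "ACGTN"


class MalformedAlignmentError(ValueError):
    pass


class SampleCounts:
    """Per-sample, per-position, per-strand base counts.

    Dense arrays per (contig, strand): shape (contig length, 5) in
    event-strand base space, plus a parallel array of G counts contributed
    by rescued (hyper-editing) reads.
    """

    def __init__(self, sample_id: str, genome: GenomeRef):
        self.sample_id = sample_id
        self.genome = genome
        self.counts: dict[tuple[str, str], np.ndarray] = {}
        self.hyper_g: dict[tuple[str, str], np.ndarray] = {}
        for name in genome.names():
            L = genome.length(name)
            for strand in "+-":
                self.counts[(name, strand)] = np.zeros((L, 5), dtype=np.int32)
                self.hyper_g[(name, strand)] = np.zeros(L, dtype=np.int32)

    def depth(self, contig: str, strand: str, pos: int) -> int:
        return int(self.counts[(contig, strand)][pos].sum())


def pileup(
    reads: Sequence[AlignedRead], genome: GenomeRef, sample_id: str = "sample"
) -> SampleCounts:
    """Accumulate base counts in transcript-strand orientation.

    Overlapping mate bases are counted once per fragment; where the mates
    disagree at an overlapping position the base is dropped (counted as
    neither).  Reads extending beyond their contig raise
    :class:`MalformedAlignmentError`.
    """
    counts = SampleCounts(sample_id, genome)
    by_fragment: dict[tuple[str, str, str], list[AlignedRead]] = {}
    for r in reads:
        if r.end > genome.length(r.contig) or r.start < 0:
            raise MalformedAlignmentError(
                f"read {r.qname} spans [{r.start},{r.end}) on contig "
                f"{r.contig} of length {genome.length(r.contig)}"
            )
        by_fragment.setdefault((r.qname, r.contig, r.transcript_strand), []).append(r)

    for (qname, contig, strand), frag_reads in by_fragment.items():
        # fragment-level consensus: one base per covered genomic position
        bases: dict[int, str] = {}
        dropped: set[int] = set()
        hyper_read = any(r.rescued for r in frag_reads)
        for r in frag_reads:
            off = 0
            for s, e in r.blocks:
                for i in range(e - s):
                    p = s + i
                    b = r.seq[off + i]
                    if p in dropped:
                        continue
                    prev = bases.get(p)
                    if prev is None:
                        bases[p] = b
                    elif prev != b:
                        del bases[p]
                        dropped.add(p)
                off += e - s
        arr = counts.counts[(contig, strand)]
        hyp = counts.hyper_g[(contig, strand)]
        if strand == "+":
            for p, b in bases.items():
                bi = BASE2IDX[b]
                arr[p, bi] += 1
                if hyper_read and bi == 2:
                    hyp[p] += 1
        else:
            for p, b in bases.items():
                bi = int(IDX_COMPLEMENT[BASE2IDX[b]])
                arr[p, bi] += 1
                if hyper_read and bi == 2:
                    hyp[p] += 1
    return counts


@dataclass(frozen=True)
class EditSite:
    """One candidate A-to-I site in one sample (1-based position in
    outputs; stored 0-based here)."""

    contig: str
    pos: int
    strand: str
    sample_id: str
    edited: int  # G reads on the event strand
    unedited: int  # A reads on the event strand
    other: int  # C/T/N reads (errors), excluded from the ratio
    depth: int
    hyper: bool

    @property
    def edit_ratio(self) -> float:
        return self.edited / (self.edited + self.unedited)


def call_candidate_sites(
    counts: SampleCounts, genome: GenomeRef
) -> list[EditSite]:
    """Emit every position whose event-strand reference base is A with at
    least one edited (G) read."""
    sites: list[EditSite] = []
    for (contig, strand), arr in counts.counts.items():
        seq = genome[contig]
        ref_base = "A" if strand == "+" else "T"  # plus-strand base at A sites
        g = arr[:, 2]
        positions = np.flatnonzero(g > 0)
        hyp = counts.hyper_g[(contig, strand)]
        for p in positions:
            if seq[p] != ref_base:
                continue
            a = int(arr[p, 0])
            gg = int(arr[p, 2])
            total = int(arr[p].sum())
            sites.append(
                EditSite(
                    contig=contig,
                    pos=int(p),
                    strand=strand,
                    sample_id=counts.sample_id,
                    edited=gg,
                    unedited=a,
                    other=total - a - gg,
                    depth=total,
                    hyper=bool(hyp[p] > 0),
                )
            )
    sites.sort(key=lambda s: (s.contig, s.pos, s.strand))
    return sites


def sites_to_frame(site_lists: Iterable[Sequence[EditSite]]) -> pd.DataFrame:
    """Stack per-sample site lists into one cohort table (1-based pos)."""
    rows = []
    for sites in site_lists:
        for s in sites:
            rows.append(
                {
                    "contig": s.contig,
                    "pos": s.pos + 1,
                    "strand": s.strand,
                    "sample_id": s.sample_id,
                    "edited": s.edited,
                    "unedited": s.unedited,
                    "other": s.other,
                    "depth": s.depth,
                    "edit_ratio": s.edit_ratio,
                    "hyper": s.hyper,
                }
            )
    cols = [
        "contig", "pos", "strand", "sample_id", "edited", "unedited",
        "other", "depth", "edit_ratio", "hyper",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class FilterConfig:
    """High-confidence cohort filter: a site is kept iff at least
    ``min_samples`` samples individually show edited reads strictly greater
    than ``min_edited_reads`` and an editing rate strictly between
    ``ratio_low`` and ``ratio_high``.  The strict bounds drop low-editing
    loci (lower bound) and likely genomic variants (upper bound)."""

    min_samples: int = 3
    min_edited_reads: int = 5  # strict: edited > 5, i.e. >= 6
    ratio_low: float = 0.1  # strict
    ratio_high: float = 0.9  # strict

    def __post_init__(self):
        if not 0.0 <= self.ratio_low < self.ratio_high <= 1.0:
            raise ValueError("need 0 <= ratio_low < ratio_high <= 1")


SITE_KEY = ["contig", "pos", "strand"]


def filter_high_confidence(
    cohort: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Apply the cohort-level high-confidence rule.

    Returns the rows of ``cohort`` (all samples) at kept sites.  Cohorts
    with fewer samples than ``min_samples`` cannot satisfy the rule; a
    warning is emitted and the result is empty.
    """
    n_samples = cohort["sample_id"].nunique()
    if n_samples < config.min_samples:
        warnings.warn(
            f"cohort has {n_samples} samples, fewer than the required "
            f"{config.min_samples}; no site can pass",
            stacklevel=2,
        )
        return cohort.iloc[0:0]
    qualifies = (
        (cohort["edited"] > config.min_edited_reads)
        & (cohort["edit_ratio"] > config.ratio_low)
        & (cohort["edit_ratio"] < config.ratio_high)
    )
    n_qual = qualifies.groupby([cohort[k] for k in SITE_KEY]).sum()
    kept = n_qual[n_qual >= config.min_samples].index
    idx = pd.MultiIndex.from_frame(cohort[SITE_KEY])
    return cohort[idx.isin(kept)].copy()


def write_cohort_vcf(
    cohort: pd.DataFrame, genome: GenomeRef, path: str | Path
) -> None:
    """VCF-like cohort file: REF=A, ALT=G on the event strand, per-sample
    edited/unedited counts in genotype-style columns."""
    samples = sorted(cohort["sample_id"].unique())
    wide = cohort.set_index(SITE_KEY + ["sample_id"])
    keys = sorted(
        {tuple(k) for k in cohort[SITE_KEY].itertuples(index=False)},
        key=lambda k: (k[0], k[1], k[2]),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Event strand">\n')
        fh.write('##FORMAT=<ID=ED,Number=2,Type=Integer,Description="Edited,unedited reads">\n')
        for name in genome.names():
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for contig, pos, strand in keys:
            cells = []
            for s in samples:
                try:
                    row = wide.loc[(contig, pos, strand, s)]
                    cells.append(f"{int(row['edited'])},{int(row['unedited'])}")
                except KeyError:
                    cells.append(".")
            fh.write(
                f"{contig}\t{pos}\t.\tA\tG\t.\tPASS\tSTRAND={strand}\tED\t"
                + "\t".join(cells)
                + "\n"
            )
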