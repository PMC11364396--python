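"""Sequence context around edit sites.

Three analyses: (1) positional motif enrichment in a ±50 nt window around
edited adenosines — ADAR prefers a G immediately 3' of the edited A (the
5'AG3' signal), detected here with exact binomial tests per position and
base against the background composition; (2) downstream A-rich "satellite"
detection for hyper-edited sites — ADAR edits recursively at ~30 nt
intervals, so hyper sites tend to have an A-rich window 20–40 nt
downstream; (3) an exact inverted-repeat (stem-loop) scanner, since long
intramolecular complementary repeats are the dsRNA substrate ADAR acts on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, GenomeRef, revcomp

BASE_ORDER = "ACGT"


class InsufficientDataError(ValueError):
    pass


def _event_strand_window(
    genome: GenomeRef, contig: str, pos: int, strand: str, halfwidth: int
) -> str | None:
    """Sequence around a site in event-strand orientation, position 0 the
    edited A; None when clipped by a contig edge."""
    lo, hi = pos - halfwidth, pos + halfwidth + 1
    if lo < 0 or hi > genome.length(contig):
        return None
    seq = genome.fetch(contig, lo, hi)
    return revcomp(seq) if strand == "-" else seq


@dataclass
class MotifProfile:
    """Per-position base frequencies and enrichment p values.

    ``frequencies``: DataFrame indexed by offset (-halfwidth..+halfwidth)
    with one column per base, rows summing to 1 over A/C/G/T.
    ``pvalues``: same shape, one-sided exact binomial P(X >= observed)
    against the background frequency of that base.
    """

    halfwidth: int
    n_sites: int
    background: dict[str, float]
    frequencies: pd.DataFrame
    pvalues: pd.DataFrame

    def top_enrichment(self, exclude_center: bool = True) -> tuple[int, str, float]:
        """(offset, base, p) of the most significant positional enrichment."""
        pv = self.pvalues.copy()
        if exclude_center:
            pv.loc[0] = 1.0
        offset = pv.min(axis=1).idxmin()
        base = pv.loc[offset].idxmin()
        return int(offset), str(base), float(pv.loc[offset, base])

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequencies.add_prefix("freq_")
        pv = self.pvalues.add_prefix("p_")
        out = freq.join(pv)
        out.index.name = "offset"
        return out.reset_index()


def motif_profile(
    sites: pd.DataFrame,
    genome: GenomeRef,
    halfwidth: int = 50,
    background: dict[str, float] | str = "genome",
) -> MotifProfile:
    """Positional base composition around edit sites (event strand).

    ``sites`` needs contig / pos (1-based) / strand columns.  Windows
    clipped at contig edges are dropped; fewer than 10 usable windows is an
    error.  ``background`` is the genome-wide composition by default, a
    base->frequency mapping, or "uniform".
    """
    windows = []
    for _, r in sites.drop_duplicates(["contig", "pos", "strand"]).iterrows():
        w = _event_strand_window(
            genome, r["contig"], int(r["pos"]) - 1, r["strand"], halfwidth
        )
        if w is not None:
            windows.append(w)
    n = len(windows)
    if n < 10:
        raise InsufficientDataError(f"only {n} usable windows (need >= 10)")
    if background == "genome":
        bg = genome.base_composition()
    elif background == "uniform":
        bg = {b: 0.25 for b in BASE_ORDER}
    else:
        bg = dict(background)

    offsets = np.arange(-halfwidth, halfwidth + 1)
    counts = np.zeros((len(offsets), 4), dtype=int)
    b2i = {b: i for i, b in enumerate(BASE_ORDER)}
    informative = np.zeros(len(offsets), dtype=int)
    for w in windows:
        for j, b in enumerate(w):
            i = b2i.get(b)
            if i is not None:
                counts[j, i] += 1
                informative[j] += 1
    with np.errstate(invalid="ignore"):
        freqs = counts / informative[:, None]
    pvals = np.ones_like(freqs)
    for j in range(len(offsets)):
        nj = int(informative[j])
        if nj == 0:
            continue
        for i, b in enumerate(BASE_ORDER):
            pvals[j, i] = stats.binomtest(
                int(counts[j, i]), nj, bg[b], alternative="greater"
            ).pvalue
    freq_df = pd.DataFrame(freqs, index=offsets, columns=list(BASE_ORDER))
    p_df = pd.DataFrame(pvals, index=offsets, columns=list(BASE_ORDER))
    return MotifProfile(
        halfwidth=halfwidth,
        n_sites=n,
        background=bg,
        frequencies=freq_df,
        pvalues=p_df,
    )


# ---------------------------------------------------------------------------
# downstream A-rich satellites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SatelliteCall:
    contig: str
    pos: int  # 0-based
    strand: str
    flagged: bool
    best_offset: int | None
    best_a_fraction: float


def a_rich_satellite(
    sites: pd.DataFrame,
    genome: GenomeRef,
    offset_range: tuple[int, int] = (20, 40),
    window: int = 10,
    a_fraction: float = 0.7,
) -> tuple[list[SatelliteCall], int]:
    """Scan downstream of hyper-edited sites for A-rich satellite windows.

    A site is flagged when some ``window``-wide stretch starting at an
    offset within ``offset_range`` downstream (event strand) has an A
    fraction of at least ``a_fraction``; the offset with the highest A
    fraction is reported.  Returns (calls, n_skipped) where skipped sites
    sat too close to a contig end.
    """
    if not len(sites):
        raise ValueError("empty hyper-edited site list")
    calls: list[SatelliteCall] = []
    skipped = 0
    lo, hi = offset_range
    for _, r in sites.drop_duplicates(["contig", "pos", "strand"]).iterrows():
        contig, pos, strand = r["contig"], int(r["pos"]) - 1, r["strand"]
        L = genome.length(contig)
        need = hi + window
        if strand == "+":
            if pos + 1 + need > L:
                skipped += 1
                continue
            down = genome.fetch(contig, pos + 1, pos + 1 + need)
        else:
            if pos - need < 0:
                skipped += 1
                continue
            down = revcomp(genome.fetch(contig, pos - need, pos))
        best_off, best_frac = None, -1.0
        for off in range(lo, hi + 1):
            frac = down[off : off + window].count("A") / window
            if frac > best_frac:
                best_off, best_frac = off, frac
        calls.append(
            SatelliteCall(
                contig=contig,
                pos=pos,
                strand=strand,
                flagged=best_frac >= a_fraction,
                best_offset=best_off,
                best_a_fraction=best_frac,
            )
        )
    return calls, skipped


def satellites_to_frame(calls: Sequence[SatelliteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.contig,
                "pos": c.pos + 1,
                "strand": c.strand,
                "flagged": c.flagged,
                "best_offset": c.best_offset,
                "best_a_fraction": c.best_a_fraction,
            }
            for c in calls
        ],
        columns=["contig", "pos", "strand", "flagged", "best_offset", "best_a_fraction"],
    )


# ---------------------------------------------------------------------------
# inverted repeats (stem-loops)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InvertedRepeat:
    """Arm intervals are half-open on the scanned sequence; arm2 equals the
    reverse complement of arm1 and the loop separates them."""

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    contig: str = ""
    gene_id: str | None = None

    @property
    def arm_length(self) -> int:
        return self.arm1[1] - self.arm1[0]

    @property
    def loop_length(self) -> int:
        return self.arm2[0] - self.arm1[1]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def find_inverted_repeats(
    seq: str,
    min_arm: int = 30,
    max_loop: int = 10_000,
    max_mismatch: int = 0,
) -> list[InvertedRepeat]:
    """All maximal inverted repeats with arm >= ``min_arm`` and loop <=
    ``max_loop``.

    A hit pairs arm1=[s1,e1) with arm2=[s2,e2) where arm2 is the reverse
    complement of arm1 (up to ``max_mismatch`` tolerated mispairs when a
    budget is given).  Hits are maximal — extendable neither inward nor
    outward — and non-redundant: hits whose arms are both contained in
    another hit's arms are removed.  Seeding uses exact ``min_arm``-mers at
    the inner arm boundary, so with ``max_mismatch`` > 0 arms whose inner
    ``min_arm`` bases already mispair can be missed (documented
    approximation; the default budget is 0 = exact complementarity).
    """
    if min_arm < 8:
        raise ValueError("min_arm must be at least 8")
    n = len(seq)
    k = min_arm
    if n < 2 * k:
        return []
    pos_by_kmer: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        pos_by_kmer.setdefault(seq[i : i + k], []).append(i)

    hits: set[tuple[int, int, int]] = set()  # (e1, s2, L)
    for i in range(n - k + 1):
        rc = revcomp(seq[i : i + k])
        if "N" in rc:
            continue
        e1 = i + k
        for s2 in pos_by_kmer.get(rc, ()):
            if s2 < e1:
                continue
            # inner maximality: the pair (e1, s2) must not extend inward
            if s2 - e1 >= 2 and seq[e1] == _COMP[seq[s2 - 1]]:
                continue
            # outward extension with mismatch budget
            L = 0
            budget = max_mismatch
            u = 0
            last_good = 0
            while e1 - 1 - u >= 0 and s2 + u < n:
                if seq[e1 - 1 - u] == _COMP[seq[s2 + u]]:
                    u += 1
                    last_good = u
                elif budget > 0:
                    budget -= 1
                    u += 1
                else:
                    break
            L = last_good
            if L < min_arm:
                continue
            if s2 - e1 > max_loop:
                continue
            hits.add((e1, s2, L))

    irs = [
        InvertedRepeat(arm1=(e1 - L, e1), arm2=(s2, s2 + L))
        for e1, s2, L in hits
    ]
    return _remove_contained(irs)


def _remove_contained(irs: list[InvertedRepeat]) -> list[InvertedRepeat]:
    irs = sorted(set(irs), key=lambda r: (r.arm1, r.arm2))
    kept: list[InvertedRepeat] = []
    for r in irs:
        contained = False
        for other in irs:
            if other is r or other == r:
                continue
            if (
                other.arm1[0] <= r.arm1[0]
                and r.arm1[1] <= other.arm1[1]
                and other.arm2[0] <= r.arm2[0]
                and r.arm2[1] <= other.arm2[1]
                and (other.arm_length > r.arm_length)
            ):
                contained = True
                break
        if not contained:
            kept.append(r)
    return kept


def inverted_repeats_by_gene(
    genome: GenomeRef,
    genes: Sequence[GeneModel],
    min_arm: int = 30,
    max_loop: int = 10_000,
    max_mismatch: int = 0,
    intronic_only: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Scan gene bodies for inverted repeats; returns (table, number of
    genes with at least one intronic hit) — the per-gene presence tally
    behind 'N genes at a given arm-length cutoff' summaries."""
    rows = []
    genes_with_ir: set[str] = set()
    for gene in genes:
        seq = genome.fetch(gene.contig, gene.start, gene.end)
        for ir in find_inverted_repeats(seq, min_arm, max_loop, max_mismatch):
            a1 = (ir.arm1[0] + gene.start, ir.arm1[1] + gene.start)
            a2 = (ir.arm2[0] + gene.start, ir.arm2[1] + gene.start)
            intronic = any(
                s <= a1[0] and a1[1] <= e for s, e in gene.introns
            ) and any(s <= a2[0] and a2[1] <= e for s, e in gene.introns)
            if intronic or not intronic_only:
                genes_with_ir.add(gene.gene_id)
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "contig": gene.contig,
                    "arm1_start": a1[0],
                    "arm1_end": a1[1],
                    "arm2_start": a2[0],
                    "arm2_end": a2[1],
                    "arm_length": ir.arm_length,
                    "loop_length": ir.loop_length,
                    "intronic": intronic,
                }
            )
    cols = [
        "gene_id", "contig", "arm1_start", "arm1_end", "arm2_start",
        "arm2_end", "arm_length", "loop_length", "intronic",
    ]
    return pd.DataFrame(rows, columns=cols), len(genes_with_ir)


def inverted_repeats_to_bedpe(df: pd.DataFrame, path) -> None:
    """BEDPE-style arm-pair output (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(
                f"{r['contig']}\t{r['arm1_start']}\t{r['arm1_end']}\t"
                f"{r['contig']}\t{r['arm2_start']}\t{r['arm2_end']}\t"
                f"{r['gene_id']}\t{r['arm_length']}\n"
            )
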