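"""Genomic annotation of edit sites.

Each site is assigned one region label (5'UTR/CDS/intron/3'UTR inside a
same-strand gene, otherwise proximal or distal intergenic relative to a
±10 kb flank around transcription start/end sites), a repeat class from a
BED track, a coding consequence when it falls in a CDS, and a splice-site
proximity label (donor / acceptor / branch-point window / none).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .models import GeneModel, GenomeRef, RepeatTrack, revcomp

REGIONS = ("5'UTR", "CDS", "intron", "3'UTR", "proximal_intergenic", "distal_intergenic")
# when isoforms/features overlap, coding and UTR labels win over intron
REGION_PRECEDENCE = ("CDS", "3'UTR", "5'UTR", "intron")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class RegionAssignment:
    contig: str
    pos: int
    strand: str
    region: str
    gene_id: str | None
    repeat_class: str | None = None


def _feature_label(gene: GeneModel, pos: int) -> str | None:
    if not gene.contains(pos):
        return None
    for label, ivs in (
        ("CDS", gene.cds),
        ("3'UTR", gene.utr3),
        ("5'UTR", gene.utr5),
        ("intron", gene.introns),
    ):
        for s, e in ivs:
            if s <= pos < e:
                return label
    return "intron"  # inside the gene but in no annotated feature


def assign_region(
    contig: str,
    pos: int,
    strand: str,
    genes: Sequence[GeneModel],
    flank: int = 10_000,
) -> RegionAssignment:
    """Assign the finest containing feature of a same-strand gene, else an
    intergenic label from the ±``flank`` rule around gene ends."""
    best: tuple[int, str, str] | None = None  # (precedence rank, label, gene)
    for gene in genes:
        if gene.contig != contig or gene.strand != strand:
            continue
        label = _feature_label(gene, pos)
        if label is None:
            continue
        rank = REGION_PRECEDENCE.index(label)
        if best is None or rank < best[0]:
            best = (rank, label, gene.gene_id)
    if best is not None:
        return RegionAssignment(contig, pos, strand, best[1], best[2])
    # outside all same-strand genes: distance to any gene's TSS/TES
    for gene in genes:
        if gene.contig != contig:
            continue
        if gene.start - flank <= pos < gene.end + flank:
            return RegionAssignment(contig, pos, strand, "proximal_intergenic", None)
    return RegionAssignment(contig, pos, strand, "distal_intergenic", None)


def region_lengths(genes: Sequence[GeneModel]) -> dict[str, int]:
    """Total annotated bases per genic region class (union not taken:
    desk-scale gene models do not overlap)."""
    out = {"5'UTR": 0, "CDS": 0, "intron": 0, "3'UTR": 0}
    for g in genes:
        out["5'UTR"] += sum(e - s for s, e in g.utr5)
        out["CDS"] += sum(e - s for s, e in g.cds)
        out["intron"] += sum(e - s for s, e in g.introns)
        out["3'UTR"] += sum(e - s for s, e in g.utr3)
    return out


def region_density(
    assignments: Sequence[RegionAssignment], lengths: dict[str, int]
) -> pd.DataFrame:
    """Sites per base of each region class (the length-normalised
    distribution); zero-length classes are omitted with a warning."""
    import warnings

    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.region] = counts.get(a.region, 0) + 1
    rows = []
    for region, length in lengths.items():
        if length <= 0:
            warnings.warn(f"region {region} has zero length; omitted", stacklevel=2)
            continue
        rows.append(
            {
                "region": region,
                "n_sites": counts.get(region, 0),
                "length": length,
                "density": counts.get(region, 0) / length,
            }
        )
    return pd.DataFrame(rows, columns=["region", "n_sites", "length", "density"])


def assign_repeat(contig: str, pos: int, repeats: RepeatTrack) -> str | None:
    """Repeat class of the covering interval; overlaps resolved by the
    smallest interval, ties by alphabetical class."""
    hits = repeats.overlapping(contig, pos)
    if not hits:
        return None
    hits.sort(key=lambda r: (len(r), r.repeat_class))
    return hits[0].repeat_class


# ---------------------------------------------------------------------------
# coding consequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsequenceCall:
    gene_id: str
    codon_index: int  # 0-based codon number within the CDS
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    consequence: str  # synonymous / nonsynonymous / stop_gain / stop_loss


def consequence(
    contig: str, pos: int, gene: GeneModel, genome: GenomeRef
) -> ConsequenceCall:
    """Recode the edited codon: the site's A (coding strand) becomes G.

    The codon is rebuilt from the annotated CDS in coding order; the
    standard genetic code is used for translation.
    """
    if gene.cds_length() % 3:
        raise AnnotationError(
            f"{gene.gene_id}: CDS length {gene.cds_length()} not divisible by 3"
        )
    cds_pos = gene.cds_positions()
    hits = [i for i, p in enumerate(cds_pos) if p == pos]
    if not hits:
        raise AnnotationError(f"position {contig}:{pos + 1} not in CDS of {gene.gene_id}")
    ci = hits[0]
    coding = gene.coding_sequence(genome)
    if coding[ci] != "A":
        raise AnnotationError(
            f"{gene.gene_id} coding base at CDS offset {ci} is {coding[ci]}, not A"
        )
    codon_index = ci // 3
    within = ci % 3
    before = coding[codon_index * 3 : codon_index * 3 + 3]
    after = before[:within] + "G" + before[within + 1 :]
    aa_before = str(Seq(before).translate())
    aa_after = str(Seq(after).translate())
    if aa_before == aa_after:
        cls = "synonymous"
    elif aa_after == "*":
        cls = "stop_gain"
    elif aa_before == "*":
        cls = "stop_loss"
    else:
        cls = "nonsynonymous"
    return ConsequenceCall(
        gene_id=gene.gene_id,
        codon_index=codon_index,
        codon_before=before,
        codon_after=after,
        aa_before=aa_before,
        aa_after=aa_after,
        consequence=cls,
    )


# ---------------------------------------------------------------------------
# splice-site proximity
# ---------------------------------------------------------------------------


def splice_proximity(
    pos: int, gene: GeneModel, branch_window: tuple[int, int] = (18, 44)
) -> str:
    """Label a site relative to splice elements of its gene's introns.

    donor = first 2 intronic nt (5' splice site), acceptor = last 2
    intronic nt (3' splice site), branch window = ``branch_window`` nt
    upstream of the 3' splice site on the transcript strand — the region
    holding the branch-point adenosine.  Everything else is 'none'.
    """
    lo, hi = branch_window
    for s, e in gene.introns:
        if not s <= pos < e:
            continue
        if gene.strand == "+":
            donor = (s, s + 2)
            acceptor = (e - 2, e)
            dist_to_3ss = e - 1 - pos  # 0 at the last intronic base
        else:
            donor = (e - 2, e)
            acceptor = (s, s + 2)
            dist_to_3ss = pos - s
        if donor[0] <= pos < donor[1]:
            return "donor"
        if acceptor[0] <= pos < acceptor[1]:
            return "acceptor"
        if lo <= dist_to_3ss <= hi:
            return "branch_window"
        return "none"
    return "none"


# ---------------------------------------------------------------------------
# table-level annotation
# ---------------------------------------------------------------------------


def annotate_sites(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    repeats: RepeatTrack,
    genome: GenomeRef,
    flank: int = 10_000,
    branch_window: tuple[int, int] = (18, 44),
) -> pd.DataFrame:
    """Annotate a site table (1-based ``pos``) with region, gene, repeat
    class, splice proximity and — for CDS sites — the codon consequence."""
    genes_by_id = {g.gene_id: g for g in genes}
    rows = []
    for _, r in sites.drop_duplicates(["contig", "pos", "strand"]).iterrows():
        contig, pos1, strand = r["contig"], int(r["pos"]), r["strand"]
        pos = pos1 - 1
        asn = assign_region(contig, pos, strand, genes, flank=flank)
        rep = assign_repeat(contig, pos, repeats)
        splice = "none"
        cons: ConsequenceCall | None = None
        if asn.gene_id is not None:
            gene = genes_by_id[asn.gene_id]
            splice = splice_proximity(pos, gene, branch_window)
            if asn.region == "CDS":
                cons = consequence(contig, pos, gene, genome)
        rows.append(
            {
                "contig": contig,
                "pos": pos1,
                "strand": strand,
                "region": asn.region,
                "gene_id": asn.gene_id,
                "repeat_class": rep,
                "splice_proximity": splice,
                "codon_before": cons.codon_before if cons else None,
                "codon_after": cons.codon_after if cons else None,
                "aa_before": cons.aa_before if cons else None,
                "aa_after": cons.aa_after if cons else None,
                "consequence": cons.consequence if cons else None,
            }
        )
    cols = [
        "contig", "pos", "strand", "region", "gene_id", "repeat_class",
        "splice_proximity", "codon_before", "codon_after", "aa_before",
        "aa_after", "consequence",
    ]
    return pd.DataFrame(rows, columns=cols)
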