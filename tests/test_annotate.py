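"""Region assignment, repeat classes, coding consequences and splice-site
proximity."""

import pytest

from editscan import (
    GeneModel,
    GenomeRef,
    RepeatInterval,
    RepeatTrack,
    assign_region,
    assign_repeat,
    consequence,
    region_density,
    splice_proximity,
)
from editscan.annotate import AnnotationError, RegionAssignment, annotate_sites
from editscan.annotate import region_lengths
from editscan.models import revcomp


def _plus_gene(offset=1000):
    """5'UTR[1000,1060) CDS[1060,1150) intron[1150,1450) CDS[1450,1540)
    3'UTR[1540,1940) on the plus strand."""
    return GeneModel(
        gene_id="gp",
        contig="c",
        strand="+",
        start=offset,
        end=offset + 940,
        exons=((offset, offset + 150), (offset + 450, offset + 940)),
        cds=((offset + 60, offset + 150), (offset + 450, offset + 540)),
        utr5=((offset, offset + 60),),
        utr3=((offset + 540, offset + 940),),
    )


class TestRegions:
    def test_site_inside_annotated_utr3(self):
        g = _plus_gene()
        asn = assign_region("c", 1600, "+", [g])
        assert asn.region == "3'UTR" and asn.gene_id == "gp"

    def test_intronic_site(self):
        asn = assign_region("c", 1200, "+", [_plus_gene()])
        assert asn.region == "intron"

    def test_site_5kb_past_tes_is_proximal_intergenic(self):
        asn = assign_region("c", 1940 + 5000, "+", [_plus_gene()])
        assert asn.region == "proximal_intergenic" and asn.gene_id is None

    def test_site_50kb_away_is_distal_intergenic(self):
        asn = assign_region("c", 1940 + 50_000, "+", [_plus_gene()])
        assert asn.region == "distal_intergenic"

    def test_opposite_strand_gene_does_not_claim_the_site(self):
        # gene on +, query on -: genic features don't apply, flank does
        asn = assign_region("c", 1600, "-", [_plus_gene()])
        assert asn.region == "proximal_intergenic"


class TestDensity:
    def test_densities_and_ranking(self):
        assignments = [
            RegionAssignment("c", p, "+", "CDS", "g") for p in (1, 2)
        ] + [RegionAssignment("c", p, "+", "3'UTR", "g") for p in (3, 4, 5)]
        out = region_density(assignments, {"CDS": 1000, "3'UTR": 500})
        cds = out[out["region"] == "CDS"]["density"].iloc[0]
        utr = out[out["region"] == "3'UTR"]["density"].iloc[0]
        assert cds == pytest.approx(0.002) and utr == pytest.approx(0.006)
        assert out.sort_values("density", ascending=False)["region"].iloc[0] == "3'UTR"

    def test_doubling_lengths_halves_densities(self):
        assignments = [RegionAssignment("c", 1, "+", "CDS", "g")]
        d1 = region_density(assignments, {"CDS": 100})["density"].iloc[0]
        d2 = region_density(assignments, {"CDS": 200})["density"].iloc[0]
        assert d2 == pytest.approx(d1 / 2)

    def test_zero_length_class_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="zero length"):
            out = region_density([], {"CDS": 0, "intron": 10})
        assert out["region"].tolist() == ["intron"]

    def test_region_lengths_match_gene_structure(self):
        lengths = region_lengths([_plus_gene()])
        assert lengths == {"5'UTR": 60, "CDS": 180, "intron": 300, "3'UTR": 400}


class TestRepeats:
    track = RepeatTrack(
        [
            RepeatInterval("c", 100, 300, "SINE"),
            RepeatInterval("c", 150, 200, "Simple_repeat"),
            RepeatInterval("c", 500, 600, "LINE"),
        ]
    )

    def test_site_inside_sine(self):
        assert assign_repeat("c", 120, self.track) == "SINE"

    def test_uncovered_site_has_no_class(self):
        assert assign_repeat("c", 400, self.track) is None

    def test_nested_interval_wins_over_container(self):
        assert assign_repeat("c", 160, self.track) == "Simple_repeat"

    def test_equal_length_overlap_resolved_alphabetically(self):
        track = RepeatTrack(
            [
                RepeatInterval("c", 0, 50, "LTR"),
                RepeatInterval("c", 0, 50, "LINE"),
            ]
        )
        assert assign_repeat("c", 10, track) == "LINE"


def _cds_genome_and_gene(codons, strand="+"):
    """One single-exon CDS gene made of the given codons (coding strand)."""
    coding = "".join(codons)
    if strand == "+":
        seq = "C" * 50 + coding + "C" * 50
    else:
        seq = "C" * 50 + revcomp(coding) + "C" * 50
    genome = GenomeRef({"c": seq})
    start, end = 50, 50 + len(coding)
    gene = GeneModel(
        gene_id="g",
        contig="c",
        strand=strand,
        start=start,
        end=end,
        exons=((start, end),),
        cds=((start, end),),
        utr5=(),
        utr3=(),
    )
    return genome, gene


class TestConsequence:
    def test_agc_to_ggc_is_ser_to_gly(self):
        genome, gene = _cds_genome_and_gene(["ATG", "AGC", "TAA"])
        call = consequence("c", 53, gene, genome)  # first base of codon 2
        assert (call.codon_before, call.codon_after) == ("AGC", "GGC")
        assert (call.aa_before, call.aa_after) == ("S", "G")
        assert call.consequence == "nonsynonymous"

    def test_cag_to_cgg_is_gln_to_arg(self):
        genome, gene = _cds_genome_and_gene(["ATG", "CAG", "TAA"])
        call = consequence("c", 54, gene, genome)  # second base of codon 2
        assert (call.codon_before, call.codon_after) == ("CAG", "CGG")
        assert (call.aa_before, call.aa_after) == ("Q", "R")
        assert call.consequence == "nonsynonymous"

    def test_cca_to_ccg_third_position_is_synonymous(self):
        genome, gene = _cds_genome_and_gene(["ATG", "CCA", "TAA"])
        call = consequence("c", 55, gene, genome)
        assert (call.codon_before, call.codon_after) == ("CCA", "CCG")
        assert call.consequence == "synonymous"

    def test_taa_to_tga_keeps_stop(self):
        genome, gene = _cds_genome_and_gene(["ATG", "TAA"])
        call = consequence("c", 54, gene, genome)
        assert call.aa_before == "*" and call.aa_after == "*"
        assert call.consequence == "synonymous"

    def test_minus_strand_ser_to_gly_is_t_to_c_on_plus(self):
        """A Ser->Gly call on a minus-strand gene corresponds to a
        plus-strand T genomic base; re-calling on the reverse-complemented
        locus reproduces the plus-strand call."""
        genome, gene = _cds_genome_and_gene(["ATG", "AGC", "TAA"], strand="-")
        # codon 2 position 1 in coding order; genomic position of that base:
        pos = int(gene.cds_positions()[3])
        assert genome["c"][pos] == "T"  # plus-strand image of the edited A
        call = consequence("c", pos, gene, genome)
        assert (call.aa_before, call.aa_after) == ("S", "G")
        # oracle: reverse-complement the locus and re-call on the plus strand
        mirror = GenomeRef({"c": revcomp(genome["c"])})
        L = len(genome["c"])
        mstart, mend = L - gene.end, L - gene.start
        mgene = GeneModel(
            gene_id="g", contig="c", strand="+", start=mstart, end=mend,
            exons=((mstart, mend),), cds=((mstart, mend),), utr5=(), utr3=(),
        )
        mcall = consequence("c", L - 1 - pos, mgene, mirror)
        assert (mcall.aa_before, mcall.aa_after) == (call.aa_before, call.aa_after)

    def test_cds_not_multiple_of_three_raises(self):
        genome, gene = _cds_genome_and_gene(["ATG", "AGC", "TAA"])
        broken = GeneModel(
            gene_id="g", contig="c", strand="+", start=50, end=58,
            exons=((50, 58),), cds=((50, 58),), utr5=(), utr3=(),
        )
        with pytest.raises(AnnotationError, match="divisible"):
            consequence("c", 53, broken, genome)


class TestSpliceProximity:
    gene = _plus_gene()  # intron [1150, 1450)

    def test_first_intronic_positions_are_donor(self):
        assert splice_proximity(1150, self.gene) == "donor"
        assert splice_proximity(1151, self.gene) == "donor"

    def test_last_intronic_positions_are_acceptor(self):
        assert splice_proximity(1448, self.gene) == "acceptor"
        assert splice_proximity(1449, self.gene) == "acceptor"

    def test_thirty_nt_upstream_of_3ss_is_branch_window(self):
        # distance to the intron's last base = 30, inside (18, 44)
        assert splice_proximity(1449 - 30, self.gene) == "branch_window"

    def test_mid_intron_and_exonic_sites_are_none(self):
        assert splice_proximity(1250, self.gene) == "none"
        assert splice_proximity(1100, self.gene) == "none"

    def test_minus_strand_donor_is_at_genomic_right_end(self):
        g = _plus_gene()
        mg = GeneModel(
            gene_id="gm", contig="c", strand="-", start=g.start, end=g.end,
            exons=g.exons, cds=g.cds, utr5=g.utr3, utr3=g.utr5,
        )
        assert splice_proximity(1449, mg) == "donor"
        assert splice_proximity(1150, mg) == "acceptor"
        assert splice_proximity(1150 + 30, mg) == "branch_window"


def test_annotate_sites_partition_is_exhaustive(genome, genes, repeats):
    """Every planted site gets exactly one region label and the labels sum
    to the planted counts."""
    import pandas as pd

    from editscan import plan_edits

    plan = plan_edits(genome, genes, group_rates={"g": 0.5}, n_sites=80, seed=7)
    sites = pd.DataFrame(
        [
            {"contig": s.contig, "pos": s.pos + 1, "strand": s.strand}
            for s in plan
        ]
    )
    ann = annotate_sites(sites, genes, repeats, genome)
    assert len(ann) == len(plan)
    planted = {}
    for s in plan:
        planted[s.region] = planted.get(s.region, 0) + 1
    called = ann["region"].value_counts().to_dict()
    assert called == planted
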