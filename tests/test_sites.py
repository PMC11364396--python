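"""Strand-aware pileup, edit-ratio computation and the high-confidence
cohort filter."""

import numpy as np
import pandas as pd
import pytest

from editscan import (
    FilterConfig,
    GenomeRef,
    call_candidate_sites,
    filter_high_confidence,
    pileup,
)
from editscan.align import AlignedRead
from editscan.sites import MalformedAlignmentError, SampleCounts, sites_to_frame


def _read(qname, contig, start, seq, strand="+", mate=2, rescued=False):
    return AlignedRead(
        qname=qname,
        contig=contig,
        start=start,
        seq=seq,
        blocks=((start, start + len(seq)),),
        transcript_strand=strand,
        mate=mate,
        rescued=rescued,
    )


@pytest.fixture
def flat_genome():
    return GenomeRef({"c": "A" * 30 + "T" * 30 + "C" * 30})


class TestPileup:
    def test_ten_reads_all_a_counts_ten(self, flat_genome):
        reads = [_read(f"r{i}", "c", 0, "A" * 10) for i in range(10)]
        counts = pileup(reads, flat_genome)
        arr = counts.counts[("c", "+")]
        assert arr[5, 0] == 10 and arr[5, 1:].sum() == 0

    def test_overlapping_mates_count_once(self, flat_genome):
        # both mates of one fragment cover position 5 with G
        r1 = _read("frag", "c", 0, "AAAAAGAAAA", mate=1)
        r2 = _read("frag", "c", 3, "AAGAAAAAAA", mate=2)
        counts = pileup([r1, r2], flat_genome)
        arr = counts.counts[("c", "+")]
        assert arr[5, 2] == 1  # G counted once, not twice
        assert arr[0, 0] == 1 and arr[12, 0] == 1

    def test_disagreeing_mate_bases_are_dropped(self, flat_genome):
        r1 = _read("frag", "c", 0, "AAAAAGAAAA", mate=1)
        r2 = _read("frag", "c", 0, "AAAAACAAAA", mate=2)
        counts = pileup([r1, r2], flat_genome)
        assert counts.counts[("c", "+")][5].sum() == 0
        assert counts.counts[("c", "+")][4, 0] == 1

    def test_minus_strand_counts_are_complemented(self, flat_genome):
        # genomic T with C reads on a minus-strand transcript: event-strand
        # A with 6 edited G reads on "-" (T-to-C in the plus-strand track)
        reads = [_read(f"r{i}", "c", 30, "C" * 10, strand="-") for i in range(6)]
        counts = pileup(reads, flat_genome)
        arr = counts.counts[("c", "-")]
        assert arr[35, 2] == 6  # G on the event strand
        assert counts.counts[("c", "+")][35].sum() == 0

    def test_read_past_contig_end_raises(self, flat_genome):
        with pytest.raises(MalformedAlignmentError):
            pileup([_read("r", "c", 85, "A" * 10)], flat_genome)


class TestCandidateSites:
    def test_edit_ratio_is_g_over_a_plus_g(self, flat_genome):
        reads = [_read(f"e{i}", "c", 0, "AAAAAGAAAA") for i in range(6)]
        reads += [_read(f"u{i}", "c", 0, "A" * 10) for i in range(4)]
        counts = pileup(reads, flat_genome)
        sites = call_candidate_sites(counts, flat_genome)
        (site,) = [s for s in sites if s.pos == 5]
        assert (site.edited, site.unedited) == (6, 4)
        assert site.edit_ratio == pytest.approx(0.6)

    def test_non_ag_bases_excluded_from_ratio(self, flat_genome):
        reads = [_read(f"e{i}", "c", 0, "AAAAAGAAAA") for i in range(6)]
        reads += [_read(f"u{i}", "c", 0, "A" * 10) for i in range(4)]
        reads += [_read("n", "c", 0, "AAAAANAAAA")]
        counts = pileup(reads, flat_genome)
        (site,) = [s for s in call_candidate_sites(counts, flat_genome) if s.pos == 5]
        assert site.edit_ratio == pytest.approx(0.6)
        assert site.other == 1 and site.depth == 11

    def test_non_a_reference_emits_no_site(self, flat_genome):
        # G reads over a reference C position
        reads = [_read(f"r{i}", "c", 60, "GCCCC") for i in range(5)]
        counts = pileup(reads, flat_genome)
        assert call_candidate_sites(counts, flat_genome) == []

    def test_conservation_depth_equals_base_sum(self, genome, genes):
        from editscan import ReadSimParams, plan_edits, simulate_sample
        from editscan.simulate import fragments_to_alignments

        plan = plan_edits(genome, genes, group_rates={"g": 0.5}, n_sites=20, seed=1)
        params = ReadSimParams(depth=15, error_rate=0.01)
        frags = simulate_sample(genome, genes, plan, params, "s", "g", seed=2)
        counts = pileup(fragments_to_alignments(frags, params), genome, "s")
        for site in call_candidate_sites(counts, genome):
            assert site.edited + site.unedited + site.other == site.depth
            assert site.depth == counts.depth(site.contig, site.strand, site.pos)

    def test_rescued_reads_flag_sites_as_hyper(self, flat_genome):
        reads = [
            _read(f"r{i}", "c", 0, "AAAAAGAAAA", rescued=(i == 0)) for i in range(6)
        ]
        counts = pileup(reads, flat_genome)
        (site,) = [s for s in call_candidate_sites(counts, flat_genome) if s.pos == 5]
        assert site.hyper


def _cohort_row(sample, pos, edited, unedited):
    return {
        "contig": "c",
        "pos": pos,
        "strand": "+",
        "sample_id": sample,
        "edited": edited,
        "unedited": unedited,
        "other": 0,
        "depth": edited + unedited,
        "edit_ratio": edited / (edited + unedited),
        "hyper": False,
    }


class TestHighConfidenceFilter:
    def test_three_qualifying_samples_keep_a_site(self):
        rows = [
            _cohort_row(s, 100, e, t - e)
            for s, (e, t) in zip(
                "abcd", [(7, 20), (8, 25), (6, 15), (2, 30)]
            )
        ]
        kept = filter_high_confidence(pd.DataFrame(rows), FilterConfig())
        assert set(kept["pos"]) == {100}

    def test_high_ratio_everywhere_rejected_as_genomic_variant(self):
        rows = [_cohort_row(s, 100, 19, 1) for s in "abcd"]  # ratio 0.95
        kept = filter_high_confidence(pd.DataFrame(rows), FilterConfig())
        assert kept.empty

    def test_exactly_five_edited_reads_fails_strict_threshold(self):
        rows = [_cohort_row(s, 100, 5, 10) for s in "abcd"]
        kept = filter_high_confidence(pd.DataFrame(rows), FilterConfig())
        assert kept.empty

    def test_six_edited_reads_passes_strict_threshold(self):
        rows = [_cohort_row(s, 100, 6, 10) for s in "abc"]
        kept = filter_high_confidence(pd.DataFrame(rows), FilterConfig())
        assert set(kept["pos"]) == {100}

    def test_small_cohort_warns_and_returns_empty(self):
        rows = [_cohort_row(s, 100, 10, 10) for s in "ab"]
        with pytest.warns(UserWarning, match="fewer"):
            kept = filter_high_confidence(pd.DataFrame(rows), FilterConfig())
        assert kept.empty

    def test_invalid_ratio_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(ratio_low=0.9, ratio_high=0.1)


def test_strand_mirror_site_set_on_reverse_complemented_genome(genome, genes):
    """Reverse-complementing the genome (and flipping annotations) must
    yield the same sites in mirrored coordinates."""
    from editscan import GeneModel, ReadSimParams, plan_edits, simulate_sample
    from editscan.models import revcomp
    from editscan.simulate import fragments_to_alignments

    plan = plan_edits(genome, genes, group_rates={"g": 0.6}, n_sites=15, seed=4)
    params = ReadSimParams(depth=20, error_rate=0.0)
    frags = simulate_sample(genome, genes, plan, params, "s", "g", seed=5)
    sites = call_candidate_sites(
        pileup(fragments_to_alignments(frags, params), genome, "s"), genome
    )

    # mirror: flip genome, flip read placements
    lengths = {n: genome.length(n) for n in genome.names()}
    mirrored = GenomeRef({n: revcomp(genome[n]) for n in genome.names()})
    flipped = []
    for r in fragments_to_alignments(frags, params):
        L = lengths[r.contig]
        blocks = tuple(
            sorted((L - e, L - s) for s, e in r.blocks)
        )
        flipped.append(
            AlignedRead(
                qname=r.qname,
                contig=r.contig,
                start=blocks[0][0],
                seq=revcomp(r.seq),
                blocks=blocks,
                transcript_strand="+" if r.transcript_strand == "-" else "-",
                mate=r.mate,
            )
        )
    mirror_sites = call_candidate_sites(pileup(flipped, mirrored, "s"), mirrored)

    def key(s, L):
        return (s.contig, L - 1 - s.pos, "+" if s.strand == "-" else "-")

    assert {key(s, lengths[s.contig]) for s in mirror_sites} == {
        (s.contig, s.pos, s.strand) for s in sites
    }
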