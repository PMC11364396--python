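"""Motif enrichment, downstream A-rich satellites and the inverted-repeat
scanner (checked against an O(n^2) brute-force oracle)."""

import numpy as np
import pandas as pd
import pytest

from editscan import (
    GenomeRef,
    a_rich_satellite,
    find_inverted_repeats,
    inverted_repeats_by_gene,
    motif_profile,
    revcomp,
)
from editscan.context import InsufficientDataError, InvertedRepeat

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_inverted_repeats(seq, min_arm=30, max_loop=10_000):
    """Independent O(n^2) enumeration of maximal exact inverted repeats.

    A hit is a pair arm1=[e1-L, e1), arm2=[s2, s2+L) with
    seq[e1-1-u] == complement(seq[s2+u]) for u < L, maximal inward and
    outward, with L >= min_arm and loop = s2-e1 in [0, max_loop]; hits
    whose arms are both contained in a longer hit's arms are removed.
    """
    n = len(seq)
    raw = []
    for e1 in range(n + 1):
        for s2 in range(e1, n + 1):
            if s2 - e1 > max_loop:
                break
            # inward maximality
            if s2 - e1 >= 2 and seq[e1] == _COMP[seq[s2 - 1]]:
                continue
            L = 0
            while (
                e1 - 1 - L >= 0
                and s2 + L < n
                and seq[e1 - 1 - L] == _COMP[seq[s2 + L]]
            ):
                L += 1
            if L >= min_arm:
                raw.append(InvertedRepeat(arm1=(e1 - L, e1), arm2=(s2, s2 + L)))
    kept = []
    for r in raw:
        if not any(
            o != r
            and o.arm1[0] <= r.arm1[0]
            and r.arm1[1] <= o.arm1[1]
            and o.arm2[0] <= r.arm2[0]
            and r.arm2[1] <= o.arm2[1]
            and o.arm_length > r.arm_length
            for o in raw
        ):
            kept.append(r)
    return sorted(set(kept), key=lambda r: (r.arm1, r.arm2))


def _sites_frame(positions, contig="c", strand="+"):
    return pd.DataFrame(
        [{"contig": contig, "pos": p + 1, "strand": strand} for p in positions]
    )


class TestMotif:
    def test_center_position_is_always_a(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 4000))
        genome = GenomeRef({"c": seq})
        a_pos = [i for i, b in enumerate(seq) if b == "A"][60:110]
        prof = motif_profile(_sites_frame(a_pos), genome, halfwidth=50)
        assert prof.frequencies.loc[0, "A"] == pytest.approx(1.0)

    def test_planted_downstream_g_detected_at_plus_one(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 6000))
        genome = GenomeRef({"c": seq})
        ag_pos = [
            i for i in range(60, 5900) if seq[i] == "A" and seq[i + 1] == "G"
        ][:80]
        prof = motif_profile(_sites_frame(ag_pos), genome, halfwidth=50)
        offset, base, p = prof.top_enrichment()
        assert (offset, base) == (1, "G")
        assert p < 1e-6

    def test_exact_binomial_enrichment_value(self):
        # 40 of 50 sites with G at +1 against background G=0.25:
        # one-sided exact binomial tail P(X >= 40 | n=50, p=0.25)
        seq_parts = []
        for i in range(50):
            nxt = "G" if i < 40 else "T"
            seq_parts.append("CCCC" + "A" + nxt + "CCCC")
        genome = GenomeRef({"c": "".join(seq_parts) * 2})
        positions = [i * 10 + 4 for i in range(50)]
        prof = motif_profile(
            _sites_frame(positions), genome, halfwidth=2,
            background={"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
        )
        assert prof.pvalues.loc[1, "G"] == pytest.approx(5.203604458813607e-16, rel=1e-9)

    def test_minus_strand_windows_are_reverse_complemented(self):
        genome = GenomeRef({"c": "CCCCCTCCCC" * 20})
        # plus-strand T at offset 5 of each repeat: event-strand A on '-'
        positions = [i * 10 + 5 for i in range(15)]
        prof = motif_profile(
            _sites_frame(positions, strand="-"), genome, halfwidth=2
        )
        assert prof.frequencies.loc[0, "A"] == pytest.approx(1.0)

    def test_null_sites_show_no_strong_enrichment(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 8000))
        genome = GenomeRef({"c": seq})
        a_pos = [i for i, b in enumerate(seq) if b == "A"]
        picks = rng.choice(a_pos[60:-60], 60, replace=False)
        prof = motif_profile(_sites_frame(sorted(picks)), genome, halfwidth=30)
        _, _, p = prof.top_enrichment()
        assert p > 1e-5  # no planted signal

    def test_fewer_than_ten_windows_is_an_error(self):
        genome = GenomeRef({"c": "A" * 200})
        with pytest.raises(InsufficientDataError):
            motif_profile(_sites_frame([100, 101]), genome, halfwidth=10)


class TestSatellites:
    def test_a_rich_window_at_offset_28_flagged(self):
        # 9 A's in the 10-nt window starting 28 nt downstream; neighbouring
        # windows hold at most 8 A's so the best offset is unambiguous
        down = "C" * 28 + "AACAAAAAAA" + "C" * 30
        genome = GenomeRef({"c": "C" * 99 + "A" + down})
        calls, skipped = a_rich_satellite(_sites_frame([99]), genome)
        assert skipped == 0
        (call,) = calls
        assert call.flagged and call.best_offset == 28
        assert call.best_a_fraction == pytest.approx(0.9)

    def test_uniform_downstream_not_flagged(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        genome = GenomeRef({"c": seq})
        a_pos = [i for i, b in enumerate(seq[:2900]) if b == "A"][:40]
        calls, _ = a_rich_satellite(_sites_frame(a_pos), genome)
        assert sum(c.flagged for c in calls) == 0

    def test_degenerate_offset_range_is_single_window(self):
        genome = GenomeRef({"c": "C" * 99 + "A" + "AAAAAAAAAA" + "C" * 50})
        calls, _ = a_rich_satellite(
            _sites_frame([99]), genome, offset_range=(0, 0), window=10
        )
        assert calls[0].flagged and calls[0].best_offset == 0

    def test_minus_strand_scans_upstream_in_genome_coordinates(self):
        # event-strand downstream of a '-' site is genomic leftward
        left = "T" * 10 + "C" * 20  # revcomp -> 20 G's then 10 A's
        genome = GenomeRef({"c": "G" * 60 + left + "T" + "G" * 60})
        pos = 60 + len(left)
        calls, _ = a_rich_satellite(
            _sites_frame([pos], strand="-"), genome, offset_range=(20, 20)
        )
        assert calls[0].flagged and calls[0].best_offset == 20

    def test_site_near_contig_end_skipped(self):
        genome = GenomeRef({"c": "A" * 120})
        calls, skipped = a_rich_satellite(_sites_frame([115]), genome)
        assert skipped == 1 and calls == []

    def test_empty_site_list_rejected(self):
        genome = GenomeRef({"c": "A" * 120})
        with pytest.raises(ValueError):
            a_rich_satellite(_sites_frame([]), genome)


class TestInvertedRepeats:
    def test_planted_stem_loop_recovered_exactly(self):
        rng = np.random.default_rng(7)
        bg = "".join(rng.choice(list("ACGT"), 2000))
        arm = "".join(rng.choice(list("ACGT"), 30))
        stem = arm + "".join(rng.choice(list("ACGT"), 50)) + revcomp(arm)
        seq = bg[:900] + stem + bg[900:]
        hits = find_inverted_repeats(seq, min_arm=30)
        oracle = brute_force_inverted_repeats(seq, min_arm=30)
        assert sorted(set(hits), key=lambda r: (r.arm1, r.arm2)) == oracle
        # the maximal hit may extend the planted arms by chance pairing,
        # but must contain them: arm1 at [900,930), arm2 at [980,1010)
        assert any(
            h.arm1[0] <= 900 and h.arm1[1] >= 930
            and h.arm2[0] <= 980 and h.arm2[1] >= 1010
            for h in hits
        )

    def test_arm_below_cutoff_not_reported(self):
        rng = np.random.default_rng(8)
        bg = "".join(rng.choice(list("ACGT"), 600))
        arm = "".join(rng.choice(list("ACGT"), 29))
        # G|G outside and T...T inside block outward/inward extension, so
        # the planted stem is exactly 29 bp: below a 30 bp cutoff
        seq = bg[:300] + "G" + arm + "T" * 20 + revcomp(arm) + "G" + bg[300:]
        assert find_inverted_repeats(seq, min_arm=30) == []
        hits29 = find_inverted_repeats(seq, min_arm=29)
        assert any(h.arm_length == 29 and h.loop_length == 20 for h in hits29)

    def test_homopolymer_has_no_inverted_repeat(self):
        assert find_inverted_repeats("A" * 500, min_arm=30) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 1200))
        # low cutoff so random hits actually occur
        hits = sorted(
            set(find_inverted_repeats(seq, min_arm=10)),
            key=lambda r: (r.arm1, r.arm2),
        )
        assert hits == brute_force_inverted_repeats(seq, min_arm=10)

    def test_strand_invariance_under_reverse_complement(self):
        rng = np.random.default_rng(11)
        bg = "".join(rng.choice(list("ACGT"), 800))
        arm = "".join(rng.choice(list("ACGT"), 15))
        seq = bg[:400] + arm + "ACGTACGT" + revcomp(arm) + bg[400:]
        n = len(seq)
        fwd = find_inverted_repeats(seq, min_arm=12)
        rev = find_inverted_repeats(revcomp(seq), min_arm=12)

        def mirror(r):
            return (
                (n - r.arm2[1], n - r.arm2[0]),
                (n - r.arm1[1], n - r.arm1[0]),
            )

        assert {(r.arm1, r.arm2) for r in fwd} == {mirror(r) for r in rev}

    def test_loop_longer_than_max_excluded(self):
        arm = "ACGTACGTACGT"
        seq = arm + "C" * 300 + revcomp(arm)
        assert find_inverted_repeats(seq, min_arm=12, max_loop=100) == []
        assert len(find_inverted_repeats(seq, min_arm=12, max_loop=400)) == 1

    def test_min_arm_below_eight_rejected(self):
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGT" * 100, min_arm=4)

    def test_per_gene_tally_counts_planted_intronic_stem(
        self, genome, genes, ir_truth
    ):
        df, n_genes = inverted_repeats_by_gene(genome, genes, min_arm=30)
        assert n_genes >= len(ir_truth)
        planted_genes = {t["gene_id"] for t in ir_truth}
        assert planted_genes <= set(df[df["intronic"]]["gene_id"])
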