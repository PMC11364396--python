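"""Synthetic genomes, editing plans and stranded paired-end read simulation.

The generator emulates the genomic context in which A-to-I editing is
measured: multi-gene contigs with 5'UTR/CDS/intron/3'UTR structure on both
strands, SINE-like repeats concentrated in introns and 3'UTRs, inverted
repeats (the dsRNA stem-loops that ADAR binds), planted per-site editing
rates that differ between sample groups, hyper-edited read clusters, and a
flat per-base sequencing-error rate.  Every planted site is recorded in a
truth table so downstream calls can be scored exactly.

Reads are stranded paired-end in F2R1 orientation (read 2 carries the
transcript-strand sequence), 2x75 by default as in stranded total RNA-seq
kits.  Edits are applied per fragment: each non-clustered site covered by a
fragment is edited with an independent Bernoulli draw at that site's group
rate, while all sites of a hyper cluster covered by one fragment are edited
together from a single draw — this reproduces the read-level mismatch
clustering that hyper-editing rescue relies on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, GenomeRef, RepeatInterval, RepeatTrack, revcomp, write_gtf

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

STOP_CODONS = {"TAA", "TAG", "TGA"}


class SizingError(ValueError):
    """Contig too short for the requested gene structure."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Layout of the synthetic genome.

    ``repeat_density`` is the fraction of 3'UTR/intron bases covered by
    SINE-like repeat copies; ``inverted_repeat_arms`` lists (arm, loop)
    lengths of stem-loops planted into introns.
    """

    n_contigs: int = 2
    contig_length: int = 12000
    n_genes: int = 6
    minus_strand_fraction: float = 0.5
    repeat_density: float = 0.3
    inverted_repeat_arms: tuple[tuple[int, int], ...] = ((30, 50),)
    rng_seed: int = 0
    # gene geometry (genomic bases per feature, transcript order)
    utr5_length: int = 60
    cds_exon_lengths: tuple[int, ...] = (150, 150)
    intron_length: int = 300
    utr3_length: int = 450
    intergenic_gap: int = 800

    def __post_init__(self):
        if min(self.n_contigs, self.contig_length, self.n_genes) <= 0:
            raise ValueError("counts and lengths must be positive")
        for p in (self.minus_strand_fraction, self.repeat_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if sum(self.cds_exon_lengths) % 3:
            raise ValueError("total CDS length must be divisible by 3")


@dataclass(frozen=True)
class PlanSite:
    """One planted editing site (0-based genomic position)."""

    contig: str
    pos: int
    strand: str
    gene_id: str
    region: str  # 5'UTR / CDS / intron / 3'UTR
    rates: dict[str, float] = field(hash=False)
    hyper: bool = False
    cluster_id: int | None = None

    def rate(self, group: str) -> float:
        return self.rates[group]


@dataclass
class EditingPlan:
    """Planted sites plus hyper-cluster bookkeeping.

    Invariant: every site's reference base is A on its gene strand, and
    hyper clusters contain at least 3 sites.
    """

    sites: list[PlanSite]

    def __post_init__(self):
        for s in self.sites:
            for g, r in s.rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"rate {r} for group {g} outside [0,1]")
        by_cluster: dict[int, int] = {}
        for s in self.sites:
            if s.cluster_id is not None:
                by_cluster[s.cluster_id] = by_cluster.get(s.cluster_id, 0) + 1
        for cid, n in by_cluster.items():
            if n < 3:
                raise ValueError(f"hyper cluster {cid} has {n} < 3 sites")

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)

    def groups(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            for g in s.rates:
                if g not in out:
                    out.append(g)
        return out

    def to_tsv(self, path: str | Path) -> None:
        groups = self.groups()
        rows = []
        for s in self.sites:
            row = {
                "contig": s.contig,
                "pos_1based": s.pos + 1,
                "strand": s.strand,
                "gene_id": s.gene_id,
                "region": s.region,
                "hyper": int(s.hyper),
                "cluster_id": -1 if s.cluster_id is None else s.cluster_id,
            }
            for g in groups:
                row[f"rate_{g}"] = s.rates[g]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EditingPlan":
        df = pd.read_csv(path, sep="\t")
        rate_cols = [c for c in df.columns if c.startswith("rate_")]
        sites = []
        for _, r in df.iterrows():
            sites.append(
                PlanSite(
                    contig=str(r["contig"]),
                    pos=int(r["pos_1based"]) - 1,
                    strand=str(r["strand"]),
                    gene_id=str(r["gene_id"]),
                    region=str(r["region"]),
                    rates={c[len("rate_"):]: float(r[c]) for c in rate_cols},
                    hyper=bool(r["hyper"]),
                    cluster_id=None if int(r["cluster_id"]) < 0 else int(r["cluster_id"]),
                )
            )
        return cls(sites)


@dataclass(frozen=True)
class ReadSimParams:
    """Sequencing parameters for the stranded paired-end simulator."""

    read_length: int = 75
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 30.0
    depth: float = 50.0
    error_rate: float = 0.001
    intron_fraction: float = 0.2  # intronic (pre-mRNA) coverage relative to exonic
    library_orientation: str = "F2R1"

    def __post_init__(self):
        if self.read_length > self.fragment_length_mean:
            raise ValueError("read_length must not exceed mean fragment length")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.library_orientation != "F2R1":
            raise ValueError("only F2R1 libraries are supported")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_bases: int) -> str:
    """Random CDS on the coding strand: ATG, non-stop codons, one stop.

    The second codon is always AGC (serine) so every gene carries a
    plantable recoding site whose edit produces the Ser->Gly change."""
    n_codons = n_bases // 3
    codons = ["ATG", "AGC"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in STOP_CODONS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _sine_consensus(rng: np.random.Generator, length: int = 140) -> str:
    """One SINE-like consensus per genome; copies diverge by point mutations."""
    return _random_seq(rng, length)


REPEAT_CLASSES = ("SINE", "SINE", "SINE", "LINE", "LTR", "Simple_repeat")


def generate_genome(
    config: SyntheticConfig,
) -> tuple[GenomeRef, list[GeneModel], RepeatTrack, dict]:
    """Build the synthetic genome, gene models and repeat annotation.

    Returns (genome, genes, repeats, truth) where ``truth`` records the
    planted inverted repeats.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.rng_seed)

    gene_span = (
        config.utr5_length
        + sum(config.cds_exon_lengths)
        + config.intron_length * (len(config.cds_exon_lengths) - 1)
        + config.utr3_length
    )
    genes_per_contig = [
        config.n_genes // config.n_contigs + (i < config.n_genes % config.n_contigs)
        for i in range(config.n_contigs)
    ]
    for n in genes_per_contig:
        need = n * gene_span + (n + 1) * config.intergenic_gap
        if need > config.contig_length:
            raise SizingError(
                f"contig of {config.contig_length} bp cannot hold {n} genes "
                f"({need} bp required)"
            )

    n_minus = int(round(config.minus_strand_fraction * config.n_genes))
    # deterministically interleave strands; minus genes first so that the
    # guaranteed AGC recoding codon always exists on a minus-strand gene
    strands = ["-"] * n_minus + ["+"] * (config.n_genes - n_minus)

    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    sine = _sine_consensus(rng)
    repeat_ivs: list[RepeatInterval] = []
    ir_truth: list[dict] = []
    gi = 0
    ir_queue = list(config.inverted_repeat_arms)

    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        seq = list(_random_seq(rng, config.contig_length))
        cursor = config.intergenic_gap
        for _ in range(genes_per_contig[ci]):
            strand = strands[gi]
            gene_id = f"gene{gi + 1}"
            gi += 1
            gstart = cursor
            # transcript-order features on the coding strand
            utr5 = _random_seq(rng, config.utr5_length)
            cds = _random_cds(rng, sum(config.cds_exon_lengths))
            introns = [
                _random_seq(rng, config.intron_length)
                for _ in range(len(config.cds_exon_lengths) - 1)
            ]
            utr3 = _random_seq(rng, config.utr3_length)

            # plant one inverted repeat per queued (arm, loop) spec, centred
            # in an intron when it fits
            ir_in_this_gene = False
            if ir_queue and introns:
                arm, loop = ir_queue[0]
                if arm * 2 + loop <= config.intron_length:
                    ir_queue.pop(0)
                    armseq = _random_seq(rng, arm)
                    stem = armseq + _random_seq(rng, loop) + revcomp(armseq)
                    off = (config.intron_length - len(stem)) // 2
                    intron0 = introns[0]
                    introns[0] = intron0[:off] + stem + intron0[off + len(stem):]
                    ir_in_this_gene = True
                    ir_truth.append(
                        {
                            "gene_id": gene_id,
                            "arm": arm,
                            "loop": loop,
                            "arm_seq": armseq,
                            "intron_offset": off,
                        }
                    )

            # assemble transcript-order genomic pieces with feature labels
            pieces: list[tuple[str, str]] = [("five_prime_utr", utr5)]
            exon_cursor = 0
            for k, clen in enumerate(config.cds_exon_lengths):
                pieces.append(("CDS", cds[exon_cursor : exon_cursor + clen]))
                exon_cursor += clen
                if k < len(introns):
                    pieces.append(("intron", introns[k]))
            pieces.append(("three_prime_utr", utr3))

            coding_seq = "".join(p[1] for p in pieces)
            if strand == "-":
                # write the reverse complement onto the plus strand; feature
                # order flips so the 5'UTR lands at the genomic right end
                genomic_seq = revcomp(coding_seq)
                rev_pieces = [(lab, revcomp(s)) for lab, s in reversed(pieces)]
            else:
                genomic_seq = coding_seq
                rev_pieces = pieces

            # genomic feature intervals
            feat: dict[str, list[tuple[int, int]]] = {
                "five_prime_utr": [],
                "CDS": [],
                "intron": [],
                "three_prime_utr": [],
            }
            p = gstart
            for lab, s in rev_pieces:
                feat[lab].append((p, p + len(s)))
                p += len(s)
            gend = p
            seq[gstart:gend] = list(genomic_seq)

            exon_ivs = sorted(
                feat["five_prime_utr"] + feat["CDS"] + feat["three_prime_utr"]
            )
            # merge abutting exon pieces
            merged: list[list[int]] = []
            for s0, e0 in exon_ivs:
                if merged and merged[-1][1] == s0:
                    merged[-1][1] = e0
                else:
                    merged.append([s0, e0])
            gene = GeneModel(
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                start=gstart,
                end=gend,
                exons=tuple((s0, e0) for s0, e0 in merged),
                cds=tuple(sorted(feat["CDS"])),
                utr5=tuple(sorted(feat["five_prime_utr"])),
                utr3=tuple(sorted(feat["three_prime_utr"])),
            )
            genes.append(gene)

            # SINE-like repeats in introns and 3'UTR at the requested density;
            # the transcript-order first intron is skipped when it holds a
            # planted inverted repeat so the stem is never overwritten
            intron_ivs = sorted(feat["intron"])
            if ir_in_this_gene and intron_ivs:
                skip_iv = intron_ivs[-1] if strand == "-" else intron_ivs[0]
                intron_ivs = [iv for iv in intron_ivs if iv != skip_iv]
            rep_targets = intron_ivs + sorted(feat["three_prime_utr"])
            for ts, te in rep_targets:
                budget = int(config.repeat_density * (te - ts))
                pos0 = ts + 5
                while budget >= 40 and pos0 + 40 < te:
                    rep_len = min(len(sine), budget, te - pos0 - 5)
                    if rep_len < 40:
                        break
                    copy = list(sine[:rep_len])
                    # ~5% divergence between copies
                    nmut = rng.binomial(rep_len, 0.05)
                    for mpos in rng.integers(0, rep_len, nmut):
                        copy[mpos] = BASES[rng.integers(0, 4)]
                    seq[pos0 : pos0 + rep_len] = copy
                    cls_label = REPEAT_CLASSES[
                        (len(repeat_ivs)) % len(REPEAT_CLASSES)
                    ]
                    repeat_ivs.append(
                        RepeatInterval(contig, pos0, pos0 + rep_len, cls_label)
                    )
                    budget -= rep_len
                    pos0 += rep_len + 20
            cursor = gend + config.intergenic_gap
        contigs[contig] = "".join(seq)

    genome = GenomeRef(contigs)
    truth = {"inverted_repeats": ir_truth}
    return genome, genes, RepeatTrack(repeat_ivs), truth


def write_genome_bundle(
    outdir: str | Path,
    genome: GenomeRef,
    genes: Sequence[GeneModel],
    repeats: RepeatTrack,
) -> dict[str, Path]:
    """Write FASTA + GTF + repeat BED into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "repeats": outdir / "repeats.bed",
    }
    genome.to_fasta(paths["fasta"])
    write_gtf(genes, paths["gtf"])
    repeats.to_bed(paths["repeats"])
    return paths


# ---------------------------------------------------------------------------
# editing plans
# ---------------------------------------------------------------------------

_REGION_OF_FEATURE = {
    "five_prime_utr": "5'UTR",
    "CDS": "CDS",
    "intron": "intron",
    "three_prime_utr": "3'UTR",
}


def _gene_region_lookup(gene: GeneModel) -> dict[int, str]:
    """Genomic position -> region label within one gene."""
    out: dict[int, str] = {}
    for ivs, lab in (
        (gene.utr5, "5'UTR"),
        (gene.cds, "CDS"),
        (gene.introns, "intron"),
        (gene.utr3, "3'UTR"),
    ):
        for s, e in ivs:
            for p in range(s, e):
                out[p] = lab
    return out


def plan_edits(
    genome: GenomeRef,
    genes: Sequence[GeneModel],
    group_rates: dict[str, float] | Sequence[dict[str, float]],
    n_sites: int = 50,
    regions: Sequence[str] = ("3'UTR", "intron", "CDS", "5'UTR"),
    n_hyper_clusters: int = 0,
    cluster_size: int = 5,
    cluster_span: int = 60,
    hyper_rate: float = 0.8,
    seed: int = 0,
) -> EditingPlan:
    """Draw an editing plan over transcript-strand adenosines.

    ``group_rates`` is either one mapping group->rate applied to all sites,
    or a sequence of such mappings cycled over sites (so alternating
    differential/null rates can be planted).  Hyper clusters are runs of
    ``cluster_size`` nearby A's in 3'UTRs edited jointly at ``hyper_rate``
    in every group.
    """
    rng = np.random.default_rng(seed)
    if isinstance(group_rates, dict):
        rate_cycle = [group_rates]
    else:
        rate_cycle = list(group_rates)

    # candidate transcript-strand A positions per gene/region
    candidates: list[tuple[str, int, str, str, str]] = []
    utr3_runs: dict[str, list[int]] = {}
    for gene in genes:
        lookup = _gene_region_lookup(gene)
        contig_seq = genome[gene.contig]
        ref_base = "A" if gene.strand == "+" else "T"
        gene_utr3_as = []
        for p, lab in lookup.items():
            if contig_seq[p] == ref_base:
                if lab in regions:
                    candidates.append((gene.contig, p, gene.strand, gene.gene_id, lab))
                if lab == "3'UTR":
                    gene_utr3_as.append(p)
        utr3_runs[gene.gene_id] = sorted(gene_utr3_as)

    sites: list[PlanSite] = []
    used: set[tuple[str, int]] = set()

    # hyper clusters first, so ordinary sites avoid their positions
    cid = 0
    hyper_genes = [g for g in genes if utr3_runs[g.gene_id]]
    while cid < n_hyper_clusters and hyper_genes:
        gene = hyper_genes[cid % len(hyper_genes)]
        pool = utr3_runs[gene.gene_id]
        placed = False
        # search outward from the pool centre so clusters avoid the
        # low-coverage transcript extremities
        mid = len(pool) // 2
        order = sorted(range(len(pool)), key=lambda i: abs(i - mid))
        for i in order:
            window = [p for p in pool[i:] if p - pool[i] < cluster_span]
            window = [p for p in window if (gene.contig, p) not in used]
            if len(window) >= cluster_size:
                chosen = window[:cluster_size]
                for p in chosen:
                    used.add((gene.contig, p))
                    sites.append(
                        PlanSite(
                            contig=gene.contig,
                            pos=p,
                            strand=gene.strand,
                            gene_id=gene.gene_id,
                            region="3'UTR",
                            rates={g: hyper_rate for g in _all_groups(rate_cycle)},
                            hyper=True,
                            cluster_id=cid,
                        )
                    )
                placed = True
                break
        if not placed:
            raise ValueError(
                f"no room for a hyper cluster of {cluster_size} sites in "
                f"{gene.gene_id}"
            )
        cid += 1

    free = [c for c in candidates if (c[0], c[1]) not in used]
    if n_sites > len(free):
        raise ValueError(f"requested {n_sites} sites but only {len(free)} A's available")
    order = rng.permutation(len(free))[:n_sites]
    for k, idx in enumerate(sorted(order)):
        contig, p, strand, gid, lab = free[idx]
        sites.append(
            PlanSite(
                contig=contig,
                pos=p,
                strand=strand,
                gene_id=gid,
                region=lab,
                rates=dict(rate_cycle[k % len(rate_cycle)]),
                hyper=False,
                cluster_id=None,
            )
        )
    sites.sort(key=lambda s: (s.contig, s.pos))
    return EditingPlan(sites)


def _all_groups(rate_cycle: list[dict[str, float]]) -> list[str]:
    out: list[str] = []
    for d in rate_cycle:
        for g in d:
            if g not in out:
                out.append(g)
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFragment:
    """Truth record for one sequenced fragment."""

    name: str
    gene_id: str
    contig: str
    strand: str  # transcript strand
    template_positions: np.ndarray  # genomic position per fragment base, 5'->3'
    seq: str  # fragment sequence on the transcript strand, after edits+errors
    n_edits: int


def _template_fragments(
    rng: np.random.Generator,
    template_seq: str,
    template_pos: np.ndarray,
    n_fragments: int,
    params: ReadSimParams,
) -> list[tuple[int, int]]:
    L = len(template_seq)
    if L < params.read_length or n_fragments <= 0:
        return []
    lens = rng.normal(params.fragment_length_mean, params.fragment_length_sd, n_fragments)
    lens = np.clip(np.round(lens).astype(int), params.read_length, L)
    starts = rng.integers(0, L - lens + 1)
    return list(zip(starts.tolist(), lens.tolist()))


def simulate_sample(
    genome: GenomeRef,
    genes: Sequence[GeneModel],
    plan: EditingPlan,
    params: ReadSimParams,
    sample_id: str,
    group_id: str,
    seed: int,
) -> list[SimulatedFragment]:
    """Simulate one sample's fragments (both mates derive from these).

    Each gene contributes mature-transcript fragments at the target depth
    and pre-mRNA fragments at ``intron_fraction`` of it.  Edits are applied
    on the transcript strand; errors afterwards, uniformly.
    """
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in genes}
    for s in plan:
        if s.gene_id not in gene_by_id:
            raise ValueError(f"planted site {s.contig}:{s.pos + 1} lies outside any gene")
        contig_seq = genome[s.contig]
        ref = contig_seq[s.pos] if s.strand == "+" else revcomp(contig_seq[s.pos])
        if ref != "A":
            raise ValueError(
                f"planted site {s.contig}:{s.pos + 1} ({s.strand}) reference "
                f"base is {ref}, not A"
            )

    # sites indexed by genomic position per contig
    site_by_pos: dict[tuple[str, int], PlanSite] = {(s.contig, s.pos): s for s in plan}

    fragments: list[SimulatedFragment] = []
    fid = 0
    for gene in genes:
        templates = []
        mat_seq = gene.transcript_sequence(genome)
        mat_pos = gene.transcript_positions()
        n_mat = int(round(params.depth * len(mat_seq) / (2 * params.read_length)))
        templates.append((mat_seq, mat_pos, n_mat))
        if params.intron_fraction > 0 and gene.introns:
            pre_seq = gene.premrna_sequence(genome)
            pre_pos = gene.premrna_positions()
            n_pre = int(
                round(
                    params.intron_fraction
                    * params.depth
                    * len(pre_seq)
                    / (2 * params.read_length)
                )
            )
            templates.append((pre_seq, pre_pos, n_pre))

        for tseq, tpos, n_frag in templates:
            # template positions of planted sites in this gene
            site_tpos: list[tuple[int, PlanSite]] = []
            pos_to_t = {int(p): i for i, p in enumerate(tpos)}
            for s in plan:
                if s.gene_id != gene.gene_id:
                    continue
                ti = pos_to_t.get(s.pos)
                if ti is not None:
                    site_tpos.append((ti, s))
            site_tpos.sort()

            for start, flen in _template_fragments(rng, tseq, tpos, n_frag, params):
                frag = list(tseq[start : start + flen])
                n_edits = 0
                cluster_draw: dict[int, bool] = {}
                for ti, s in site_tpos:
                    if not start <= ti < start + flen:
                        continue
                    r = s.rates.get(group_id, 0.0)
                    if s.cluster_id is not None:
                        if s.cluster_id not in cluster_draw:
                            cluster_draw[s.cluster_id] = rng.random() < r
                        edited = cluster_draw[s.cluster_id]
                    else:
                        edited = rng.random() < r
                    if edited:
                        frag[ti - start] = "G"
                        n_edits += 1
                fragments.append(
                    SimulatedFragment(
                        name=f"{sample_id}.f{fid}",
                        gene_id=gene.gene_id,
                        contig=gene.contig,
                        strand=gene.strand,
                        template_positions=tpos[start : start + flen],
                        seq="".join(frag),
                        n_edits=n_edits,
                    )
                )
                fid += 1

    # sequencing errors: uniform substitutions over all fragment bases
    if params.error_rate > 0:
        for f in fragments:
            n = len(f.seq)
            nerr = rng.binomial(n, params.error_rate)
            if nerr == 0:
                continue
            s = list(f.seq)
            for p in rng.integers(0, n, nerr):
                cur = s[p]
                alt = BASES[rng.integers(0, 4)]
                while alt == cur:
                    alt = BASES[rng.integers(0, 4)]
                s[p] = alt
            f.seq = "".join(s)
    return fragments


def fragments_to_fastq(
    fragments: Sequence[SimulatedFragment],
    params: ReadSimParams,
    fastq1: str | Path,
    fastq2: str | Path,
) -> None:
    """Write F2R1 mate pairs: R2 = transcript-strand 5' end, R1 = reverse
    complement of the 3' end."""
    import gzip as _gzip
    import io

    def _open(path):
        # mtime pinned so identical simulations give identical bytes
        if str(path).endswith(".gz"):
            raw = open(path, "wb")
            return io.TextIOWrapper(
                _gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            )
        return open(path, "wt")

    rl = params.read_length
    qual = "I" * rl
    with _open(fastq1) as f1, _open(fastq2) as f2:
        for f in fragments:
            r2 = f.seq[:rl]
            r1 = revcomp(f.seq[-rl:])
            f1.write(f"@{f.name}/1\n{r1}\n+\n{qual}\n")
            f2.write(f"@{f.name}/2\n{r2}\n+\n{qual}\n")


def fragments_to_alignments(
    fragments: Sequence[SimulatedFragment],
    params: ReadSimParams,
):
    """Truth alignments for simulated fragments (both mates).

    Returns a list of :class:`editscan.align.AlignedRead` with exact known
    placements — the simulator's equivalent of an aligner's output, used to
    exercise pileup and statistics without the toy aligner in the loop.
    Spliced mates carry multi-block placements.
    """
    from .align import AlignedRead

    rl = params.read_length
    out = []
    for f in fragments:
        for mate in (1, 2):
            if mate == 2:
                pos = f.template_positions[:rl]
                seq_t = f.seq[:rl]
            else:
                pos = f.template_positions[-rl:]
                seq_t = f.seq[-rl:]
            # seq_t is on the transcript strand over transcript-ordered pos;
            # convert to genome-forward orientation
            if f.strand == "-":
                gpos = pos[::-1]
                gseq = revcomp(seq_t)
            else:
                gpos = pos
                gseq = seq_t
            blocks = _positions_to_blocks(gpos)
            out.append(
                AlignedRead(
                    qname=f.name,
                    contig=f.contig,
                    start=int(gpos[0]),
                    seq=gseq,
                    blocks=blocks,
                    transcript_strand=f.strand,
                    mate=mate,
                    rescued=False,
                )
            )
    return out


def _positions_to_blocks(gpos: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Collapse ascending genomic positions into half-open blocks."""
    breaks = np.flatnonzero(np.diff(gpos) != 1)
    blocks = []
    s = 0
    for b in breaks:
        blocks.append((int(gpos[s]), int(gpos[b]) + 1))
        s = b + 1
    blocks.append((int(gpos[s]), int(gpos[-1]) + 1))
    return tuple(blocks)
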