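"""End-to-end pipeline: simulate → align → rescue → call → filter → test →
annotate → context, driven by one YAML config with a global seed.

Every stage writes plain-text outputs into the run directory and records
input/output checksums and record counts in a JSON run manifest, so a rerun
with the same config and seed reproduces the files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import (
    AlignParams,
    PseudoGenomes,
    hyper_rescue,
    read_fastq_pair,
    toy_align,
    write_sam,
    read_sam,
)
from .annotate import annotate_sites, region_density, region_lengths
from .context import (
    a_rich_satellite,
    inverted_repeats_by_gene,
    inverted_repeats_to_bedpe,
    motif_profile,
    satellites_to_frame,
)
from .differential import Comparison, summarize_directions, differential_test, top_sites
from .models import GenomeRef, RepeatTrack, read_gtf
from .simulate import (
    EditingPlan,
    ReadSimParams,
    SyntheticConfig,
    fragments_to_fastq,
    plan_edits,
    simulate_sample,
    fragments_to_alignments,
    generate_genome,
    write_genome_bundle,
)
from .sites import (
    FilterConfig,
    call_candidate_sites,
    filter_high_confidence,
    pileup,
    sites_to_frame,
    write_cohort_vcf,
    SITE_KEY,
)

log = logging.getLogger("editscan")


class ValidationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One config object for the whole run.

    ``samples`` maps sample id -> group id; ``comparisons`` lists
    (group1, group2) pairs, defaulting to all ordered unique pairs.
    """

    outdir: Path
    samples: dict[str, str]
    seed: int = 0
    alpha: float = 0.05
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    reads: ReadSimParams = field(default_factory=ReadSimParams)
    align: AlignParams = field(default_factory=AlignParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    plan: dict[str, Any] = field(default_factory=dict)
    use_truth_alignments: bool = False
    genome_fasta: Path | None = None
    gtf: Path | None = None
    repeat_bed: Path | None = None
    sample_sams: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self):
        if not self.samples:
            raise ValidationError("no samples configured")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample ids must be unique")
        groups = sorted(set(self.samples.values()))
        if any(not g for g in self.samples.values()):
            raise ValidationError("every sample needs a group label")
        if not self.comparisons:
            self.comparisons = [
                (g1, g2) for i, g1 in enumerate(groups) for g2 in groups[i + 1 :]
            ]
        for g1, g2 in self.comparisons:
            if g1 not in groups or g2 not in groups:
                raise ValidationError(f"comparison ({g1},{g2}) names unknown group")
        for p in (self.genome_fasta, self.gtf, self.repeat_bed):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "PipelineConfig":
        def sub(name, klass):
            block = raw.get(name) or {}
            if name == "synthetic" and "inverted_repeat_arms" in block:
                block["inverted_repeat_arms"] = tuple(
                    tuple(x) for x in block["inverted_repeat_arms"]
                )
            return klass(**block)

        samples = raw.get("samples")
        if not isinstance(samples, dict) or not samples:
            raise ValidationError("config needs a non-empty 'samples' mapping")
        if any(v in (None, "") for v in samples.values()):
            raise ValidationError("config missing group labels for some samples")
        return cls(
            outdir=base / raw.get("outdir", "editscan_run"),
            samples={str(k): str(v) for k, v in samples.items()},
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
            synthetic=sub("synthetic", SyntheticConfig),
            reads=sub("reads", ReadSimParams),
            align=sub("align", AlignParams),
            filter=sub("filter", FilterConfig),
            comparisons=[tuple(c) for c in raw.get("comparisons", [])],
            plan=raw.get("plan") or {},
            use_truth_alignments=bool(raw.get("use_truth_alignments", False)),
            genome_fasta=base / raw["genome_fasta"] if raw.get("genome_fasta") else None,
            gtf=base / raw["gtf"] if raw.get("gtf") else None,
            repeat_bed=base / raw["repeat_bed"] if raw.get("repeat_bed") else None,
            sample_sams={
                k: base / v for k, v in (raw.get("sample_sams") or {}).items()
            },
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str = __version__
    config_hash: str = ""
    seed: int = 0
    counts: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record_file(self, path: Path, outdir: Path) -> None:
        self.checksums[str(path.relative_to(outdir))] = _sha256(path)

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "counts": self.counts,
                    "checksums": self.checksums,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _seed_for(global_seed: int, stage: str, item: str = "") -> int:
    """Stable per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}:{item}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    manifest.config_hash = hashlib.sha256(
        repr(
            (
                sorted(config.samples.items()),
                config.seed,
                config.alpha,
                config.synthetic,
                config.reads,
                config.align,
                config.filter,
                tuple(config.comparisons),
                tuple(sorted(config.plan.items())),
            )
        ).encode()
    ).hexdigest()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, outdir, manifest)
        manifest.warnings = sorted({str(w.message) for w in caught})

    manifest.to_json(outdir / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, outdir: Path, manifest: RunManifest) -> None:
    groups = sorted(set(config.samples.values()))

    # --- genome -----------------------------------------------------------
    stage = "simulate"
    try:
        if config.genome_fasta is not None:
            genome = GenomeRef.from_fasta(config.genome_fasta)
            genes = read_gtf(config.gtf) if config.gtf else []
            repeats = (
                RepeatTrack.from_bed(config.repeat_bed)
                if config.repeat_bed
                else RepeatTrack([])
            )
        else:
            syn = SyntheticConfig(
                **{
                    **{
                        f.name: getattr(config.synthetic, f.name)
                        for f in config.synthetic.__dataclass_fields__.values()
                    },
                    "rng_seed": _seed_for(config.seed, "genome"),
                }
            )
            genome, genes, repeats, _ = generate_genome(syn)
            paths = write_genome_bundle(outdir / "ref", genome, genes, repeats)
            for p in paths.values():
                manifest.record_file(p, outdir)
        manifest.counts["genes"] = len(genes)

        sample_fragments: dict[str, list] = {}
        if config.sample_sams:
            # real alignments supplied: no simulation stage
            manifest.counts["planted_sites"] = 0
        else:
            plan_kwargs = dict(config.plan)
            group_rates = plan_kwargs.pop(
                "group_rates", [{g: 0.3 for g in groups}]
            )
            if isinstance(group_rates, dict):
                group_rates = [group_rates]
            plan = plan_edits(
                genome,
                genes,
                group_rates=group_rates,
                seed=_seed_for(config.seed, "plan"),
                **plan_kwargs,
            )
            plan.to_tsv(outdir / "truth_sites.tsv")
            manifest.record_file(outdir / "truth_sites.tsv", outdir)
            manifest.counts["planted_sites"] = len(plan)

            for sample, group in sorted(config.samples.items()):
                frags = simulate_sample(
                    genome,
                    genes,
                    plan,
                    config.reads,
                    sample,
                    group,
                    seed=_seed_for(config.seed, "reads", sample),
                )
                sample_fragments[sample] = frags
                fq1 = outdir / f"{sample}_R1.fastq.gz"
                fq2 = outdir / f"{sample}_R2.fastq.gz"
                fragments_to_fastq(frags, config.reads, fq1, fq2)
                manifest.record_file(fq1, outdir)
                manifest.record_file(fq2, outdir)
            manifest.counts["fragments"] = sum(
                len(v) for v in sample_fragments.values()
            )
    except (ValidationError, ValueError) as exc:
        raise StageError(stage, str(exc)) from exc

    # --- align + rescue ---------------------------------------------------
    stage = "align"
    sample_reads: dict[str, list] = {}
    try:
        if config.sample_sams:
            n_aligned = n_rescued = 0
            for sample in sorted(config.samples):
                aligned, unmapped = read_sam(config.sample_sams[sample], genome)
                resc = hyper_rescue(unmapped, genome, config.align)
                sample_reads[sample] = aligned + resc.rescued
                n_aligned += len(aligned)
                n_rescued += len(resc.rescued)
            manifest.counts["reads_aligned"] = n_aligned
            manifest.counts["reads_rescued"] = n_rescued
        elif config.use_truth_alignments:
            for sample, frags in sample_fragments.items():
                sample_reads[sample] = fragments_to_alignments(frags, config.reads)
            manifest.counts["reads_aligned"] = sum(
                len(v) for v in sample_reads.values()
            )
            manifest.counts["reads_rescued"] = 0
        else:
            from .align import KmerIndex

            index = KmerIndex(genome.contigs, config.align.seed_kmer)
            pseudo = PseudoGenomes(genome, config.align.seed_kmer)
            n_aligned = n_rescued = 0
            for sample in sorted(config.samples):
                fq1 = outdir / f"{sample}_R1.fastq.gz"
                fq2 = outdir / f"{sample}_R2.fastq.gz"
                reads = read_fastq_pair(fq1, fq2)
                res = toy_align(reads, genome, config.align, index=index)
                resc = hyper_rescue(res.unaligned, genome, config.align, pseudo=pseudo)
                aligned = res.aligned + resc.rescued
                sample_reads[sample] = aligned
                n_aligned += len(res.aligned)
                n_rescued += len(resc.rescued)
                sam = outdir / f"{sample}.sam"
                write_sam(aligned, genome, sam)
                manifest.record_file(sam, outdir)
            manifest.counts["reads_aligned"] = n_aligned
            manifest.counts["reads_rescued"] = n_rescued
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc

    # --- call + filter ----------------------------------------------------
    stage = "call"
    try:
        site_lists = []
        for sample in sorted(config.samples):
            counts = pileup(sample_reads[sample], genome, sample_id=sample)
            site_lists.append(call_candidate_sites(counts, genome))
        cohort = sites_to_frame(site_lists)
        cohort.to_csv(outdir / "sites_all.tsv", sep="\t", index=False)
        manifest.record_file(outdir / "sites_all.tsv", outdir)
        manifest.counts["sites_called"] = (
            cohort[SITE_KEY].drop_duplicates().shape[0]
        )

        filtered = filter_high_confidence(cohort, config.filter)
        filtered.to_csv(outdir / "sites_filtered.tsv", sep="\t", index=False)
        manifest.record_file(outdir / "sites_filtered.tsv", outdir)
        write_cohort_vcf(filtered, genome, outdir / "sites_filtered.vcf")
        manifest.record_file(outdir / "sites_filtered.vcf", outdir)
        manifest.counts["sites_filtered"] = (
            filtered[SITE_KEY].drop_duplicates().shape[0]
        )
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc

    # --- differential -----------------------------------------------------
    stage = "diff"
    try:
        results: dict[str, pd.DataFrame] = {}
        n_tested = n_sig = 0
        for g1, g2 in config.comparisons:
            comp = Comparison(name=f"{g1}_vs_{g2}", group1=g1, group2=g2)
            res = differential_test(filtered, config.samples, comp, alpha=config.alpha)
            results[comp.name] = res
            res.to_csv(outdir / f"diff_{comp.name}.tsv", sep="\t", index=False)
            manifest.record_file(outdir / f"diff_{comp.name}.tsv", outdir)
            n_tested += len(res)
            n_sig += int(res["significant"].sum())
        manifest.counts["sites_tested"] = n_tested
        manifest.counts["sites_significant"] = n_sig
        summary = summarize_directions(results, alpha=config.alpha)
        summary.to_csv(outdir / "direction_summary.tsv", sep="\t", index=False)
        manifest.record_file(outdir / "direction_summary.tsv", outdir)
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc

    # --- annotate ---------------------------------------------------------
    stage = "annotate"
    try:
        uniq = filtered[SITE_KEY + ["hyper"]].drop_duplicates(SITE_KEY)
        ann = annotate_sites(uniq, genes, repeats, genome)
        ann.to_csv(outdir / "sites_annotated.tsv", sep="\t", index=False)
        manifest.record_file(outdir / "sites_annotated.tsv", outdir)
        from .annotate import RegionAssignment

        assignments = [
            RegionAssignment(r["contig"], r["pos"] - 1, r["strand"], r["region"], r["gene_id"])
            for _, r in ann.iterrows()
        ]
        dens = region_density(assignments, region_lengths(genes))
        dens.to_csv(outdir / "region_density.tsv", sep="\t", index=False)
        manifest.record_file(outdir / "region_density.tsv", outdir)

        for name, res in results.items():
            key = res[SITE_KEY].merge(
                ann[SITE_KEY + ["repeat_class"]], on=SITE_KEY, how="left"
            )
            top = top_sites(res, k=500, repeat_classes=key["repeat_class"])
            top.to_csv(outdir / f"top_sites_{name}.tsv", sep="\t", index=False)
            manifest.record_file(outdir / f"top_sites_{name}.tsv", outdir)
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc

    # --- sequence context -------------------------------------------------
    stage = "context"
    try:
        if len(uniq) >= 10:
            prof = motif_profile(uniq, genome)
            prof.to_frame().to_csv(outdir / "motif_profile.tsv", sep="\t", index=False)
            manifest.record_file(outdir / "motif_profile.tsv", outdir)
        hyper_sites = uniq[uniq["hyper"]]
        if len(hyper_sites):
            calls, skipped = a_rich_satellite(hyper_sites, genome)
            satellites_to_frame(calls).to_csv(
                outdir / "satellites.tsv", sep="\t", index=False
            )
            manifest.record_file(outdir / "satellites.tsv", outdir)
            manifest.counts["satellite_skipped"] = skipped
        ir_df, n_genes_ir = inverted_repeats_by_gene(genome, genes)
        inverted_repeats_to_bedpe(ir_df, outdir / "inverted_repeats.bedpe")
        manifest.record_file(outdir / "inverted_repeats.bedpe", outdir)
        manifest.counts["genes_with_intronic_ir"] = n_genes_ir
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc

    # --- browser tracks ---------------------------------------------------
    stage = "tracks"
    try:
        export_browser_tracks(filtered, results, outdir, alpha=config.alpha)
        for p in sorted(outdir.glob("tracks/*")):
            manifest.record_file(p, outdir)
    except ValueError as exc:
        raise StageError(stage, str(exc)) from exc


def export_browser_tracks(
    filtered: pd.DataFrame,
    results: dict[str, pd.DataFrame],
    outdir: Path,
    alpha: float = 0.05,
) -> None:
    """One bedGraph per sample (edit ratio per site, 0-based half-open) and
    one BED of significant sites per comparison."""
    tracks = Path(outdir) / "tracks"
    tracks.mkdir(parents=True, exist_ok=True)
    for sample, df in filtered.groupby("sample_id"):
        path = tracks / f"{sample}.edit_ratio.bedGraph"
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{sample} edit ratio"\n')
            for _, r in df.sort_values(SITE_KEY).iterrows():
                fh.write(
                    f"{r['contig']}\t{r['pos'] - 1}\t{r['pos']}\t{r['edit_ratio']:.6g}\n"
                )
    for name, res in results.items():
        path = tracks / f"significant_{name}.bed"
        with open(path, "w") as fh:
            fh.write(f'track name="significant sites {name}"\n')
            sig = res[res["p_adj"] < alpha]
            for _, r in sig.sort_values(SITE_KEY).iterrows():
                fh.write(
                    f"{r['contig']}\t{r['pos'] - 1}\t{r['pos']}\t"
                    f"{name}\t0\t{r['strand']}\n"
                )
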