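"""Stage orchestration: simulate fixtures, run the analysis, summarize.

Each stage is a pure function of its inputs and the config; the manifest
records read counts surviving every stage (trim → align → filter) so
filtering behavior is auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import coverage as cov
from . import profiles as prof
from . import reads as rp
from . import simulate as sim
from .config import RunConfig
from .features import FeatureSet
from .genome import AppliedEdit, apply_reference_edits, dinucleotide_frequency, load_genomes

__all__ = ["run_simulate", "run_pipeline", "run_report"]


def run_simulate(config: RunConfig) -> dict:
    """Generate the fixture bundle: genomes, GFF, FASTQ reads, truth TSV."""
    outdir = Path(config.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.simulate
    genomes = {}
    for i, gs in enumerate(spec.genomes):
        genomes[gs.id] = sim.make_random_genome(
            gs.length,
            gs.at_fraction,
            gs.topology,
            seed=config.seed * 101 + i,
            genome_id=gs.id,
            compartment=gs.compartment,
        )
    for j, dup in enumerate(spec.duplications):
        target, _truth = sim.plant_duplication(
            genomes[dup.target],
            genomes[dup.donor],
            (dup.donor_start, dup.donor_end),
            dup.insertion_site,
            dup.divergence_rate,
            seed=config.seed * 211 + j,
        )
        genomes[dup.target] = target

    d = spec.damage
    model = sim.DamageModel(
        mechanism=d.mechanism,
        primary_length=d.primary_length,
        trim_step=d.trim_step,
        trim_max_steps=d.trim_max_steps,
        dimer_offset_3p=d.dimer_offset_3p,
    )
    source = spec.source_genome or next(iter(genomes))
    reads, truth = sim.simulate_fragments(
        genomes[source],
        model,
        spec.n_reads,
        seed=config.seed * 307 + 1,
        adapter=config.adapter,
    )

    fasta = outdir / "genomes.fasta"
    fastq = outdir / "reads.fastq"
    truth_tsv = outdir / "truth.tsv"
    sim.write_fasta(list(genomes.values()), fasta)
    sim.write_fastq(reads, fastq)
    sim.write_truth(truth, truth_tsv)
    config.to_yaml(outdir / "config.yaml")
    return {
        "genomes": genomes,
        "reads": reads,
        "truth": truth,
        "fasta": fasta,
        "fastq": fastq,
        "truth_tsv": truth_tsv,
    }


def _load_inputs(config: RunConfig):
    p = config.paths
    if p.genomes_fasta is None:
        raise ValueError("paths.genomes_fasta is required for the pipeline")
    genomes = load_genomes([p.genomes_fasta], p.topology, p.compartment)
    by_id = {g.id: g for g in genomes}
    for e in config.edits:
        if e.genome not in by_id:
            raise ValueError(f"edit names unknown genome {e.genome!r}")
    for gid in {e.genome for e in config.edits}:
        edits = [
            AppliedEdit(e.kind, e.start, e.end, e.reason)
            for e in config.edits
            if e.genome == gid
        ]
        by_id[gid] = apply_reference_edits(by_id[gid], edits)
    features = (
        FeatureSet.from_gff(p.gff) if p.gff is not None else FeatureSet()
    )
    return list(by_id.values()), features


def run_pipeline(config: RunConfig) -> dict:
    """Trim → align → filter → weight → spectra/profiles/coverage outputs."""
    outdir = Path(config.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, features = _load_inputs(config)
    by_id = {g.id: g for g in genomes}

    if config.paths.sam is not None:
        unfiltered = rp.import_sam(
            config.paths.sam, genomes, mapq_min=config.filters.mapq_min
        )
        n_input = len(unfiltered)
        trim_report = None
    else:
        if config.paths.reads_fastq is None:
            raise ValueError("paths.reads_fastq or paths.sam is required")
        raw = sim.read_fastq(config.paths.reads_fastq)
        n_input = len(raw)
        trimmed, trim_report = rp.trim_adapter(raw, config.adapter)
        unfiltered = rp.align_exact(trimmed, genomes)

    filtered, filter_report = rp.filter_fragments(
        unfiltered, max_mismatches=config.filters.max_mismatches
    )
    filtered = rp.apply_halving_weights(filtered, genomes)

    # mappability per genome
    mapp_frames = []
    for g in genomes:
        mapp = rp.compute_mappability(unfiltered, filtered, g, features)
        mapp_frames.append(mapp.to_frame())
    import pandas as pd

    mapp_df = pd.concat(mapp_frames, ignore_index=True)
    mapp_df.to_csv(outdir / "mappability.tsv", sep="\t", index=False)

    comp = {g.id: g.compartment for g in genomes}
    spectra = prof.length_spectrum(filtered, comp)
    spec_df = pd.concat(
        [s.to_frame() for s in spectra.values() if s.counts], ignore_index=True
    ) if any(s.counts for s in spectra.values()) else pd.DataFrame()
    spec_df.to_csv(outdir / "length_spectra.tsv", sep="\t", index=False)

    # positional profiles per organellar genome and abundant length class
    profile_frames, enrich_rows = [], []
    pconf = config.profile
    anchor = {"5p": "five_prime", "3p": "three_prime"}.get(pconf.anchor, pconf.anchor)
    for g in genomes:
        if g.compartment == "nuclear":
            continue
        frags = [f for f in filtered if f.chrom == g.id]
        if not frags:
            continue
        if pconf.null_value is not None:
            p0 = pconf.null_value
        else:
            p0 = dinucleotide_frequency(g, "TT")
        lengths = pconf.lengths or sorted({f.length for f in frags})
        for L in lengths:
            sub = [f for f in frags if f.length == L]
            if not sub:
                continue
            seqs = [rp.fragment_sequence(g, f) for f in sub]
            profile = prof.positional_dinuc_profile(
                sub, seqs, L, anchor=anchor, null_p0=p0, min_reads=pconf.min_reads
            )
            profile_frames.append(profile.to_frame().assign(genome=g.id))
            for call in prof.call_enrichment(profile, tuple(pconf.dinucs)):
                enrich_rows.append(
                    {
                        "genome": g.id,
                        "length": call.length,
                        "position": call.position,
                        "dinucleotide": call.dinucleotide,
                        "observed": call.observed,
                        "null_p0": call.null_p0,
                        "significant": call.significant,
                    }
                )
    (pd.concat(profile_frames, ignore_index=True) if profile_frames
     else pd.DataFrame()).to_csv(outdir / "dinuc_profiles.tsv", sep="\t", index=False)
    pd.DataFrame(enrich_rows).to_csv(
        outdir / "enrichment_calls.tsv", sep="\t", index=False
    )

    table = cov.coverage_table(filtered, genomes, features if len(features) else None)
    table.to_frame().to_csv(outdir / "coverage.tsv", sep="\t", index=False)

    strand_frames = []
    if len(features):
        for g in genomes:
            if g.compartment == "nuclear":
                continue
            rep = cov.strand_normalized_coverage(
                filtered, features, g, tuple(config.coverage.dipyr_set)
            )
            strand_frames.append(rep.to_frame())
    (pd.concat(strand_frames, ignore_index=True) if strand_frames
     else pd.DataFrame()).to_csv(outdir / "strand_report.tsv", sep="\t", index=False)

    rp.write_bed(filtered, outdir / "filtered_fragments.bed")

    manifest = {
        "n_input_reads": n_input,
        "n_trimmed": trim_report.trimmed if trim_report else None,
        "n_discarded_untrimmed": (
            trim_report.discarded_untrimmed if trim_report else None
        ),
        "n_aligned": sum(1 for f in unfiltered if f.uniqueness != "unmapped"),
        "n_unique": sum(1 for f in unfiltered if f.uniqueness == "unique"),
        "n_filtered_kept": filter_report.kept,
        "removed_multimapping": filter_report.removed_multimapping,
        "removed_mismatch": filter_report.removed_mismatch,
        "removed_unmapped": filter_report.removed_unmapped,
        "seed": config.seed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "genomes": genomes,
        "features": features,
        "unfiltered": unfiltered,
        "filtered": filtered,
        "spectra": spectra,
        "coverage": table,
        "manifest": manifest,
        "outdir": outdir,
    }


def run_report(outdir) -> Path:
    """Combine stage TSVs into one human-readable summary document."""
    import pandas as pd

    outdir = Path(outdir)
    lines = ["# xrfrag run summary", ""]
    manifest = outdir / "manifest.json"
    if manifest.exists():
        counts = json.loads(manifest.read_text())
        lines.append("## Stage counts")
        for k in sorted(counts):
            lines.append(f"- {k}: {counts[k]}")
        lines.append("")
    for name, title in [
        ("mappability.tsv", "Mappability (fraction retained)"),
        ("length_spectra.tsv", "Length spectra"),
        ("enrichment_calls.tsv", "TT enrichment calls"),
        ("coverage.tsv", "Coverage (RPKM)"),
        ("strand_report.tsv", "Template vs coding strand"),
    ]:
        path = outdir / name
        if not path.exists():
            continue
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            continue
        lines.append(f"## {title}")
        lines.append("")
        lines.append(df.to_string(index=False, max_rows=40))
        lines.append("")
    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report
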