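"""End-to-end orchestration: simulate -> detect -> annotate -> express/DE ->
conserve -> co-expression modules -> ceRNA networks.

The pipeline runs fully in memory on a simulated dataset (or one loaded from
files) and can optionally persist every intermediate as plain-text formats.
All stage parameters and the seed are logged to stderr.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import annotate, cerna, conserve, coexpr, detect, express, io, simdata
from .genomic import revcomp

logger = logging.getLogger("circleaf")


@dataclass
class PipelineConfig:
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    detect: detect.DetectConfig = field(default_factory=detect.DetectConfig)
    modules: coexpr.ModuleConfig = field(default_factory=coexpr.ModuleConfig)
    max_expectation: float = cerna.MAX_EXPECTATION
    e_threshold: float = conserve.E_THRESHOLD
    outdir: str | None = None
    write_files: bool = False

    @property
    def seed(self) -> int:
        return self.sim.seed


@dataclass
class PipelineResult:
    dataset: simdata.SimulatedDataset
    detections: dict[str, detect.SampleDetection]
    junction_counts: pd.DataFrame  # distinct back-spliced reads per sample
    calls: list[detect.CircCall]
    annotated: list[annotate.AnnotatedCall]
    characterization: dict
    stage_overlap: dict
    circ_tpm: express.ExpressionMatrix
    mrna_fpkm: express.ExpressionMatrix
    circ_de: dict
    mrna_de: dict
    de_circs: set[str]
    de_mrnas: set[str]
    conservation_hits: dict[str, list]
    conservation: dict
    modules: list[coexpr.CoexModule]
    networks: dict[str, object]
    summary: dict


def call_sequence(genome: dict[str, str], call) -> str:
    seq = genome[call.chrom][call.start - 1 : call.end]
    return revcomp(seq) if call.strand == "-" else seq


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    config.sim.validate()
    config.detect.validate()
    config.modules.validate()
    logger.info("pipeline start: seed=%d", config.seed)

    ds = simdata.simulate_dataset(config.sim)
    logger.info(
        "simulated %d circles over %d samples", len(ds.truth), len(ds.design)
    )

    # --- detection -----------------------------------------------------
    dconf = config.detect
    dconf.anchor_length = config.sim.anchor_length
    index = detect.KmerIndex(ds.genome, dconf.anchor_length)
    transcripts = ds.annotation.transcripts(ds.genome)
    tindex = detect.TranscriptIndex(transcripts, dconf.anchor_length)
    detections = {
        sample: detect.process_sample(
            sample, reads, index, ds.genome, tindex, dconf
        )
        for sample, reads in ds.reads.items()
    }
    calls = [c for d in detections.values() for c in d.calls]
    identified = sorted({c.circ_id for c in calls})
    call_by_id = {}
    for c in calls:
        call_by_id.setdefault(c.circ_id, c)
    logger.info("identified %d circRNAs", len(identified))

    # per-sample distinct junction-read counts (threshold-free) for TPM
    count_conf = detect.DetectConfig(
        anchor_length=dconf.anchor_length, min_distinct_reads=1,
        max_span=dconf.max_span, allow_minus_strand=dconf.allow_minus_strand,
    )
    samples = list(ds.design)
    jc = pd.DataFrame(0, index=identified, columns=samples, dtype=int)
    for sample, det in detections.items():
        for c in detect.call_circrnas(det.candidates, count_conf, sample):
            if c.circ_id in jc.index:
                jc.loc[c.circ_id, sample] = c.supporting_reads

    # --- annotation ----------------------------------------------------
    annotated = [
        annotate.classify_call(call_by_id[cid], ds.annotation) for cid in identified
    ]
    characterization = (
        annotate.summarize_calls(annotated) if annotated else {"n_calls": 0}
    )
    per_stage: dict[str, set[str]] = {st: set() for st in config.sim.stages}
    for c in calls:
        per_stage[ds.design[c.sample_id][0]].add(c.circ_id)
    overlap = annotate.stage_overlap(per_stage)

    # --- expression & DE ----------------------------------------------
    design = express.make_design(ds.design)
    totals = pd.Series({s: len(ds.reads[s]) for s in samples})
    circ_tpm = express.quantify_circ_tpm(jc, totals, design)
    circ_tpm = express.replicate_filter(circ_tpm)
    circ_de = express.all_pairwise_de(circ_tpm, "circRNA")
    de_circs = express.de_feature_set(circ_de)

    gene_ids = sorted(detections[samples[0]].transcript_counts.keys() | {
        g for d in detections.values() for g in d.transcript_counts
    })
    mc = pd.DataFrame(
        {
            s: {g: detections[s].transcript_counts.get(g, 0) for g in gene_ids}
            for s in samples
        }
    )
    lengths = pd.Series(
        {g: ds.annotation.genes[g].spliced_length for g in gene_ids}
    )
    mrna_fpkm = express.quantify_mrna_fpkm(mc, lengths, totals, design)
    mrna_de = express.all_pairwise_de(mrna_fpkm, "mRNA")
    de_mrnas = express.de_feature_set(mrna_de)
    logger.info("DE circRNAs: %d, DE mRNAs: %d", len(de_circs), len(de_mrnas))

    # --- conservation --------------------------------------------------
    hits: dict[str, list] = {}
    for cid in identified:
        seq = call_sequence(ds.genome, call_by_id[cid])
        if len(seq) < conserve.MIN_SPAN:
            continue
        bs = conserve.reassemble_backsplice(seq, circ_id=cid)
        hits[cid] = conserve.search_circdb(bs, ds.circdb, config.e_threshold)
    conservation = conserve.conservation_summary(hits, identified)

    # --- co-expression modules ----------------------------------------
    de_circ_tpm = circ_tpm.values.loc[sorted(de_circs)]
    de_mrna_fpkm = mrna_fpkm.values.loc[sorted(de_mrnas)]
    combined = coexpr.combine_and_filter(de_circ_tpm, de_mrna_fpkm, config.modules)
    if len(combined) >= config.modules.min_module_size:
        modules = coexpr.run_wgcna(
            combined, design, list(config.sim.stages), config.modules
        )
    else:
        modules = [coexpr.CoexModule(coexpr.UNASSIGNED, list(combined.index))]

    # --- ceRNA networks ------------------------------------------------
    circ_seqs = {
        cid: call_sequence(ds.genome, call_by_id[cid]) for cid in sorted(de_circs)
    }
    mrna_seqs = {g: transcripts[g] for g in sorted(de_mrnas)}
    sites = cerna.scan_targets(
        ds.mirnas, circ_seqs, "circRNA", config.max_expectation
    ) + cerna.scan_targets(ds.mirnas, mrna_seqs, "mRNA", config.max_expectation)
    networks = {}
    for m in modules:
        if m.label == coexpr.UNASSIGNED:
            continue
        mod_circs = {x.split("::", 1)[1] for x in m.members if x.startswith("circ::")}
        mod_mrnas = {x.split("::", 1)[1] for x in m.members if x.startswith("mrna::")}
        net = cerna.build_cerna_network(m.label, mod_circs, mod_mrnas, sites)
        if net.number_of_edges():
            networks[m.label] = net

    summary = {
        "seed": config.seed,
        "n_reads_total": int(totals.sum()),
        "n_planted_circles": len(ds.truth),
        "n_identified": len(identified),
        "class_counts": characterization.get("class_counts"),
        "all_stage_intersection": overlap["all_stage_intersection"],
        "n_filtered_circ": int(len(circ_tpm.values)),
        "n_de_circ": len(de_circs),
        "n_de_mrna": len(de_mrnas),
        "n_homologous": conservation["n_homologous"],
        "n_modules": sum(1 for m in modules if m.label != coexpr.UNASSIGNED),
        "module_classes": {
            m.label: m.classification
            for m in modules
            if m.label != coexpr.UNASSIGNED
        },
        "n_networks": len(networks),
        "units": {"circRNA": "TPM", "mRNA": "FPKM",
                  "conservation": "E-value", "cerna": "expectation"},
    }
    result = PipelineResult(
        ds, detections, jc, calls, annotated, characterization, overlap,
        circ_tpm, mrna_fpkm, circ_de, mrna_de, de_circs, de_mrnas, hits,
        conservation, modules, networks, summary,
    )
    if config.write_files and config.outdir:
        write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = io.ensure_dir(config.outdir)
    ds = result.dataset
    io.write_fasta(os.path.join(out, "genome.fa"), ds.genome)
    io.write_gff3(os.path.join(out, "annotation.gff3"), ds.annotation)
    io.write_design(os.path.join(out, "design.tsv"), ds.design)
    io.write_circdb(os.path.join(out, "circdb.fa"), ds.circdb)
    io.write_fasta(os.path.join(out, "mirnas.fa"), ds.mirnas)
    reads_dir = io.ensure_dir(os.path.join(out, "reads"))
    for sample, reads in ds.reads.items():
        io.write_fastq(os.path.join(reads_dir, f"{sample}.fastq"), reads)
    io.write_calls(os.path.join(out, "calls.tsv"), result.calls)
    io.write_matrix(
        os.path.join(out, "circ_tpm.tsv"), result.circ_tpm.values, "TPM"
    )
    io.write_matrix(
        os.path.join(out, "mrna_fpkm.tsv"), result.mrna_fpkm.values, "FPKM"
    )
    for label, net in result.networks.items():
        cerna.export_network(net, os.path.join(out, f"cerna_{label}"))
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
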