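"""Generator invariants: determinism, splice motifs, truth consistency."""

import numpy as np
import pytest

from circleaf import annotate, simdata
from circleaf.genomic import revcomp


def test_identical_config_gives_byte_identical_outputs(small_config):
    a = simdata.simulate_dataset(small_config)
    b = simdata.simulate_dataset(small_config)
    assert a.genome == b.genome
    assert a.reads == b.reads
    assert [(t.circ_id, t.counts) for t in a.truth] == [
        (t.circ_id, t.counts) for t in b.truth
    ]
    assert [(e.entry_id, e.sequence) for e in a.circdb] == [
        (e.entry_id, e.sequence) for e in b.circdb
    ]
    assert a.mirnas == b.mirnas


def test_every_intron_carries_gt_ag_on_gene_strand(small_dataset):
    ds = small_dataset
    n_introns = 0
    for g in ds.annotation:
        chrom = ds.genome[g.chrom]
        for istart, iend in g.introns:
            n_introns += 1
            intron = chrom[istart - 1 : iend]
            if g.strand == "-":
                intron = revcomp(intron)
            assert intron[:2] == "GT" and intron[-2:] == "AG"
    assert n_introns > 0


def test_genes_non_overlapping(small_dataset):
    by_chrom = {}
    for g in small_dataset.annotation:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


def test_infeasible_packing_raises_sizing_error():
    cfg = simdata.SimConfig(
        chromosome_length=12_000, n_chromosomes=1, n_genes=100,
        circ_span_range=(120, 1200),
    )
    with pytest.raises(simdata.SimSizingError):
        simdata.generate_genome(cfg)


def test_class_counts_echo_request(small_dataset):
    counts = {}
    for t in small_dataset.truth:
        counts[t.cls] = counts.get(t.cls, 0) + 1
    cfg = small_dataset.config
    assert counts == {
        "exonic": cfg.n_circ_exonic,
        "intronic": cfg.n_circ_intronic,
        "intergenic": cfg.n_circ_intergenic,
    }


def test_planted_backsplice_motifs_present(small_dataset):
    ds = small_dataset
    for t in ds.truth:
        chrom = ds.genome[t.chrom]
        acc, don = ("AG", "GT") if t.strand == "+" else ("AC", "CT")
        assert chrom[t.start - 3 : t.start - 1] == acc
        assert chrom[t.end : t.end + 2] == don


def test_truth_class_rederived_by_classifier(small_dataset):
    """The annotate module is the oracle for planted class labels."""
    ds = small_dataset
    for t in ds.truth:
        ac = annotate.classify_call(t, ds.annotation)
        assert ac.cls == t.cls
        assert ac.parental_gene == t.parental_gene


def test_junction_read_construction_is_tail_plus_head(small_dataset):
    ds = small_dataset
    t = next(t for t in ds.truth if t.strand == "+")
    chrom = ds.genome[t.chrom]
    k, L = 25, 50
    read = simdata.junction_read(ds.genome, t, k, L)
    assert read == chrom[t.end - k : t.end] + chrom[t.start - 1 : t.start - 1 + L - k]


def test_total_reads_per_sample_equals_depth(small_dataset):
    for sample, reads in small_dataset.reads.items():
        assert len(reads) == small_dataset.config.depth


def test_turnpoint_profile_peaks_at_middle_stage():
    m = simdata.profile_multipliers("turnpoint", 5)
    assert m[2] == m.max() and m[2] > m[0] and m[2] > m[4]
    assert np.all(np.diff(simdata.profile_multipliers("down", 5)) < 0)
    assert np.all(np.diff(simdata.profile_multipliers("up", 5)) > 0)


def test_turnpoint_counts_peak_at_fl3(small_dataset):
    ds = small_dataset
    stages = ds.config.stages
    by_stage = lambda t, st: np.mean(
        [n for s, n in t.counts.items() if ds.design[s][0] == st]
    )
    tps = [t for t in ds.truth if t.profile == "turnpoint"]
    assert tps  # the fixture's profile fractions guarantee turn-point circles
    for t in tps:
        assert by_stage(t, "FL3") > by_stage(t, stages[0])
        assert by_stage(t, "FL3") > by_stage(t, stages[-1])


def test_reference_db_identity_and_decoys(small_dataset):
    ds = small_dataset
    from circleaf.conserve import reassemble_backsplice

    truth_by_id = {t.circ_id: t for t in ds.truth}
    kmers = set()
    for t in ds.truth:
        bs = reassemble_backsplice(simdata.circle_sequence(ds.genome, t))
        for i in range(len(bs.sequence) - 19):
            kmers.add(bs.sequence[i : i + 20])
    n_hom = 0
    for e in ds.circdb:
        if e.source_circ is not None:
            n_hom += 1
            t = truth_by_id[e.source_circ]
            bs = reassemble_backsplice(simdata.circle_sequence(ds.genome, t))
            assert e.sequence == bs.sequence  # db_divergence = 0
        else:
            decoy_kmers = {
                e.sequence[i : i + 20] for i in range(len(e.sequence) - 19)
            }
            assert decoy_kmers.isdisjoint(kmers)
    assert n_hom == int(ds.config.db_homolog_fraction * len(ds.truth))


def test_mirnas_are_21nt_with_designed_scores(small_dataset):
    ds = small_dataset
    assert all(len(s) == 21 for s in ds.mirnas.values())
    assert all(mt.expected_score == 0.0 for mt in ds.mirna_truth)


def test_designed_seed_mismatch_scores_two(small_config):
    """A single designed seed-region mismatch carries a doubled penalty."""
    import dataclasses

    from circleaf import cerna

    cfg = dataclasses.replace(small_config)
    genome, annotation = simdata.generate_genome(cfg)
    genome, truth = simdata.plant_circrnas(genome, annotation, cfg)
    profiles = simdata.assign_gene_profiles(annotation, cfg)
    genome, mirnas, site_truth = simdata.make_mirnas(
        genome, annotation, truth, profiles, cfg, mismatch_positions={0: [5]}
    )
    first = [st for st in site_truth if st.mirna_id == "mir001"]
    assert all(st.expected_score == 2.0 for st in first)
    for st in first:
        if st.target_kind == "circRNA":
            t = next(t for t in truth if t.circ_id == st.target_id)
            seq = simdata.circle_sequence(genome, t)
        else:
            seq = annotation.genes[st.target_id].spliced_sequence(genome)
        got = cerna.score_mirna_target(
            st.mirna_id, mirnas[st.mirna_id], st.target_id, seq, allow_gaps=False
        )
        assert got is not None and got.expectation == 2.0


def test_short_read_length_rejected():
    cfg = simdata.SimConfig(read_length=39)
    with pytest.raises(ValueError):
        cfg.validate()
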