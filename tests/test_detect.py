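"""Anchor-based back-splice detection against an exhaustive oracle."""

import numpy as np
import pytest

from circleaf import detect, simdata
from circleaf.genomic import revcomp

from oracles import brute_force_backsplice, is_linear


def test_kmer_index_hand_example():
    idx = detect.KmerIndex({"c": "ACGTACGT"}, 4)
    assert idx.positions("ACGT") == [("c", 1), ("c", 5)]
    assert idx.positions("NNNN") == []
    # every stored k-mer occurs at every returned position
    for kmer, hits in idx._pos.items():
        for chrom, pos in hits:
            assert "ACGTACGT"[pos - 1 : pos + 3] == kmer


def test_kmer_index_rejects_k_over_chromosome():
    with pytest.raises(ValueError):
        detect.KmerIndex({"c": "ACGT"}, 5)


def test_extract_anchors():
    read = "".join("ACGT"[i % 4] for i in range(50))
    left, right = detect.extract_anchors(read, 20)
    assert left == read[:20] and right == read[-20:]
    l40, r40 = detect.extract_anchors(read[:40], 20)
    assert l40 + r40 == read[:40]  # anchors tile a 40-nt read exactly
    assert detect.extract_anchors(read[:39], 20) is None


def test_triage_linear_cases(small_dataset):
    ds = small_dataset
    idx = detect.KmerIndex(ds.genome, 20)
    tx = ds.annotation.transcripts(ds.genome)
    tidx = detect.TranscriptIndex(tx, 20)
    chrom = ds.genome["chr1"]
    assert detect.triage_linear(chrom[1000:1100], idx, ds.genome, tidx) == "linear"
    # an exon-exon junction read maps to a transcript, not the genome
    g = next(g for g in ds.annotation if len(g.exons) >= 2 and g.strand == "+")
    t = tx[g.gene_id]
    e1 = g.exons[0][1] - g.exons[0][0] + 1
    splice_read = t[e1 - 50 : e1 + 50]
    assert splice_read not in chrom
    assert detect.triage_linear(splice_read, idx, ds.genome, tidx) == "linear"
    # a junction read spanning a planted back-splice is unmapped
    circ = next(c for c in ds.truth if c.strand == "+")
    jread = simdata.junction_read(ds.genome, circ, 50, 100)
    assert detect.triage_linear(jread, idx, ds.genome, tidx) == "unmapped"
    rng = np.random.default_rng(0)
    random_read = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    assert detect.triage_linear(random_read, idx, ds.genome, tidx) == "unmapped"


@pytest.fixture(scope="module")
def junction_genome():
    """A small genome with a planted plus- and minus-strand junction."""
    rng = np.random.default_rng(42)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 3000)))
    s1, e1 = 501, 800
    seq[s1 - 3 : s1 - 1] = "AG"
    seq[e1 : e1 + 2] = "GT"
    s2, e2 = 1501, 1900
    seq[s2 - 3 : s2 - 1] = "AC"
    seq[e2 : e2 + 2] = "CT"
    return {"chr1": "".join(seq)}, (s1, e1), (s2, e2)


def test_detect_backsplice_plus_and_minus(junction_genome):
    genome, (s1, e1), (s2, e2) = junction_genome
    idx = detect.KmerIndex(genome, 20)
    chrom = genome["chr1"]
    k, L = 30, 60
    plus_read = chrom[e1 - k : e1] + chrom[s1 - 1 : s1 - 1 + L - k]
    cand = detect.detect_backsplice(plus_read, idx, genome)
    assert (cand.start, cand.end, cand.strand) == (s1, e1, "+")
    assert cand.junction_offset == k and cand.splice_motif == "AG|GT"
    minus_read = revcomp(chrom[e2 - k : e2] + chrom[s2 - 1 : s2 - 1 + L - k])
    cand = detect.detect_backsplice(minus_read, idx, genome)
    assert (cand.start, cand.end, cand.strand) == (s2, e2, "-")


def test_forward_order_anchors_give_none(junction_genome):
    genome, _, _ = junction_genome
    idx = detect.KmerIndex(genome, 20)
    linear_read = genome["chr1"][100:160]
    cand, reason = detect.detect_backsplice(
        linear_read, idx, genome, with_reason=True
    )
    assert cand is None and reason == "forward_orientation"


def test_duplicated_anchor_rejected_as_ambiguous():
    rng = np.random.default_rng(3)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    s, e = 301, 600
    seq = list(base)
    seq[s - 3 : s - 1] = "AG"
    seq[e : e + 2] = "GT"
    chrom = "".join(seq)
    k, L = 30, 60
    read = chrom[e - k : e] + chrom[s - 1 : s - 1 + L - k]
    # duplicate the left anchor elsewhere -> two placements
    dup = chrom[:1500] + read[:20] + chrom[1520:]
    genome = {"chr1": dup}
    assert brute_force_backsplice(read, genome) is None
    cand, reason = detect.detect_backsplice(
        read, detect.KmerIndex(genome, 20), genome, with_reason=True
    )
    assert cand is None and reason == "ambiguous_anchor"


def test_call_circrnas_distinct_read_rule():
    mk = lambda seq, off: detect.BackspliceCandidate(
        "chr1", 100, 400, "+", "r", seq, off, "AG|GT"
    )
    config = detect.DetectConfig(min_distinct_reads=2)
    assert detect.call_circrnas([mk("A" * 60, 25)], config) == []
    # duplicates (same sequence and offset) are one distinct read
    assert detect.call_circrnas([mk("A" * 60, 25), mk("A" * 60, 25)], config) == []
    calls = detect.call_circrnas(
        [mk("A" * 60, 25), mk("A" * 60, 25), mk("C" * 60, 30)], config
    )
    assert len(calls) == 1 and calls[0].supporting_reads == 2
    assert calls[0].circ_id == "chr1:100|400"


def test_calls_invariant_under_read_order(small_dataset):
    ds = small_dataset
    idx = detect.KmerIndex(ds.genome, 20)
    tidx = detect.TranscriptIndex(ds.annotation.transcripts(ds.genome), 20)
    sample = list(ds.reads)[0]
    reads = list(ds.reads[sample])
    fwd = detect.process_sample(sample, reads, idx, ds.genome, tidx)
    rev = detect.process_sample(sample, reads[::-1], idx, ds.genome, tidx)
    key = lambda c: (c.circ_id, c.strand, c.supporting_reads)
    assert sorted(map(key, fwd.calls)) == sorted(map(key, rev.calls))
    order = [(c.chrom, c.start, c.end) for c in fwd.calls]
    assert order == sorted(order)  # sorted by chrom then start


def test_detector_matches_brute_force_oracle_on_random_genome():
    """Accept/reject and coordinates agree with exhaustive enumeration."""
    cfg = simdata.SimConfig(
        seed=11, n_chromosomes=1, chromosome_length=5_000, n_genes=4,
        exons_per_gene=(2, 3), exon_length_range=(80, 150),
        intron_length_range=(60, 120), intergenic_gap_range=(80, 200),
        n_circ_exonic=3, n_circ_intronic=1, n_circ_intergenic=2,
        circ_span_range=(80, 300), read_length=60, depth=60,
        base_junction_rate=5.0, n_mirnas=2, n_sponge_triples=0, n_db_decoys=2,
    )
    ds = simdata.simulate_dataset(cfg)
    idx = detect.KmerIndex(ds.genome, 20)
    tx = ds.annotation.transcripts(ds.genome)
    rng = np.random.default_rng(99)
    reads = [seq for sample in ds.reads.values() for _rid, seq in sample][:150]
    reads += [
        "".join("ACGT"[i] for i in rng.integers(0, 4, 60)) for _ in range(50)
    ]
    n_accepted = 0
    for read in reads[:200]:
        if is_linear(read, ds.genome, tx):
            continue
        expected = brute_force_backsplice(read, ds.genome)
        got = detect.detect_backsplice(read, idx, ds.genome)
        if expected is None:
            assert got is None
        else:
            n_accepted += 1
            chrom, s, e, strand = expected
            assert got is not None
            assert (got.chrom, got.start, got.end, got.strand) == (chrom, s, e, strand)
    assert n_accepted >= 20  # the read set must actually exercise junctions
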