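"""Back-splicing-sequence reassembly and cross-species conservation search.

A circRNA's *back-splicing sequence* is a linear, junction-centered
representation of the circle: for genomic spans over 200 nt it is the last
100 nt followed by the first 100 nt (junction exactly in the middle); for
spans of 51-200 nt the second half of the sequence is moved in front of the
first half, so the output keeps the full length with the junction in the
middle. Queries are searched against a database of such sequences with a
seed-filtered local alignment under blastn-style scoring (match +2, mismatch
-3, gap open 5, gap extend 2) and a Karlin-Altschul E-value threshold of
1e-5; a hit *spans* a junction when the theoretical junction position falls
strictly inside the aligned interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

# Karlin-Altschul nucleotide constants for +2/-3 scoring (blastn defaults)
KA_LAMBDA = 0.625
KA_K = 0.41
E_THRESHOLD = 1e-5
SEED_LENGTH = 11

MIN_SPAN = 51
MAX_BS_LENGTH = 200


@dataclass
class BackSpliceSeq:
    """Junction-centered linear representation of a circRNA."""

    circ_id: str
    sequence: str
    junction_offset: int  # bases preceding the head-tail junction
    source_length: int


@dataclass
class ConservationHit:
    query_id: str
    subject_id: str
    identity: float  # percent over alignment columns
    alignment_length: int  # columns, gaps included
    e_value: float
    score: int  # raw local-alignment score
    query_interval: tuple[int, int]  # 1-based inclusive on the query
    subject_interval: tuple[int, int]
    spans_query_junction: bool | None = None
    spans_subject_junction: bool | None = None


def reassemble_backsplice(sequence: str, circ_id: str = "") -> BackSpliceSeq:
    """Reassemble a circle's genomic sequence around its junction.

    L > 200: last 100 nt + first 100 nt (junction offset 100).
    51 <= L <= 200: tail = last ceil(L/2) nt moved in front of the head
    (junction offset ceil(L/2), full length preserved).
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("back-splice reassembly requires an ACGT sequence")
    L = len(seq)
    if L < MIN_SPAN:
        raise ValueError(f"genomic sequence shorter than {MIN_SPAN} nt: {L}")
    if L > MAX_BS_LENGTH:
        out = seq[-100:] + seq[:100]
        return BackSpliceSeq(circ_id, out, 100, L)
    tail_len = math.ceil(L / 2)
    out = seq[L - tail_len :] + seq[: L - tail_len]
    return BackSpliceSeq(circ_id, out, tail_len, L)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    # blast convention: a gap of length g costs open + g*extend
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def e_value(raw_score: float, m: int, n: int) -> float:
    """Karlin-Altschul expect for a raw score with query length m over a
    database of n residues (no effective-length correction)."""
    return m * n * 2.0 ** (-bit_score(raw_score))


def _hit_from_alignment(alignment, query_id, subject_id, m, n) -> ConservationHit:
    # biopython alignment.aligned is (target blocks, query blocks); we align
    # with target = subject, query = reassembled query
    blocks_s, blocks_q = alignment.aligned
    qstart, qend = int(blocks_q[0][0]) + 1, int(blocks_q[-1][1])
    sstart, send = int(blocks_s[0][0]) + 1, int(blocks_s[-1][1])
    matches = 0
    aligned_cols = 0
    q, s = alignment.query, alignment.target
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        for i in range(qe - qs):
            aligned_cols += 1
            if q[qs + i] == s[ss + i]:
                matches += 1
    # count gap columns between blocks
    gap_cols = 0
    for k in range(1, len(blocks_q)):
        gap_cols += (blocks_q[k][0] - blocks_q[k - 1][1]) + (
            blocks_s[k][0] - blocks_s[k - 1][1]
        )
    length = aligned_cols + gap_cols
    return ConservationHit(
        query_id,
        subject_id,
        round(100.0 * matches / max(1, length), 2),
        length,
        e_value(alignment.score, m, n),
        int(alignment.score),
        (qstart, qend),
        (sstart, send),
    )


def _seeds(seq: str, k: int = SEED_LENGTH) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search_circdb(
    query: BackSpliceSeq,
    database: list,
    e_threshold: float = E_THRESHOLD,
    seed_length: int = SEED_LENGTH,
) -> list[ConservationHit]:
    """Local-alignment search of one reassembled query against the database.

    ``database`` entries need ``entry_id``, ``sequence`` and (optionally)
    ``junction_offset`` attributes. Subjects sharing no ``seed_length``-mer
    with the query are skipped; survivors get a full local alignment, scored
    hits are kept below the E-value threshold and sorted by E ascending.
    """
    if not database:
        raise ValueError("empty reference database")
    n_total = sum(len(d.sequence) for d in database)
    m = len(query.sequence)
    qseeds = _seeds(query.sequence, seed_length)
    aligner = _aligner()
    hits = []
    for entry in database:
        if qseeds.isdisjoint(_seeds(entry.sequence, seed_length)):
            continue
        alns = aligner.align(entry.sequence, query.sequence)
        if len(alns) == 0 or alns[0].score <= 0:
            continue
        aln = alns[0]
        hit = _hit_from_alignment(aln, query.circ_id, entry.entry_id, m, n_total)
        if hit.e_value < e_threshold:
            hit = flag_junction_span(
                hit, query, getattr(entry, "junction_offset", None)
            )
            hits.append(hit)
    hits.sort(key=lambda h: (h.e_value, h.subject_id))
    return hits


def _spans(interval: tuple[int, int], junction_offset: int) -> bool:
    # the junction sits between positions offset and offset+1; it is spanned
    # when strictly interior to the aligned interval
    start, end = interval
    return start <= junction_offset < end


def flag_junction_span(
    hit: ConservationHit,
    query: BackSpliceSeq,
    subject_junction_offset: int | None,
) -> ConservationHit:
    """Set the query/subject junction-span flags on a hit.

    An unknown subject junction offset leaves the subject flag indeterminate
    (None).
    """
    hit.spans_query_junction = _spans(hit.query_interval, query.junction_offset)
    hit.spans_subject_junction = (
        _spans(hit.subject_interval, subject_junction_offset)
        if subject_junction_offset is not None
        else None
    )
    return hit


def conservation_summary(
    hits_per_query: dict[str, list[ConservationHit]], all_query_ids: list[str]
) -> dict:
    """Counts/fractions of homologous queries and the junction-span classes."""
    homologous = [q for q in all_query_ids if hits_per_query.get(q)]
    span_q = [
        q for q in homologous
        if any(h.spans_query_junction for h in hits_per_query[q])
    ]
    span_s = [
        q for q in homologous
        if any(h.spans_subject_junction for h in hits_per_query[q])
    ]
    span_both = [
        q for q in homologous
        if any(
            h.spans_query_junction and h.spans_subject_junction
            for h in hits_per_query[q]
        )
    ]
    all_hits = [h for hs in hits_per_query.values() for h in hs]
    identities = [h.identity for h in all_hits]
    lengths = [h.alignment_length for h in all_hits]
    n = len(all_query_ids)
    return {
        "n_queries": n,
        "n_homologous": len(homologous),
        "fraction_homologous": len(homologous) / n if n else 0.0,
        "n_span_query": len(span_q),
        "n_span_subject": len(span_s),
        "n_span_both": len(span_both),
        "identity_range": (min(identities), max(identities)) if identities else None,
        "alignment_length_range": (min(lengths), max(lengths)) if lengths else None,
    }
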