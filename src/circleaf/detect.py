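"""Back-splice junction detection from single-end reads.

The procedure mirrors split-anchor circRNA callers: reads that fail a linear
mapping triage have a 20-nt anchor taken from each end; anchors placed at a
unique genomic position in *reversed* orientation (left anchor downstream of
the right anchor) indicate a head-to-tail junction. Both anchor alignments
are extended toward the read interior until the read is fully explained by
two genomic blocks ``genome[j..e] + genome[s..i]``, and the breakpoint is
accepted only when the canonical splice dinucleotides flank the circle on its
annotated strand (AG immediately before ``s``, GT immediately after ``e``;
minus-strand circles show AC/CT on the plus genome). A circRNA is called per
sample when at least ``min_distinct_reads`` distinct back-spliced reads
support the same junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genomic import circ_id, revcomp


@dataclass
class DetectConfig:
    anchor_length: int = 20
    min_distinct_reads: int = 2
    max_span: int = 100_000
    allow_minus_strand: bool = True
    max_mismatches: int = 0  # tolerated in linear triage extension

    def validate(self) -> None:
        if self.anchor_length < 10:
            raise ValueError("anchor_length must be >= 10")
        if self.min_distinct_reads < 1:
            raise ValueError("min_distinct_reads must be >= 1")


@dataclass
class BackspliceCandidate:
    """A single read explained as a head-to-tail junction."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    read_id: str
    read_seq: str  # oriented to the annotated strand of the circle
    junction_offset: int  # bases of the oriented read preceding the junction
    splice_motif: str  # acceptor|donor on the annotated strand, e.g. "AG|GT"
    multi_breakpoint: bool = False


@dataclass
class CircCall:
    """A called circRNA in one sample."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str
    supporting_reads: int


class KmerIndex:
    """Exact k-mer -> 1-based plus-strand positions over a genome dict.

    Minus-strand placements are resolved by querying the reverse complement;
    k-mers containing non-ACGT characters are not indexed and never match.
    """

    def __init__(self, genome: dict[str, str], k: int):
        if k > min(len(s) for s in genome.values()):
            raise ValueError("k exceeds the shortest chromosome")
        self.k = k
        self._pos: dict[str, list[tuple[str, int]]] = {}
        allowed = frozenset("ACGT")
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if allowed.issuperset(kmer):
                    self._pos.setdefault(kmer, []).append((chrom, i + 1))

    def positions(self, kmer: str) -> list[tuple[str, int]]:
        """Plus-strand occurrences of ``kmer`` (chrom, 1-based position)."""
        return self._pos.get(kmer, [])

    def placements(self, kmer: str) -> list[tuple[str, int, str]]:
        """Occurrences on both strands as (chrom, plus-strand position, strand)."""
        out = [(c, p, "+") for c, p in self.positions(kmer)]
        rc = revcomp(kmer)
        out += [(c, p, "-") for c, p in self.positions(rc)]
        return out

    def unique_placement(self, kmer: str) -> tuple[str, int, str] | None:
        """The single both-strand placement, or None if absent/ambiguous."""
        pl = self.placements(kmer)
        return pl[0] if len(pl) == 1 else None


class TranscriptIndex(KmerIndex):
    """KmerIndex over spliced transcript sequences (sense orientation)."""

    def __init__(self, transcripts: dict[str, str], k: int):
        usable = {t: s for t, s in transcripts.items() if len(s) >= k}
        super().__init__(usable or {"_": "A" * k}, k)
        self.transcripts = transcripts


def extract_anchors(read: str, anchor_length: int) -> tuple[str, str] | None:
    """First and last ``anchor_length`` bases; None if the read is too short."""
    if len(read) < 2 * anchor_length:
        return None
    return read[:anchor_length], read[-anchor_length:]


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _matches_genome(read: str, index: KmerIndex, genome: dict[str, str], mm: int) -> bool:
    for oriented in (read, revcomp(read)):
        seed = oriented[: index.k]
        for chrom, pos in index.positions(seed):
            ref = genome[chrom][pos - 1 : pos - 1 + len(oriented)]
            if len(ref) == len(oriented) and _mismatches(oriented, ref, mm) <= mm:
                return True
    return False


def match_transcript(
    read: str, tindex: TranscriptIndex, mm: int = 0
) -> str | None:
    """Transcript id whose spliced sequence contains the read, or None.

    Ambiguous matches resolve to the lexicographically smallest id.
    """
    hits = []
    seed = read[: tindex.k]
    for tid, pos in tindex.positions(seed):
        ref = tindex.transcripts.get(tid, "")[pos - 1 : pos - 1 + len(read)]
        if len(ref) == len(read) and _mismatches(read, ref, mm) <= mm:
            hits.append(tid)
    return min(hits) if hits else None


def triage_linear(
    read: str,
    index: KmerIndex,
    genome: dict[str, str],
    transcript_index: TranscriptIndex | None = None,
    max_mismatches: int = 0,
) -> str:
    """'linear' if the read matches the genome contiguously (either strand)
    or an annotated spliced transcript; otherwise 'unmapped'."""
    if _matches_genome(read, index, genome, max_mismatches):
        return "linear"
    if transcript_index is not None and match_transcript(
        read, transcript_index, max_mismatches
    ):
        return "linear"
    return "unmapped"


_MOTIFS = {"+": ("AG", "GT"), "-": ("AC", "CT")}


def _motif_ok(chromseq: str, s: int, e: int, strand: str) -> bool:
    acc, don = _MOTIFS[strand]
    return (
        s >= 3
        and e + 2 <= len(chromseq)
        and chromseq[s - 3 : s - 1] == acc
        and chromseq[e : e + 2] == don
    )


def detect_backsplice(
    read: str,
    index: KmerIndex,
    genome: dict[str, str],
    config: DetectConfig | None = None,
    read_id: str = "",
    with_reason: bool = False,
):
    """Explain one unmapped read as a back-splice junction, or return None.

    Both orientations of the read are tried (plus first); anchors must place
    uniquely across both strands, in reversed orientation, and the extension
    must explain the read exactly with a valid splice motif. When several
    breakpoints are valid the smallest start coordinate wins and the
    candidate is flagged ``multi_breakpoint``.
    """
    config = config or DetectConfig()
    A = config.anchor_length
    L = len(read)
    reasons: list[str] = []
    orientations = ["+", "-"] if config.allow_minus_strand else ["+"]
    result = None
    for strand in orientations:
        seq = read if strand == "+" else revcomp(read)
        anchors = extract_anchors(seq, A)
        if anchors is None:
            reasons.append("short_read")
            continue
        left, right = anchors
        pl, pr = index.unique_placement(left), index.unique_placement(right)
        if pl is None or pr is None:
            n_l, n_r = len(index.placements(left)), len(index.placements(right))
            reasons.append(
                "ambiguous_anchor" if max(n_l, n_r) > 1 else "unaligned_anchor"
            )
            continue
        if pl[2] != "+" or pr[2] != "+" or pl[0] != pr[0]:
            reasons.append("strand_or_chrom_mismatch")
            continue
        chrom, j = pl[0], pl[1]
        p_r = pr[1]
        if j <= p_r:
            reasons.append("forward_orientation")
            continue
        chromseq = genome[chrom]
        hits: list[tuple[int, int, int]] = []
        for k in range(A, L - A + 1):
            e = j + k - 1
            s = p_r + A - 1 - (L - k) + 1
            if s < 1 or e > len(chromseq) or e - s + 1 > config.max_span or s >= e:
                continue
            if (
                seq[:k] == chromseq[j - 1 : e]
                and seq[k:] == chromseq[s - 1 : s + (L - k) - 1]
                and _motif_ok(chromseq, s, e, strand)
            ):
                hits.append((s, e, k))
        if not hits:
            reasons.append("no_breakpoint")
            continue
        s, e, k = min(hits)  # smallest start wins (deterministic tie-break)
        result = BackspliceCandidate(
            chrom, s, e, strand, read_id, seq, k, "AG|GT",
            multi_breakpoint=len(hits) > 1,
        )
        break
    if with_reason:
        if result is not None:
            return result, "ok"
        for tag in ("ambiguous_anchor", "forward_orientation", "no_breakpoint"):
            if tag in reasons:
                return None, tag
        return None, reasons[-1] if reasons else "no_orientation"
    return result


def call_circrnas(
    candidates: list[BackspliceCandidate],
    config: DetectConfig | None = None,
    sample_id: str = "",
) -> list[CircCall]:
    """Group one sample's candidates by junction and apply the distinct-read
    filter: a circRNA is called when supported by at least
    ``min_distinct_reads`` distinct (read sequence, junction offset) pairs."""
    config = config or DetectConfig()
    grouped: dict[tuple[str, int, int, str], set[tuple[str, int]]] = {}
    for c in candidates:
        grouped.setdefault((c.chrom, c.start, c.end, c.strand), set()).add(
            (c.read_seq, c.junction_offset)
        )
    calls = []
    for (chrom, s, e, strand), distinct in sorted(grouped.items()):
        if len(distinct) >= config.min_distinct_reads:
            calls.append(
                CircCall(circ_id(chrom, s, e), chrom, s, e, strand, sample_id, len(distinct))
            )
    return calls


@dataclass
class SampleDetection:
    """Per-sample detection output: calls plus linear-read attribution."""

    sample_id: str
    calls: list[CircCall]
    candidates: list[BackspliceCandidate]
    transcript_counts: dict[str, int] = field(default_factory=dict)
    n_linear: int = 0
    n_unmapped: int = 0


def process_sample(
    sample_id: str,
    reads: list[tuple[str, str]],
    index: KmerIndex,
    genome: dict[str, str],
    transcript_index: TranscriptIndex | None = None,
    config: DetectConfig | None = None,
) -> SampleDetection:
    """Triage + anchor detection + calling for one sample's reads.

    Linear reads matching a spliced transcript are attributed to it so mRNA
    abundance can be quantified from the same data.
    """
    config = config or DetectConfig()
    out = SampleDetection(sample_id, [], [])
    for read_id, seq in reads:
        if _matches_genome(seq, index, genome, config.max_mismatches):
            out.n_linear += 1
            tid = (
                match_transcript(seq, transcript_index, config.max_mismatches)
                if transcript_index is not None
                else None
            )
            if tid:
                out.transcript_counts[tid] = out.transcript_counts.get(tid, 0) + 1
            continue
        if transcript_index is not None:
            tid = match_transcript(seq, transcript_index, config.max_mismatches)
            if tid:
                out.n_linear += 1
                out.transcript_counts[tid] = out.transcript_counts.get(tid, 0) + 1
                continue
        out.n_unmapped += 1
        cand = detect_backsplice(seq, index, genome, config, read_id=read_id)
        if cand is not None:
            out.candidates.append(cand)
    out.calls = call_circrnas(out.candidates, config, sample_id)
    return out
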