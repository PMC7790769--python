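"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's k-mer index and aligner machinery:
back-splice explanation is an exhaustive enumeration over breakpoints via
substring scanning, and local alignment is a direct Gotoh dynamic program.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _occurrences(hay: str, needle: str) -> list[int]:
    """All 0-based occurrence positions of needle in hay."""
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def count_placements(genome: dict[str, str], kmer: str) -> int:
    """Occurrences of a k-mer across both strands of the genome."""
    n = 0
    for seq in genome.values():
        n += len(_occurrences(seq, kmer))
        n += len(_occurrences(seq, rc(kmer)))
    return n


def is_linear(read: str, genome: dict[str, str], transcripts: dict[str, str]) -> bool:
    """Contiguous genome match on either strand, or spliced-transcript match."""
    for seq in genome.values():
        if read in seq or rc(read) in seq:
            return True
    return any(read in t for t in transcripts.values())


_MOTIFS = {"+": ("AG", "GT"), "-": ("AC", "CT")}


def brute_force_backsplice(
    read: str, genome: dict[str, str], anchor_length: int = 20
) -> tuple[str, int, int, str] | None:
    """Exhaustive (s, e, k) enumeration of a back-splice explanation.

    Returns (chrom, start, end, strand) with 1-based inclusive coordinates,
    or None. Mirrors the method's contract: both end anchors must place
    uniquely across both genome strands, the read must decompose as
    genome[e-k+1..e] + genome[s..s+L-k-1] for some k with both anchors
    flanking the junction, the splice motif must be present (AG..GT on the
    annotated strand), and the smallest start wins.
    """
    A, L = anchor_length, len(read)
    if L < 2 * A:
        return None
    for strand in ("+", "-"):
        seq = read if strand == "+" else rc(read)
        if (
            count_placements(genome, seq[:A]) != 1
            or count_placements(genome, seq[-A:]) != 1
        ):
            continue
        acc, don = _MOTIFS[strand]
        found: list[tuple[str, int, int]] = []
        for chrom, g in genome.items():
            for k in range(A, L - A + 1):
                tail, head = seq[:k], seq[k:]
                tail_pos = _occurrences(g, tail)
                head_pos = _occurrences(g, head)
                for tp in tail_pos:
                    e = tp + k  # 1-based end of the tail block
                    for hp in head_pos:
                        s = hp + 1
                        if s >= e:
                            continue
                        if (
                            s >= 3
                            and e + 2 <= len(g)
                            and g[s - 3 : s - 1] == acc
                            and g[e : e + 2] == don
                        ):
                            found.append((chrom, s, e))
        if found:
            chrom, s, e = min(found, key=lambda t: (t[1], t[2], t[0]))
            return chrom, s, e, strand
    return None


def smith_waterman(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Best local-alignment score, affine gaps costing open + len*extend."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    best = 0
    h_prev = [0] * (m + 1)
    e_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        h_cur = [0] * (m + 1)
        e_cur = [NEG] * (m + 1)
        f = NEG
        for j in range(1, m + 1):
            e_cur[j] = max(h_prev[j] - gap_open - gap_extend, e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - gap_open - gap_extend, f - gap_extend)
            diag = h_prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            h_cur[j] = max(0, diag, e_cur[j], f)
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev, e_prev = h_cur, e_cur
    return best
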