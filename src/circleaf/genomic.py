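"""Shared genomic primitives: sequences, genes, annotations, circRNA ids.

Coordinates are 1-based inclusive throughout, matching GFF3. A genome is a
plain ``dict`` mapping chromosome name to an uppercase ACGT string; gene
models are lightweight dataclasses with exon blocks sorted by start.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CIRC_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)\|(?P<end>\d+)$")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (U is not accepted; use T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def circ_id(chrom: str, start: int, end: int) -> str:
    """Serialize a back-splice locus as ``chrom:start|end`` (no separators)."""
    return f"{chrom}:{start}|{end}"


def parse_circ_id(cid: str) -> tuple[str, int, int]:
    """Parse ``chrom:start|end`` back to coordinates.

    Thousands separators (as printed in some reports) are stripped.
    """
    m = _CIRC_ID_RE.match(cid.replace(",", ""))
    if m is None:
        raise ValueError(f"not a circRNA id: {cid!r}")
    return m.group("chrom"), int(m.group("start")), int(m.group("end"))


@dataclass
class Gene:
    """A gene model with one implicit transcript made of its exons.

    ``exons`` are (start, end) 1-based inclusive blocks on the + strand
    coordinate system, sorted by start regardless of gene strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intron blocks between consecutive exons (may be empty)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """mRNA sequence: exons concatenated, reverse-complemented for '-'."""
        chrom = genome[self.chrom]
        seq = "".join(chrom[s - 1 : e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


class Annotation:
    """A set of non-overlapping gene models with fast interval lookup."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts = {
            chrom: [g.start for g in gl] for chrom, gl in self._by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        for gl in self._by_chrom.values():
            yield from gl

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span intersects [start, end] on ``chrom``."""
        gl = self._by_chrom.get(chrom, [])
        if not gl:
            return []
        i = bisect.bisect_right(self._starts[chrom], end)
        hits = []
        # genes are non-overlapping and sorted; scan left from insertion point
        for g in gl[:i][::-1]:
            if g.end < start:
                break
            hits.append(g)
        return hits[::-1]

    def transcripts(self, genome: dict[str, str]) -> dict[str, str]:
        """Spliced mRNA sequence per gene id."""
        return {g.gene_id: g.spliced_sequence(genome) for g in self}
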