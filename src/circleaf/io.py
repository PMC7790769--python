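"""File formats: FASTA/FASTQ (via Biopython), GFF3, TSV matrices.

GFF3 uses 1-based inclusive coordinates and the gene/mRNA/exon feature
dialect with mandatory ID/Parent attributes; FASTQ is Phred+33. All writers
round-trip losslessly with the matching readers.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomic import Annotation, Gene
from .simdata import CircDbEntry


class ParseError(ValueError):
    """Malformed record, with a 1-based line number."""

    def __init__(self, path: str, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.line = line


def write_fasta(path: str, records: dict[str, str], descriptions: dict[str, str] | None = None):
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records.items()
    ]
    SeqIO.write(recs, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}


def write_fastq(path: str, reads: list[tuple[str, str]], quality: int = 40):
    recs = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, path, "fastq")


def read_fastq(path: str) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fastq")]


def write_gff3(path: str, annotation: Annotation):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            fh.write(
                f"{g.chrom}\tcircleaf\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tcircleaf\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tcircleaf\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )


def _attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str) -> Annotation:
    """Read the gene/mRNA/exon dialect back into an Annotation."""
    genes: dict[str, Gene] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, ln, f"expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr = cols
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ParseError(path, ln, "non-integer coordinates") from None
            if e < s:
                raise ParseError(path, ln, f"end < start ({e} < {s})")
            attrs = _attrs(attr)
            if ftype == "gene":
                if "ID" not in attrs:
                    raise ParseError(path, ln, "gene without ID attribute")
                genes[attrs["ID"]] = Gene(attrs["ID"], chrom, strand, s, e, [])
            elif ftype == "mRNA":
                if "Parent" not in attrs or "ID" not in attrs:
                    raise ParseError(path, ln, "mRNA needs ID and Parent")
                mrna_to_gene[attrs["ID"]] = attrs["Parent"]
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(path, ln, "exon without Parent")
                gid = mrna_to_gene.get(parent, parent)
                if gid not in genes:
                    raise ParseError(path, ln, f"exon parent unknown: {parent}")
                genes[gid].exons.append((s, e))
    for g in genes.values():
        g.exons.sort()
    return Annotation(list(genes.values()))


def write_matrix(path: str, df: pd.DataFrame, unit: str = ""):
    """TSV matrix with a unit-bearing index header, 6-decimal floats."""
    out = df.copy()
    out.index.name = f"feature_id[{unit}]" if unit else "feature_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_matrix(path: str) -> tuple[pd.DataFrame, str]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    name = df.index.name or ""
    unit = name[name.find("[") + 1 : name.rfind("]")] if "[" in name else ""
    df.index.name = None
    return df, unit


def write_circdb(path: str, entries: list[CircDbEntry]):
    write_fasta(
        path,
        {e.entry_id: e.sequence for e in entries},
        {e.entry_id: f"junction_offset={e.junction_offset}" for e in entries},
    )


def read_circdb(path: str) -> list[CircDbEntry]:
    entries = []
    for r in SeqIO.parse(path, "fasta"):
        off = None
        for tok in r.description.split():
            if tok.startswith("junction_offset="):
                off = int(tok.split("=", 1)[1])
        entries.append(
            CircDbEntry(r.id, str(r.seq).upper(), off if off is not None else len(r.seq) // 2)
        )
    return entries


def write_design(path: str, design: dict[str, tuple[str, int]]):
    with open(path, "w") as fh:
        fh.write("sample\tstage\treplicate\n")
        for sample, (stage, rep) in design.items():
            fh.write(f"{sample}\t{stage}\t{rep}\n")


def read_design(path: str) -> dict[str, tuple[str, int]]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample\t"):
            raise ParseError(path, 1, "missing design header")
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(path, ln, "expected 3 columns")
            out[parts[0]] = (parts[1], int(parts[2]))
    return out


def write_calls(path: str, calls: list) -> None:
    """Per-sample circRNA calls as TSV (one row per call and sample)."""
    with open(path, "w") as fh:
        fh.write("circ_id\tchrom\tstart\tend\tstrand\tsample\tsupporting_reads\n")
        for c in calls:
            fh.write(
                f"{c.circ_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t"
                f"{c.sample_id}\t{c.supporting_reads}\n"
            )


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
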