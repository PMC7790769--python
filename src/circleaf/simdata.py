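"""Synthetic staged RNA-seq dataset with planted circRNAs and full truth.

Emulates a flag-leaf senescence style design: a multi-chromosome genome with
GT/AG-spliced genes, planted exonic / intronic / intergenic circRNAs whose
back-splice junctions are flanked by the canonical acceptor/donor
dinucleotides (AG before the circle start, GT after the circle end, on the
annotated strand), single-end reads over five stages x three replicates with
continuous-down / continuous-up / turn-point / flat abundance profiles, a
homolog-seeded reference database of back-splicing sequences, and miRNAs with
designed binding sites in circRNAs and co-profiled mRNAs.

Every random draw is taken from a substream derived from ``SimConfig.seed``,
so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genomic import Annotation, Gene, circ_id, revcomp

_BASES = "ACGT"


class SimSizingError(ValueError):
    """Requested features do not fit on the requested chromosomes."""


class PlacementError(ValueError):
    """No valid placement found after bounded retries."""


PROFILES = ("down", "up", "turnpoint", "flat")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults mirror the emulated design: five stages (booting to dough,
    FL1..FL5) with three biological replicates, 100-nt reads, an exon-heavy
    circRNA class mix, and Poisson junction-read counts whose expectation is
    scaled multiplicatively per stage by the planted profile.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 60_000
    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length_range: tuple[int, int] = (120, 350)
    intron_length_range: tuple[int, int] = (90, 400)
    intergenic_gap_range: tuple[int, int] = (150, 600)
    n_circ_exonic: int = 30
    n_circ_intronic: int = 8
    n_circ_intergenic: int = 12
    circ_span_range: tuple[int, int] = (120, 1200)
    read_length: int = 100
    anchor_length: int = 20
    error_rate: float = 0.0
    stages: tuple[str, ...] = ("FL1", "FL2", "FL3", "FL4", "FL5")
    replicates_per_stage: int = 3
    depth: int = 20_000
    base_junction_rate: float = 35.0
    profile_fractions: dict[str, float] = field(
        default_factory=lambda: {"down": 0.2, "up": 0.2, "turnpoint": 0.2, "flat": 0.4}
    )
    profile_assignment: dict[str, str] | None = None
    minus_strand_fraction: float = 0.3
    db_homolog_fraction: float = 0.2
    db_divergence: float = 0.0
    n_db_decoys: int = 40
    n_mirnas: int = 8
    n_sponge_triples: int = 4
    mirna_length: int = 21

    def validate(self) -> None:
        if self.read_length < 2 * self.anchor_length:
            raise ValueError(
                "read_length must be at least twice the anchor length "
                f"({self.read_length} < {2 * self.anchor_length})"
            )
        if self.chromosome_length < 10 * self.circ_span_range[1]:
            raise SimSizingError(
                "chromosome_length must be >= 10x the maximum circRNA span"
            )
        if self.circ_span_range[0] < 51:
            raise ValueError("minimum circRNA span is 51 nt")
        for p in (self.error_rate, self.db_divergence, self.minus_strand_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if abs(sum(self.profile_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("profile_fractions must sum to 1")


@dataclass
class TruthRecord:
    """One planted circRNA with its ground-truth coordinates and counts."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cls: str  # exonic | intronic | intergenic
    parental_gene: str | None
    profile: str
    counts: dict[str, int] = field(default_factory=dict)
    db_homolog: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class CircDbEntry:
    """A reference-database back-splicing sequence (homolog or decoy)."""

    entry_id: str
    sequence: str
    junction_offset: int
    source_circ: str | None = None


@dataclass
class MirnaSiteTruth:
    """A designed miRNA binding site and its expected expectation score."""

    mirna_id: str
    target_id: str
    target_kind: str  # circRNA | mRNA
    expected_score: float
    position: int  # 0-based offset of the site on the target sequence


def profile_multipliers(profile: str, n_stages: int) -> np.ndarray:
    """Per-stage multiplicative factors for the expected junction-read rate.

    down: monotone decreasing (8-fold FL1->FL5); up: the mirror image;
    turnpoint: peaks at the middle stage (8-fold against both ends);
    flat: constant 1.
    """
    lo, hi = 0.125, 1.0
    if profile == "flat":
        return np.ones(n_stages)
    if profile == "down":
        return np.geomspace(hi, lo, n_stages)
    if profile == "up":
        return np.geomspace(lo, hi, n_stages)
    if profile == "turnpoint":
        mid = n_stages // 2
        left = np.geomspace(lo, hi, mid + 1)
        right = np.geomspace(hi, lo, n_stages - mid)
        return np.concatenate([left, right[1:]])
    raise ValueError(f"unknown profile: {profile}")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def generate_genome(config: SimConfig) -> tuple[dict[str, str], Annotation]:
    """Random genome plus non-overlapping gene models with GT/AG introns.

    Introns carry the canonical splice dinucleotides on the gene strand
    (GT..AG), written into the chromosome sequence; minus-strand genes show
    CT..AC on the plus strand.
    """
    config.validate()
    rng = _rng(config, 1)
    chroms = {
        f"chr{i + 1}": bytearray(_random_seq(rng, config.chromosome_length), "ascii")
        for i in range(config.n_chromosomes)
    }
    cursors = {c: int(rng.integers(*config.intergenic_gap_range)) for c in chroms}
    genes: list[Gene] = []
    chrom_names = list(chroms)
    ci = 0
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
        intron_lens = rng.integers(*config.intron_length_range, size=max(0, n_exons - 1))
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        gap = int(rng.integers(*config.intergenic_gap_range))
        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[ci % len(chrom_names)]
            ci += 1
            if cursors[chrom] + gene_len + gap < config.chromosome_length - 10:
                placed = True
                break
        if not placed:
            raise SimSizingError(
                f"cannot place gene {gi + 1}/{config.n_genes}: chromosomes full"
            )
        start = cursors[chrom] + 1
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        exons = []
        pos = start
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el) - 1))
            pos += int(el)
            if k < len(intron_lens):
                istart, iend = pos, pos + int(intron_lens[k]) - 1
                seq = chroms[chrom]
                if strand == "+":
                    seq[istart - 1 : istart + 1] = b"GT"
                    seq[iend - 2 : iend] = b"AG"
                else:
                    seq[istart - 1 : istart + 1] = b"CT"
                    seq[iend - 2 : iend] = b"AC"
                pos = iend + 1
        end = exons[-1][1]
        genes.append(Gene(f"gene{gi + 1:04d}", chrom, strand, start, end, exons))
        cursors[chrom] = end + gap
    genome = {c: bytes(b).decode("ascii") for c, b in chroms.items()}
    return genome, Annotation(genes)


def _write_motifs(seq: bytearray, start: int, end: int, strand: str) -> None:
    """Force the back-splice dinucleotides around a planted circle.

    Plus strand: AG at start-2..start-1 and GT at end+1..end+2; minus strand
    circles read AG/GT on the minus strand, i.e. AC / CT on the plus strand.
    """
    if strand == "+":
        seq[start - 3 : start - 1] = b"AG"
        seq[end : end + 2] = b"GT"
    else:
        seq[start - 3 : start - 1] = b"AC"
        seq[end : end + 2] = b"CT"


def _assign_profiles(n: int, config: SimConfig, rng: np.random.Generator) -> list[str]:
    counts = {p: int(round(f * n)) for p, f in config.profile_fractions.items()}
    while sum(counts.values()) < n:
        counts["flat"] = counts.get("flat", 0) + 1
    labels: list[str] = []
    for p in PROFILES:
        labels.extend([p] * counts.get(p, 0))
    labels = labels[:n]
    rng.shuffle(labels)
    return labels


def plant_circrnas(
    genome: dict[str, str], annotation: Annotation, config: SimConfig
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Plant exonic, intronic and intergenic circRNAs; returns edited genome.

    Exonic circles span whole exon runs of one gene; intronic circles sit
    strictly inside a single intron; intergenic circles overlap no gene. The
    chromosome sequence is edited so the back-splice dinucleotides are present
    around every planted circle.
    """
    rng = _rng(config, 2)
    chroms = {c: bytearray(s, "ascii") for c, s in genome.items()}
    used: set[tuple[str, int, int]] = set()
    lo, hi = config.circ_span_range
    genes = list(annotation)
    truth: list[TruthRecord] = []

    def _take(chrom, s, e, strand, cls, gene_id):
        used.add((chrom, s, e))
        _write_motifs(chroms[chrom], s, e, strand)
        truth.append(
            TruthRecord(circ_id(chrom, s, e), chrom, s, e, strand, cls, gene_id, "flat")
        )

    for _ in range(config.n_circ_exonic):
        for _try in range(2000):
            g = genes[rng.integers(len(genes))]
            i = int(rng.integers(len(g.exons)))
            j = int(rng.integers(i, len(g.exons)))
            s, e = g.exons[i][0], g.exons[j][1]
            if lo <= e - s + 1 <= hi and (g.chrom, s, e) not in used:
                _take(g.chrom, s, e, g.strand, "exonic", g.gene_id)
                break
        else:
            raise PlacementError("no exonic circRNA placement found")
    for _ in range(config.n_circ_intronic):
        for _try in range(2000):
            g = genes[rng.integers(len(genes))]
            introns = g.introns
            if not introns:
                continue
            istart, iend = introns[int(rng.integers(len(introns)))]
            room = iend - istart + 1 - 8  # keep the intron's own GT/AG intact
            if room < lo:
                continue
            span = int(rng.integers(lo, min(hi, room) + 1))
            s = int(rng.integers(istart + 4, iend - 4 - span + 2))
            e = s + span - 1
            if (g.chrom, s, e) not in used:
                _take(g.chrom, s, e, g.strand, "intronic", g.gene_id)
                break
        else:
            raise PlacementError("no intronic circRNA placement found")
    # gaps between genes (and chromosome edges), per chromosome
    gaps: list[tuple[str, int, int]] = []
    for chrom, seq in genome.items():
        bounds = sorted(
            (g.start, g.end) for g in genes if g.chrom == chrom
        )
        prev = 1
        for gs, ge in bounds:
            if gs - 1 - prev > 20:
                gaps.append((chrom, prev + 4, gs - 5))
            prev = ge + 1
        if len(seq) - prev > 20:
            gaps.append((chrom, prev + 4, len(seq) - 4))
    for _ in range(config.n_circ_intergenic):
        for _try in range(2000):
            chrom, gs, ge = gaps[int(rng.integers(len(gaps)))]
            room = ge - gs + 1
            if room < lo + 4:
                continue
            span = int(rng.integers(lo, min(hi, room - 4) + 1))
            s = int(rng.integers(gs + 2, ge - span))
            e = s + span - 1
            strand = "-" if rng.random() < 0.5 else "+"
            if (chrom, s, e) not in used:
                _take(chrom, s, e, strand, "intergenic", None)
                break
        else:
            raise PlacementError("no intergenic circRNA placement found")

    if config.profile_assignment is not None:
        for t in truth:
            t.profile = config.profile_assignment.get(t.circ_id, "flat")
    else:
        for t, p in zip(truth, _assign_profiles(len(truth), config, rng)):
            t.profile = p
    return {c: bytes(b).decode("ascii") for c, b in chroms.items()}, truth


def assign_gene_profiles(annotation: Annotation, config: SimConfig) -> dict[str, str]:
    """Stage profile per gene, drawn with the same class fractions as circles."""
    rng = _rng(config, 5)
    ids = [g.gene_id for g in annotation]
    return dict(zip(ids, _assign_profiles(len(ids), config, rng)))


def sample_ids(config: SimConfig) -> dict[str, tuple[str, int]]:
    """Ordered design: sample id -> (stage, replicate)."""
    return {
        f"{stage}-{r + 1}": (stage, r + 1)
        for stage in config.stages
        for r in range(config.replicates_per_stage)
    }


def junction_read(
    genome: dict[str, str], t: TruthRecord, k: int, read_length: int
) -> str:
    """The error-free junction read with ``k`` bases before the junction.

    Plus strand: genome[end-k+1..end] + genome[start..start+(L-k)-1]; minus
    strand circles yield the reverse complement of that construction.
    """
    chrom = genome[t.chrom]
    tail = chrom[t.end - k : t.end]
    head = chrom[t.start - 1 : t.start - 1 + read_length - k]
    read = tail + head
    return revcomp(read) if t.strand == "-" else read


def _apply_errors(read: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return read
    mask = rng.random(len(read)) < rate
    if not mask.any():
        return read
    out = list(read)
    for i in np.nonzero(mask)[0]:
        out[i] = _BASES[(_BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def simulate_reads(
    genome: dict[str, str],
    annotation: Annotation,
    truth: list[TruthRecord],
    config: SimConfig,
    gene_profiles: dict[str, str] | None = None,
):
    """Single-end reads per sample plus exact planted-count truth tables.

    Returns ``(reads, design, gene_counts)`` where ``reads`` maps sample id to
    a list of (read_id, sequence); junction-read counts are written into each
    ``TruthRecord.counts`` and linear-read counts per gene into
    ``gene_counts``. Total reads per sample equals ``config.depth``.
    """
    if config.read_length < 40:
        raise ValueError("read_length < 40: anchors cannot flank the junction")
    rng = _rng(config, 3)
    if gene_profiles is None:
        gene_profiles = assign_gene_profiles(annotation, config)
    design = sample_ids(config)
    n_stages = len(config.stages)
    mult = {p: profile_multipliers(p, n_stages) for p in PROFILES}
    transcripts = annotation.transcripts(genome)
    gene_ids = sorted(
        g for g, s in transcripts.items() if len(s) >= config.read_length
    )
    tlens = np.array([len(transcripts[g]) for g in gene_ids], dtype=float)
    A, L = config.anchor_length, config.read_length
    reads: dict[str, list[tuple[str, str]]] = {}
    gene_counts: dict[str, dict[str, int]] = {g: {} for g in gene_ids}
    for sample, (stage, _rep) in design.items():
        si = config.stages.index(stage)
        out: list[tuple[str, str]] = []
        serial = 0
        for t in truth:
            lam = config.base_junction_rate * mult[t.profile][si]
            n = int(rng.poisson(lam))
            klo = max(A, L - t.span)
            khi = min(L - A, t.span)
            if khi < klo:  # circle too short for flanking anchors
                n = 0
            t.counts[sample] = n
            for _ in range(n):
                k = int(rng.integers(klo, khi + 1))
                r = _apply_errors(junction_read(genome, t, k, L), rng, config.error_rate)
                out.append((f"{sample}_r{serial:06d}", r))
                serial += 1
        n_linear = max(0, config.depth - len(out))
        w = np.array(
            [tlens[i] * mult[gene_profiles[g]][si] for i, g in enumerate(gene_ids)]
        )
        picks = rng.choice(len(gene_ids), size=n_linear, p=w / w.sum())
        counts = np.bincount(picks, minlength=len(gene_ids))
        for gi, c in enumerate(counts):
            gene_counts[gene_ids[gi]][sample] = int(c)
        for gi in picks:
            tseq = transcripts[gene_ids[gi]]
            p = int(rng.integers(0, len(tseq) - L + 1))
            r = _apply_errors(tseq[p : p + L], rng, config.error_rate)
            out.append((f"{sample}_r{serial:06d}", r))
            serial += 1
        reads[sample] = out
    return reads, design, gene_counts


def circle_sequence(genome: dict[str, str], t: TruthRecord) -> str:
    """Genomic sequence of the circularized segment on its annotated strand."""
    seq = genome[t.chrom][t.start - 1 : t.end]
    return revcomp(seq) if t.strand == "-" else seq


def make_reference_circdb(
    truth: list[TruthRecord], genome: dict[str, str], config: SimConfig
) -> list[CircDbEntry]:
    """Reference database of back-splicing sequences plus length/GC decoys.

    A ``db_homolog_fraction`` subset of planted circles contributes its own
    reassembled back-splicing sequence (diverged at ``db_divergence``) under a
    synthetic species tag; decoys are rejection-sampled so they share no
    20-mer with any planted circle's reassembly.
    """
    from .conserve import reassemble_backsplice

    rng = _rng(config, 4)
    n_hom = int(math.floor(config.db_homolog_fraction * len(truth)))
    order = rng.permutation(len(truth))
    species = ["speciesA", "speciesB", "speciesC", "speciesD"]
    entries: list[CircDbEntry] = []
    truth_kmers: set[str] = set()
    reassemblies = []
    for t in truth:
        bs = reassemble_backsplice(circle_sequence(genome, t), circ_id=t.circ_id)
        reassemblies.append(bs)
        for i in range(len(bs.sequence) - 19):
            truth_kmers.add(bs.sequence[i : i + 20])
    for n, ti in enumerate(order[:n_hom]):
        t = truth[ti]
        bs = reassemblies[ti]
        seq = _apply_errors(bs.sequence, rng, config.db_divergence)
        t.db_homolog = True
        entries.append(
            CircDbEntry(
                f"{species[n % len(species)]}|bsj{n + 1:04d}",
                seq,
                bs.junction_offset,
                t.circ_id,
            )
        )
    gc = float(np.mean([(e.sequence.count("G") + e.sequence.count("C")) / len(e.sequence)
                        for e in entries])) if entries else 0.5
    lengths = [len(e.sequence) for e in entries] or [200]
    n_dec = 0
    while n_dec < config.n_db_decoys:
        ln = int(lengths[int(rng.integers(len(lengths)))])
        seq = _random_seq(rng, ln, gc)
        if any(seq[i : i + 20] in truth_kmers for i in range(len(seq) - 19)):
            continue  # decoys must share no 20-mer with any truth reassembly
        n_dec += 1
        entries.append(
            CircDbEntry(f"decoy|bsj{n_dec:04d}", seq, (ln + 1) // 2, None)
        )
    return entries


# penalties of the plant-target expectation scheme, used to compute the
# *designed* score of a planted site without calling the scorer under test
_SEED_LO, _SEED_HI = 2, 13


def _designed_score(mirna_len: int, mismatch_positions: list[int]) -> float:
    s = 0.0
    for p in mismatch_positions:
        s += 1.0 * (2.0 if _SEED_LO <= p <= _SEED_HI else 1.0)
    return s


def _mutate_site(site: str, mirna: str, positions: list[int]) -> str:
    """Introduce designed mismatches at the given miRNA positions (1-based).

    ``site`` is the target-strand site (revcomp of the miRNA); miRNA position
    p maps to site index len-p. The substituted base is neither complementary
    nor a G:U wobble partner of the miRNA base.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = list(site)
    m = len(mirna)
    for p in positions:
        i = m - p
        mb = mirna[p - 1]
        banned = {comp[mb]}
        if mb == "G":
            banned.add("T")
        if mb == "T":
            banned.add("G")
        out[i] = next(b for b in _BASES if b not in banned and b != site[i])
    return "".join(out)


def make_mirnas(
    genome: dict[str, str],
    annotation: Annotation,
    truth: list[TruthRecord],
    gene_profiles: dict[str, str],
    config: SimConfig,
    mismatch_positions: dict[int, list[int]] | None = None,
) -> tuple[dict[str, str], dict[str, str], list[MirnaSiteTruth]]:
    """Generate 21-nt miRNAs and embed designed sites; returns edited genome.

    For each sponge triple a miRNA gets a binding site embedded both in a
    non-flat planted circRNA and in an mRNA sharing that circle's stage
    profile (the pair will co-cluster, making the mRNA a crossover target).
    ``mismatch_positions`` optionally lists miRNA positions (1-based) to
    mutate per triple index, with the designed expectation score recorded in
    truth. Remaining miRNAs are decoys without designed sites.
    """
    rng = _rng(config, 6)
    mismatch_positions = mismatch_positions or {}
    chroms = {c: bytearray(s, "ascii") for c, s in genome.items()}
    mirnas = {
        f"mir{i + 1:03d}": _random_seq(rng, config.mirna_length)
        for i in range(config.n_mirnas)
    }
    site_truth: list[MirnaSiteTruth] = []
    # interleave candidate circles across profiles so sponge triples cover
    # down-, up- and turn-point-regulated modules
    by_profile = {p: [t for t in truth if t.profile == p and t.cls == "exonic"]
                  for p in ("down", "up", "turnpoint")}
    candidates = []
    while any(by_profile.values()):
        for p in ("down", "up", "turnpoint"):
            if by_profile[p]:
                candidates.append(by_profile[p].pop(0))
    genes_by_profile: dict[str, list[Gene]] = {}
    for g in annotation:
        genes_by_profile.setdefault(gene_profiles[g.gene_id], []).append(g)
    m = config.mirna_length
    embeddings: list[tuple[str, int, str, str, float]] = []  # chrom, start, strand, mirna, score
    for i in range(config.n_sponge_triples):
        if i >= len(candidates):
            raise PlacementError("not enough non-flat exonic circles for triples")
        t = candidates[i]
        mid = f"mir{i + 1:03d}"
        site = revcomp(mirnas[mid])
        muts = mismatch_positions.get(i, [])
        site = _mutate_site(site, mirnas[mid], muts)
        score = _designed_score(m, muts)
        # site inside one exon of the circle, clear of exon boundaries
        gene = annotation.genes[t.parental_gene]
        exons = [
            (s, e) for s, e in gene.exons if s >= t.start and e <= t.end and e - s + 1 >= m + 8
        ]
        if not exons:
            raise PlacementError(f"site conflicts with an exon boundary on {t.circ_id}")
        es, ee = exons[0]
        pos = int(rng.integers(es + 4, ee - 4 - m + 2))
        plus_site = site if t.strand == "+" else revcomp(site)
        chroms[t.chrom][pos - 1 : pos - 1 + m] = plus_site.encode("ascii")
        embeddings.append((t.chrom, pos, t.strand, mid, score))
        # a co-profiled mRNA target, site inside one exon interior; each
        # triple consumes a fresh gene so designed sites never collide
        pool = genes_by_profile.get(t.profile, [])
        placed = False
        for g in list(pool):
            wide = [(s, e) for s, e in g.exons if e - s + 1 >= m + 8]
            if g.gene_id != t.parental_gene and wide:
                pool.remove(g)
                es, ee = wide[0]
                pos = int(rng.integers(es + 4, ee - 4 - m + 2))
                plus_site = site if g.strand == "+" else revcomp(site)
                chroms[g.chrom][pos - 1 : pos - 1 + m] = plus_site.encode("ascii")
                embeddings.append((g.chrom, pos, g.strand, mid, score))
                placed = True
                break
        if not placed:
            raise PlacementError("no co-profiled mRNA with room for a site")

    # derive the site truth from the embedded intervals: a site inside an
    # exonic circle is also carried by the parental mRNA, and a site in an
    # exon may fall inside any same-strand circle overlapping that exon
    seen: set[tuple[str, str]] = set()
    for chrom, s, strand, mid, score in embeddings:
        e = s + m - 1
        for t in truth:
            if (
                t.chrom == chrom and t.strand == strand
                and t.start <= s and e <= t.end
                and (mid, t.circ_id) not in seen
            ):
                seen.add((mid, t.circ_id))
                off = (s - t.start) if strand == "+" else (t.end - e)
                site_truth.append(MirnaSiteTruth(mid, t.circ_id, "circRNA", score, off))
        for g in annotation:
            if g.chrom != chrom or g.strand != strand or (mid, g.gene_id) in seen:
                continue
            offset = 0
            for es2, ee2 in g.exons:
                if es2 <= s and e <= ee2:
                    seen.add((mid, g.gene_id))
                    plus_off = offset + (s - es2)
                    tpos = (
                        plus_off if strand == "+"
                        else g.spliced_length - (plus_off + m)
                    )
                    site_truth.append(
                        MirnaSiteTruth(mid, g.gene_id, "mRNA", score, tpos)
                    )
                    break
                offset += ee2 - es2 + 1
    genome_out = {c: bytes(b).decode("ascii") for c, b in chroms.items()}
    return genome_out, mirnas, site_truth


@dataclass
class SimulatedDataset:
    """Everything the downstream pipeline needs, plus ground truth."""

    config: SimConfig
    genome: dict[str, str]
    annotation: Annotation
    truth: list[TruthRecord]
    gene_profiles: dict[str, str]
    reads: dict[str, list[tuple[str, str]]]
    design: dict[str, tuple[str, int]]
    gene_counts: dict[str, dict[str, int]]
    circdb: list[CircDbEntry]
    mirnas: dict[str, str]
    mirna_truth: list[MirnaSiteTruth]


def simulate_dataset(config: SimConfig | None = None, **overrides) -> SimulatedDataset:
    """Run the full generator in canonical order for one configuration."""
    config = replace(config or SimConfig(), **overrides)
    config.validate()
    genome, annotation = generate_genome(config)
    genome, truth = plant_circrnas(genome, annotation, config)
    gene_profiles = assign_gene_profiles(annotation, config)
    genome, mirnas, mirna_truth = make_mirnas(
        genome, annotation, truth, gene_profiles, config
    )
    reads, design, gene_counts = simulate_reads(
        genome, annotation, truth, config, gene_profiles
    )
    circdb = make_reference_circdb(truth, genome, config)
    return SimulatedDataset(
        config, genome, annotation, truth, gene_profiles, reads, design,
        gene_counts, circdb, mirnas, mirna_truth,
    )
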