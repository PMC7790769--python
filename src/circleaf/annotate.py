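"""Classification of circRNA calls against a gene annotation.

A call is *exonic* when its interval lies within one gene and overlaps at
least one exon of that gene, *intronic* when it sits entirely inside a single
intron, and *intergenic* when it overlaps no gene. A circle straddling a
gene boundary has no defined parental relationship and is classed intergenic
with a warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .genomic import Annotation

CLASSES = ("exonic", "intronic", "intergenic")


@dataclass
class AnnotatedCall:
    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cls: str
    parental_gene: str | None
    n_exons_contained: int
    span_length: int
    endpoints_on_splice_sites: bool = False
    boundary_warning: bool = False


def classify_call(call, annotation: Annotation) -> AnnotatedCall:
    """Assign class and parental gene to one call (or truth record).

    ``call`` needs chrom/start/end/strand attributes and a ``circ_id``.
    """
    chrom, s, e = call.chrom, call.start, call.end
    genes = annotation.overlapping(chrom, s, e)
    cls, parent, n_ex, on_sites, warn = "intergenic", None, 0, False, False
    if genes:
        containing = [g for g in genes if g.start <= s and e <= g.end]
        if len(genes) == 1 and containing:
            g = containing[0]
            overlapped = [ex for ex in g.exons if ex[0] <= e and ex[1] >= s]
            in_intron = any(i0 <= s and e <= i1 for i0, i1 in g.introns)
            if in_intron:
                cls, parent = "intronic", g.gene_id
            elif overlapped:
                cls, parent, n_ex = "exonic", g.gene_id, len(overlapped)
                on_sites = any(ex[0] == s for ex in g.exons) and any(
                    ex[1] == e for ex in g.exons
                )
            else:
                # contained in a gene but in no single intron and no exon
                # cannot occur for contiguous models; treat as boundary case
                warn = True
        else:
            warn = True  # partially genic / multi-gene straddle
    return AnnotatedCall(
        getattr(call, "circ_id", f"{chrom}:{s}|{e}"),
        chrom, s, e, getattr(call, "strand", "+"),
        cls, parent, n_ex, e - s + 1, on_sites, warn,
    )


def class_percentages(counts: dict[str, int], decimals: int = 2) -> dict[str, float]:
    """Percentage of calls per class, rounded to ``decimals`` places."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no calls to summarize")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


def percent(part: int, whole: int, decimals: int = 2) -> float:
    """Plain rounded percentage (``decimals=0`` gives a nearest integer)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    v = round(100.0 * part / whole, decimals)
    return v if decimals else int(v)


def summarize_calls(calls: list[AnnotatedCall], span_bin: int = 200) -> dict:
    """Characterization summary of a set of annotated circRNA calls.

    Includes class counts and percentages, per-chromosome counts, a
    span-length histogram (200-nt bins), the exons-per-circRNA distribution,
    parental-gene tallies and the fraction of parental genes producing
    exactly one circRNA (nearest-integer percent).
    """
    if not calls:
        raise ValueError("no calls to summarize")
    class_counts = {c: 0 for c in CLASSES}
    chrom_counts: dict[str, int] = {}
    span_hist: dict[int, int] = {}
    exon_dist: dict[int, int] = {}
    per_gene: dict[str, int] = {}
    for c in calls:
        class_counts[c.cls] += 1
        chrom_counts[c.chrom] = chrom_counts.get(c.chrom, 0) + 1
        b = (c.span_length // span_bin) * span_bin
        span_hist[b] = span_hist.get(b, 0) + 1
        if c.cls == "exonic":
            exon_dist[c.n_exons_contained] = exon_dist.get(c.n_exons_contained, 0) + 1
        if c.parental_gene is not None:
            per_gene[c.parental_gene] = per_gene.get(c.parental_gene, 0) + 1
    n_single = sum(1 for v in per_gene.values() if v == 1)
    n_genes = len(per_gene)
    return {
        "n_calls": len(calls),
        "class_counts": class_counts,
        "class_percentages": class_percentages(class_counts),
        "per_chromosome": dict(sorted(chrom_counts.items())),
        "span_histogram": dict(sorted(span_hist.items())),
        "exons_per_circ": dict(sorted(exon_dist.items())),
        "n_parental_genes": n_genes,
        "circs_per_gene": dict(
            sorted(
                (per_gene and
                 {k: sum(1 for v in per_gene.values() if v == k)
                  for k in set(per_gene.values())} or {}).items()
            )
        ),
        "pct_genes_single_circ": percent(n_single, n_genes, 0) if n_genes else 0,
        "n_genic": sum(1 for c in calls if c.parental_gene is not None),
        "pct_genic": percent(
            sum(1 for c in calls if c.parental_gene is not None), len(calls)
        ),
    }


def stage_overlap(calls_per_stage: dict[str, set[str]]) -> dict:
    """Venn-style counts of circ_ids per exact stage subset.

    ``calls_per_stage`` maps stage label to the set of circ_ids detected in
    at least one replicate of that stage. Returns counts for every non-empty
    subset of stages plus the all-stage intersection count.
    """
    stages = list(calls_per_stage)
    membership: dict[str, frozenset[str]] = {}
    for stage, ids in calls_per_stage.items():
        for cid in ids:
            membership[cid] = membership.get(cid, frozenset()) | {stage}
    subset_counts: dict[frozenset[str], int] = {}
    for cid, sub in membership.items():
        subset_counts[sub] = subset_counts.get(sub, 0) + 1
    out = {
        frozenset(combo): subset_counts.get(frozenset(combo), 0)
        for r in range(1, len(stages) + 1)
        for combo in combinations(stages, r)
    }
    all_stages = frozenset(stages)
    return {
        "exact_subset_counts": out,
        "all_stage_intersection": sum(
            1 for sub in membership.values() if sub == all_stages
        ),
    }
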