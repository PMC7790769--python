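"""Plant-style miRNA target scoring and ceRNA network construction.

Targets are scored with a complementarity expectation penalty: sliding the
reverse-complemented miRNA along the target, each position contributes 0 for
a Watson-Crick pair, 0.5 for a G:U wobble, 1 for a mismatch and 2 for a gap,
with penalties doubled in the seed region (miRNA positions 2-13 from the 5'
end). Sites with expectation at or below ``max_expectation`` (default 5.0)
are retained; a perfect complement scores 0. Networks are tripartite
circRNA-miRNA-mRNA graphs restricted to one co-expression module: a miRNA is
kept only when it has a retained site on a module-member DE circRNA (sponge
edge) and on a module-member DE mRNA (crossover target edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .genomic import revcomp

MAX_EXPECTATION = 5.0
SEED_START, SEED_END = 2, 13  # miRNA positions with doubled penalties
_WOBBLE = {("G", "T"), ("T", "G")}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TargetSite:
    mirna_id: str
    target_id: str
    target_kind: str  # circRNA | mRNA
    interval: tuple[int, int]  # 1-based inclusive on the target
    expectation: float
    alignment: str  # pairing string, '|' pair, 'o' wobble, '.' mismatch, '-' gap


def _position_weight(mirna_pos: int) -> float:
    return 2.0 if SEED_START <= mirna_pos <= SEED_END else 1.0


def _pair_penalty(mirna_base: str, target_base: str) -> tuple[float, str]:
    if _COMP[mirna_base] == target_base:
        return 0.0, "|"
    if (mirna_base, target_base) in _WOBBLE:
        return 0.5, "o"
    return 1.0, "."


def _score_window(
    mirna: str, window: str, cutoff: float = float("inf")
) -> tuple[float, str]:
    """Ungapped expectation of one window (len == len(mirna)).

    Window position i pairs with miRNA position m - i (the target runs
    antiparallel to the miRNA). Scoring aborts early once ``cutoff`` is
    exceeded (the returned marks string is then truncated).
    """
    m = len(mirna)
    total = 0.0
    marks = []
    for i in range(m):
        pos = m - i
        pen, mark = _pair_penalty(mirna[pos - 1], window[i])
        total += pen * _position_weight(pos)
        marks.append(mark)
        if total > cutoff:
            break
    return total, "".join(marks)


def _score_window_gapped(mirna: str, window: str) -> tuple[float, str] | None:
    """Best single-gap alignment of a window one base longer or shorter.

    One target base is bulged (gap in the miRNA strand) for windows of
    m + 1 bases, or one miRNA base is unpaired (gap in the target strand)
    for m - 1 bases; the gap penalty of 2 is doubled inside the seed.
    """
    m = len(mirna)
    best = None
    if len(window) == m + 1:
        for g in range(1, m):  # bulge between miRNA positions
            reduced = window[:g] + window[g + 1 :]
            total, marks = _score_window(mirna, reduced)
            pos = m - g + 1
            total += 2.0 * _position_weight(pos)
            cand = (total, marks[:g] + "-" + marks[g:])
            if best is None or cand[0] < best[0]:
                best = cand
    elif len(window) == m - 1:
        # drop (leave unpaired) one interior miRNA position p; remaining
        # positions keep their index in the shortened sequence, a small
        # approximation to full positional bookkeeping
        for p in range(2, m):
            sub = mirna[: p - 1] + mirna[p:]
            total, marks = _score_window(sub, window)
            total += 2.0 * _position_weight(p)
            cand = (total, marks)
            if best is None or cand[0] < best[0]:
                best = cand
    return best


def score_mirna_target(
    mirna_id: str,
    mirna_seq: str,
    target_id: str,
    target_seq: str,
    target_kind: str = "mRNA",
    max_expectation: float = MAX_EXPECTATION,
    allow_gaps: bool = True,
) -> TargetSite | None:
    """Best (lowest-expectation) site of a miRNA on a target, or None.

    RNA input (U) is accepted and normalized to DNA letters. miRNA length
    must be 19-24 nt.
    """
    mirna = mirna_seq.upper().replace("U", "T")
    target = target_seq.upper().replace("U", "T")
    if not 19 <= len(mirna) <= 24:
        raise ValueError("miRNA length must be 19-24 nt")
    m = len(mirna)
    best: TargetSite | None = None

    def consider(start0: int, length: int, total: float, marks: str):
        nonlocal best
        if total <= max_expectation and (best is None or total < best.expectation):
            best = TargetSite(
                mirna_id, target_id, target_kind,
                (start0 + 1, start0 + length), total, marks,
            )

    for i in range(len(target) - m + 1):
        total, marks = _score_window(mirna, target[i : i + m], max_expectation)
        if total <= max_expectation:
            consider(i, m, total, marks)
    if allow_gaps:
        for i in range(len(target) - m):
            res = _score_window_gapped(mirna, target[i : i + m + 1])
            if res:
                consider(i, m + 1, *res)
        for i in range(len(target) - m + 2):
            res = _score_window_gapped(mirna, target[i : i + m - 1])
            if res:
                consider(i, m - 1, *res)
    return best


def scan_targets(
    mirnas: dict[str, str],
    targets: dict[str, str],
    target_kind: str,
    max_expectation: float = MAX_EXPECTATION,
    allow_gaps: bool = False,
) -> list[TargetSite]:
    """All retained best sites over a set of miRNAs and target sequences.

    Gapped sites are off by default here (the genome-wide scan); the
    single-site scorer allows them.
    """
    sites = []
    for mid in sorted(mirnas):
        for tid in sorted(targets):
            site = score_mirna_target(
                mid, mirnas[mid], tid, targets[tid], target_kind,
                max_expectation, allow_gaps=allow_gaps,
            )
            if site is not None:
                sites.append(site)
    return sites


def build_cerna_network(
    module_label: str,
    module_circs: set[str],
    module_mrnas: set[str],
    sites: list[TargetSite],
) -> nx.Graph:
    """Module-constrained tripartite circRNA-miRNA-mRNA graph.

    ``module_circs`` / ``module_mrnas`` are the DE features belonging to the
    module. A miRNA survives only with at least one sponge edge (site on a
    module circRNA) and one crossover edge (site on a module mRNA).
    """
    sponge = {}
    target = {}
    for s in sites:
        if s.target_kind == "circRNA" and s.target_id in module_circs:
            sponge.setdefault(s.mirna_id, []).append(s)
        elif s.target_kind == "mRNA" and s.target_id in module_mrnas:
            target.setdefault(s.mirna_id, []).append(s)
    g = nx.Graph(module=module_label)
    for mid in sorted(set(sponge) & set(target)):
        g.add_node(mid, kind="miRNA", module=module_label)
        for s in sponge[mid]:
            g.add_node(s.target_id, kind="circRNA", module=module_label)
            g.add_edge(
                mid, s.target_id, interaction="sponge",
                expectation=s.expectation, interval=s.interval,
            )
        for s in target[mid]:
            g.add_node(s.target_id, kind="mRNA", module=module_label)
            g.add_edge(
                mid, s.target_id, interaction="target",
                expectation=s.expectation, interval=s.interval,
            )
    return g


def export_network(network: nx.Graph, path_prefix: str, fmt: str = "tsv+gml") -> list[str]:
    """Write the edge list (TSV) and/or a GML graph exchange file.

    The edge list columns are source, interaction, target, expectation and
    module; a companion ``.nodes.tsv`` carries node kind and module.
    """
    written = []
    parts = set(fmt.split("+"))
    unknown = parts - {"tsv", "gml"}
    if unknown:
        raise ValueError(f"unknown export format(s): {sorted(unknown)}")
    module = network.graph.get("module", "")
    if "tsv" in parts:
        epath = f"{path_prefix}.edges.tsv"
        with open(epath, "w") as fh:
            fh.write("source\tinteraction\ttarget\texpectation\tmodule\n")
            for u, v, d in sorted(network.edges(data=True)):
                src, dst = (u, v) if network.nodes[u]["kind"] == "miRNA" else (v, u)
                fh.write(
                    f"{src}\t{d['interaction']}\t{dst}\t{d['expectation']}\t{module}\n"
                )
        npath = f"{path_prefix}.nodes.tsv"
        with open(npath, "w") as fh:
            fh.write("node\tkind\tmodule\n")
            for n, d in sorted(network.nodes(data=True)):
                fh.write(f"{n}\t{d['kind']}\t{d['module']}\n")
        written += [epath, npath]
    if "gml" in parts:
        gpath = f"{path_prefix}.gml"
        g = network.copy()
        for *_e, d in g.edges(data=True):
            d.pop("interval", None)  # GML cannot carry tuples
        nx.write_gml(g, gpath)
        written.append(gpath)
    return written


def read_edge_list(path: str) -> nx.Graph:
    """Reconstruct a network from an exported edge list."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source\t"):
            raise ValueError("not a ceRNA edge list")
        for line in fh:
            src, interaction, dst, expectation, module = line.rstrip("\n").split("\t")
            g.graph.setdefault("module", module)
            kind = "circRNA" if interaction == "sponge" else "mRNA"
            g.add_node(src, kind="miRNA", module=module)
            g.add_node(dst, kind=kind, module=module)
            g.add_edge(src, dst, interaction=interaction, expectation=float(expectation))
    return g
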