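"""Simplified weighted co-expression network analysis.

Combines DE circRNA TPM and DE mRNA FPKM matrices, builds an unsigned
adjacency ``|cor|^power`` (power 5 by default), converts it to topological
overlap, clusters 1-TOM with average linkage, cuts the dendrogram into
modules of at least 30 members (a static-branch simplification of the
dynamic hybrid tree cut), merges modules whose eigengenes are closer than
the 0.217 dissimilarity cut, and correlates module eigengenes with per-stage
indicator traits to classify each module as continuous-down, continuous-up
or turn-point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
]
UNASSIGNED = "grey"


@dataclass
class ModuleConfig:
    soft_power: int = 5
    min_module_size: int = 30
    merge_cut_height: float = 0.217
    fpkm_min: float = 0.001
    variation_min: float = 0.5  # minimum coefficient of variation
    network_type: str = "unsigned"

    def validate(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge_cut_height must be in (0, 1)")


@dataclass
class CoexModule:
    label: str
    members: list[str]
    eigengene: np.ndarray | None = None  # per-sample, unit variance
    stage_correlations: dict[str, tuple[float, float]] = field(default_factory=dict)
    classification: str | None = None


def combine_and_filter(
    circ_tpm: pd.DataFrame, mrna_fpkm: pd.DataFrame, config: ModuleConfig | None = None
) -> pd.DataFrame:
    """Row-bind the two matrices (feature-kind tagged index) and drop
    features with mean abundance below ``fpkm_min`` or coefficient of
    variation below ``variation_min``."""
    config = config or ModuleConfig()
    if list(circ_tpm.columns) != list(mrna_fpkm.columns):
        raise ValueError("sample columns of the two matrices must match")
    combined = pd.concat(
        [
            circ_tpm.set_axis([f"circ::{i}" for i in circ_tpm.index]),
            mrna_fpkm.set_axis([f"mrna::{i}" for i in mrna_fpkm.index]),
        ]
    )
    mean = combined.mean(axis=1)
    std = combined.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, std / mean, 0.0)
    keep = (mean >= config.fpkm_min) & (cv >= config.variation_min)
    return combined.loc[keep]


def adjacency_matrix(matrix: pd.DataFrame, config: ModuleConfig | None = None) -> np.ndarray:
    """Unsigned soft-threshold adjacency a_ij = |pearson(x_i, x_j)|^power."""
    config = config or ModuleConfig()
    x = matrix.to_numpy(float)
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if (x.std(axis=1) == 0).any():
        raise ValueError("zero-variance feature reached adjacency (filter first)")
    cor = np.corrcoef(x)
    adj = np.abs(cor) ** config.soft_power
    np.fill_diagonal(adj, 1.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def _branch_modules(node, min_size: int) -> list[list[int]]:
    """Static-branch cut: descend while both children can stand alone."""
    if node.get_count() < min_size:
        return []
    if node.is_leaf():
        return []
    left, right = node.get_left(), node.get_right()
    if left.get_count() >= min_size and right.get_count() >= min_size:
        return _branch_modules(left, min_size) + _branch_modules(right, min_size)
    return [node.pre_order(lambda n: n.id)]


def detect_modules(
    tom: np.ndarray, feature_ids: list[str], config: ModuleConfig | None = None
) -> list[CoexModule]:
    """Average-linkage clustering of 1-TOM with a static branch cut.

    Features not assigned to any branch of at least ``min_module_size``
    members fall into the grey (unassigned) pool. Module labels are colors
    in descending size order.
    """
    config = config or ModuleConfig()
    n = len(feature_ids)
    if n < config.min_module_size:
        return [CoexModule(UNASSIGNED, list(feature_ids))]
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    link = average(squareform(diss, checks=False))
    tree = to_tree(link)
    branches = _branch_modules(tree, config.min_module_size)
    assigned: set[int] = set()
    modules = []
    for idxs in sorted(branches, key=len, reverse=True):
        modules.append([feature_ids[i] for i in sorted(idxs)])
        assigned |= set(idxs)
    out = [
        CoexModule(MODULE_COLORS[i % len(MODULE_COLORS)], members)
        for i, members in enumerate(modules)
    ]
    grey = [feature_ids[i] for i in range(n) if i not in assigned]
    if grey:
        out.append(CoexModule(UNASSIGNED, grey))
    return out


def module_eigengene(member_rows: pd.DataFrame) -> np.ndarray:
    """First principal component of the standardized member profiles.

    Unit variance, sign-oriented so its correlation with the mean member
    profile is positive.
    """
    x = member_rows.to_numpy(float)
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    sd = e.std(ddof=1)
    return e / sd if sd > 0 else e


def _attach_eigengenes(modules: list[CoexModule], matrix: pd.DataFrame) -> None:
    for m in modules:
        if m.label != UNASSIGNED and m.members:
            m.eigengene = module_eigengene(matrix.loc[m.members])


def merge_close_modules(
    modules: list[CoexModule], matrix: pd.DataFrame, config: ModuleConfig | None = None
) -> list[CoexModule]:
    """Iteratively merge module pairs with eigengene dissimilarity
    1 - pearson(E_i, E_j) below the merge cut height, to a fixed point."""
    config = config or ModuleConfig()
    real = [m for m in modules if m.label != UNASSIGNED]
    grey = [m for m in modules if m.label == UNASSIGNED]
    _attach_eigengenes(real, matrix)
    changed = True
    while changed and len(real) > 1:
        changed = False
        best = None
        for i in range(len(real)):
            for j in range(i + 1, len(real)):
                d = 1.0 - float(np.corrcoef(real[i].eigengene, real[j].eigengene)[0, 1])
                if d < config.merge_cut_height and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is not None:
            _d, i, j = best
            merged = CoexModule("", sorted(real[i].members + real[j].members))
            real = [m for k, m in enumerate(real) if k not in (i, j)] + [merged]
            _attach_eigengenes([merged], matrix)
            changed = True
    real.sort(key=lambda m: len(m.members), reverse=True)
    for i, m in enumerate(real):
        m.label = MODULE_COLORS[i % len(MODULE_COLORS)]
    return real + grey


def _monotone(v: np.ndarray, direction: int) -> bool:
    d = np.diff(v) * direction
    return bool((d >= 0).all())


def module_trait_correlation(
    modules: list[CoexModule],
    design: pd.DataFrame,
    sample_order: list[str],
    stages: list[str],
) -> list[CoexModule]:
    """Correlate eigengenes with per-stage indicator traits and classify.

    Classification uses the eigengene's stage means: monotone decreasing ->
    continuous-down, monotone increasing -> continuous-up, a peak at the
    middle stage -> turn-point; otherwise the stage with the strongest
    indicator correlation decides (first/middle/last -> down/turnpoint/up,
    anything else -> other).
    """
    stage_of = design.loc[sample_order, "stage"].to_numpy()
    mid = len(stages) // 2
    for m in modules:
        if m.eigengene is None:
            continue
        cors = {}
        for st in stages:
            ind = (stage_of == st).astype(float)
            r, p = stats.pearsonr(m.eigengene, ind)
            cors[st] = (float(r), float(p))
        m.stage_correlations = cors
        means = np.array(
            [m.eigengene[stage_of == st].mean() for st in stages]
        )
        if _monotone(means, -1):
            m.classification = "continuous-down"
        elif _monotone(means, +1):
            m.classification = "continuous-up"
        elif means.argmax() == mid:
            m.classification = "turn-point"
        else:
            top = max(cors, key=lambda s: cors[s][0])
            idx = stages.index(top)
            m.classification = (
                "continuous-down" if idx == 0
                else "continuous-up" if idx == len(stages) - 1
                else "turn-point" if idx == mid
                else "other"
            )
    return modules


def run_wgcna(
    combined: pd.DataFrame,
    design: pd.DataFrame,
    stages: list[str],
    config: ModuleConfig | None = None,
) -> list[CoexModule]:
    """Adjacency -> TOM -> modules -> merge -> eigengenes -> trait profile."""
    config = config or ModuleConfig()
    config.validate()
    adj = adjacency_matrix(combined, config)
    tom = topological_overlap(adj)
    modules = detect_modules(tom, list(combined.index), config)
    modules = merge_close_modules(modules, combined, config)
    return module_trait_correlation(
        modules, design, list(combined.columns), stages
    )
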