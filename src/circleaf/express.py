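"""circRNA TPM / mRNA FPKM quantification and pairwise differential expression.

circRNA abundance is back-spliced read count x 1e6 / total mapped reads of
the sample (TPM); mRNA abundance is count x 1e9 / (transcript length x total)
(FPKM). Differential expression between any two stages uses a two-sided
Welch t-test on log2(abundance + 1) with the fold change taken as the ratio
of group means (epsilon-adjusted); circRNAs are significant at fold change
magnitude > 1.5 and P < 0.05, mRNAs at fold change magnitude > 2 and
Benjamini-Hochberg FDR < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EPSILON = 0.01  # pseudo-abundance protecting fold changes against zero means

THRESHOLDS = {
    "circRNA": {"fold_change": 1.5, "alpha": 0.05, "use_fdr": False},
    "mRNA": {"fold_change": 2.0, "alpha": 0.05, "use_fdr": True},
}


@dataclass
class ExpressionMatrix:
    """Features x samples abundance with the stage/replicate design."""

    values: pd.DataFrame  # index: feature ids, columns: sample ids
    design: pd.DataFrame  # index: sample ids, columns: stage, replicate
    unit: str  # "TPM" | "FPKM"

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    def stage_samples(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.design.loc[s, "stage"] == stage]

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            st = self.design.loc[s, "stage"]
            if st not in seen:
                seen.append(st)
        return seen


@dataclass
class DEResult:
    feature_id: str
    contrast: tuple[str, str]
    fold_change: float  # group-B mean over group-A mean, epsilon-adjusted
    p_value: float
    fdr: float | None
    direction: str  # up | down
    significant: bool


def make_design(design_map: dict[str, tuple[str, int]]) -> pd.DataFrame:
    """Design frame from {sample: (stage, replicate)}."""
    return pd.DataFrame(
        {
            "stage": {s: st for s, (st, _r) in design_map.items()},
            "replicate": {s: r for s, (_st, r) in design_map.items()},
        }
    )


def quantify_circ_tpm(
    counts: pd.DataFrame, total_mapped: pd.Series, design: pd.DataFrame
) -> ExpressionMatrix:
    """TPM = junction-read count x 1e6 / total mapped reads per sample."""
    if (total_mapped <= 0).any():
        raise ValueError("total mapped reads must be positive")
    tpm = counts * 1e6 / total_mapped.reindex(counts.columns)
    return ExpressionMatrix(tpm, design, "TPM")


def quantify_mrna_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    total_mapped: pd.Series,
    design: pd.DataFrame,
) -> ExpressionMatrix:
    """FPKM = count x 1e9 / (transcript length x total mapped reads)."""
    if (total_mapped <= 0).any():
        raise ValueError("total mapped reads must be positive")
    if (lengths.reindex(counts.index) <= 0).any():
        raise ValueError("transcript lengths must be positive")
    fpkm = counts.mul(1e9, axis=0).div(lengths.reindex(counts.index), axis=0).div(
        total_mapped.reindex(counts.columns), axis=1
    )
    return ExpressionMatrix(fpkm, design, "FPKM")


def replicate_filter(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep features detected (abundance > 0) in >= 2 replicates of a stage."""
    keep = pd.Series(False, index=matrix.values.index)
    for stage in matrix.stages:
        cols = matrix.stage_samples(stage)
        keep |= (matrix.values[cols] > 0).sum(axis=1) >= 2
    return ExpressionMatrix(matrix.values.loc[keep], matrix.design, matrix.unit)


def pairwise_de(
    matrix: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    kind: str = "circRNA",
    epsilon: float = EPSILON,
) -> list[DEResult]:
    """Welch-test DE of ``stage_b`` versus ``stage_a`` for every feature.

    fold_change = (mean_B + eps) / (mean_A + eps); significance needs
    fold-change magnitude above the kind's threshold and P (circRNA) or BH
    FDR (mRNA) below 0.05.
    """
    thr = THRESHOLDS[kind]
    for st in (stage_a, stage_b):
        if st not in matrix.stages:
            raise ValueError(f"stage not in design: {st}")
    a = matrix.values[matrix.stage_samples(stage_a)].to_numpy(float)
    b = matrix.values[matrix.stage_samples(stage_b)].to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    fc = (mean_b + epsilon) / (mean_a + epsilon)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical groups trigger scipy precision warnings; their p is
        # forced to 1 below, so the warning is moot
        warnings.simplefilter("ignore", RuntimeWarning)
        _t, p = stats.ttest_ind(
            np.log2(b + 1.0), np.log2(a + 1.0), axis=1, equal_var=False
        )
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    fdr = benjamini_hochberg(p) if thr["use_fdr"] else None
    out = []
    for i, fid in enumerate(matrix.values.index):
        magnitude = max(fc[i], 1.0 / fc[i])
        crit = fdr[i] if thr["use_fdr"] else p[i]
        out.append(
            DEResult(
                fid,
                (stage_a, stage_b),
                float(fc[i]),
                float(p[i]),
                float(fdr[i]) if fdr is not None else None,
                "up" if fc[i] >= 1.0 else "down",
                bool(magnitude > thr["fold_change"] and crit < thr["alpha"]),
            )
        )
    return out


def all_pairwise_de(
    matrix: ExpressionMatrix, kind: str = "circRNA", epsilon: float = EPSILON
) -> dict[tuple[str, str], list[DEResult]]:
    """All stage-pair contrasts in stage order (10 pairs for five stages)."""
    return {
        (a, b): pairwise_de(matrix, a, b, kind, epsilon)
        for a, b in combinations(matrix.stages, 2)
    }


def de_feature_set(results: dict[tuple[str, str], list[DEResult]]) -> set[str]:
    """Features significant in at least one contrast."""
    return {
        r.feature_id for res in results.values() for r in res if r.significant
    }


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up adjusted FDR values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample,
    ct_target_calibrator: float,
    ct_ref_calibrator,
) -> float:
    """Relative expression by the 2^-ddCt method.

    Reference Ct arguments may be scalars or sequences of several reference
    genes, in which case the mean delta-Ct is used (multi-reference
    normalization).
    """
    ref_s = float(np.mean(ct_ref_sample))
    ref_c = float(np.mean(ct_ref_calibrator))
    d_sample = ct_target_sample - ref_s
    d_cal = ct_target_calibrator - ref_c
    return float(2.0 ** (-(d_sample - d_cal)))
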