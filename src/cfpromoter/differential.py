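"""Differential promoter-coverage screen between two patient classes.

Per feature: two-sided Wilcoxon rank-sum test, Benjamini–Hochberg FDR
across features, and a fold change on class means. A feature is called
significant when fold change ≥ 1.5 and FDR ≤ 0.05 (both thresholds
configurable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiling import PromoterProfileMatrix
from .simulate import NEGATIVE, POSITIVE


class DifferentialError(ValueError):
    pass


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses the exact null distribution when the smaller group has ≤ 8
    observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections. Returns ``(U, p)``; degenerate
    input with every value identical in both groups gives p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise DifferentialError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up FDR adjustment, preserving input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DifferentialError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _class_split(matrix: PromoterProfileMatrix, labels: pd.Series):
    labels = pd.Series(labels)
    if not labels.index.equals(pd.Index(matrix.sample_ids)):
        labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        raise DifferentialError("labels missing for some samples in the matrix")
    classes = set(labels.unique())
    if classes != {POSITIVE, NEGATIVE}:
        raise DifferentialError(
            f"labels must be exactly {{{POSITIVE!r}, {NEGATIVE!r}}}, got {sorted(classes)}"
        )
    vals = matrix.values.to_numpy(float)
    pos = vals[(labels == POSITIVE).to_numpy()]
    neg = vals[(labels == NEGATIVE).to_numpy()]
    return pos, neg


def differential_screen(
    matrix: PromoterProfileMatrix,
    labels: pd.Series,
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Feature-wise Wilcoxon + BH screen with a fold-change filter.

    Fold change is ``max(mean_pos/mean_neg, mean_neg/mean_pos)`` computed
    on class means with a pseudocount added to both, so it is ≥ 1 and
    direction is reported separately ('increased'/'decreased' in the
    ALN-positive class). Result rows keep the matrix's feature order.
    """
    pos, neg = _class_split(matrix, labels)
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise DifferentialError("each class needs at least 2 samples")
    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    ratio = (mean_pos + pseudocount) / (mean_neg + pseudocount)
    fold_change = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio >= 1, "increased", "decreased")

    n_min = min(pos.shape[0], neg.shape[0])
    if n_min > 8:
        # large-sample screen: vectorized normal approximation with ties
        res = stats.mannwhitneyu(
            pos, neg, alternative="two-sided", method="asymptotic", use_continuity=True, axis=0
        )
        p_raw = np.asarray(res.pvalue, float)
        # all-identical columns give nan under the approximation → p = 1
        degenerate = np.ptp(matrix.values.to_numpy(float), axis=0) == 0
        p_raw = np.where(degenerate | ~np.isfinite(p_raw), 1.0, p_raw)
    else:
        p_raw = np.array(
            [wilcoxon_rank_sum(pos[:, j], neg[:, j])[1] for j in range(pos.shape[1])]
        )
    fdr = benjamini_hochberg(p_raw)
    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
            "fold_change": fold_change,
            "direction": direction,
            "p_raw": p_raw,
            "fdr": fdr,
        }
    )
    out["significant"] = (out["fold_change"] >= fc_min) & (out["fdr"] <= fdr_max)
    return out


def compare_gene_sets(
    matrix: PromoterProfileMatrix, set_a, set_b
) -> tuple[float, float, float]:
    """Compare per-gene mean profiling between two disjoint gene sets.

    Returns ``(mean_a, mean_b, p)`` where p is a two-sided Wilcoxon
    rank-sum test on the per-gene means (each gene's value averaged over
    samples).
    """
    set_a, set_b = list(set_a), list(set_b)
    overlap = sorted(set(set_a) & set(set_b))
    if overlap:
        raise DifferentialError(f"gene sets overlap: {overlap[:5]}")
    missing = [g for g in set_a + set_b if g not in matrix.values.columns]
    if missing:
        raise DifferentialError(f"genes absent from matrix: {missing[:5]}")
    if not set_a or not set_b:
        raise DifferentialError("both gene sets must be non-empty")
    per_gene = matrix.values.mean(axis=0)
    a = per_gene[set_a].to_numpy()
    b = per_gene[set_b].to_numpy()
    _, p = wilcoxon_rank_sum(a, b)
    return float(a.mean()), float(b.mean()), p


def volcano_table(result: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change (signed by direction) and −log10 FDR for plotting."""
    signed = np.where(
        result["direction"] == "increased", result["fold_change"], 1.0 / result["fold_change"]
    )
    return pd.DataFrame(
        {
            "feature_id": result["feature_id"],
            "log2_fc": np.log2(signed),
            "neg_log10_fdr": -np.log10(np.clip(result["fdr"], 1e-300, None)),
            "significant": result["significant"],
        }
    )
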