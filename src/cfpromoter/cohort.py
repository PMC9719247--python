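"""Cohort splitting and Table-1-style balance statistics.

The training/validation split is stratified by class with round-half-up
sizing (7:3 by default). Balance between the two cohorts is tested per
covariate with the conventional trio: Wilcoxon rank-sum for continuous
covariates, Yates-corrected chi-square for well-filled 2×2 tables, Pearson
chi-square for larger well-filled tables, and Fisher's exact test whenever
any observed cell is small (< 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .differential import wilcoxon_rank_sum


class CohortError(ValueError):
    pass


# ------------------------------------------------------------------ split


def split_cohort(
    sample_sheet: pd.DataFrame,
    train_fraction: float = 0.7,
    stratify_by: str = "label",
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified train/validation split with round-half-up sizing.

    Within each stratum the training size is ``floor(f * n + 0.5)``; the
    remainder goes to validation. Deterministic per seed. With the study's
    design (162 and 168 per class at f = 0.7) this yields 113/49 and
    118/50.
    """
    if not 0.0 < train_fraction < 1.0:
        raise CohortError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    for _, grp in sample_sheet.groupby(stratify_by, sort=True):
        ids = grp["sample_id"].to_numpy()
        if len(ids) < 2:
            raise CohortError(f"stratum of size {len(ids)} cannot be split")
        n_train = int(math.floor(train_fraction * len(ids) + 0.5))
        perm = rng.permutation(len(ids))
        train.extend(ids[perm[:n_train]])
        val.extend(ids[perm[n_train:]])
    return sorted(train), sorted(val)


# ------------------------------------------------------------ chi-square


def _check_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise CohortError("contingency table must be at least 2×2")
    if (t < 0).any() or not np.isfinite(t).all():
        raise CohortError("counts must be non-negative finite")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise CohortError("table has a zero margin")
    return t


def chi_square_2x2_yates(table) -> tuple[float, float]:
    """Yates-corrected chi-square for a 2×2 table.

    The continuity correction is floored: each cell contributes
    ``(|O−E| − min(0.5, |O−E|))² / E``, so perfectly null-consistent
    tables give χ² = 0 and p = 1 rather than a negative-overshoot
    statistic.
    """
    t = _check_table(table)
    if t.shape != (2, 2):
        raise CohortError("chi_square_2x2_yates requires a 2×2 table")
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    adj = np.abs(t - exp) - np.minimum(0.5, np.abs(t - exp))
    chi2 = float((adj**2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def chi_square_rxc(table) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) for an r×c table."""
    t = _check_table(table)
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    chi2 = float(((t - exp) ** 2 / exp).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df=df)), df


# ---------------------------------------------------------- Fisher exact


def _table_logprob(t: np.ndarray, row_sums, col_sums, log_n_fact) -> float:
    return float(
        gammaln(np.asarray(row_sums) + 1).sum()
        + gammaln(np.asarray(col_sums) + 1).sum()
        - log_n_fact
        - gammaln(t + 1).sum()
    )


def _enumerate_tables(row_sums, col_sums, cap: int):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    count = 0

    def rec(i, remaining_cols, rows):
        nonlocal count
        if i == r - 1:
            count += 1
            if count > cap:
                raise OverflowError
            yield rows + [tuple(remaining_cols)]
            return
        target = row_sums[i]

        def fill(j, left, partial):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield partial + (left,)
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from fill(j + 1, left - v, partial + (v,))

        for row in fill(0, target, ()):
            yield from rec(i + 1, [rc - rv for rc, rv in zip(remaining_cols, row)], rows + [row])

    yield from rec(0, list(col_sums), [])


def fisher_exact_rxc(table, cap: int = 2_000_000, mc_draws: int = 1_000_000, seed: int = 0) -> float:
    """Two-sided Fisher exact test for an r×c table.

    p is the total hypergeometric probability of all tables with the same
    margins whose probability does not exceed the observed table's (the
    convention used by R's ``fisher.test``). Tables too large to enumerate
    (more than ``cap`` candidate tables) fall back to Monte-Carlo sampling
    of margin-preserving tables with ``mc_draws`` draws.
    """
    t = _check_table(table)
    if not np.allclose(t, np.round(t)):
        raise CohortError("Fisher exact requires integer counts")
    t = np.round(t).astype(int)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    log_n_fact = gammaln(t.sum() + 1)
    lp_obs = _table_logprob(t, row_sums, col_sums, log_n_fact)
    tol = 1e-7  # relative tolerance on probabilities, as in R
    try:
        total = 0.0
        for cand in _enumerate_tables(list(row_sums), list(col_sums), cap):
            lp = _table_logprob(np.asarray(cand, float), row_sums, col_sums, log_n_fact)
            if lp <= lp_obs + tol:
                total += math.exp(lp)
        return float(min(1.0, total))
    except OverflowError:
        rng = np.random.default_rng(seed)
        draws = stats.random_table(row_sums, col_sums).rvs(mc_draws, random_state=rng)
        lps = (
            gammaln(row_sums + 1).sum()
            + gammaln(col_sums + 1).sum()
            - log_n_fact
            - gammaln(draws + 1).sum(axis=(1, 2))
        )
        return float(np.mean(lps <= lp_obs + tol))


# -------------------------------------------------------- balance report


@dataclass
class BalanceRow:
    covariate: str
    test: str
    statistic: float
    p: float


def _categorical_test(table: np.ndarray) -> BalanceRow:
    if (table < 5).any():
        return BalanceRow("", "fisher_exact", float("nan"), fisher_exact_rxc(table))
    if table.shape == (2, 2):
        chi2, p = chi_square_2x2_yates(table)
        return BalanceRow("", "chi_square", chi2, p)
    chi2, p, _ = chi_square_rxc(table)
    return BalanceRow("", "chi_square", chi2, p)


def balance_report(
    sample_sheet: pd.DataFrame,
    split: tuple[list[str], list[str]],
    covariate_types: dict[str, str],
) -> pd.DataFrame:
    """Per-covariate train-vs-validation balance tests.

    ``covariate_types`` maps column name → 'continuous' or 'categorical'.
    Continuous covariates use the Wilcoxon rank-sum test; categorical ones
    use a cohort × level contingency table with Yates chi-square (2×2),
    Pearson chi-square (larger), or Fisher's exact test when any observed
    cell is below 5.
    """
    train_ids, val_ids = split
    sheet = sample_sheet.set_index("sample_id")
    missing = [s for s in list(train_ids) + list(val_ids) if s not in sheet.index]
    if missing:
        raise CohortError(f"split references unknown samples: {missing[:5]}")
    rows = []
    for cov, kind in covariate_types.items():
        if cov not in sheet.columns:
            raise CohortError(f"covariate {cov!r} not in sample sheet")
        tr = sheet.loc[train_ids, cov]
        va = sheet.loc[val_ids, cov]
        if kind == "continuous":
            stat, p = wilcoxon_rank_sum(tr.to_numpy(float), va.to_numpy(float))
            row = BalanceRow(cov, "wilcoxon", stat, p)
        elif kind == "categorical":
            levels = sorted(pd.unique(pd.concat([tr, va])))
            table = np.array(
                [[(tr == lv).sum(), (va == lv).sum()] for lv in levels], dtype=float
            )
            row = _categorical_test(table)
            row.covariate = cov
        else:
            raise CohortError(f"covariate {cov!r} has unknown type {kind!r}")
        row.covariate = cov
        rows.append(row)
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.insert(1, "n_train", len(train_ids))
    out.insert(2, "n_validation", len(val_ids))
    return out
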