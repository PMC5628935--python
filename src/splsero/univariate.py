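"""Univariate differential-abundance screening on log2 protein quantities.

Per protein and contrast: Welch's unequal-variance t-test, geometric-mean
fold change with a 95% confidence interval on the ratio scale, Storey
q-values for multiple testing (computed per contrast), the joint
significance rule (|fold change| beyond 1.2x and q < 0.05), and the
confidence-interval-based replication-validation rule.

A result table is a pandas DataFrame with one row per protein and columns

    protein_id, contrast, fc, fc_ci_low, fc_ci_high, t_stat, welch_df,
    p_value, q_value, significant[, validated, fc_replication]

Fold changes are linear ratios (group A geometric mean over group B);
values below 1 mean lower abundance in group A.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import Contrast, contrast_samples, get_contrast
from .data_io import NPXMatrix

__all__ = [
    "welch_test",
    "fold_change",
    "storey_qvalues",
    "run_univariate",
    "call_differential",
    "validate_in_replication",
]


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Welch–Satterthwaite df, p).

    Zero variance in both groups is degenerate: equal means give t=0, p=1;
    unequal means give an infinite statistic, reported as p=0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs >= 2 values")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return 0.0, float(nx + ny - 2), 1.0
        warnings.warn("both groups have zero variance with unequal means; p ~ 0")
        return float(np.sign(mx - my)) * np.inf, float(nx + ny - 2), 0.0
    se2 = vx / nx + vy / ny
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fold_change(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Linear fold change 2^(mean(x)-mean(y)) with a 100(1-alpha)% CI.

    Inputs are log2-scale; the CI is symmetric on the log2 scale and uses
    the Welch degrees of freedom, so ``fold_change(x, y)`` and
    ``fold_change(y, x)`` are exact reciprocals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    delta = x.mean() - y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    if se2 == 0.0:
        return float(2.0**delta), float(2.0**delta), float(2.0**delta)
    df = se2**2 / ((vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1))
    half = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(se2)
    return float(2.0**delta), float(2.0 ** (delta - half)), float(2.0 ** (delta + half))


def estimate_pi0(p_values, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 over a lambda grid with a smoother.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is computed on the
    grid 0.05, 0.10, ..., 0.95, smoothed with a cubic polynomial and read
    off at the largest lambda, then clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coeff = np.polyfit(lambdas, pi0_lambda, 3)
    pi0 = float(np.polyval(coeff, lambdas.max()))
    return min(max(pi0, 1.0 / p.size), 1.0)


def storey_qvalues(
    p_values,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey q-values.

    The null proportion pi0 is estimated with :func:`estimate_pi0` unless
    given.  Pass ``pi0=1`` to recover Benjamini–Hochberg adjusted p-values
    exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p, lambdas)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def run_univariate(
    matrix: NPXMatrix,
    annot: pd.DataFrame,
    contrast: Contrast | str,
    alpha: float = 0.05,
    fc_threshold: float = 1.2,
    q_threshold: float = 0.05,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Test every protein for the given contrast and call significance.

    The FDR correction is applied within the contrast (one family per
    comparison).
    """
    if isinstance(contrast, str):
        contrast = get_contrast(contrast)
    ids_a, ids_b = contrast_samples(annot.loc[annot.index.intersection(matrix.sample_ids)], contrast)
    a = matrix.values.loc[ids_a]
    b = matrix.values.loc[ids_b]
    rows = []
    for pid in matrix.protein_ids:
        t, df, p = welch_test(a[pid], b[pid])
        fc, lo, hi = fold_change(a[pid], b[pid], alpha=alpha)
        rows.append(
            {
                "protein_id": pid,
                "contrast": contrast.name,
                "fc": fc,
                "fc_ci_low": lo,
                "fc_ci_high": hi,
                "t_stat": t,
                "welch_df": df,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = storey_qvalues(out["p_value"].to_numpy(), pi0=pi0)
    return call_differential(out, fc_threshold=fc_threshold, q_threshold=q_threshold)


def call_differential(
    results: pd.DataFrame, fc_threshold: float = 1.2, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Apply the joint rule: |fold change| beyond the threshold and q below it."""
    out = results.copy()
    fc = out["fc"].to_numpy()
    out["significant"] = (
        ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold))
        & (out["q_value"].to_numpy() < q_threshold)
    )
    return out


def _nearer_ci_bound_log2(fc: float, lo: float, hi: float) -> float:
    """|log2| of the CI bound nearer to 1: the weakest fold change still
    consistent with the discovery estimate."""
    return min(abs(np.log2(lo)), abs(np.log2(hi)))


def validate_in_replication(
    discovery: pd.DataFrame,
    replication: NPXMatrix,
    annot: pd.DataFrame,
    contrast: Contrast | str | None = None,
) -> pd.DataFrame:
    """Assess discovery-significant proteins in the replication cohort.

    A protein is validated when its replication fold change has the same
    direction as in discovery and a magnitude at least as large as the
    discovery CI bound nearer to 1 ("similar or larger fold change of
    identical direction").  Non-significant proteins and proteins absent
    from the replication panel are marked not-assessed (validated = NA).
    """
    if contrast is None:
        names = discovery["contrast"].unique()
        if len(names) != 1:
            raise ValueError("pass an explicit contrast for multi-contrast tables")
        contrast = names[0]
    if isinstance(contrast, str):
        contrast = get_contrast(contrast)
    rep_annot = annot.loc[annot.index.intersection(replication.sample_ids)]
    ids_a, ids_b = contrast_samples(rep_annot, contrast)
    a = replication.values.loc[ids_a]
    b = replication.values.loc[ids_b]

    out = discovery.copy()
    fc_rep = np.full(len(out), np.nan)
    validated: list[object] = [pd.NA] * len(out)
    for i, row in enumerate(out.itertuples(index=False)):
        if not row.significant:
            continue
        if row.protein_id not in replication.values.columns:
            continue
        fc, _, _ = fold_change(a[row.protein_id], b[row.protein_id])
        fc_rep[i] = fc
        same_dir = np.sign(np.log2(fc)) == np.sign(np.log2(row.fc))
        big_enough = abs(np.log2(fc)) >= _nearer_ci_bound_log2(
            row.fc, row.fc_ci_low, row.fc_ci_high
        )
        validated[i] = bool(same_dir and big_enough)
    out["fc_replication"] = fc_rep
    out["validated"] = pd.array(validated, dtype="boolean")
    return out
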