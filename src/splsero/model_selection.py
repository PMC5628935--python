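"""Model selection and validation for sparse PLS-DA classifiers.

Double (nested) cross-validation: the outer loop is leave-one-out and
estimates the prediction error; the inner loop, run inside each outer
training set, is a stratified K-fold grid search over the number of
components and the VIP cutoff used for variable selection.  Hyperparameter
selection therefore never sees the held-out sample.  Significance of the
observed LOO error rate comes from label-permutation resampling (the full
double CV re-run per permutation).  Transfer to an independently normalized
replication cohort reports an error rate and a tie-corrected ROC/AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .spls import SPLSModel, fit_splsda, predict, vip_scores

__all__ = [
    "DoubleCVResult",
    "PermutationResult",
    "TransferResult",
    "select_by_vip",
    "double_cv",
    "permutation_pvalue",
    "transfer_evaluate",
    "mann_whitney_auc",
    "roc_points",
]

DEFAULT_COMPONENT_GRID = (1, 2, 3)
DEFAULT_CUTOFF_GRID = (0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.5)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class DoubleCVResult:
    contrast: str
    folds: pd.DataFrame  # sample_id, true, predicted, correct, n_components, cutoff, n_proteins
    loo_error_rate: float
    seed: int
    n_samples: int


@dataclass
class PermutationResult:
    observed_error: float
    permuted_errors: np.ndarray
    B: int
    count_at_or_below: int
    p_value: float        # count / B; 0 means "below resolution"
    p_label: str          # e.g. "<0.025" when no permutation matched
    seed: int


@dataclass
class TransferResult:
    contrast: str
    error_rate: float
    auc: float
    roc: pd.DataFrame  # threshold, fpr, tpr
    positive_class: str
    n_components: int
    cutoff: float
    selected_proteins: list[str]
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# VIP-based variable selection
# ---------------------------------------------------------------------------

def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def select_by_vip(
    X, labels, cutoff: float, n_components: int = 2
) -> tuple[list[str], np.ndarray, SPLSModel]:
    """Select proteins by VIP cutoff and refit on the subset.

    Fits a dense (all-predictor) model, keeps predictors with
    ``VIP >= cutoff``, and refits on that subset.  An empty subset falls
    back to the single top-VIP protein with a warning.

    Returns (selected feature names, selected column indices, refit model).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    Xa, features = _as_array(X)
    labels = np.asarray(labels)
    dense = fit_splsda(Xa, labels, n_components=n_components, keepX=None,
                       drop_constant=False)
    vip = vip_scores(dense)
    idx = np.flatnonzero(vip >= cutoff)
    if idx.size == 0:
        warnings.warn(f"no protein reaches VIP cutoff {cutoff}; keeping the top-1")
        idx = np.array([int(np.argmax(vip))])
    h = min(n_components, idx.size)
    refit = fit_splsda(Xa[:, idx], labels, n_components=h, keepX=None,
                       drop_constant=False)
    refit.features = [features[i] for i in idx]
    return refit.features, idx, refit


# ---------------------------------------------------------------------------
# inner-loop grid search
# ---------------------------------------------------------------------------

def _grid_errors_one_split(Xtr, ytr, Xte, yte, component_grid, cutoff_grid, tally):
    """Evaluate every (n_components, cutoff) cell on one inner split.

    A single dense fit at the largest component number serves all component
    counts (PLS components are nested), with VIP truncated per count.
    """
    h_max = max(component_grid)
    dense = fit_splsda(Xtr, ytr, n_components=h_max, keepX=None, drop_constant=False)
    for h in component_grid:
        vip = vip_scores(dense, n_components=h)
        for cutoff in cutoff_grid:
            idx = np.flatnonzero(vip >= cutoff)
            if idx.size == 0:
                idx = np.array([int(np.argmax(vip))])
            sub = fit_splsda(Xtr[:, idx], ytr, n_components=min(h, idx.size),
                             keepX=None, drop_constant=False)
            _, pred = predict(sub, Xte[:, idx])
            errs = int((pred != yte).sum())
            e, n, prot = tally.get((h, cutoff), (0, 0, 0))
            tally[(h, cutoff)] = (e + errs, n + len(yte), prot + idx.size)
    return tally


def _inner_select(
    Xtr, ytr, component_grid, cutoff_grid, inner_folds, seed, inner_loo=False
):
    """Pick (n_components, cutoff) by inner CV misclassification.

    Ties break toward fewer selected proteins, then fewer components, then
    the larger cutoff (stable order).
    """
    classes, counts = np.unique(ytr, return_counts=True)
    if inner_loo:
        splitter = LeaveOneOut()
        split_iter = splitter.split(Xtr)
    else:
        n_splits = max(2, min(inner_folds, int(counts.min())))
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xtr, ytr)
    tally: dict = {}
    for tr_idx, te_idx in split_iter:
        if np.unique(ytr[tr_idx]).size < classes.size:
            continue  # a class missing from this inner training split
        _grid_errors_one_split(
            Xtr[tr_idx], ytr[tr_idx], Xtr[te_idx], ytr[te_idx],
            component_grid, cutoff_grid, tally,
        )
    if not tally:
        raise RuntimeError("no usable inner split; too few samples per class")

    def sort_key(item):
        (h, cutoff), (e, n, prot) = item
        return (e / n, prot / n, h, -cutoff)

    (h, cutoff), _ = min(tally.items(), key=sort_key)
    return int(h), float(cutoff)


# ---------------------------------------------------------------------------
# double cross-validation
# ---------------------------------------------------------------------------

def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def double_cv(
    X,
    labels,
    component_grid=DEFAULT_COMPONENT_GRID,
    cutoff_grid=DEFAULT_CUTOFF_GRID,
    inner_folds: int = 7,
    seed: int = 0,
    inner_loo: bool = False,
    contrast: str = "",
    sample_ids=None,
) -> DoubleCVResult:
    """Leave-one-out outer loop around an inner hyperparameter grid search.

    Each outer fold holds out one sample; the inner stratified K-fold CV on
    the remaining samples chooses (n_components, VIP cutoff); the winning
    model is refit on the outer training samples and predicts the held-out
    sample.  The LOO error rate is misclassifications over samples.
    Deterministic given (data, seed).
    """
    Xa, features = _as_array(X)
    y = np.asarray(labels)
    if sample_ids is None:
        sample_ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(y)))
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples")
    n = Xa.shape[0]
    records = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        h, cutoff = _inner_select(
            Xa[tr], y[tr], component_grid, cutoff_grid, inner_folds,
            seed=_derive_seed(seed, i), inner_loo=inner_loo,
        )
        dense = fit_splsda(Xa[tr], y[tr], n_components=h, keepX=None, drop_constant=False)
        vip = vip_scores(dense)
        idx = np.flatnonzero(vip >= cutoff)
        if idx.size == 0:
            idx = np.array([int(np.argmax(vip))])
        model = fit_splsda(Xa[tr][:, idx], y[tr], n_components=min(h, idx.size),
                           keepX=None, drop_constant=False)
        _, pred = predict(model, Xa[i][idx][None, :])
        records.append(
            {
                "sample_id": sample_ids[i],
                "true": y[i],
                "predicted": pred[0],
                "correct": bool(pred[0] == y[i]),
                "n_components": h,
                "cutoff": cutoff,
                "n_proteins": int(idx.size),
            }
        )
    folds = pd.DataFrame(records)
    err = float((~folds["correct"]).mean())
    return DoubleCVResult(contrast=contrast, folds=folds, loo_error_rate=err,
                          seed=seed, n_samples=n)


def permutation_pvalue(
    X,
    labels,
    B: int = 40,
    seed: int = 0,
    include_identity: bool = False,
    observed: DoubleCVResult | None = None,
    **cv_kwargs,
) -> PermutationResult:
    """Permutation p-value for the observed LOO error rate.

    Re-runs the full double cross-validation on ``B`` label permutations;
    ``p = #{err_perm <= err_obs} / B``, reported as the bound ``< 1/B``
    when no permutation matches.  ``include_identity`` forces the identity
    permutation into the draws, guaranteeing ``p >= 1/B``.
    """
    if B < 20:
        warnings.warn(f"B={B} gives a coarse p-value resolution of {1 / B:g}")
    if observed is None:
        observed = double_cv(X, labels, seed=seed, **cv_kwargs)
    y = np.asarray(labels)
    rng = np.random.default_rng(_derive_seed(seed, 1_000_000))
    errors = np.empty(B)
    for b in range(B):
        if include_identity and b == 0:
            yb = y
        else:
            yb = rng.permutation(y)
        errors[b] = double_cv(
            X, yb, seed=_derive_seed(seed, 1_000_001 + b), **cv_kwargs
        ).loo_error_rate
    count = int((errors <= observed.loo_error_rate + 1e-12).sum())
    p = count / B
    label = f"<{1 / B:g}" if count == 0 else f"{p:g}"
    return PermutationResult(
        observed_error=observed.loo_error_rate,
        permuted_errors=errors,
        B=B,
        count_at_or_below=count,
        p_value=p,
        p_label=label,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# replication transfer, ROC/AUC
# ---------------------------------------------------------------------------

def mann_whitney_auc(scores, is_positive) -> float:
    """AUC by the rank (Mann–Whitney) formula with tie correction."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    n1 = int(pos.sum())
    n0 = pos.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both positive and negative samples")
    r = stats.rankdata(scores)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores, is_positive) -> pd.DataFrame:
    """ROC curve points (FPR, TPR) over the distinct score thresholds."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], pos[order]
    n1 = int(pos.sum())
    n0 = pos.size - n1
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.flatnonzero(np.diff(s, append=np.nan))
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for i in distinct:
        rows.append({"threshold": s[i], "fpr": fps[i] / n0, "tpr": tps[i] / n1})
    return pd.DataFrame(rows)


def transfer_evaluate(
    X_disc,
    y_disc,
    X_rep,
    y_rep,
    positive_class: str | None = None,
    component_grid=DEFAULT_COMPONENT_GRID,
    cutoff_grid=DEFAULT_CUTOFF_GRID,
    inner_folds: int = 7,
    seed: int = 0,
    contrast: str = "",
) -> TransferResult:
    """Fit one model on the full discovery cohort and score the replication.

    Hyperparameters are chosen by a single-level stratified CV on the whole
    discovery cohort (the final model is one model, not per-fold); the
    replication error rate counts misclassified replication samples and the
    ROC/AUC uses the positive class's continuous dummy-response score.
    """
    Xd, features = _as_array(X_disc)
    yd = np.asarray(y_disc)
    if isinstance(X_rep, pd.DataFrame):
        Xr = X_rep[list(X_disc.columns)].to_numpy(dtype=float) if isinstance(
            X_disc, pd.DataFrame
        ) else X_rep.to_numpy(dtype=float)
        rep_ids = list(X_rep.index)
    else:
        Xr = np.asarray(X_rep, dtype=float)
        rep_ids = list(range(Xr.shape[0]))
    yr = np.asarray(y_rep)
    missing = set(np.unique(yd)) - set(np.unique(yr))
    if missing:
        raise ValueError(f"class(es) missing from replication cohort: {sorted(missing)}")

    h, cutoff = _inner_select(
        Xd, yd, component_grid, cutoff_grid, inner_folds,
        seed=_derive_seed(seed, 2_000_000),
    )
    selected, idx, model = select_by_vip(X_disc, y_disc, cutoff, n_components=h)
    scores, pred = predict(model, Xr[:, idx])
    error = float((pred != yr).mean())

    if positive_class is None:
        positive_class = str(model.classes_[0])
    cls_idx = int(np.flatnonzero(model.classes_ == positive_class)[0])
    pos_scores = scores[:, cls_idx]
    is_pos = yr == positive_class
    auc = mann_whitney_auc(pos_scores, is_pos)
    roc = roc_points(pos_scores, is_pos)
    preds = pd.DataFrame(
        {"sample_id": rep_ids, "true": yr, "predicted": pred, "score": pos_scores}
    )
    return TransferResult(
        contrast=contrast,
        error_rate=error,
        auc=auc,
        roc=roc,
        positive_class=str(positive_class),
        n_components=h,
        cutoff=cutoff,
        selected_proteins=list(selected),
        predictions=preds,
    )
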