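"""NPX preprocessing: LOD-prevalence exclusion, quantile normalization and
reference projection, below-LOD reset.

The processing order mirrors diagnostic practice for a two-cohort design:
the discovery cohort is quantile-normalized as a whole and its mean sorted
vector kept as a reference distribution; every replication sample is then
projected *independently* onto that reference, as a newly measured sample
would be.  Below-LOD cells keep their instrument values through
normalization and are reset to zero afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import NPXMatrix

__all__ = [
    "ReferenceDistribution",
    "detect_excludable_proteins",
    "quantile_normalize",
    "normalize_against_reference",
    "project_matrix",
    "reset_below_lod",
    "exact_independence_test",
]


@dataclass
class ReferenceDistribution:
    """Sorted reference quantile vector derived from the discovery cohort."""

    quantiles: np.ndarray
    n_discovery_samples: int
    protein_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        if np.any(np.diff(self.quantiles) < 0):
            raise ValueError("reference quantile vector must be non-decreasing")

    def __len__(self) -> int:
        return len(self.quantiles)

    def save(self, path: str | Path) -> None:
        pd.DataFrame(
            {"rank": np.arange(1, len(self) + 1), "quantile": self.quantiles}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, n_discovery_samples: int = 0) -> "ReferenceDistribution":
        df = pd.read_csv(path, sep="\t")
        return cls(df["quantile"].to_numpy(), n_discovery_samples)


# ---------------------------------------------------------------------------
# exact independence test for the "evenly distributed" criterion
# ---------------------------------------------------------------------------

def exact_independence_test(table: np.ndarray) -> float:
    """Fisher–Freeman–Halton exact test for a 2 x k contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed one
    (conditional multivariate hypergeometric null).  Used to judge whether
    detection status (detected/censored) is independent of the sample group.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (table < 0).any():
        raise ValueError("negative cell count")
    col_tot = table.sum(axis=0)
    row1 = int(table.sum(axis=1)[0])
    n = int(table.sum())
    if n == 0 or row1 == 0 or row1 == n or (col_tot == 0).any():
        return 1.0

    lf = [math.lgamma(i + 1) for i in range(n + 1)]

    def log_prob(cells: tuple[int, ...]) -> float:
        # product of per-column binomials over the total binomial
        s = -(lf[n] - lf[row1] - lf[n - row1])
        for a, c in zip(cells, col_tot):
            s += lf[c] - lf[a] - lf[c - a]
        return s

    obs = log_prob(tuple(int(x) for x in table[0]))
    k = len(col_tot)

    p = 0.0
    # enumerate first-row cell counts with fixed margins (k small: 2 or 3)
    def rec(idx: int, remaining: int, cells: list[int]) -> None:
        nonlocal p
        if idx == k - 1:
            if remaining <= col_tot[idx]:
                lp = log_prob(tuple(cells + [remaining]))
                if lp <= obs + 1e-9:
                    p += math.exp(lp)
            return
        tail_cap = int(col_tot[idx + 1:].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(col_tot[idx], remaining)
        for a in range(lo, hi + 1):
            rec(idx + 1, remaining - a, cells + [a])

    rec(0, row1, [])
    return min(p, 1.0)


def detect_excludable_proteins(
    matrix: NPXMatrix,
    annot: pd.DataFrame,
    prevalence_threshold: float = 0.80,
    evenness_alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag proteins censored in more than ``prevalence_threshold`` of samples
    whose remaining detections are evenly distributed between the groups.

    A protein is excluded iff (a) its below-LOD fraction strictly exceeds
    the prevalence threshold and (b) an exact test of detection status
    against group shows no association (p >= ``evenness_alpha``), i.e. the
    sparse signal carries no group information worth keeping.

    Returns a per-protein frame with columns ``frac_below_lod``,
    ``prevalence_exceeded``, ``evenness_p``, ``evenly_distributed`` and
    ``excluded``.  Depends only on the mask and group labels, never on the
    values themselves.
    """
    if not matrix.below_lod.to_numpy().any():
        warnings.warn("no below-LOD information; nothing to exclude")
    groups = annot.loc[matrix.sample_ids, "group"]
    levels = [g for g in ("CD", "UC", "HC") if (groups == g).any()]
    out = []
    for pid in matrix.protein_ids:
        mask = matrix.below_lod[pid].to_numpy()
        frac = float(mask.mean())
        exceeded = frac > prevalence_threshold
        p_even = np.nan
        even = False
        if exceeded:
            table = np.array(
                [
                    [int((~mask)[groups.to_numpy() == g].sum()) for g in levels],
                    [int(mask[groups.to_numpy() == g].sum()) for g in levels],
                ]
            )
            p_even = exact_independence_test(table)
            even = p_even >= evenness_alpha
        out.append(
            {
                "protein_id": pid,
                "frac_below_lod": frac,
                "prevalence_exceeded": exceeded,
                "evenness_p": p_even,
                "evenly_distributed": even,
                "excluded": exceeded and even,
            }
        )
    return pd.DataFrame(out).set_index("protein_id", drop=False)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def _project_vector(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace the rank-r value of ``x`` by the r-th reference quantile.

    Ties within ``x`` receive the mean of the reference values their sorted
    positions span, so the output's sorted vector equals ``ref`` exactly up
    to tie averaging.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n != ref.size:
        raise ValueError(f"sample has {n} proteins but reference has {ref.size}")
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    out = np.empty(n)
    i = 0
    while i < n:
        j = i + 1
        while j < n and xs[j] == xs[i]:
            j += 1
        out[order[i:j]] = ref[i:j].mean()
        i = j
    return out


def quantile_normalize(matrix: NPXMatrix) -> tuple[NPXMatrix, ReferenceDistribution]:
    """Across-sample quantile normalization over the protein axis.

    Each sample's sorted value vector is replaced by the column-wise mean of
    all samples' sorted vectors; afterwards every sample carries the same
    multiset of values (the reference), up to tie averaging.  The reference
    is returned for projecting later cohorts.
    """
    if matrix.n_samples < 2:
        raise ValueError(
            "quantile_normalize needs >= 2 samples; project single samples "
            "with normalize_against_reference instead"
        )
    values = matrix.values.to_numpy(dtype=float)
    ref = np.sort(values, axis=1).mean(axis=0)
    normalized = np.vstack([_project_vector(row, ref) for row in values])
    out = NPXMatrix(
        pd.DataFrame(normalized, index=matrix.values.index, columns=matrix.values.columns),
        matrix.below_lod.copy(),
    )
    return out, ReferenceDistribution(ref, matrix.n_samples, matrix.protein_ids)


def normalize_against_reference(sample: np.ndarray, ref: ReferenceDistribution) -> np.ndarray:
    """Project one sample's value vector onto the reference distribution.

    Idempotent: projecting an already-projected vector changes nothing.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size != len(ref):
        raise ValueError(
            f"sample length {sample.size} != reference length {len(ref)}; "
            "restrict both to the retained protein set first"
        )
    return _project_vector(sample, ref.quantiles)


def project_matrix(matrix: NPXMatrix, ref: ReferenceDistribution) -> NPXMatrix:
    """Project every sample of ``matrix`` independently onto ``ref``.

    Column order follows ``ref.protein_ids`` when set; missing/extra
    proteins raise.
    """
    if ref.protein_ids is not None:
        missing = [p for p in ref.protein_ids if p not in matrix.values.columns]
        if missing:
            raise ValueError(f"proteins missing from matrix: {missing}")
        matrix = NPXMatrix(
            matrix.values[ref.protein_ids].copy(),
            matrix.below_lod[ref.protein_ids].copy(),
        )
    values = matrix.values.to_numpy(dtype=float)
    projected = np.vstack([_project_vector(row, ref.quantiles) for row in values])
    return NPXMatrix(
        pd.DataFrame(projected, index=matrix.values.index, columns=matrix.values.columns),
        matrix.below_lod.copy(),
    )


def reset_below_lod(matrix: NPXMatrix) -> NPXMatrix:
    """Set every below-LOD cell to zero (after normalization, never before)."""
    values = matrix.values.copy()
    values[matrix.below_lod] = 0.0
    return NPXMatrix(values, matrix.below_lod.copy())
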