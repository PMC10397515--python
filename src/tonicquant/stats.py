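"""Group summaries and the exact Mann-Whitney U test.

For the small tie-free samples typical of patch-clamp group comparisons
(n of 5-8 cells per group) the Mann-Whitney p-value is computed exactly:
the null distribution of U is enumerated by the counting recursion

    N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1),

the number of rank arrangements giving each U value (the coefficients of
the Gaussian binomial), and the two-sided p is the doubled smaller tail
including the observed point mass, capped at 1 — the convention of the
classical exact tables. With ties the exact null no longer applies and
the test falls back to a seeded permutation of mid-ranks.

Also provides mean +/- SEM summaries and the 2^-ddCt relative
quantification helper for qPCR.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError

__all__ = [
    "GroupComparison",
    "GroupSummary",
    "DdctResult",
    "u_null_counts",
    "exact_p_from_u",
    "mann_whitney_exact",
    "summarize",
    "ddct_fold_change",
]

_EXACT_MAX_N = 30  # beyond this the permutation fallback is used


@dataclass(frozen=True)
class GroupComparison:
    n1: int
    n2: int
    u_stat: float                      # min of the two orientations
    p_two_sided: float
    method: Literal["exact", "permutation"]
    tie_count: int

    def as_row(self) -> dict:
        return {
            "n1": self.n1, "n2": self.n2, "u_stat": self.u_stat,
            "p_two_sided": self.p_two_sided, "method": self.method,
            "tie_count": self.tie_count,
        }


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float  # NaN for a single observation
    n: int


@dataclass(frozen=True)
class DdctResult:
    delta_ct_sample: float
    delta_ct_calibrator: float
    ddct: float
    fold_change: float


def u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U as arrangement counts, indices 0..n1*n2.

    ``counts[u]`` is the number of the C(n1+n2, n1) equally likely rank
    arrangements whose U statistic equals ``u``. Computed by dynamic
    programming over the counting recursion; exact in int64 for the
    small-sample sizes the exact path accepts.
    """
    if n1 < 0 or n2 < 0:
        raise ValidationError("n1, n2: must be >= 0")
    # table[b] = counts for (a, b) at current a, updated in place over a
    max_u = n1 * n2
    table = np.zeros((n2 + 1, max_u + 1), dtype=np.int64)
    table[:, 0] = 1  # a = 0: single arrangement with U = 0
    for _a in range(1, n1 + 1):
        new = np.zeros_like(table)
        new[0, 0] = 1
        for b in range(1, n2 + 1):
            new[b] = new[b - 1]
            shifted = table[b]
            new[b, b:] += shifted[: max_u + 1 - b]
        table = new
    return table[n2]


def exact_p_from_u(u: float, n1: int, n2: int) -> float:
    """Exact two-sided p for an observed U under the tie-free null.

    Doubled smaller tail including the point mass, capped at 1:
    p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("n1, n2: must be >= 1")
    if not float(u).is_integer() and 2 * u != int(2 * u):
        raise ValidationError("u: must be integer or half-integer")
    if not (0 <= u <= n1 * n2):
        raise ValidationError(f"u: must lie in [0, {n1 * n2}], got {u}")
    counts = u_null_counts(n1, n2)
    total = counts.sum()
    ui = int(np.floor(u))
    lower = counts[: ui + 1].sum() / total
    upper = counts[int(np.ceil(u)):].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _u_from_ranks(ranks_x: np.ndarray, n1: int, n2: int) -> float:
    r1 = float(np.sum(ranks_x))
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    return u1


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 100_000,
    seed: int = 0,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test, exact for small tie-free samples.

    U is the smaller of the two orientations. Without ties and with
    n1 + n2 <= 30 the p-value comes from the full enumerated null
    (:func:`exact_p_from_u`); otherwise a seeded permutation test on
    mid-ranks with ``n_permutations`` resamples is used and the result
    is labelled ``method="permutation"``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("x, y: both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    tie_count = pooled.size - np.unique(pooled).size
    ranks = rankdata(pooled)  # mid-ranks under ties
    u1 = _u_from_ranks(ranks[:n1], n1, n2)
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    if tie_count == 0 and n1 + n2 <= _EXACT_MAX_N:
        p = exact_p_from_u(u, n1, n2)
        method: Literal["exact", "permutation"] = "exact"
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_permutations, pooled.size)), axis=1)
        perm_ranks = ranks[idx[:, :n1]]
        r1 = perm_ranks.sum(axis=1)
        u1_perm = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
        lo = (np.sum(u1_perm <= u1) + 1) / (n_permutations + 1)
        hi = (np.sum(u1_perm >= u1) + 1) / (n_permutations + 1)
        p = float(min(1.0, 2.0 * min(lo, hi)))
        method = "permutation"
    return GroupComparison(
        n1=n1, n2=n2, u_stat=float(u), p_two_sided=p,
        method=method, tie_count=int(tie_count),
    )


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean +/- SEM summary; SEM is NaN when n = 1 (undefined)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("values: must be non-empty")
    mean = float(np.mean(v))
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return GroupSummary(mean=mean, sem=sem, n=int(v.size))


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> DdctResult:
    """Relative qPCR quantification by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference gene) within each sample; ddCt is
    the sample dCt minus the calibrator dCt; the fold change is
    2^-ddCt (1 when the normalized levels are equal).
    """
    for name, v in [
        ("ct_target_sample", ct_target_sample),
        ("ct_ref_sample", ct_ref_sample),
        ("ct_target_calibrator", ct_target_calibrator),
        ("ct_ref_calibrator", ct_ref_calibrator),
    ]:
        if not np.isfinite(v):
            raise ValidationError(f"{name}: must be finite")
    d_s = ct_target_sample - ct_ref_sample
    d_c = ct_target_calibrator - ct_ref_calibrator
    ddct = d_s - d_c
    return DdctResult(
        delta_ct_sample=d_s,
        delta_ct_calibrator=d_c,
        ddct=ddct,
        fold_change=float(2.0 ** (-ddct)),
    )
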