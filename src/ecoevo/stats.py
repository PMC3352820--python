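"""Permutation machinery shared by the analysis modules.

Two engines live here:

* :func:`permute_two_sample` — label permutation of two groups of scalar
  measurements (difference of group means), used for treatment contrasts on
  growth rates, interaction effects, and community respiration.
* :func:`grouped_permutation` — relabelling of whole multivariate profiles
  over (species, treatment) groups with group sizes fixed, used for the
  Monte Carlo tests on metabolic footprints.

Both report a two-tailed p as the doubled smaller tail with the add-one
correction p = (k + 1)/(B + 1) (the observed arrangement counts once), capped
at 1, and both support an exhaustive-enumeration mode in which every distinct
arrangement is evaluated once and the observed arrangement is already in the
set, so no correction is added.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ContrastResult",
    "PermutationTestResult",
    "permute_two_sample",
    "grouped_permutation",
    "two_tailed_p",
]

# Tie tolerance: permuted statistics are recomputed through the same code
# path as the observed one, so exact ties are exact; the epsilon only guards
# against last-ulp drift when an oracle recomputes the statistic differently.
_TIE_EPS = 1e-9


def _tail_counts(null: np.ndarray, observed: float) -> tuple[int, int]:
    eps = _TIE_EPS * max(1.0, abs(observed))
    ge = int(np.count_nonzero(null >= observed - eps))
    le = int(np.count_nonzero(null <= observed + eps))
    return ge, le


def two_tailed_p(null: np.ndarray, observed: float, *, add_one: bool = True) -> float:
    """Doubled smaller tail of ``observed`` within ``null``, capped at 1.

    With ``add_one`` (Monte Carlo sampling) the observed arrangement is
    counted once in both tails and the denominator, giving the usual
    (k+1)/(B+1) correction; without it (exhaustive enumeration, where the
    identity arrangement is already among the draws) counts are used as-is.
    """
    null = np.asarray(null, dtype=float)
    ge, le = _tail_counts(null, observed)
    n = null.size
    if add_one:
        ge, le, n = ge + 1, le + 1, n + 1
    return min(1.0, 2.0 * min(ge, le) / n)


@dataclass
class ContrastResult:
    """Two-group contrast: difference/ratio of means and a permutation p."""

    mean_a: float
    mean_b: float
    difference: float          # mean_a - mean_b
    ratio: float | None        # mean_a / mean_b, None when mean_b <= 0
    p: float
    n_a: int
    n_b: int
    B: int                     # permutations actually evaluated
    exhaustive: bool
    seed: int | None = None


@dataclass
class PermutationTestResult:
    """Monte Carlo test on a profile statistic under label shuffling."""

    statistic_name: str
    observed: float
    null_draws: np.ndarray = field(repr=False)
    p_two_tailed: float = math.nan
    B: int = 0
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.null_draws = np.asarray(self.null_draws, dtype=float)
        if not (0.0 < self.p_two_tailed <= 1.0):
            raise ValueError(f"p must lie in (0, 1], got {self.p_two_tailed}")
        if self.null_draws.size != self.B:
            raise ValueError("length of null_draws must equal B")


def _mean_diff_stats(pooled: np.ndarray, picks: np.ndarray, n_a: int) -> np.ndarray:
    """Mean difference (group A - group B) for each row of index picks."""
    total = pooled.sum()
    sum_a = pooled[picks].sum(axis=1)
    n_b = pooled.size - n_a
    return sum_a / n_a - (total - sum_a) / n_b


def permute_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    B: int = 9999,
    seed: int | None = None,
    exhaustive: bool | None = None,
    max_exhaustive: int = 200_000,
) -> ContrastResult:
    """Two-sided permutation test on the difference of group means.

    ``exhaustive=None`` auto-enables enumeration when the number of distinct
    group-A assignments C(n, n_a) does not exceed ``max_exhaustive``; set it
    to True/False to force either mode.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    observed = a.mean() - b.mean()
    ratio = float(a.mean() / b.mean()) if b.mean() > 0 else None

    n_comb = math.comb(n, n_a)
    if exhaustive is None:
        exhaustive = n_comb <= max_exhaustive
    if exhaustive:
        picks = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), n_a)),
            dtype=np.intp,
        ).reshape(n_comb, n_a)
        null = _mean_diff_stats(pooled, picks, n_a)
        p = two_tailed_p(null, observed, add_one=False)
        n_eval = n_comb
    else:
        rng = np.random.default_rng(seed)
        # argsort of uniforms = uniformly random permutation per row
        picks = np.argsort(rng.random((B, n)), axis=1)[:, :n_a]
        null = _mean_diff_stats(pooled, picks, n_a)
        p = two_tailed_p(null, observed, add_one=True)
        n_eval = B

    return ContrastResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(observed),
        ratio=ratio,
        p=float(p),
        n_a=int(n_a),
        n_b=int(b.size),
        B=int(n_eval),
        exhaustive=bool(exhaustive),
        seed=seed,
    )


def _random_orders(
    rng: np.random.Generator, B: int, n: int, blocks: np.ndarray | None
) -> np.ndarray:
    """B random row orders, unrestricted or within-block only."""
    if blocks is None:
        return np.argsort(rng.random((B, n)), axis=1)
    perms = np.tile(np.arange(n), (B, 1))
    u = rng.random((B, n))
    for b in np.unique(blocks):
        pos = np.where(blocks == b)[0]
        within = np.argsort(u[:, pos], axis=1)
        perms[:, pos] = pos[within]
    return perms


def _exhaustive_orders(n: int, blocks: np.ndarray | None, limit: int) -> np.ndarray:
    """Every distinct row order (within-block when blocks are given)."""
    if blocks is None:
        total = math.factorial(n)
        if total > limit:
            raise ValueError(f"exhaustive enumeration too large ({total} orders)")
        return np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    groups = [np.where(blocks == b)[0] for b in np.unique(blocks)]
    total = math.prod(math.factorial(len(g)) for g in groups)
    if total > limit:
        raise ValueError(f"exhaustive enumeration too large ({total} orders)")
    orders = np.empty((total, n), dtype=np.intp)
    for i, combo in enumerate(
        itertools.product(*(itertools.permutations(g) for g in groups))
    ):
        for g, perm in zip(groups, combo):
            orders[i, g] = perm
    return orders


def grouped_permutation(
    X: np.ndarray,
    group_codes: np.ndarray,
    stat_fn: Callable[[np.ndarray], np.ndarray],
    statistic_name: str,
    B: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
    blocks: np.ndarray | None = None,
    chunk: int = 2_000,
    max_exhaustive: int = 400_000,
) -> PermutationTestResult:
    """Shuffle whole profiles among fixed (group) labels and recompute a statistic.

    ``X`` is (n_samples, n_features); ``group_codes`` assigns each row to one
    of G groups. The labels stay attached to positions and the *rows* are
    permuted, which is the same relabelling but keeps every group's size
    fixed by construction. When ``blocks`` is given (e.g. species codes),
    rows are only shuffled within a block: a restricted permutation scheme
    that respects blocking structure the statistic is not meant to test.
    ``stat_fn`` receives group means of shape (..., G, n_features) and must
    reduce the trailing two axes.

    Exhaustive mode enumerates every distinct row order (all n!, or the
    product of per-block factorials) so that the enumeration-mode p
    coincides exactly with an exhaustive oracle.
    """
    X = np.asarray(X, dtype=float)
    g = np.asarray(group_codes)
    n = X.shape[0]
    if g.shape != (n,):
        raise ValueError("group_codes must have one entry per profile")
    G = int(g.max()) + 1
    counts = np.bincount(g, minlength=G)
    if np.any(counts == 0):
        raise ValueError("every group code in 0..max must be populated")
    if blocks is not None:
        blocks = np.asarray(blocks)
        if blocks.shape != (n,):
            raise ValueError("blocks must have one entry per profile")
    M = np.zeros((G, n))
    M[g, np.arange(n)] = 1.0 / counts[g]

    observed = float(stat_fn(M @ X))

    if exhaustive:
        perms = _exhaustive_orders(n, blocks, max_exhaustive)
        draws = []
        for start in range(0, perms.shape[0], chunk):
            block = perms[start : start + chunk]
            means = np.einsum("gn,bnp->bgp", M, X[block])
            draws.append(stat_fn(means))
        null = np.concatenate(draws)
        # group sizes are preserved by construction under any row order
        assert null.size == perms.shape[0]
        p = two_tailed_p(null, observed, add_one=False)
        B_eval = int(null.size)
    else:
        rng = np.random.default_rng(seed)
        draws = []
        remaining = int(B)
        while remaining > 0:
            b = min(chunk, remaining)
            block = _random_orders(rng, b, n, blocks)
            means = np.einsum("gn,bnp->bgp", M, X[block])
            draws.append(stat_fn(means))
            remaining -= b
        null = np.concatenate(draws)
        p = two_tailed_p(null, observed, add_one=True)
        B_eval = int(B)

    return PermutationTestResult(
        statistic_name=statistic_name,
        observed=observed,
        null_draws=null,
        p_two_tailed=float(p),
        B=B_eval,
        seed=seed,
        exhaustive=exhaustive,
    )
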