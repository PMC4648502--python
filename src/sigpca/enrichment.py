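"""Exact XL-mHG enrichment testing on ranked binary lists.

The minimum-hypergeometric (mHG) test asks, for a ranked list of ``N``
binary indicators with ``K`` ones: over all cutoffs ``n`` = 1..N, what is the
smallest hypergeometric tail probability of seeing at least ``k(n)`` ones in
the first ``n`` positions?  That minimum, ``s_mhg``, is a test statistic, not
a p-value — it is optimised over cutoffs.  Its exact p-value ``p_mhg`` (the
probability under a uniform random permutation that the statistic is as small
or smaller) is computed by an O(NK) dynamic program over the lattice of
(prefix length, ones seen) states, avoiding the infeasible enumeration of
all arrangements.

The XL extension restricts the cutoffs considered:

* ``X`` — a cutoff is only tested once at least ``X`` ones lie above it,
  preventing enrichment calls driven by a tiny fraction of an annotation;
* ``L`` — only the first ``L`` ranks are tested, preventing weak enrichment
  deep in the list from reaching significance.

Setting ``X = 1, L = N`` recovers the classical mHG test.

A brute-force enumeration oracle (:func:`xlmhg_pvalue_oracle`) is included
for verification at small ``N``; it enumerates all C(N, K) arrangements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "CutoffConstraints",
    "EnrichmentResult",
    "hypergeom_tail",
    "term_constraints",
    "fold_enrichment",
    "xlmhg_statistic",
    "xlmhg_pvalue_dp",
    "xlmhg_test",
    "xlmhg_pvalue_oracle",
]

# Relative slack when classifying lattice cells as "statistic <= s"; guards
# against floating-point asymmetry between the statistic computation and the
# region test inside the DP.
_REL_TOL = 1e-12


@dataclass(frozen=True)
class CutoffConstraints:
    """Cutoff restrictions for the XL-mHG test.

    A cutoff ``n`` is testable iff ``n <= L`` and at least ``X`` ones occur
    among the first ``n`` entries.
    """

    X: int = 1
    L: int = 0  # 0 means "use N" (set at test time)

    def __post_init__(self):
        if self.X < 1:
            raise ValueError("X must be >= 1")
        if self.L < 0:
            raise ValueError("L must be >= 0")

    def resolve_L(self, N: int) -> int:
        L = self.L if self.L else N
        if not 1 <= L <= N:
            raise ValueError(f"L={L} out of range for N={N}")
        return L


@dataclass
class EnrichmentResult:
    """Outcome of one XL-mHG test of a gene set against one ranking.

    ``pc_index`` is signed: positive for the descending-loadings ranking of a
    principal component, negative for the ascending one.
    """

    term_id: str
    term_name: str
    namespace: str
    pc_index: int
    s_mhg: float
    p_mhg: float
    n_star: int
    k_star: int
    K: int
    N: int
    X: int
    L: int
    escore: float
    driving_genes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def label(self) -> str:
        prefix = {
            "biological_process": "BP",
            "molecular_function": "MF",
            "cellular_component": "CC",
        }.get(self.namespace, self.namespace[:2].upper() if self.namespace else "GS")
        return f"{prefix} {self.term_name}"


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper hypergeometric tail P(X >= k) for X ~ Hypergeom(N, K, n).

    This is the one-sided Fisher's exact test p-value for observing ``k`` or
    more annotated genes among the first ``n`` of ``N``, when ``K`` are
    annotated overall.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric parameters k={k} N={N} K={K} n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def term_constraints(
    K: int, N: int, x_frac: float = 0.25, x_min: int = 5, l_rank: int | None = None
) -> CutoffConstraints:
    """Per-term constraints: ``X = max(x_min, ceil(x_frac * K))``, ``L = l_rank``.

    ``x_frac`` ensures enrichment is based on a sizeable fraction of the
    term's annotated genes, so the label plausibly describes the pattern;
    ``x_min`` puts an absolute floor under small terms.
    """
    if not 0 <= x_frac <= 1:
        raise ValueError("x_frac must be in [0, 1]")
    if x_min < 1:
        raise ValueError("x_min must be >= 1")
    X = max(x_min, math.ceil(x_frac * K))
    return CutoffConstraints(X=X, L=l_rank if l_rank is not None else N)


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Fold enrichment ``(k/n) / (K/N)`` at a cutoff.

    The density of annotated genes above the cutoff relative to their
    density in the whole list; the effect size accompanying the p-value.
    """
    if n < 1 or K < 1 or N < 1:
        raise ValueError("fold_enrichment requires n >= 1, K >= 1, N >= 1")
    return (k / n) / (K / N)


def _tail_matrix(N: int, K: int, L: int) -> np.ndarray:
    """Hypergeometric tails P(X >= k) for n = 1..L (rows) and k = 0..K (cols)."""
    n = np.arange(1, L + 1)[:, None]
    k = np.arange(0, K + 1)[None, :]
    with np.errstate(invalid="ignore"):
        tails = hypergeom.sf(k - 1, N, K, n)
    # cells with k > min(n, K) are impossible; mark as +inf so they never
    # enter the "at or below s" region
    impossible = k > np.minimum(n, K)
    tails = np.where(impossible, np.inf, tails)
    tails[:, 0] = 1.0
    return tails


def xlmhg_statistic(
    v: np.ndarray, constraints: CutoffConstraints
) -> tuple[float, int, int]:
    """XL-mHG statistic: minimal hypergeometric tail over testable cutoffs.

    Parameters
    ----------
    v
        Ranked binary list (1 = annotated), best rank first.
    constraints
        The ``X`` and ``L`` cutoff restrictions.

    Returns
    -------
    (s_mhg, n_star, k_star)
        The minimal tail probability, the cutoff attaining it (smallest such
        cutoff on ties), and the number of ones at or above it.  If no
        cutoff is testable the degenerate ``(1.0, 0, 0)`` is returned.
    """
    v = np.asarray(v, dtype=np.int8)
    N = len(v)
    K = int(v.sum())
    if K == 0 or N == 0:
        return 1.0, 0, 0
    L = constraints.resolve_L(N)
    X = constraints.X
    k_cum = np.cumsum(v[:L])
    n_arr = np.arange(1, L + 1)
    testable = k_cum >= X
    if not testable.any():
        return 1.0, 0, 0
    n_t = n_arr[testable]
    k_t = k_cum[testable]
    tails = hypergeom.sf(k_t - 1, N, K, n_t)
    i = int(np.argmin(tails))  # argmin returns first occurrence -> smallest n
    return float(tails[i]), int(n_t[i]), int(k_t[i])


def _region_kmin(N: int, K: int, X: int, L: int, s: float) -> np.ndarray:
    """For each prefix length n = 1..N, the minimal k whose tail is <= s.

    Cells (n, k) with ``k >= kmin[n-1]`` constitute the rejection region of
    the DP.  ``kmin = K + 1`` encodes an empty region at that n (always the
    case for n > L).
    """
    kmin = np.full(N, K + 1, dtype=np.int64)
    tails = _tail_matrix(N, K, L)
    threshold = s * (1.0 + _REL_TOL)
    in_region = tails <= threshold
    in_region[:, :X] = False  # cutoffs with fewer than X ones are not testable
    for n in range(L):
        hits = np.nonzero(in_region[n])[0]
        if hits.size:
            kmin[n] = hits[0]
    return kmin


def xlmhg_pvalue_dp(N: int, K: int, constraints: CutoffConstraints, s: float) -> float:
    """Exact XL-mHG p-value by O(NK) dynamic programming.

    Computes the probability, under a uniform random arrangement of ``K``
    ones among ``N`` positions, that some testable cutoff attains a
    hypergeometric tail at or below ``s``.  The forward recursion tracks the
    probability of reaching each (prefix length, ones seen) state without
    having entered the rejection region; the p-value is one minus the
    surviving mass.  Depends on the data only through ``(N, K, X, L, s)``.
    """
    if K == 0:
        return 1.0
    if not 0 < s <= 1:
        raise ValueError("statistic s must be in (0, 1]")
    if s * (1.0 + _REL_TOL) >= 1.0:
        # every arrangement has statistic <= 1 (the no-testable-cutoff case
        # is defined to attain exactly 1), so the event is certain
        return 1.0
    L = constraints.resolve_L(N)
    X = constraints.X
    if X > K:
        return 1.0  # no cutoff can ever be testable
    kmin = _region_kmin(N, K, X, L, s)
    if (kmin > K).all():
        return 0.0  # empty region: P(statistic <= s) under constraints
    # f[k] = P(prefix of length n has k ones and never touched the region)
    f = np.zeros(K + 1)
    f[0] = 1.0
    k_idx = np.arange(K + 1)
    for n in range(N):
        # survival check at prefix length n happens after the n-th draw;
        # here we advance from length n to n+1
        p_one = (K - k_idx) / (N - n)
        np.clip(p_one, 0.0, 1.0, out=p_one)
        stay = f * (1.0 - p_one)
        step = np.zeros(K + 1)
        step[1:] = f[:-1] * p_one[:-1]
        f = stay + step
        f[kmin[n]:] = 0.0  # mass entering the region at length n+1 is absorbed
    return float(min(1.0, max(0.0, 1.0 - f[K])))


def xlmhg_test(
    v: np.ndarray, constraints: CutoffConstraints
) -> tuple[float, float, int, int]:
    """Statistic and exact p-value in one call: ``(s, p, n_star, k_star)``."""
    v = np.asarray(v, dtype=np.int8)
    s, n_star, k_star = xlmhg_statistic(v, constraints)
    if n_star == 0:
        return s, 1.0, n_star, k_star
    p = xlmhg_pvalue_dp(len(v), int(v.sum()), constraints, s)
    # the attaining arrangement itself lies in the region, so p >= "s-ish";
    # clamp to preserve s <= p under floating point
    return s, max(p, s), n_star, k_star


def xlmhg_pvalue_oracle(
    N: int, K: int, constraints: CutoffConstraints, max_arrangements: int = 200_000
) -> dict[float, int]:
    """Exact distribution of the XL-mHG statistic by exhaustive enumeration.

    Enumerates every arrangement of ``K`` ones among ``N`` positions once
    (combinations, not permutations) and tallies the statistic.  Intended as
    an independent verification oracle for the dynamic program at small
    ``N``; raises if C(N, K) exceeds ``max_arrangements``.

    Returns
    -------
    dict mapping statistic value -> number of arrangements attaining it;
    counts sum to C(N, K).
    """
    total = math.comb(N, K)
    if total > max_arrangements:
        raise ValueError(
            f"C({N},{K}) = {total} arrangements exceed limit {max_arrangements}"
        )
    L = constraints.resolve_L(N)
    X = constraints.X
    tails = _tail_matrix(N, K, L) if K else None
    counts: dict[float, int] = {}
    for ones in combinations(range(N), K):
        v = np.zeros(N, dtype=np.int8)
        v[list(ones)] = 1
        if K == 0:
            s = 1.0
        else:
            k_cum = np.cumsum(v[:L])
            testable = k_cum >= X
            if testable.any():
                idx = np.nonzero(testable)[0]
                s = float(tails[idx, k_cum[idx]].min())
            else:
                s = 1.0
        counts[s] = counts.get(s, 0) + 1
    return counts


def oracle_pvalue(
    N: int,
    K: int,
    constraints: CutoffConstraints,
    s: float,
    counts: dict[float, int] | None = None,
) -> float:
    """P(statistic <= s) from the enumeration oracle (small instances only).

    ``counts`` may be supplied to reuse a distribution already computed by
    :func:`xlmhg_pvalue_oracle` for the same ``(N, K, constraints)``.
    """
    if counts is None:
        counts = xlmhg_pvalue_oracle(N, K, constraints)
    total = math.comb(N, K)
    hit = sum(c for value, c in counts.items() if value <= s * (1.0 + _REL_TOL))
    return hit / total
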