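"""Sign-test + permutation procedure for proportional ownership use.

The null hypothesis is *proportional use*: each ownership burns in
proportion to its availability, so for every fire with the ownership
available the indicator {use > availability} is Bernoulli(1/2). Per
ownership j the sign statistic is

    t_j = max(n_j+, n_j - n_j+)

with n_j+ the number of fires whose used proportion exceeds the available
proportion and n_j the number of fires for which the ownership is
available; its P-value comes from Binomial(n_j, 1/2). The per-ownership
P-values are combined through their minimum, whose significance is assessed
by a permutation procedure: replicate datasets are drawn under the null by
resampling the sign indicators, the minimum P recomputed each time, and the
overall P-value is the (add-one) fraction of replicate minima at least as
extreme as the observed one. When the overall test rejects at level alpha,
each ownership with p <= alpha is called preferred if the fraction
f_j = n_j+/n_j is at least 1/2 and avoided otherwise; all remaining
ownerships are proportionally used.

Two resampling modes are provided. ``pairwise`` draws each (fire,
ownership) indicator independently, matching the Binomial(n_j, 1/2)
marginal null directly. ``fire`` flips all of one fire's indicators
together, preserving within-fire dependence between ownerships; both modes
share the same marginal null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .io_formats import logger
from .selectivity import SelectivityRecord

__all__ = [
    "OwnershipTest",
    "OverallTestResult",
    "sign_statistic",
    "binomial_pvalue",
    "permutation_overall",
    "rank_ownerships",
    "run_proportional_use_tests",
]

DECISIONS = ("preferred", "proportionally_used", "avoided")
DEFAULT_TIE_TOL = 1e-9


@dataclass(frozen=True)
class OwnershipTest:
    """Per-ownership sign-test quantities for one fire type."""

    owner_class: str
    fire_type: str
    n: int  # fires with the ownership available, after tie removal
    n_plus: int  # fires with use > availability
    t: int  # max(n_plus, n - n_plus)
    f: float  # n_plus / n
    p_binomial: float


@dataclass(frozen=True)
class OverallTestResult:
    fire_type: str
    overall_p: float
    n_permutations: int
    seed: int
    alpha: float
    null_mode: str
    tests: tuple[OwnershipTest, ...]
    decisions: dict[str, str]
    ranking: tuple[str, ...]


# ---------------------------------------------------------------------------
# sign statistic and exact binomial P
# ---------------------------------------------------------------------------


def sign_statistic(
    records: Sequence[SelectivityRecord],
    tie_tol: float = DEFAULT_TIE_TOL,
) -> OwnershipTest:
    """Sign-test quantities for the records of one (ownership, fire type).

    Fires with |o - pi| <= tie_tol are ties and are removed from both the
    positive count and the total, the classical sign-test convention. A
    group that is all ties degenerates to n = 0 with p = 1 (reported
    proportionally used downstream).
    """
    if not records:
        raise ValueError("no records for sign statistic")
    owner = {r.owner_class for r in records}
    ftype = {r.fire_type for r in records}
    if len(owner) != 1 or len(ftype) != 1:
        raise ValueError("sign_statistic expects records of one ownership and fire type")
    n = 0
    n_plus = 0
    for r in records:
        if abs(r.o - r.pi) <= tie_tol:
            continue
        n += 1
        if r.o > r.pi:
            n_plus += 1
    if n == 0:
        return OwnershipTest(
            owner_class=owner.pop(),
            fire_type=ftype.pop(),
            n=0,
            n_plus=0,
            t=0,
            f=0.5,
            p_binomial=1.0,
        )
    t = max(n_plus, n - n_plus)
    return OwnershipTest(
        owner_class=owner.pop(),
        fire_type=ftype.pop(),
        n=n,
        n_plus=n_plus,
        t=t,
        f=n_plus / n,
        p_binomial=binomial_pvalue(t, n),
    )


@lru_cache(maxsize=None)
def _tail_counts(n: int) -> tuple[int, ...]:
    """tail[k] = #{0/1 vectors of length n with >= k ones} = sum_{i>=k} C(n,i)."""
    tail = [0] * (n + 2)
    for k in range(n, -1, -1):
        tail[k] = tail[k + 1] + math.comb(n, k)
    return tuple(tail[: n + 1])


def binomial_pvalue(t: int, n: int) -> float:
    """Exact two-sided sign-test P-value, P(max(X, n - X) >= t), X~Bin(n, 1/2).

    Computed with integer arithmetic (sums of binomial coefficients divided
    as exact integers), so it agrees bit-for-bit with exhaustive enumeration
    of all 2^n sign vectors.
    """
    t = int(t)
    n = int(n)
    if n < 1 or t > n or t < math.ceil(n / 2):
        raise ValueError(f"sign statistic t={t} out of range for n={n}")
    if 2 * t <= n:  # t == n/2, n even: every outcome is at least this extreme
        return 1.0
    count = 2 * _tail_counts(n)[t]  # X >= t or X <= n-t, disjoint since n-t < t
    return count / (1 << n)


@lru_cache(maxsize=None)
def _pvalue_by_nplus(n: int) -> np.ndarray:
    """Lookup p-value indexed by n_plus for fixed n (vectorised permutations)."""
    if n == 0:
        return np.array([1.0])
    return np.array([binomial_pvalue(max(k, n - k), n) for k in range(n + 1)])


# ---------------------------------------------------------------------------
# permutation combination
# ---------------------------------------------------------------------------


def _group_by_class(
    records: Sequence[SelectivityRecord],
) -> dict[str, list[SelectivityRecord]]:
    groups: dict[str, list[SelectivityRecord]] = {}
    for r in records:
        groups.setdefault(r.owner_class, []).append(r)
    return groups


def _permuted_minima_pairwise(
    tests: Sequence[OwnershipTest], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    mins = np.ones(n_perm)
    for tj in tests:
        if tj.n == 0:
            continue
        n_plus = rng.binomial(tj.n, 0.5, size=n_perm)
        mins = np.minimum(mins, _pvalue_by_nplus(tj.n)[n_plus])
    return mins


def _permuted_minima_fire(
    records: Sequence[SelectivityRecord],
    tests: Sequence[OwnershipTest],
    n_perm: int,
    rng: np.random.Generator,
    tie_tol: float,
) -> np.ndarray:
    """Whole-fire sign flips: one Bernoulli per fire applied to all its classes."""
    fire_ids = sorted({r.footprint_id for r in records})
    class_ids = [tj.owner_class for tj in tests if tj.n > 0]
    fi = {f: i for i, f in enumerate(fire_ids)}
    ci = {c: j for j, c in enumerate(class_ids)}
    A = np.zeros((len(fire_ids), len(class_ids)))  # available & untied
    S = np.zeros_like(A)  # sign: use > availability
    for r in records:
        if r.owner_class not in ci or abs(r.o - r.pi) <= tie_tol:
            continue
        A[fi[r.footprint_id], ci[r.owner_class]] = 1.0
        if r.o > r.pi:
            S[fi[r.footprint_id], ci[r.owner_class]] = 1.0
    keep = S  # A*S: positive untied pairs
    flip = A - S  # A*(1-S): negative untied pairs
    b = rng.integers(0, 2, size=(n_perm, len(fire_ids))).astype(float)
    n_plus = (1.0 - b) @ keep + b @ flip  # (n_perm, J)
    mins = np.ones(n_perm)
    for j, c in enumerate(class_ids):
        n_j = int(A[:, j].sum())
        mins = np.minimum(mins, _pvalue_by_nplus(n_j)[n_plus[:, j].astype(np.int64)])
    return mins


def permutation_overall(
    records: Sequence[SelectivityRecord],
    n_perm: int = 50_000,
    alpha: float = 0.05,
    seed: int | None = None,
    null_mode: str = "pairwise",
    tie_tol: float = DEFAULT_TIE_TOL,
) -> OverallTestResult:
    """Min-P permutation test of proportional use for one fire type.

    The observed statistic is the minimum per-ownership binomial P-value.
    Replicate minima are drawn under the proportional-use null by
    resampling sign indicators (``null_mode``: ``pairwise`` independent per
    (fire, ownership) pair, ``fire`` joint per fire). The overall P uses
    the add-one estimator (1 + #{replicate <= observed}) / (n_perm + 1) so
    it is never exactly zero. Per-ownership decisions and the preference
    ranking follow from alpha and f_j.
    """
    records = list(records)
    if not records:
        raise ValueError("no records for permutation test")
    ftypes = {r.fire_type for r in records}
    if len(ftypes) != 1:
        raise ValueError("permutation_overall expects records of a single fire type")
    fire_type = ftypes.pop()
    if null_mode not in ("pairwise", "fire"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; Monte-Carlo error will be large", n_perm)

    groups = _group_by_class(records)
    tests = tuple(
        sign_statistic(groups[c], tie_tol=tie_tol) for c in sorted(groups)
    )
    live = [tj for tj in tests if tj.n > 0]
    if not live:
        # every class all-tied: nothing to test
        decisions = {tj.owner_class: "proportionally_used" for tj in tests}
        return OverallTestResult(
            fire_type=fire_type,
            overall_p=1.0,
            n_permutations=n_perm,
            seed=-1 if seed is None else int(seed),
            alpha=alpha,
            null_mode=null_mode,
            tests=tests,
            decisions=decisions,
            ranking=rank_ownerships(tests, decisions),
        )

    observed_min = min(tj.p_binomial for tj in live)
    rng = np.random.default_rng(seed)
    if null_mode == "pairwise":
        mins = _permuted_minima_pairwise(live, n_perm, rng)
    else:
        mins = _permuted_minima_fire(records, tests, n_perm, rng, tie_tol)
    overall_p = (1 + int(np.count_nonzero(mins <= observed_min))) / (n_perm + 1)

    decisions: dict[str, str] = {}
    for tj in tests:
        if overall_p > alpha or tj.p_binomial > alpha or tj.n == 0:
            decisions[tj.owner_class] = "proportionally_used"
        elif tj.f >= 0.5:
            decisions[tj.owner_class] = "preferred"
        else:
            decisions[tj.owner_class] = "avoided"

    return OverallTestResult(
        fire_type=fire_type,
        overall_p=overall_p,
        n_permutations=n_perm,
        seed=-1 if seed is None else int(seed),
        alpha=alpha,
        null_mode=null_mode,
        tests=tests,
        decisions=decisions,
        ranking=rank_ownerships(tests, decisions),
    )


def rank_ownerships(
    tests: Sequence[OwnershipTest], decisions: Mapping[str, str]
) -> tuple[str, ...]:
    """Order ownerships by decreasing preference.

    Decision group dominates (preferred, then proportionally used, then
    avoided); within a group, by f_j descending; ties on f_j alphabetically.
    """
    group_rank = {d: i for i, d in enumerate(DECISIONS)}
    return tuple(
        tj.owner_class
        for tj in sorted(
            tests,
            key=lambda tj: (group_rank[decisions[tj.owner_class]], -tj.f, tj.owner_class),
        )
    )


def run_proportional_use_tests(
    records: Sequence[SelectivityRecord],
    n_perm: int = 50_000,
    alpha: float = 0.05,
    seed: int | None = None,
    null_mode: str = "pairwise",
    tie_tol: float = DEFAULT_TIE_TOL,
) -> dict[str, OverallTestResult]:
    """Run the overall test separately for each fire type present."""
    by_type: dict[str, list[SelectivityRecord]] = {}
    for r in records:
        by_type.setdefault(r.fire_type, []).append(r)
    ss = np.random.SeedSequence(seed)
    out: dict[str, OverallTestResult] = {}
    for k, ftype in enumerate(sorted(by_type)):
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        out[ftype] = permutation_overall(
            by_type[ftype], n_perm=n_perm, alpha=alpha, seed=sub_seed,
            null_mode=null_mode, tie_tol=tie_tol,
        )
    return out
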