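"""Trial-level simulation and exact enumeration of two-stage serial search.

This module provides the independent oracles for the closed forms in
:mod:`prioritytag.model`:

* :func:`simulate_search_trial` — a literal stochastic rendering of the
  model's assumptions (uniform target placement, uniformly drawn
  priority subset, random scan order within each stage);
* :func:`mc_expected_comparisons` — Monte-Carlo mean and standard error
  over many simulated trials;
* :func:`enumerate_expected_comparisons` — exact expectation by brute
  force.  It enumerates every priority subset and target identity, and
  the scan position of the target within its stage using a rank
  distribution obtained by enumerating permutations outright.  It never
  evaluates the closed-form expressions, so exact agreement with
  :func:`prioritytag.model.expected_comparisons` is a genuine
  cross-check.

:func:`sample_comparisons` is a vectorized sampler of per-trial
comparison counts used by the synthetic-data generator; its distribution
is identical to the per-trial simulator (tested exactly against the
enumeration pmf).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pandas as pd

from .model import NO_ONSET, ONSET, SearchCondition

__all__ = [
    "TrialOutcome",
    "simulate_search_trial",
    "simulate_blocked_trial",
    "mc_expected_comparisons",
    "sample_comparisons",
    "enumerate_expected_comparisons",
    "comparison_pmf",
    "run_trials",
]

#: Largest display size the exhaustive enumerator accepts.
ENUMERATION_MAX_N = 10


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome of one simulated search trial.

    ``comparisons`` is the 1-based position at which the target was
    inspected (so ``1 <= comparisons <= n``); ``priority_set`` holds the
    item indices tagged on this trial and ``target_in_priority`` whether
    the target was among them.
    """

    comparisons: int
    priority_set: frozenset[int]
    target_in_priority: bool


def simulate_search_trial(
    c: int, cond: SearchCondition, rng: np.random.Generator
) -> TrialOutcome:
    """Simulate one serial self-terminating search trial.

    Items are indexed 0..n-1 with the first ``x`` being onsets.  The
    target is placed uniformly among the items of its type; a priority
    subset of size ``min(c, x)`` is drawn uniformly from the onsets; a
    uniformly random permutation of the priority set is scanned, then a
    uniformly random permutation of the remainder; the comparison count
    is the scan position of the target.
    """
    if c < 0:
        raise ValueError(f"invalid capacity c={c!r}: violates 'c >= 0 integer'")
    n, x, t = cond.n, cond.x, cond.t
    m = min(c, x)
    if t == ONSET:
        target = int(rng.integers(0, x))
    else:
        target = int(x + rng.integers(0, n - x))
    priority = rng.choice(x, size=m, replace=False) if x else np.empty(0, dtype=int)
    rest = np.setdiff1d(np.arange(n), priority, assume_unique=False)
    scan = np.concatenate([rng.permutation(priority), rng.permutation(rest)])
    comparisons = int(np.nonzero(scan == target)[0][0]) + 1
    pset = frozenset(int(i) for i in priority)
    return TrialOutcome(
        comparisons=comparisons,
        priority_set=pset,
        target_in_priority=target in pset,
    )


def simulate_blocked_trial(
    c: int, n: int, r: int, rng: np.random.Generator
) -> TrialOutcome:
    """One blocked-design trial: the ``r`` search-relevant items play the
    role of the tagged pool and the target is always among them."""
    return simulate_search_trial(c, SearchCondition(n=n, x=r, t=ONSET), rng)


def mc_expected_comparisons(
    c: int, cond: SearchCondition, trials: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo estimate of the expected comparison count.

    Returns the sample mean and its standard error over ``trials``
    independent simulated trials from a single seeded stream.  With a
    single trial the standard error is undefined and returned as NaN.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.fromiter(
        (simulate_search_trial(c, cond, rng).comparisons for _ in range(trials)),
        dtype=np.int64,
        count=trials,
    )
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / math.sqrt(trials)) if trials > 1 else float("nan")
    return mean, se


def sample_comparisons(
    c: int, cond: SearchCondition, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` per-trial comparison counts, vectorized.

    Exploits the exchangeability of the scan: the target's position
    within its stage is uniform on that stage, and an onset target falls
    in the priority stage with probability ``min(c, x)/x``.  The
    resulting distribution is exactly that of
    :func:`simulate_search_trial` (asserted against the enumeration pmf
    in the test suite).
    """
    n, x, t = cond.n, cond.x, cond.t
    m = min(c, x)
    out = np.empty(size, dtype=np.int64)
    if t == ONSET:
        in_priority = rng.random(size) < (m / x)
        k = int(in_priority.sum())
        if m > 0:
            out[in_priority] = rng.integers(1, m + 1, size=k)
        out[~in_priority] = m + rng.integers(1, n - m + 1, size=size - k)
    else:
        out[:] = m + rng.integers(1, n - m + 1, size=size)
    return out


@lru_cache(maxsize=None)
def _rank_pmf(size: int) -> tuple[Fraction, ...]:
    """Distribution of a designated element's 1-based position in a
    uniformly random permutation of ``size`` elements, by explicit
    enumeration of all permutations (cached)."""
    if size == 0:
        return ()
    counts = [0] * size
    for perm in itertools.permutations(range(size)):
        counts[perm.index(0)] += 1
    total = math.factorial(size)
    return tuple(Fraction(k, total) for k in counts)


def enumerate_expected_comparisons(c: int, cond: SearchCondition) -> Fraction:
    """Exact expected comparison count by exhaustive enumeration.

    Sums over every priority subset (uniform over ``C(x, m)`` choices),
    every target identity (uniform within its type) and every scan rank
    of the target within its stage, weighting ranks by the enumerated
    permutation distribution.  Independent of the closed forms.
    """
    if c < 0:
        raise ValueError(f"invalid capacity c={c!r}: violates 'c >= 0 integer'")
    n, x, t = cond.n, cond.x, cond.t
    if n > ENUMERATION_MAX_N:
        raise ValueError(
            f"display size n={n} exceeds the enumeration bound {ENUMERATION_MAX_N}"
        )
    m = min(c, x, n)
    targets = range(x) if t == ONSET else range(x, n)
    n_subsets = math.comb(x, m)
    n_targets = len(targets)
    weight = Fraction(1, n_subsets * n_targets)
    total = Fraction(0)
    pmf_priority = _rank_pmf(m)
    pmf_rest = _rank_pmf(n - m)
    for subset in itertools.combinations(range(x), m):
        in_subset = set(subset)
        for target in targets:
            if target in in_subset:
                expected = sum(
                    p * (j + 1) for j, p in enumerate(pmf_priority)
                )
            else:
                expected = sum(
                    p * (m + j + 1) for j, p in enumerate(pmf_rest)
                )
            total += weight * expected
    return total


def comparison_pmf(c: int, cond: SearchCondition) -> dict[int, Fraction]:
    """Exact pmf of the per-trial comparison count, by the same
    enumeration as :func:`enumerate_expected_comparisons`."""
    n, x, t = cond.n, cond.x, cond.t
    if n > ENUMERATION_MAX_N:
        raise ValueError(
            f"display size n={n} exceeds the enumeration bound {ENUMERATION_MAX_N}"
        )
    m = min(c, x, n)
    targets = range(x) if t == ONSET else range(x, n)
    weight = Fraction(1, math.comb(x, m) * len(targets))
    pmf: dict[int, Fraction] = {}
    pmf_priority = _rank_pmf(m)
    pmf_rest = _rank_pmf(n - m)
    for subset in itertools.combinations(range(x), m):
        in_subset = set(subset)
        for target in targets:
            if target in in_subset:
                for j, p in enumerate(pmf_priority):
                    pmf[j + 1] = pmf.get(j + 1, Fraction(0)) + weight * p
            else:
                for j, p in enumerate(pmf_rest):
                    pmf[m + j + 1] = pmf.get(m + j + 1, Fraction(0)) + weight * p
    return pmf


def run_trials(
    c: int, cond: SearchCondition, trials: int, seed: int
) -> pd.DataFrame:
    """Simulate a batch of trials and return them as a tidy table with
    columns ``trial, c, n, x, target_type, comparisons, target_in_priority``."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(trials):
        out = simulate_search_trial(c, cond, rng)
        records.append(
            {
                "trial": i,
                "c": c,
                "n": cond.n,
                "x": cond.x,
                "target_type": cond.t,
                "comparisons": out.comparisons,
                "target_in_priority": out.target_in_priority,
            }
        )
    return pd.DataFrame.from_records(records)
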