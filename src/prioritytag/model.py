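"""Closed-form predictions of the priority-tag model of visual search.

The model describes serial self-terminating search through a display of
``n`` items of which ``x`` appeared as abrupt onsets.  Up to ``c`` onsets
are marked with a priority tag: the tagged subset (drawn uniformly at
random from the onsets when there are more onsets than tags) is scanned
first in random order, then the remaining items are scanned in random
order.  The quantity of interest is ``y``, the expected number of
item-by-item comparisons until the target is inspected.

The expectation has a closed form that splits on two factors: whether the
capacity covers all onsets (``c >= x``) and whether the target is itself
an onset.  Writing the effective priority-set size ``m = min(c, x)``:

* onset target, ``c < x``:   ``y = (n + c + 1)/2 - c*n/(2x)``
* onset target, ``c >= x``:  ``y = (x + 1)/2``
* no-onset target, ``c < x``:  ``y = (n + c + 1)/2``
* no-onset target, ``c >= x``: ``y = x + (n - x + 1)/2``

All values are computed in exact rational arithmetic so that equality
against the brute-force enumeration oracle in
:mod:`prioritytag.simulate` can be asserted without tolerances.

In a blocked design the participant knows the target's type in advance,
so the tagged pool is the set of ``r`` search-relevant items (whichever
type they are) and the onset-target branch applies to both block types;
see :func:`blocked_expected_comparisons`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ONSET",
    "NO_ONSET",
    "TARGET_TYPES",
    "SearchCondition",
    "TagModel",
    "expected_comparisons",
    "blocked_expected_comparisons",
    "prediction_table",
    "equivalent_capacities",
]

ONSET = "onset"
NO_ONSET = "no_onset"
TARGET_TYPES = (ONSET, NO_ONSET)

#: Column order of prediction tables (the CSV contract).
PREDICTION_COLUMNS = ["c", "n", "x", "target_type", "mode", "y"]


@dataclass(frozen=True)
class SearchCondition:
    """A single display/target cell: display size, onset count, target type.

    Parameters
    ----------
    n : int
        Display size (number of items), ``n >= 1``.
    x : int
        Number of abrupt-onset items, ``0 <= x <= n``.
    t : str
        Target type, ``"onset"`` or ``"no_onset"``.  An onset target
        requires ``x >= 1``; a no-onset target requires ``x <= n - 1``.
    """

    n: int
    x: int
    t: str

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or isinstance(self.n, bool) or self.n < 1:
            raise ValueError(
                f"invalid display size n={self.n!r}: violates 'n is a positive integer'"
            )
        if not isinstance(self.x, int) or isinstance(self.x, bool):
            raise ValueError(f"invalid onset count x={self.x!r}: must be an integer")
        if not 0 <= self.x <= self.n:
            raise ValueError(
                f"invalid onset count x={self.x} for n={self.n}: violates '0 <= x <= n'"
            )
        if self.t not in TARGET_TYPES:
            raise ValueError(
                f"invalid target type {self.t!r}: must be one of {TARGET_TYPES}"
            )
        if self.t == ONSET and self.x < 1:
            raise ValueError(
                f"invalid cell (x={self.x}, t=onset): violates 't = onset requires x >= 1'"
            )
        if self.t == NO_ONSET and self.x > self.n - 1:
            raise ValueError(
                f"invalid cell (x={self.x}, t=no_onset, n={self.n}): "
                "violates 't = no_onset requires x <= n - 1'"
            )


def _check_capacity(c: int) -> None:
    if not isinstance(c, int) or isinstance(c, bool) or c < 0:
        raise ValueError(f"invalid capacity c={c!r}: violates 'c >= 0 integer'")


def _y_exact(c: int, n: int, x: int, t: str) -> Fraction:
    """Piecewise closed form, exact.  ``c`` is clamped to ``n``."""
    c = min(c, n)
    if t == ONSET:
        if c < x:
            return Fraction(n + c + 1, 2) - Fraction(c * n, 2 * x)
        return Fraction(x + 1, 2)
    # no-onset target
    if c < x:
        return Fraction(n + c + 1, 2)
    return x + Fraction(n - x + 1, 2)


def expected_comparisons(
    c: int, cond: SearchCondition, *, exact: bool = False
) -> float | Fraction:
    """Expected number of comparisons to find the target.

    Parameters
    ----------
    c : int
        Priority-set capacity.  Capacities above ``n`` are accepted and
        clamped to ``n`` (they predict identically to ``c = n``).
    cond : SearchCondition
        The display/target cell.
    exact : bool
        If True return an exact :class:`~fractions.Fraction`, otherwise
        a float.

    Returns
    -------
    float or Fraction
        ``y``, satisfying ``1 <= y <= n``.
    """
    _check_capacity(c)
    y = _y_exact(c, cond.n, cond.x, cond.t)
    return y if exact else float(y)


def blocked_expected_comparisons(
    c: int, n: int, r: int, *, exact: bool = False
) -> float | Fraction:
    """Expected comparisons in a blocked design with ``r`` search-relevant items.

    When the relevant target type is known in advance, the tagged pool is
    the relevant set itself, so the onset-target branch of the model
    applies regardless of whether the relevant items are onsets or
    no-onsets: ``y = (r + 1)/2`` when ``c >= r`` and the ``c < x`` onset
    form with ``x := r`` otherwise.
    """
    _check_capacity(c)
    if not isinstance(n, int) or isinstance(n, bool) or n < 1:
        raise ValueError(f"invalid display size n={n!r}")
    if not isinstance(r, int) or isinstance(r, bool) or not 1 <= r <= n:
        raise ValueError(
            f"invalid relevant-set size r={r!r} for n={n}: violates '1 <= r <= n'"
        )
    y = _y_exact(c, n, r, ONSET)
    return y if exact else float(y)


def prediction_table(
    c: int,
    n: int,
    x_values: Iterable[int],
    mode: str = "mixed",
) -> pd.DataFrame:
    """Tabulate model predictions over a range of onset counts.

    In ``mixed`` mode ``x`` is the number of onsets and rows are emitted
    for every valid (x, target type) cell — invalid cells (onset target
    with x=0; no-onset target with x=n) are omitted, not NaN-filled.  In
    ``blocked`` mode ``x`` is read as the number of search-relevant
    items ``r`` (valid range 1..n) and the two target-type rows carry the
    same prediction.

    Returns a DataFrame with columns ``c, n, x, target_type, mode, y``.
    """
    _check_capacity(c)
    if mode not in ("mixed", "blocked"):
        raise ValueError(f"invalid mode {mode!r}: must be 'mixed' or 'blocked'")
    rows: list[dict] = []
    for x in x_values:
        for t in TARGET_TYPES:
            if mode == "mixed":
                try:
                    cond = SearchCondition(n=n, x=int(x), t=t)
                except ValueError:
                    if not 0 <= int(x) <= n:
                        raise
                    continue  # structurally invalid (x, t) cell: omit row
                y = expected_comparisons(c, cond)
            else:
                if not 1 <= int(x) <= n:
                    raise ValueError(
                        f"invalid relevant-set size {x} in blocked mode for n={n}"
                    )
                y = blocked_expected_comparisons(c, n, int(x))
            rows.append(
                {"c": c, "n": n, "x": int(x), "target_type": t, "mode": mode, "y": y}
            )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def equivalent_capacities(
    n: int, design_cells: Sequence[SearchCondition]
) -> list[list[int]]:
    """Partition capacities 0..n into groups with identical predictions.

    Two capacities fall in the same group iff their exact predictions
    agree on every cell of the design.  Groups are returned in ascending
    order of capacity.  For the classic mixed design with display size 8
    the top group is {6, 7, 8}: capacities 6 and 7 only differ from 8 on
    cells with 7 or 8 onsets and a no-onset target, which the design
    does not contain.
    """
    if not design_cells:
        raise ValueError("design_cells must be non-empty")
    signatures: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for c in range(n + 1):
        sig = tuple(_y_exact(c, cell.n, cell.x, cell.t) for cell in design_cells)
        if sig not in signatures:
            signatures[sig] = []
            order.append(sig)
        signatures[sig].append(c)
    return [signatures[sig] for sig in order]


@dataclass(frozen=True)
class TagModel:
    """A priority-tag model with fixed capacity ``c``.

    Thin object wrapper over the module functions, convenient when a
    single capacity is threaded through a pipeline.
    """

    c: int

    def __post_init__(self) -> None:
        _check_capacity(self.c)

    def expected_comparisons(
        self, cond: SearchCondition, *, exact: bool = False
    ) -> float | Fraction:
        return expected_comparisons(self.c, cond, exact=exact)

    def blocked_expected_comparisons(
        self, n: int, r: int, *, exact: bool = False
    ) -> float | Fraction:
        return blocked_expected_comparisons(self.c, n, r, exact=exact)

    def prediction_table(
        self, n: int, x_values: Iterable[int], mode: str = "mixed"
    ) -> pd.DataFrame:
        return prediction_table(self.c, n, x_values, mode=mode)
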