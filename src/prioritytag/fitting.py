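"""Preprocessing, per-capacity regression fits, and capacity selection.

The observable prediction of a capacity-``c`` priority-tag model is the
expected comparison count ``y(c; n, x, t)``.  Mapping comparisons to
milliseconds gives the mixed-design regression

    RT = a * y(c; n, x) + b * 1[t = onset] + d

with search rate ``a`` (ms/comparison), onset advantage ``b`` (onset
targets coded 1, so a negative ``b`` is an advantage) and base time
``d``.  Blocked designs drop the target-type indicator:

    RT = a * y(c; n, r) + d

fit separately per target type, with ``r`` the number of
search-relevant items.

Capacity selection fits every capacity 0..n by OLS on cell-mean RTs,
compares pooled R², and backs the comparison statistically with a
repeated-measures ANOVA (Greenhouse-Geisser corrected) on per-participant
R² plus uncorrected pairwise (LSD) post-hoc tests.  Capacities whose
predictions coincide on the design ("equivalence groups") necessarily
share identical fits and are collapsed to one ANOVA level.

The module is organised around two scikit-learn style estimators,
:class:`PriorityTagRegressor` and :class:`CapacitySelector`; the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from . import model as _model
from .model import NO_ONSET, ONSET, SearchCondition

__all__ = [
    "CellMeans",
    "FitResult",
    "PriorityTagRegressor",
    "CapacitySelector",
    "preprocess",
    "fit_capacity",
    "compare_capacities",
    "classify_participants",
]

REQUIRED_TRIAL_COLUMNS = [
    "participant",
    "x",
    "target_type",
    "correct",
    "rt_ms",
]


@dataclass
class CellMeans:
    """Per-participant cell means plus preprocessing bookkeeping.

    ``table`` has one row per (participant, x, target_type) cell with
    columns ``mean_rt`` (over correct, in-range trials), ``n_used``,
    ``n_error``, ``n_outlier``, ``n_raw`` and ``error_pct``.  Cells in
    which every trial was excluded are absent from ``table`` and listed
    in ``empty_cells``.
    """

    table: pd.DataFrame
    n: int
    outlier_fraction: float
    error_fraction: float
    empty_cells: list[tuple] = field(default_factory=list)

    def pooled(self) -> pd.DataFrame:
        """Grand mean over participant cell means per (x, target_type),
        unweighted; ``n_used`` is summed for optional weighting."""
        g = self.table.groupby(["x", "target_type"], as_index=False).agg(
            mean_rt=("mean_rt", "mean"), n_used=("n_used", "sum")
        )
        return g


@dataclass
class FitResult:
    """One capacity's OLS fit: coefficients, standard errors, R²."""

    c: int
    form: str
    a: float | None
    a_se: float | None
    b: float | None
    b_se: float | None
    d: float | None
    d_se: float | None
    r2: float | None
    nobs: int
    predicts_no_variation: bool = False
    residuals: pd.Series | None = None

    def to_row(self) -> dict:
        return {
            "c": self.c,
            "a": self.a,
            "a_se": self.a_se,
            "b": self.b,
            "b_se": self.b_se,
            "d": self.d,
            "d_se": self.d_se,
            "r2": self.r2,
        }


def preprocess(
    trials: pd.DataFrame, rt_min: float = 200.0, rt_max: float = 2000.0
) -> CellMeans:
    """Reduce a trial table to per-participant cell means.

    Practice trials are dropped.  Error trials are excluded from RT
    means but counted in the error rate.  Correct trials with RT
    strictly below ``rt_min`` or strictly above ``rt_max`` are excluded
    as outliers.  Counts reconcile per cell:
    ``n_used + n_error + n_outlier == n_raw``.
    """
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    if trials.empty:
        raise ValueError("trial table is empty")
    df = trials.copy()
    if "practice" in df.columns:
        df = df.loc[~df["practice"].astype(bool)]
    if df.empty:
        raise ValueError("trial table contains no experimental trials")
    n = int(df["n"].iloc[0]) if "n" in df.columns else 8

    correct = df["correct"].astype(bool)
    rt = df["rt_ms"].astype(float)
    outlier = correct & ((rt < rt_min) | (rt > rt_max))
    used = correct & ~outlier
    df = df.assign(_error=~correct, _outlier=outlier, _used=used)

    grouped = df.groupby(["participant", "x", "target_type"])
    table = grouped.apply(
        lambda g: pd.Series(
            {
                "mean_rt": g.loc[g["_used"], "rt_ms"].mean(),
                "n_used": int(g["_used"].sum()),
                "n_error": int(g["_error"].sum()),
                "n_outlier": int(g["_outlier"].sum()),
                "n_raw": len(g),
            }
        ),
        include_groups=False,
    ).reset_index()
    table["error_pct"] = 100.0 * table["n_error"] / table["n_raw"]
    empty = table.loc[table["n_used"] == 0]
    empty_cells = list(
        empty[["participant", "x", "target_type"]].itertuples(index=False, name=None)
    )
    table = table.loc[table["n_used"] > 0].reset_index(drop=True)
    return CellMeans(
        table=table,
        n=n,
        outlier_fraction=float(df["_outlier"].mean()),
        error_fraction=float(df["_error"].mean()),
        empty_cells=empty_cells,
    )


def _predictors(
    cells: pd.DataFrame, c: int, form: str, n: int, exclude_r: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Model predictions and design matrix for one capacity.

    Returns (y_model, design_matrix, kept cells)."""
    if form == "eq5_mixed":
        y_model = np.array(
            [
                _model.expected_comparisons(
                    c, SearchCondition(n=n, x=int(row.x), t=row.target_type)
                )
                for row in cells.itertuples()
            ]
        )
        t_ind = (cells["target_type"] == ONSET).to_numpy(dtype=float)
        X = np.column_stack([y_model, t_ind, np.ones(len(cells))])
        return y_model, X, cells
    if form == "eq6_blocked":
        r = np.where(
            cells["target_type"] == ONSET, cells["x"], n - cells["x"]
        ).astype(int)
        keep = ~np.isin(r, list(exclude_r))
        cells = cells.loc[keep].reset_index(drop=True)
        r = r[keep]
        y_model = np.array(
            [_model.blocked_expected_comparisons(c, n, int(ri)) for ri in r]
        )
        X = np.column_stack([y_model, np.ones(len(cells))])
        return y_model, X, cells
    raise ValueError(f"unknown form {form!r}: expected 'eq5_mixed' or 'eq6_blocked'")


class PriorityTagRegressor(RegressorMixin, BaseEstimator):
    """OLS regression of RT on the capacity-``c`` model's predictions.

    Parameters
    ----------
    c : int
        Priority-set capacity whose predictions are the regressor.
    form : {"eq5_mixed", "eq6_blocked"}
        Mixed form regresses RT on ``y`` and a target-type indicator
        (onset = 1); blocked form on ``y`` alone.
    n : int
        Display size.

    ``X`` has two columns ``(x, onset_indicator)`` in mixed form and a
    single column ``(r,)`` in blocked form; ``y`` is the RT in ms.

    Fitted attributes: ``a_``, ``b_`` (None in blocked form), ``d_``
    with standard errors ``a_se_``, ``b_se_``, ``d_se_``, and ``r2_``.
    When the capacity predicts no RT variation over the design (e.g.
    ``c = 0``), ``predicts_no_variation_`` is True, ``a_`` is None and a
    reduced model (indicator + intercept, or intercept only) is fit.
    """

    def __init__(self, c: int = 1, form: str = "eq5_mixed", n: int = 8):
        self.c = c
        self.form = form
        self.n = n

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.form == "eq5_mixed":
            if X.shape[1] != 2:
                raise ValueError("mixed form expects columns (x, onset_indicator)")
            conds = [
                SearchCondition(
                    n=self.n, x=int(xi), t=ONSET if ti >= 0.5 else NO_ONSET
                )
                for xi, ti in X
            ]
            y_model = np.array(
                [_model.expected_comparisons(self.c, cond) for cond in conds]
            )
            return np.column_stack([y_model, X[:, 1], np.ones(len(X))])
        if self.form == "eq6_blocked":
            if X.shape[1] != 1:
                raise ValueError("blocked form expects a single column (r,)")
            y_model = np.array(
                [
                    _model.blocked_expected_comparisons(self.c, self.n, int(ri))
                    for ri in X[:, 0]
                ]
            )
            return np.column_stack([y_model, np.ones(len(X))])
        raise ValueError(f"unknown form {self.form!r}")

    def fit(self, X, y, sample_weight=None):
        D = self._design(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(D):
            raise ValueError("X and y have inconsistent lengths")
        min_cells = 3 if self.form == "eq5_mixed" else 2
        if len(y) < min_cells:
            raise ValueError(
                f"need at least {min_cells} cells to fit form {self.form!r}"
            )
        y_model = D[:, 0]
        degenerate = np.ptp(y_model) == 0
        if degenerate:
            D_red = D[:, 1:]
        else:
            D_red = D
            rank = np.linalg.matrix_rank(D)
            if rank < D.shape[1]:
                raise ValueError(
                    "rank-deficient design matrix: predictors are collinear "
                    f"(rank {rank} < {D.shape[1]})"
                )
        if sample_weight is None:
            res = sm.OLS(y, D_red).fit()
        else:
            res = sm.WLS(y, D_red, weights=np.asarray(sample_weight, float)).fit()
        params = list(res.params)
        bse = list(res.bse)
        if degenerate:
            params = [None] + params
            bse = [None] + bse
        if self.form == "eq5_mixed":
            self.a_, self.b_, self.d_ = params
            self.a_se_, self.b_se_, self.d_se_ = bse
        else:
            self.a_, self.d_ = params
            self.a_se_, self.d_se_ = bse
            self.b_ = None
            self.b_se_ = None
        self.r2_ = 0.0 if (degenerate and self.form == "eq6_blocked") else float(
            res.rsquared
        )
        self.predicts_no_variation_ = bool(degenerate)
        self.residuals_ = pd.Series(res.resid)
        self.n_features_in_ = np.asarray(X).shape[1]
        self._ols_result = res
        return self

    def predict(self, X):
        D = self._design(X)
        a = 0.0 if self.a_ is None else self.a_
        coefs = np.array(
            [a, self.b_, self.d_]
            if self.form == "eq5_mixed"
            else [a, self.d_],
            dtype=float,
        )
        return D @ coefs

    def result(self) -> FitResult:
        """Package the fitted coefficients as a :class:`FitResult`."""
        return FitResult(
            c=self.c,
            form=self.form,
            a=self.a_,
            a_se=self.a_se_,
            b=self.b_,
            b_se=self.b_se_,
            d=self.d_,
            d_se=self.d_se_,
            r2=self.r2_,
            nobs=len(self.residuals_),
            predicts_no_variation=self.predicts_no_variation_,
            residuals=self.residuals_,
        )


def _cells_to_Xy(
    cells: pd.DataFrame, form: str, n: int, exclude_r: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert pooled cell means to estimator inputs (X, y, weights)."""
    if form == "eq6_blocked":
        r = np.where(cells["target_type"] == ONSET, cells["x"], n - cells["x"]).astype(
            int
        )
        keep = ~np.isin(r, list(exclude_r))
        cells = cells.loc[keep]
        X = r[keep].reshape(-1, 1)
    else:
        X = np.column_stack(
            [
                cells["x"].to_numpy(dtype=float),
                (cells["target_type"] == ONSET).to_numpy(dtype=float),
            ]
        )
    y = cells["mean_rt"].to_numpy(dtype=float)
    w = cells["n_used"].to_numpy(dtype=float) if "n_used" in cells else None
    return X, y, w


def fit_capacity(
    cells: CellMeans | pd.DataFrame,
    c: int,
    form: str = "eq5_mixed",
    n: int | None = None,
    weighted: bool = False,
    exclude_r: Sequence[int] = (1,),
) -> FitResult:
    """Fit the capacity-``c`` regression on cell-mean RTs.

    ``cells`` may be a :class:`CellMeans` (participant cells are pooled
    by unweighted grand mean) or a pooled DataFrame with columns
    ``x, target_type, mean_rt`` (optionally ``n_used``).  ``weighted``
    switches to WLS with cell trial counts as weights.  Blocked fits
    exclude the ``r`` levels in ``exclude_r`` (the single-relevant-item
    level by default, where the target location is fully predictable).
    """
    if isinstance(cells, CellMeans):
        n = n if n is not None else cells.n
        table = cells.pooled()
    else:
        table = cells
        if "participant" in table.columns:
            table = (
                table.groupby(["x", "target_type"], as_index=False)
                .agg(mean_rt=("mean_rt", "mean"), n_used=("n_used", "sum"))
            )
        n = n if n is not None else 8
    X, y, w = _cells_to_Xy(table, form, n, exclude_r)
    reg = PriorityTagRegressor(c=c, form=form, n=n)
    reg.fit(X, y, sample_weight=w if weighted else None)
    return reg.result()


def classify_participants(
    r2_matrix: pd.DataFrame, boundary: int = 2
) -> dict:
    """Classify each participant by the capacity maximising their R².

    Ties go to the smallest capacity.  Returns the per-participant best
    capacity and the counts at-or-below vs above ``boundary``.
    """
    cols = sorted(r2_matrix.columns)
    best = r2_matrix[cols].idxmax(axis=1)
    at_or_below = int((best <= boundary).sum())
    return {
        "boundary": boundary,
        "best_capacity": best,
        "n_at_or_below": at_or_below,
        "n_above": int(len(best) - at_or_below),
    }


class CapacitySelector(BaseEstimator):
    """Sweep capacities 0..n, fit each, and select the best by R².

    ``fit`` takes a trial table (the CSV schema of
    :mod:`prioritytag.datasets`; real data in the same schema works
    identically).  The pipeline is: preprocess to per-participant cell
    means; pooled OLS per capacity; per-participant OLS per capacity;
    one-way repeated-measures ANOVA on participant R² across
    prediction-distinct capacity levels with Greenhouse-Geisser
    correction; uncorrected pairwise paired t-tests (LSD post-hoc);
    selection of the pooled-R² maximiser with ties broken toward smaller
    capacity and the full prediction-equivalence group reported.

    Parameters
    ----------
    capacities : sequence of int, optional
        Capacities to fit (default 0..n).
    form : {"eq5_mixed", "eq6_blocked"}
    n : int
        Display size.
    target_type : str, optional
        For blocked data, restrict to one block type ("onset" or
        "no_onset"); required when both types are present under the
        blocked form.
    rt_min, rt_max : float
        Outlier exclusion bounds in ms.
    weighted : bool
        Weight pooled cells by trial count (WLS).
    run_anova : bool
        Skip the ANOVA/post-hoc stage when False (used by large
        recovery sweeps where only selection is needed).
    boundary : int
        Classification boundary for :func:`classify_participants`.
    exclude_r : sequence of int
        Relevant-set sizes excluded from blocked fits.
    """

    def __init__(
        self,
        capacities: Sequence[int] | None = None,
        form: str = "eq5_mixed",
        n: int = 8,
        target_type: str | None = None,
        rt_min: float = 200.0,
        rt_max: float = 2000.0,
        weighted: bool = False,
        run_anova: bool = True,
        boundary: int = 2,
        exclude_r: Sequence[int] = (1,),
    ):
        self.capacities = capacities
        self.form = form
        self.n = n
        self.target_type = target_type
        self.rt_min = rt_min
        self.rt_max = rt_max
        self.weighted = weighted
        self.run_anova = run_anova
        self.boundary = boundary
        self.exclude_r = exclude_r

    # -- helpers ----------------------------------------------------------
    def _design_conditions(self, cells: pd.DataFrame) -> list[SearchCondition]:
        conds = []
        for x, t in cells[["x", "target_type"]].drop_duplicates().itertuples(
            index=False
        ):
            if self.form == "eq6_blocked":
                r = int(x) if t == ONSET else self.n - int(x)
                if r in tuple(self.exclude_r):
                    continue
                conds.append(SearchCondition(n=self.n, x=r, t=ONSET))
            else:
                conds.append(SearchCondition(n=self.n, x=int(x), t=t))
        return conds

    # -- fitting ----------------------------------------------------------
    def fit(self, trials: pd.DataFrame, y=None):
        df = trials
        if self.form == "eq6_blocked":
            if self.target_type is not None:
                df = df.loc[df["target_type"] == self.target_type]
            elif df["target_type"].nunique() > 1:
                raise ValueError(
                    "blocked form fits one block type at a time: pass "
                    "target_type='onset' or 'no_onset'"
                )
            if df.empty:
                raise ValueError(f"no trials with target_type={self.target_type!r}")
        cells = preprocess(df, rt_min=self.rt_min, rt_max=self.rt_max)
        self.cells_ = cells
        caps = (
            list(self.capacities)
            if self.capacities is not None
            else list(range(self.n + 1))
        )
        if len(caps) < 2:
            raise ValueError("need at least 2 capacity levels to compare")

        pooled = cells.pooled()
        self.fits_ = {}
        for c in caps:
            X, yv, w = _cells_to_Xy(pooled, self.form, self.n, self.exclude_r)
            reg = PriorityTagRegressor(c=c, form=self.form, n=self.n)
            reg.fit(X, yv, sample_weight=w if self.weighted else None)
            self.fits_[c] = reg.result()
        self.results_ = pd.DataFrame([self.fits_[c].to_row() for c in caps])

        # per-participant fits
        r2_rows = {}
        for pid, ptable in cells.table.groupby("participant"):
            row = {}
            for c in caps:
                X, yv, _ = _cells_to_Xy(ptable, self.form, self.n, self.exclude_r)
                reg = PriorityTagRegressor(c=c, form=self.form, n=self.n).fit(X, yv)
                if not reg.predicts_no_variation_:
                    row[c] = reg.r2_
            r2_rows[pid] = row
        self.r2_matrix_ = pd.DataFrame.from_dict(r2_rows, orient="index").sort_index()
        self.r2_matrix_.index.name = "participant"

        # prediction-equivalence groups over the observed design cells
        conds = self._design_conditions(cells.table)
        groups = _model.equivalent_capacities(self.n, conds)
        self.equivalence_groups_ = [
            [c for c in g if c in caps] for g in groups if any(c in caps for c in g)
        ]

        # selection on pooled R² (degenerate fits excluded)
        valid = [
            c for c in caps if not self.fits_[c].predicts_no_variation
        ]
        if not valid:
            raise ValueError("every requested capacity predicts no variation")
        r2s = np.array([self.fits_[c].r2 for c in valid])
        self.selected_capacity_ = int(valid[int(np.argmax(r2s))])
        self.tie_group_ = next(
            g for g in self.equivalence_groups_ if self.selected_capacity_ in g
        )

        self._run_anova_stage()
        cls = classify_participants(self.r2_matrix_, boundary=self.boundary)
        self.classification_ = cls
        return self

    def _run_anova_stage(self) -> None:
        self.anova_ = None
        self.posthoc_ = None
        self.anova_applicable_ = False
        if not self.run_anova:
            return
        # one level per prediction-equivalence group (identical columns
        # would otherwise make the within factor singular)
        reps = [
            g[0]
            for g in self.equivalence_groups_
            if g[0] in self.r2_matrix_.columns
        ]
        mat = self.r2_matrix_[reps]
        if len(mat) < 2 or mat.shape[1] < 2:
            return
        if float(mat.to_numpy().std()) == 0.0:
            return  # constant R² everywhere: ANOVA inapplicable
        long = mat.reset_index().melt(
            id_vars="participant", var_name="capacity", value_name="r2"
        )
        long["capacity"] = long["capacity"].astype(str)
        try:
            # near-tied R^2 columns (common on low-noise synthetic data)
            # trigger harmless precision warnings inside the test stats
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                aov = pg.rm_anova(
                    data=long,
                    dv="r2",
                    within="capacity",
                    subject="participant",
                    correction=True,
                    detailed=False,
                )
                self.posthoc_ = pg.pairwise_tests(
                    data=long,
                    dv="r2",
                    within="capacity",
                    subject="participant",
                    padjust="none",
                )
        except Exception:
            return
        self.anova_ = aov
        self.anova_applicable_ = True

    # -- reporting --------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-ready model-comparison report."""
        def _aov_dict(aov: pd.DataFrame | None) -> dict | None:
            if aov is None:
                return None
            row = aov.iloc[0].to_dict()
            return {k: (None if pd.isna(v) else v) for k, v in row.items()
                    if not isinstance(v, (pd.Series, pd.DataFrame))}

        posthoc = None
        if self.posthoc_ is not None:
            posthoc = self.posthoc_[
                [c for c in ("A", "B", "T", "dof", "p_unc") if c in self.posthoc_]
            ].to_dict(orient="records")
        return {
            "form": self.form,
            "n": self.n,
            "selected_capacity": self.selected_capacity_,
            "tie_group": list(self.tie_group_),
            "equivalence_groups": [list(g) for g in self.equivalence_groups_],
            "pooled_fits": self.results_.where(pd.notna(self.results_), None).to_dict(
                orient="records"
            ),
            "r2_matrix": {
                str(p): {str(c): float(v) for c, v in row.items()}
                for p, row in self.r2_matrix_.iterrows()
            },
            "anova": _aov_dict(self.anova_),
            "anova_applicable": self.anova_applicable_,
            "posthoc": posthoc,
            "classification": {
                "boundary": self.classification_["boundary"],
                "n_at_or_below": self.classification_["n_at_or_below"],
                "n_above": self.classification_["n_above"],
                "best_capacity": {
                    str(p): int(c)
                    for p, c in self.classification_["best_capacity"].items()
                },
            },
            "preprocessing": {
                "outlier_fraction": self.cells_.outlier_fraction,
                "error_fraction": self.cells_.error_fraction,
                "empty_cells": [list(map(str, t)) for t in self.cells_.empty_cells],
            },
        }


def compare_capacities(
    trials: pd.DataFrame,
    form: str = "eq5_mixed",
    capacities: Sequence[int] | None = None,
    n: int = 8,
    **kwargs,
) -> CapacitySelector:
    """Fit every capacity and select the best; returns the fitted
    :class:`CapacitySelector` (the model-comparison object)."""
    sel = CapacitySelector(capacities=capacities, form=form, n=n, **kwargs)
    return sel.fit(trials)
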