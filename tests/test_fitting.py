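"""Preprocessing, per-capacity regression, and capacity selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from prioritytag import (
    NO_ONSET,
    ONSET,
    CapacitySelector,
    GenerativeParams,
    PriorityTagRegressor,
    build_design,
    classify_participants,
    compare_capacities,
    fit_capacity,
    generate_trials,
    preprocess,
)


def tiny_trials(rows):
    """Trial table from (participant, x, t, correct, rt) tuples."""
    return pd.DataFrame(
        [
            {
                "participant": p, "block": 1, "experiment": "exp1", "n": 8,
                "x": x, "target_type": t, "target_pos": 1,
                "correct": ok, "rt_ms": rt, "practice": False,
            }
            for p, x, t, ok, rt in rows
        ]
    )


class TestPreprocess:
    def test_outlier_and_error_exclusion_reconciles(self):
        trials = tiny_trials([
            (1, 1, NO_ONSET, True, 150.0),    # fast outlier
            (1, 1, NO_ONSET, True, 2500.0),   # slow outlier
            (1, 1, NO_ONSET, True, 600.0),
            (1, 1, NO_ONSET, True, 800.0),
            (1, 1, NO_ONSET, False, 700.0),   # error, in range
            (1, 2, ONSET, True, 500.0),
        ])
        cells = preprocess(trials)
        row = cells.table.set_index(["x", "target_type"]).loc[(1, NO_ONSET)]
        assert row.n_raw == 5
        assert row.n_outlier == 2
        assert row.n_error == 1
        assert row.n_used == 2
        assert row.n_used + row.n_error + row.n_outlier == row.n_raw
        assert row.mean_rt == 700.0  # mean of the two kept trials

    def test_boundary_rts_are_kept(self):
        trials = tiny_trials([
            (1, 1, NO_ONSET, True, 200.0),
            (1, 1, NO_ONSET, True, 2000.0),
        ])
        cells = preprocess(trials)
        assert cells.table.iloc[0].n_used == 2

    def test_all_excluded_cell_reported_not_dropped_silently(self):
        trials = tiny_trials([
            (1, 1, NO_ONSET, False, 700.0),
            (1, 2, ONSET, True, 500.0),
        ])
        cells = preprocess(trials)
        assert (1, 1, NO_ONSET) in cells.empty_cells
        assert (1, NO_ONSET) not in set(
            zip(cells.table.x, cells.table.target_type)
        )

    def test_planted_outlier_fraction_recovered(self, exp1_design):
        params = GenerativeParams(outlier_rate=0.011, sigma=120.0)
        trials = generate_trials(exp1_design, params, 20, seed=13)
        cells = preprocess(trials)
        n = (~trials.practice).sum()
        se = np.sqrt(0.011 * 0.989 / n)
        assert abs(cells.outlier_fraction - 0.011) < 5 * se

    def test_empty_and_malformed_inputs(self):
        valid = tiny_trials([(1, 1, NO_ONSET, True, 700.0)])
        with pytest.raises(ValueError, match="empty"):
            preprocess(valid.iloc[0:0])
        with pytest.raises(ValueError, match="missing required columns"):
            preprocess(pd.DataFrame({"rt_ms": [1.0]}))


class TestFitCapacity:
    def test_noiseless_exact_recovery(self, noiseless_trials_exp1, noiseless_params):
        cells = preprocess(noiseless_trials_exp1)
        fr = fit_capacity(cells, c=noiseless_params.c_true)
        assert abs(fr.a - noiseless_params.a) / noiseless_params.a < 1e-9
        assert abs(fr.b - noiseless_params.b) / abs(noiseless_params.b) < 1e-9
        assert abs(fr.d - noiseless_params.d) / noiseless_params.d < 1e-9
        assert fr.r2 == pytest.approx(1.0, abs=1e-12)
        assert fr.a_se == pytest.approx(0.0, abs=1e-6)

    def test_zero_capacity_flagged_predicts_no_variation(
        self, noiseless_trials_exp1
    ):
        fr = fit_capacity(preprocess(noiseless_trials_exp1), c=0)
        assert fr.predicts_no_variation
        assert fr.a is None and fr.a_se is None

    def test_r2_profile_decreases_beyond_true_capacity(self, noisy_trials_exp1):
        cells = preprocess(noisy_trials_exp1)
        r2 = {c: fit_capacity(cells, c=c).r2 for c in range(1, 9)}
        assert r2[1] == max(r2.values())
        # monotone decline from the true capacity to the top group
        vals = [r2[c] for c in range(1, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_equivalent_capacities_share_identical_fits(self, noisy_trials_exp1):
        cells = preprocess(noisy_trials_exp1)
        fits = [fit_capacity(cells, c=c) for c in (6, 7, 8)]
        assert fits[0].a == fits[1].a == fits[2].a
        assert fits[0].r2 == fits[1].r2 == fits[2].r2

    def test_r2_invariant_to_affine_rt_rescaling(self, noisy_trials_exp1):
        cells = preprocess(noisy_trials_exp1)
        fr = fit_capacity(cells, c=1)
        scaled = cells.table.copy()
        scaled["mean_rt"] = 2.0 * scaled["mean_rt"] + 100.0
        fr2 = fit_capacity(scaled, c=1)
        assert fr2.r2 == pytest.approx(fr.r2, abs=1e-12)
        assert fr2.a == pytest.approx(2.0 * fr.a, rel=1e-9)
        assert fr2.d == pytest.approx(2.0 * fr.d + 100.0, rel=1e-9)

    def test_weighted_option_runs_and_differs(self, noisy_trials_exp1):
        cells = preprocess(noisy_trials_exp1)
        fr_u = fit_capacity(cells, c=1, weighted=False)
        fr_w = fit_capacity(cells, c=1, weighted=True)
        assert fr_w.r2 is not None and fr_w.a != fr_u.a

    def test_blocked_fit_excludes_single_relevant_item(self):
        design = build_design("exp3")
        params = GenerativeParams(c_true=8, sigma=0, lapse=0, outlier_rate=0,
                                  a_sd=0, b_sd=0, d_sd=0, a=90.0, b=0.0, d=520.0)
        trials = generate_trials(design, params, 2, seed=21)
        onset = trials[trials.target_type == ONSET]
        cells = preprocess(onset)
        fr = fit_capacity(cells, c=8, form="eq6_blocked")
        assert fr.nobs == 7  # r = 2..8
        assert fr.b is None
        assert fr.a == pytest.approx(90.0, rel=1e-9)
        assert fr.d == pytest.approx(520.0, rel=1e-9)
        assert fr.r2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_cells_rejected(self):
        trials = tiny_trials([(1, 1, NO_ONSET, True, 700.0),
                              (1, 2, ONSET, True, 500.0)])
        with pytest.raises(ValueError, match="at least 3 cells"):
            fit_capacity(preprocess(trials), c=1)


class TestPriorityTagRegressorAPI:
    """scikit-learn estimator contract."""

    def test_get_set_params_and_clone(self):
        reg = PriorityTagRegressor(c=3, form="eq6_blocked", n=8)
        assert reg.get_params() == {"c": 3, "form": "eq6_blocked", "n": 8}
        reg2 = clone(reg).set_params(c=5)
        assert reg2.c == 5 and reg2.form == "eq6_blocked"

    def test_fit_predict_roundtrip(self):
        X = np.array([[x, t] for x in range(1, 7) for t in (0, 1)], dtype=float)
        y = 30.0 * np.array(
            [
                PriorityTagRegressor(c=2)._design(X[i: i + 1])[0, 0]
                for i in range(len(X))
            ]
        ) - 70.0 * X[:, 1] + 760.0
        reg = PriorityTagRegressor(c=2).fit(X, y)
        assert np.allclose(reg.predict(X), y)
        assert reg.score(X, y) == pytest.approx(1.0)

    def test_rank_deficient_design_rejected(self):
        # single onset count with both target types: y and the indicator
        # are collinear with the intercept
        X = np.array([[2, 0], [2, 1], [2, 0], [2, 1]], dtype=float)
        y = np.array([700.0, 650.0, 710.0, 640.0])
        with pytest.raises(ValueError, match="rank-deficient"):
            PriorityTagRegressor(c=1).fit(X, y)


class TestCapacitySelector:
    def test_selects_true_capacity_on_noiseless_data(
        self, noiseless_trials_exp1
    ):
        sel = compare_capacities(noiseless_trials_exp1)
        assert sel.selected_capacity_ == 1
        assert sel.tie_group_ == [1]
        assert sel.fits_[1].r2 == pytest.approx(1.0, abs=1e-12)

    def test_anova_and_posthoc_on_noisy_data(self, noisy_trials_exp1):
        sel = compare_capacities(noisy_trials_exp1)
        assert sel.selected_capacity_ in (1, 2)
        assert sel.anova_applicable_
        aov = sel.anova_.iloc[0]
        # 6 prediction-distinct levels (c=1..5 and the 6/7/8 group),
        # 22 participants -> df = (5, 105)
        assert aov["ddof1"] == 5
        assert aov["ddof2"] == 105
        assert "p_GG_corr" in sel.anova_.columns
        assert len(sel.posthoc_) == 15  # all pairs of 6 levels
        assert [6, 7, 8] in sel.equivalence_groups_

    def test_selection_reports_full_tie_group(self, exp1_design):
        params = GenerativeParams(c_true=8, sigma=80.0)
        trials = generate_trials(exp1_design, params, 22, seed=19)
        sel = compare_capacities(trials)
        if sel.selected_capacity_ in (6, 7, 8):
            assert sel.selected_capacity_ == 6  # tie broken toward smaller c
            assert sel.tie_group_ == [6, 7, 8]

    def test_blocked_requires_single_target_type(self):
        design = build_design("exp3")
        trials = generate_trials(design, GenerativeParams(), 3, seed=23)
        with pytest.raises(ValueError, match="one block type"):
            compare_capacities(trials, form="eq6_blocked")
        sel = compare_capacities(trials, form="eq6_blocked", target_type=ONSET)
        assert sel.selected_capacity_ in range(0, 9)

    def test_blocked_selection_at_top_group(self):
        design = build_design("exp3")
        params = GenerativeParams(c_true=8, sigma=60.0, a=90.0, d=520.0)
        trials = generate_trials(design, params, 12, seed=29)
        sel = compare_capacities(trials, form="eq6_blocked", target_type=ONSET)
        # r = 2..8 distinguishes all capacities except 7 vs 8
        assert sel.selected_capacity_ in (7, 8)
        assert sel.tie_group_ == [7, 8]

    def test_degenerate_constant_r2_flagged_inapplicable(
        self, noisy_trials_exp1
    ):
        sel = compare_capacities(noisy_trials_exp1, capacities=[6, 7, 8])
        assert not sel.anova_applicable_
        assert sel.anova_ is None

    def test_report_is_json_ready(self, noisy_trials_exp1):
        import json

        sel = compare_capacities(noisy_trials_exp1)
        report = json.dumps(sel.to_dict(), default=float)
        assert "selected_capacity" in report

    def test_get_params_roundtrip(self):
        sel = CapacitySelector(n=8, boundary=3)
        assert clone(sel).get_params()["boundary"] == 3


class TestClassifyParticipants:
    def test_exact_on_noiseless_single_participant(self, exp1_design):
        params = GenerativeParams(c_true=4, sigma=0, lapse=0, outlier_rate=0,
                                  a_sd=0, b_sd=0, d_sd=0)
        trials = generate_trials(exp1_design, params, 1, seed=31)
        sel = compare_capacities(trials.assign(participant=1), run_anova=False)
        cls = sel.classification_
        assert cls["best_capacity"].iloc[0] == 4
        assert cls["n_above"] == 1 and cls["n_at_or_below"] == 0

    def test_mixture_splits_near_half(self, exp1_design):
        lo = generate_trials(
            exp1_design, GenerativeParams(c_true=1, sigma=80.0), 8, seed=37
        )
        hi = generate_trials(
            exp1_design, GenerativeParams(c_true=8, sigma=80.0), 8, seed=41
        )
        hi["participant"] += 8
        sel = compare_capacities(pd.concat([lo, hi]), run_anova=False)
        frac = sel.classification_["n_at_or_below"] / 16
        assert 0.25 <= frac <= 0.75

    def test_tie_break_toward_smaller_capacity(self):
        mat = pd.DataFrame({1: [0.9], 2: [0.9], 3: [0.5]}, index=["p1"])
        cls = classify_participants(mat, boundary=2)
        assert cls["best_capacity"].loc["p1"] == 1
        assert cls["n_at_or_below"] == 1
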