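# prioritytag

Tools for modelling attention capture by abrupt onsets in visual search.

When some items in a search display appear abruptly at previously empty
locations ("onsets") they tend to be inspected before the items revealed
from existing placeholders ("no-onsets"). The priority-tag account of
this effect holds that up to *c* onsets are tagged and searched first;
this package turns that account into a quantitative, testable pipeline:

* **Closed-form predictions** (`prioritytag.model`) — the expected
  number of item comparisons *y*(*c*; *n*, *x*, *t*) in a serial
  self-terminating search over *n* items with *x* onsets and target type
  *t*, for any priority-set capacity *c*. With the effective priority
  set *m* = min(*c*, *x*):

  | regime | onset target | no-onset target |
  |---|---|---|
  | *c* < *x* | (*n* + *c* + 1)/2 − *cn*/(2*x*) | (*n* + *c* + 1)/2 |
  | *c* ≥ *x* | (*x* + 1)/2 | *x* + (*n* − *x* + 1)/2 |

  Blocked designs (target type known in advance) reuse the onset-target
  branch with the number of search-relevant items *r* in place of *x*.
* **Simulation oracles** (`prioritytag.simulate`) — a trial-level
  stochastic simulator of the two-stage search and an exhaustive
  enumerator that reproduces the expectations exactly in rational
  arithmetic, independently of the closed forms.
* **Synthetic experiments** (`prioritytag.datasets`) — generators for
  the three classic designs (mixed onset counts with inverse-probability
  target-type allocation at 400 and 560 trials per participant; a
  blocked design at 512), with RTs from the linear model
  RT = *a*·*y* + *b*·1[onset target] + *d* plus noise, lapses and
  planted outliers.
* **Capacity selection** (`prioritytag.fitting`) — scikit-learn style
  estimators that regress cell-mean RTs on each capacity's predictions
  (`PriorityTagRegressor`) and select the best-fitting capacity by
  pooled R², backed by a Greenhouse-Geisser-corrected repeated-measures
  ANOVA on per-participant R² with LSD post-hoc tests
  (`CapacitySelector`).

It is aimed at researchers in visual attention who want to fit the
capacity model to their own trial tables, validate analysis pipelines on
synthetic data with known ground truth, or explore the model's
predictions.

## Worked example

Generate a synthetic 22-participant mixed-design dataset whose true
capacity is 1, then fit all capacities:

```bash
$ prioritytag simulate --design exp1 --participants 22 --seed 7 --out-dir demo
[3d93d4a5c4b0] wrote demo/trials_exp1.csv: 8800 experimental trials (22 x 400),
error rate 3.9%, outliers outside [200, 2000] ms 1.1%

$ prioritytag fit --input demo/trials_exp1.csv --out-dir demo
wrote demo/fits_trials_exp1.csv and demo/comparison_trials_exp1.json:
selected c = 1 (tie group [1]), 19/22 participants best fit at c <= 2
```

The fit table (one row per capacity) starts:

```
c,a,a_se,b,b_se,d,d_se,r2
0,,,-114.1,18.3,917.6,13.0,0.829
1,27.47,2.13,-71.99,5.12,782.98,10.80,0.993
2,21.25,4.87,-65.94,15.02,807.08,26.34,0.954
```

Reading the selected row (*c* = 1): the search rate *a* ≈ 27 ms per
comparison, the onset advantage *b* ≈ −72 ms (onset targets are found
faster than the comparison count alone predicts), and the base time
*d* ≈ 783 ms covers encoding and response processes. R² = 0.993 at the
true capacity and declines for every larger capacity; the *c* = 0 row
carries no slope because a zero-capacity model predicts no variation
with onset count. The JSON report adds the per-participant R² matrix,
the ANOVA and post-hoc tables, and the participant classification.

The same pipeline is available as library calls:

```python
from prioritytag import GenerativeParams, build_design, generate_trials, compare_capacities

trials = generate_trials(build_design("exp1"), GenerativeParams(c_true=1), 22, seed=7)
sel = compare_capacities(trials)
sel.selected_capacity_   # 1
```

`prioritytag predict` writes the model's prediction tables,
`prioritytag recover` runs simulate-and-refit recovery studies, and
blocked (exp3-style) data are fitted per block type automatically.

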