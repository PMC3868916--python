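"""Synthetic trial-level datasets with the structure of the three designs.

The three experiment designs share a display of ``n = 8`` letters in
which the number of abrupt onsets varies:

* ``exp1`` — mixed design, onsets in {0, 1, 2, 4, 6, 8}, 400
  experimental trials per participant.  The probability that the target
  is an onset equals ``x/8`` at every onset count, so target type is
  uninformative.
* ``exp2`` — same logic with two extra onset levels (3 and 5), 560
  trials per participant.
* ``exp3`` — target type blocked into two sessions (order
  counterbalanced across participants); 32 trials for each combination
  of target type and number of search-relevant items 1..8, 512 trials
  total.

Reaction times are generated from the linear mapping
``RT = a * k + b * 1[t = onset] + d + noise`` where ``k`` is the
per-trial comparison count drawn from the search simulator at the
generating capacity ``c_true``, ``a`` is the search rate (ms per
comparison), ``b`` the onset advantage (negative: onset targets are
faster) and ``d`` the base time for everything outside the scan.
Participant-level coefficients are drawn around the population values.
A fixed proportion of trials are lapses (errors) and a fixed proportion
are RT outliers planted outside the 200–2000 ms analysis window.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import NO_ONSET, ONSET, SearchCondition, expected_comparisons
from .simulate import sample_comparisons

__all__ = [
    "DesignCell",
    "DesignSpec",
    "GenerativeParams",
    "build_design",
    "generate_trials",
    "target_position_distribution",
    "write_config",
    "load_config",
    "generate_from_config",
]

#: Schema of generated trial tables (the CSV contract).
TRIAL_COLUMNS = [
    "participant",
    "block",
    "experiment",
    "n",
    "x",
    "target_type",
    "target_pos",
    "correct",
    "rt_ms",
    "practice",
]

# Per-cell experimental trial counts for the mixed designs, keyed by
# (number of onsets, target type).  Onset-target counts are inversely
# proportional to the number of onsets so that the onset-target fraction
# at each x equals x/8 exactly.
_EXP1_CELLS: dict[tuple[int, str], int] = {
    (0, NO_ONSET): 20,
    (1, NO_ONSET): 140,
    (1, ONSET): 20,
    (2, NO_ONSET): 60,
    (2, ONSET): 20,
    (4, NO_ONSET): 20,
    (4, ONSET): 20,
    (6, NO_ONSET): 20,
    (6, ONSET): 60,
    (8, ONSET): 20,
}

_EXP2_CELLS: dict[tuple[int, str], int] = {
    (0, NO_ONSET): 20,
    (1, NO_ONSET): 140,
    (1, ONSET): 20,
    (2, NO_ONSET): 60,
    (2, ONSET): 20,
    (3, NO_ONSET): 50,
    (3, ONSET): 30,
    (4, NO_ONSET): 20,
    (4, ONSET): 20,
    (5, NO_ONSET): 30,
    (5, ONSET): 50,
    (6, NO_ONSET): 20,
    (6, ONSET): 60,
    (8, ONSET): 20,
}

_EXP3_TRIALS_PER_CELL = 32
_BLOCK_SIZE = {"exp1": 50, "exp2": 56, "exp3": 32}


@dataclass(frozen=True)
class DesignCell:
    """One design cell: ``x`` onsets, target type, trials per participant."""

    x: int
    t: str
    n_trials: int


@dataclass(frozen=True)
class DesignSpec:
    """An experiment's cell structure and blocking."""

    experiment: str
    n: int
    cells: tuple[DesignCell, ...]
    blocking: str  # "mixed" | "blocked_by_target_type"
    practice_trials: int = 20

    @property
    def trials_per_participant(self) -> int:
        return sum(cell.n_trials for cell in self.cells)

    def relevant_set_size(self, cell: DesignCell) -> int:
        """Number of search-relevant items for a blocked cell: the onsets
        in an onset block, the no-onsets in a no-onset block."""
        return cell.x if cell.t == ONSET else self.n - cell.x


def build_design(experiment: str) -> DesignSpec:
    """Return the cell structure of one of the three designs.

    ``exp1``/``exp2`` are the mixed designs (400 and 560 experimental
    trials); ``exp3`` is the blocked design (512 trials).
    """
    if experiment == "exp1":
        cells = tuple(DesignCell(x, t, k) for (x, t), k in _EXP1_CELLS.items())
        return DesignSpec("exp1", 8, cells, "mixed")
    if experiment == "exp2":
        cells = tuple(DesignCell(x, t, k) for (x, t), k in _EXP2_CELLS.items())
        return DesignSpec("exp2", 8, cells, "mixed")
    if experiment == "exp3":
        n = 8
        cells = []
        for t in (ONSET, NO_ONSET):
            for r in range(1, n + 1):
                x = r if t == ONSET else n - r
                cells.append(DesignCell(x, t, _EXP3_TRIALS_PER_CELL))
        return DesignSpec("exp3", n, tuple(cells), "blocked_by_target_type")
    raise ValueError(f"unknown experiment {experiment!r}: expected exp1, exp2 or exp3")


@dataclass(frozen=True)
class GenerativeParams:
    """Population parameters of the RT-generating process.

    ``a``/``b``/``d`` are the population regression coefficients in ms;
    ``c_true`` the generating capacity; ``sigma`` the trial-level
    Gaussian RT noise SD; ``lapse`` the per-trial error probability;
    ``outlier_rate`` the probability of replacing a trial's RT with a
    value outside the analysis window; ``a_sd``/``b_sd``/``d_sd`` the
    between-participant SDs of the coefficients (``a`` is truncated at
    zero).  ``noise="lognormal"`` switches the trial noise to a
    log-normal multiplicative model with the same SD scale.
    """

    a: float = 31.6
    b: float = -74.1
    d: float = 764.0
    c_true: int = 1
    sigma: float = 150.0
    lapse: float = 0.037
    outlier_rate: float = 0.011
    outlier_low: tuple[float, float] = (50.0, 195.0)
    outlier_high: tuple[float, float] = (2100.0, 5000.0)
    a_sd: float = 8.0
    b_sd: float = 25.0
    d_sd: float = 80.0
    noise: str = "normal"
    timeout_ms: float = 10_000.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("search rate a must be positive")
        if self.d <= 0:
            raise ValueError("base time d must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must lie in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.noise not in ("normal", "lognormal"):
            raise ValueError("noise must be 'normal' or 'lognormal'")
        if self.c_true < 0:
            raise ValueError("c_true must be a non-negative integer")


def _draw_participant_coefs(
    params: GenerativeParams, rng: np.random.Generator
) -> tuple[float, float, float]:
    a_i = -1.0
    while a_i <= 0:  # truncate the search rate at zero
        a_i = params.a + params.a_sd * rng.standard_normal()
    b_i = params.b + params.b_sd * rng.standard_normal()
    d_i = params.d + params.d_sd * rng.standard_normal()
    return a_i, b_i, d_i


def _cell_order_mixed(
    design: DesignSpec, rng: np.random.Generator
) -> np.ndarray:
    """Randomized order of cell indices for one participant's run."""
    idx = np.repeat(
        np.arange(len(design.cells)),
        [cell.n_trials for cell in design.cells],
    )
    return rng.permutation(idx)


def _cell_order_blocked(
    design: DesignSpec, first_type: str, rng: np.random.Generator
) -> np.ndarray:
    """Two sessions, one per target type, trials shuffled within session."""
    order = []
    second = NO_ONSET if first_type == ONSET else ONSET
    for t in (first_type, second):
        idx = np.repeat(
            [i for i, cell in enumerate(design.cells) if cell.t == t],
            [cell.n_trials for cell in design.cells if cell.t == t],
        )
        order.append(rng.permutation(idx))
    return np.concatenate(order)


def generate_trials(
    design: DesignSpec,
    params: GenerativeParams,
    n_participants: int,
    seed: int,
) -> pd.DataFrame:
    """Generate a full trial table for ``n_participants`` participants.

    Per trial the comparison count ``k`` is drawn from the search
    simulator at ``c_true`` (blocked cells use the relevant set as the
    tagged pool), then
    ``RT = a_i * k + b_i * 1[t = onset] + d_i + noise``.  Error (lapse)
    trials keep their RT but are flagged incorrect; outlier trials have
    their RT replaced by a draw from outside the analysis window.  RTs
    above the response timeout are censored at the timeout and flagged
    as errors.  Fully reproducible from ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    root = np.random.SeedSequence(seed)
    frames = []
    block_size = _BLOCK_SIZE.get(design.experiment, 50)
    for p, child in enumerate(root.spawn(n_participants), start=1):
        rng = np.random.default_rng(child)
        a_i, b_i, d_i = _draw_participant_coefs(params, rng)
        if design.blocking == "mixed":
            order = _cell_order_mixed(design, rng)
        else:
            # counterbalance session order: odd participants start with onsets
            first = ONSET if p % 2 == 1 else NO_ONSET
            order = _cell_order_blocked(design, first, rng)
        n_practice = design.practice_trials
        cell_probs = np.array([c.n_trials for c in design.cells], dtype=float)
        cell_probs /= cell_probs.sum()
        practice_idx = rng.choice(len(design.cells), size=n_practice, p=cell_probs)
        all_idx = np.concatenate([practice_idx, order])
        practice_flag = np.concatenate(
            [np.ones(n_practice, dtype=bool), np.zeros(len(order), dtype=bool)]
        )

        # Per-trial comparison counts, drawn cell by cell for speed.  In
        # the noiseless limit (sigma = 0) the scan-order variability is
        # removed too and each trial carries the model's expected count,
        # so cell means equal a*y + b*t + d exactly.
        k = np.empty(len(all_idx), dtype=float)
        for ci, cell in enumerate(design.cells):
            mask = all_idx == ci
            m = int(mask.sum())
            if m == 0:
                continue
            if design.blocking == "mixed":
                cond = SearchCondition(n=design.n, x=cell.x, t=cell.t)
            else:
                r = design.relevant_set_size(cell)
                cond = SearchCondition(n=design.n, x=r, t=ONSET)
            if params.sigma == 0:
                k[mask] = expected_comparisons(params.c_true, cond)
            else:
                k[mask] = sample_comparisons(params.c_true, cond, m, rng)

        x_arr = np.array([design.cells[i].x for i in all_idx])
        t_arr = np.array([design.cells[i].t for i in all_idx])
        is_onset = (t_arr == ONSET).astype(float)
        rt = a_i * k + b_i * is_onset + d_i
        if params.sigma > 0:
            if params.noise == "normal":
                rt = rt + params.sigma * rng.standard_normal(len(rt))
            else:
                # multiplicative log-normal noise with matching SD scale
                cv = params.sigma / params.d
                log_sd = np.sqrt(np.log1p(cv**2))
                rt = rt * rng.lognormal(-(log_sd**2) / 2, log_sd, len(rt))
        rt = np.maximum(rt, 1.0)

        correct = rng.random(len(rt)) >= params.lapse
        if params.outlier_rate > 0:
            out_mask = rng.random(len(rt)) < params.outlier_rate
            n_out = int(out_mask.sum())
            if n_out:
                low = rng.uniform(*params.outlier_low, size=n_out)
                high = rng.uniform(*params.outlier_high, size=n_out)
                pick_low = rng.random(n_out) < 0.5
                rt[out_mask] = np.where(pick_low, low, high)
        timeout = rt > params.timeout_ms
        rt[timeout] = params.timeout_ms
        correct[timeout] = False

        target_pos = rng.integers(1, design.n + 1, size=len(rt))
        block = np.where(
            practice_flag, 0, (np.maximum(np.cumsum(~practice_flag) - 1, 0)) // block_size + 1
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "block": block,
                    "experiment": design.experiment,
                    "n": design.n,
                    "x": x_arr,
                    "target_type": t_arr,
                    "target_pos": target_pos,
                    "correct": correct,
                    "rt_ms": rt,
                    "practice": practice_flag,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def target_position_distribution(trials: pd.DataFrame) -> pd.Series:
    """Empirical frequency of the target at each display position,
    computed over experimental (non-practice) trials."""
    if trials.empty:
        raise ValueError("trials table is empty")
    exp = trials.loc[~trials["practice"].astype(bool)]
    counts = exp["target_pos"].value_counts().sort_index()
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Regeneration configs: a written config + seed reproduces a dataset
# bit-for-bit.

def write_config(
    path: str | Path,
    design: DesignSpec,
    params: GenerativeParams,
    n_participants: int,
    seed: int,
) -> dict:
    cfg = {
        "experiment": design.experiment,
        "n_participants": n_participants,
        "seed": seed,
        "params": asdict(params),
    }
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return cfg


def load_config(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def generate_from_config(cfg: dict) -> pd.DataFrame:
    """Regenerate a dataset from a config dict as written by
    :func:`write_config`."""
    params_dict = dict(cfg["params"])
    for key in ("outlier_low", "outlier_high"):
        if key in params_dict:
            params_dict[key] = tuple(params_dict[key])
    params = GenerativeParams(**params_dict)
    design = build_design(cfg["experiment"])
    return generate_trials(design, params, cfg["n_participants"], cfg["seed"])
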