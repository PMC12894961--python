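"""Inner-loop hyperparameter selection.

Three strategies estimate the PLSR number of components (NoC):

* ``repeated_cv`` — repeated k-fold CV; each repetition picks the NoC
  minimising the mean validation MSE across folds (NoC_MSE(opt)); the
  consensus NoC_MSE is the most frequent per-repetition optimum.
* ``single_cv`` — one k-fold CV; returns the MSE-minimising NoC directly.
* ``press`` — repeated random train/test sub-sampling (default 100 splits,
  80/20); squared prediction errors on the held-out side accumulate into a
  PRESS statistic per candidate NoC, minimised over the grid.

A fourth selector tunes the SVR regularization constant C by k-fold CV MSE
over a log-spaced grid.  All ties (in an argmin or in the mode) break to
the smallest hyperparameter — the parsimonious choice, which also matches
the observed tendency of PRESS to favour slightly smaller NoC.  Candidate
NoC values infeasible for the smallest training fold are dropped up front.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._folds import child_rngs, group_kfold_indices, kfold_indices, train_test_split_indices
from .models import fit_linear_svr, fit_plsr

DEFAULT_NOC_GRID = tuple(range(1, 41))
DEFAULT_C_GRID = tuple(np.logspace(-3, 3, 9))


@dataclass
class CalibrationResult:
    """Error curves and the selected hyperparameter for one inner loop."""

    strategy: str
    candidate_grid: np.ndarray
    error_curve: np.ndarray            # aggregate error per candidate
    per_repetition_errors: np.ndarray  # (reps, n_candidates)
    per_repetition_opt: np.ndarray     # optimum per repetition / sub-sample
    consensus: float
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_repetitions(self) -> int:
        return self.per_repetition_errors.shape[0]

    def curve_frame(self) -> pd.DataFrame:
        """Tidy long-format error curve: one row per candidate × repetition."""
        reps, n_cand = self.per_repetition_errors.shape
        return pd.DataFrame(
            {
                "repetition": np.repeat(np.arange(reps), n_cand),
                "candidate": np.tile(self.candidate_grid, reps),
                "error": self.per_repetition_errors.ravel(),
            }
        )

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "consensus": float(self.consensus)
            if self.strategy == "svr_c"
            else int(self.consensus),
            "seed": self.seed,
            "grid": [float(g) for g in self.candidate_grid],
            "error_curve": [float(e) for e in self.error_curve],
            "per_repetition_opt": [
                float(v) for v in self.per_repetition_opt
            ],
            **self.params,
        }


def _feasible_grid(noc_grid, n: int, k_folds: int, p: int) -> np.ndarray:
    """Truncate the NoC grid to what the smallest training fold can fit."""
    grid = np.unique(np.asarray(noc_grid, dtype=int))
    if grid.size == 0:
        raise ValueError("empty NoC grid")
    if grid[0] < 1:
        raise ValueError(f"NoC candidates must be >= 1, got {grid[0]}")
    n_train_min = n - int(np.ceil(n / k_folds))
    feasible_max = min(n_train_min - 1, p)
    kept = grid[grid <= feasible_max]
    if kept.size == 0:
        raise ValueError(
            f"no NoC candidate is feasible: smallest training fold supports "
            f"at most {feasible_max} components"
        )
    return kept

def _smallest_argmin(values: np.ndarray, grid: np.ndarray) -> float:
    # np.argmin returns the first minimum; the grid is sorted ascending,
    # so ties already break to the smallest hyperparameter.
    return grid[int(np.argmin(values))]


def _mode_smallest(values: np.ndarray) -> float:
    counts = Counter(values.tolist())
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def _cv_mse_curve(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    folds: list[np.ndarray],
) -> np.ndarray:
    """Mean validation MSE per NoC candidate across the given folds."""
    n = X.shape[0]
    all_idx = np.arange(n)
    fold_mse = np.empty((len(folds), grid.size))
    max_k = int(grid.max())
    for i, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(all_idx, val_idx)
        model = fit_plsr(X[tr_idx], y[tr_idx], max_noc=max_k)
        preds = model.predict_components(X[val_idx])
        # candidates beyond the effective rank predict like the last component
        cols = np.minimum(grid, max(model.n_components, 1)) - 1
        err = preds[:, cols] - y[val_idx][:, None]
        fold_mse[i] = np.mean(err**2, axis=0)
    return fold_mse.mean(axis=0)


def select_noc_repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    noc_grid=DEFAULT_NOC_GRID,
    reps: int = 20,
    k_folds: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> CalibrationResult:
    """Consensus NoC_MSE: mode of per-repetition CV-MSE optima.

    With ``groups`` given (e.g. genotype labels), folds are group-exclusive
    so no group appears on both sides of any split.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    grid = _feasible_grid(noc_grid, X.shape[0], k_folds, X.shape[1])
    rngs = child_rngs(seed, reps)
    curves = np.empty((reps, grid.size))
    opts = np.empty(reps)
    for r, rng in enumerate(rngs):
        folds = (
            kfold_indices(X.shape[0], k_folds, rng)
            if groups is None
            else group_kfold_indices(groups, k_folds, rng)
        )
        curves[r] = _cv_mse_curve(X, y, grid, folds)
        opts[r] = _smallest_argmin(curves[r], grid)
    consensus = _mode_smallest(opts)
    return CalibrationResult(
        strategy="repeated_cv",
        candidate_grid=grid,
        error_curve=curves.mean(axis=0),
        per_repetition_errors=curves,
        per_repetition_opt=opts,
        consensus=consensus,
        seed=seed,
        params={"reps": reps, "k_folds": k_folds},
    )


def select_noc_single_cv(
    X: np.ndarray,
    y: np.ndarray,
    noc_grid=DEFAULT_NOC_GRID,
    k_folds: int = 3,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> CalibrationResult:
    """NoC_MSE(opt) from one k-fold CV (default 3-fold)."""
    res = select_noc_repeated_cv(
        X, y, noc_grid, reps=1, k_folds=k_folds, seed=seed, groups=groups
    )
    res.strategy = "single_cv"
    res.params = {"k_folds": k_folds}
    return res


def select_noc_press(
    X: np.ndarray,
    y: np.ndarray,
    noc_grid=DEFAULT_NOC_GRID,
    n_subsamples: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> CalibrationResult:
    """NoC_PRESS: minimiser of the PRESS statistic accumulated over random
    train/test sub-samples (default 100 splits at 80/20)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    n_train = int(round(n * train_fraction))
    grid = np.unique(np.asarray(noc_grid, dtype=int))
    feasible_max = min(n_train - 1, p)
    grid = grid[grid <= feasible_max]
    if grid.size == 0:
        raise ValueError(
            f"no NoC candidate feasible for training size {n_train} "
            f"(max {feasible_max})"
        )
    rngs = child_rngs(seed, n_subsamples)
    sse = np.empty((n_subsamples, grid.size))
    opts = np.empty(n_subsamples)
    max_k = int(grid.max())
    for r, rng in enumerate(rngs):
        if groups is None:
            tr_idx, te_idx = train_test_split_indices(n, train_fraction, rng)
        else:
            uniq = np.unique(groups)
            n_tr_g = int(round(len(uniq) * train_fraction))
            if n_tr_g == 0 or n_tr_g == len(uniq):
                raise ValueError("group split leaves an empty side")
            perm = rng.permutation(uniq)
            tr_idx = np.flatnonzero(np.isin(groups, perm[:n_tr_g]))
            te_idx = np.flatnonzero(np.isin(groups, perm[n_tr_g:]))
        model = fit_plsr(X[tr_idx], y[tr_idx], max_noc=max_k)
        preds = model.predict_components(X[te_idx])
        cols = np.minimum(grid, max(model.n_components, 1)) - 1
        err = preds[:, cols] - y[te_idx][:, None]
        sse[r] = np.sum(err**2, axis=0)
        opts[r] = _smallest_argmin(sse[r], grid)
    press = sse.sum(axis=0)
    return CalibrationResult(
        strategy="press",
        candidate_grid=grid,
        error_curve=press,
        per_repetition_errors=sse,
        per_repetition_opt=opts,
        consensus=_smallest_argmin(press, grid),
        seed=seed,
        params={"n_subsamples": n_subsamples, "train_fraction": train_fraction},
    )


def select_svr_c(
    X: np.ndarray,
    y: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    k_folds: int = 3,
    seed: int = 0,
    groups: np.ndarray | None = None,
    epsilon: float = 0.1,
) -> CalibrationResult:
    """Select the SVR regularization constant C by k-fold CV MSE."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    grid = np.sort(np.asarray(c_grid, dtype=float))
    if grid.size == 0 or grid[0] <= 0:
        raise ValueError("C grid must contain positive values")
    rng = child_rngs(seed, 1)[0]
    folds = (
        kfold_indices(X.shape[0], k_folds, rng)
        if groups is None
        else group_kfold_indices(groups, k_folds, rng)
    )
    all_idx = np.arange(X.shape[0])
    fold_mse = np.empty((len(folds), grid.size))
    for i, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(all_idx, val_idx)
        for j, C in enumerate(grid):
            model = fit_linear_svr(X[tr_idx], y[tr_idx], C=C, epsilon=epsilon)
            err = model.predict(X[val_idx]) - y[val_idx]
            fold_mse[i, j] = np.mean(err**2)
    curve = fold_mse.mean(axis=0)
    return CalibrationResult(
        strategy="svr_c",
        candidate_grid=grid,
        error_curve=curve,
        per_repetition_errors=curve[None, :],
        per_repetition_opt=np.array([_smallest_argmin(curve, grid)]),
        consensus=_smallest_argmin(curve, grid),
        seed=seed,
        params={"k_folds": k_folds, "epsilon": epsilon},
    )
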