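"""Training-set optimization by CDmean with a stochastic exchange search.

The coefficient of determination (CD) of a contrast c under the mixed model
y_train = 1 mu + Z u + e,  u ~ N(0, A sigma_u^2),  e ~ N(0, I sigma_e^2),
lambda = sigma_e^2 / sigma_u^2, measures the squared correlation between
the true and predicted contrast value:

    CD(c) = c^T (A - lambda (Z^T M Z + lambda A^{-1})^{-1}) c / (c^T A c)

with M = I_m - 11^T/m the within-training-set centering projector and Z
the training-set incidence onto all N individuals.  CDmean averages CD over
the contrasts c_i = e_i - (1/N) 1 between each unphenotyped (here:
unselected) individual and the population mean.  It is phenotype-free: the
only trait-dependent input is lambda.

The exchange search starts from a random subset of size m and, for a fixed
number of iterations, proposes swapping one selected individual against one
unselected one, accepting the swap only if CDmean strictly increases.  The
contrast targets are the currently unselected calibration individuals and
are re-derived after every accepted swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng
from .models import KinshipMatrix

__all__ = [
    "TrainingSelection",
    "cd_of_contrasts",
    "algo1_exchange",
    "random_subset",
]


@dataclass
class TrainingSelection:
    """Result of a training-set selection run."""

    selected: np.ndarray            # indices into the kinship matrix
    cdmean_trace: list[float]       # accepted CDmean values (non-decreasing)
    n_iterations: int
    lmbda: float
    seed: int | None = None

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=int)
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


def _as_matrix(A) -> np.ndarray:
    return A.values if isinstance(A, KinshipMatrix) else np.asarray(A, dtype=float)


def _mean_cd(
    A: np.ndarray,
    A_inv: np.ndarray,
    train: np.ndarray,
    target: np.ndarray,
    lmbda: float,
) -> float:
    """Mean CD of mean-vs-individual contrasts for the target individuals."""
    N = A.shape[0]
    m = len(train)
    if m == 0:
        raise ValueError("training set is empty")
    s = np.zeros(N)
    s[train] = 1.0
    ZtMZ = np.diag(s) - np.outer(s, s) / m
    C = np.linalg.inv(ZtMZ + lmbda * A_inv)
    B = A - lmbda * C
    # contrast c_i = e_i - 1/N: c^T B c = B_ii - 2 rowmean_i(B) + grandmean(B)
    def quad(Bm: np.ndarray) -> np.ndarray:
        rows = Bm[target].sum(axis=1) / N
        total = Bm.sum() / N**2
        return np.diag(Bm)[target] - 2.0 * rows + total

    numer = quad(B)
    denom = quad(A)
    return float(np.mean(numer / denom))


def cd_of_contrasts(
    A: KinshipMatrix | np.ndarray,
    train_idx,
    target_idx,
    lmbda: float,
) -> float:
    """Mean CD of the target individuals' mean-deviation contrasts.

    ``train_idx`` indexes the phenotyped (training) individuals and
    ``target_idx`` the individuals whose contrasts are evaluated, both into
    the kinship matrix.  ``lmbda`` is the noise-to-genetic variance ratio.
    """
    Am = _as_matrix(A)
    train = np.asarray(train_idx, dtype=int)
    target = np.asarray(target_idx, dtype=int)
    if lmbda <= 0:
        raise ValueError("lambda must be positive")
    if len(train) == 0:
        raise ValueError("training set is empty")
    N = Am.shape[0]
    if train.max(initial=-1) >= N or target.max(initial=-1) >= N:
        raise ValueError("indices exceed kinship dimension")
    A_inv = np.linalg.inv(Am)
    return _mean_cd(Am, A_inv, train, target, lmbda)


def algo1_exchange(
    A: KinshipMatrix | np.ndarray,
    calibration_idx,
    m: int = 200,
    n_iter: int = 3000,
    lmbda: float = 1.0,
    seed=None,
) -> TrainingSelection:
    """Greedy stochastic exchange maximization of CDmean.

    Starts from a seeded random ``m``-subset of the calibration set and
    performs exactly ``n_iter`` one-for-one swap proposals, accepting a swap
    only when CDmean strictly increases.  Contrasts always target the
    calibration individuals not currently selected.
    """
    Am = _as_matrix(A)
    calib = np.asarray(calibration_idx, dtype=int)
    if m >= len(calib):
        raise ValueError("m must be smaller than the calibration set")
    if m < 1:
        raise ValueError("m must be positive")
    rng = as_rng(seed)
    A_inv = np.linalg.inv(Am)

    perm = rng.permutation(len(calib))
    sel_pos = set(perm[:m].tolist())          # positions within calib

    def evaluate(positions: set) -> float:
        train = calib[sorted(positions)]
        target = calib[sorted(set(range(len(calib))) - positions)]
        return _mean_cd(Am, A_inv, train, target, lmbda)

    current = evaluate(sel_pos)
    trace = [current]
    for _ in range(n_iter):
        out_pos = int(rng.choice(sorted(sel_pos)))
        in_pos = int(rng.choice(sorted(set(range(len(calib))) - sel_pos)))
        proposal = (sel_pos - {out_pos}) | {in_pos}
        value = evaluate(proposal)
        if value > current:
            sel_pos = proposal
            current = value
            trace.append(current)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return TrainingSelection(
        selected=calib[sorted(sel_pos)],
        cdmean_trace=trace,
        n_iterations=n_iter,
        lmbda=lmbda,
        seed=seed_int,
    )


def random_subset(
    calibration_idx,
    m: int = 200,
    seed=None,
    A: KinshipMatrix | np.ndarray | None = None,
    lmbda: float = 1.0,
) -> TrainingSelection:
    """Uniform random subset baseline.

    When a kinship matrix is supplied the subset's CDmean (contrasts over
    the unselected calibration individuals) is recorded as the single trace
    entry.
    """
    calib = np.asarray(calibration_idx, dtype=int)
    if m > len(calib):
        raise ValueError("m exceeds calibration-set size")
    if m < 1:
        raise ValueError("m must be positive")
    rng = as_rng(seed)
    chosen = np.sort(rng.choice(calib, size=m, replace=False))
    trace: list[float] = []
    if A is not None:
        target = np.setdiff1d(calib, chosen)
        if len(target):
            trace = [cd_of_contrasts(A, chosen, target, lmbda)]
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return TrainingSelection(
        selected=chosen, cdmean_trace=trace, n_iterations=0, lmbda=lmbda, seed=seed_int
    )
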