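"""Prediction-accuracy evaluation harnesses.

Accuracy is the Pearson correlation between observed (or simulated)
phenotypes and GEBVs in a validation set.  Three experiment layouts are
provided:

* **within-panel**: replicated k-fold cross-validation inside one panel,
  comparing RR-BLUP trained on the whole training fold, on a random subset,
  on a CDmean-optimized subset, and the PC-only structure model;
* **cross-panel**: seven training-set configurations built from two whole
  diversity panels (random / CDmean / whole subsets of each panel plus the
  summed-GEBV two-panel configuration) evaluated on an external target
  population, optionally with bootstrap resampling of the target;
* **simulation**: the cross-panel configurations evaluated on simulated F2
  families under the QTN-sharing scenarios.

Undefined correlations (zero variance in either vector) are flagged as NaN
and excluded from summaries, never imputed as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_rng, spawn_seeds
from .meiosis import F2Family
from .models import (
    RRBLUP,
    code_markers,
    kinship,
    lambda_from_phenotypes,
    pca_fit_predict,
    sum_gebv,
)
from .popsim import GenotypeMatrix, Panel
from .trainsel import algo1_exchange, random_subset
from .traitsim import simulate_trait_suite

__all__ = [
    "CONFIGURATIONS",
    "CVPlan",
    "pearson_accuracy",
    "make_cv_plan",
    "bootstrap_accuracy",
    "within_panel_experiment",
    "cross_panel_experiment",
    "simulation_experiment",
]

#: the seven cross-panel training configurations
CONFIGURATIONS = (
    "Msi.Random",
    "Msa.Random",
    "Msi.CDmean",
    "Msa.CDmean",
    "Msi.Whole",
    "Msa.Whole",
    "Whole.MsiMsa",
)


def pearson_accuracy(y_true, gebv) -> float:
    """Sample Pearson correlation; NaN when either vector has no variance."""
    y = np.asarray(y_true, dtype=float)
    g = np.asarray(gebv, dtype=float)
    if y.shape != g.shape:
        raise ValueError("vectors must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 pairs for a meaningful correlation")
    if np.std(y) == 0 or np.std(g) == 0:
        return float("nan")
    return float(np.corrcoef(y, g)[0, 1])


@dataclass
class CVPlan:
    """Replicated k-fold cross-validation assignment.

    ``folds[rep][fold]`` is an index array; within a rep the folds
    partition all individuals and differ in size by at most 1.
    """

    n_individuals: int
    k: int
    n_reps: int
    folds: list[list[np.ndarray]]
    seed: int | None = None


def make_cv_plan(n: int, k: int = 5, n_reps: int = 10, seed=None) -> CVPlan:
    """Fresh random permutation split into k near-equal folds, per replicate."""
    if n < k:
        raise ValueError("need at least k individuals")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = as_rng(seed)
    folds = []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        folds.append([np.sort(f) for f in np.array_split(perm, k)])
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return CVPlan(n_individuals=n, k=k, n_reps=n_reps, folds=folds, seed=seed_int)


def bootstrap_accuracy(
    y_target, gebv_target, n_boot: int = 1000, seed=None
) -> tuple[np.ndarray, int]:
    """Bootstrap distribution of prediction accuracy on a target population.

    Resamples the target with replacement ``n_boot`` times (resample size =
    population size) and computes Pearson r per resample.  Returns the
    defined correlations and the count of excluded zero-variance resamples.
    """
    y = np.asarray(y_target, dtype=float)
    g = np.asarray(gebv_target, dtype=float)
    if y.shape != g.shape:
        raise ValueError("vectors must be aligned")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = as_rng(seed)
    n = len(y)
    out = np.empty(n_boot)
    n_undefined = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb, gb = y[idx], g[idx]
        if np.std(yb) == 0 or np.std(gb) == 0:
            out[b] = np.nan
            n_undefined += 1
        else:
            out[b] = np.corrcoef(yb, gb)[0, 1]
    return out[~np.isnan(out)], n_undefined


def _effective_subset_size(subset_size: int | None, n_train: int) -> int:
    """The paper-scale default of 200, scaled to round(n/2) on small folds."""
    if subset_size is None:
        return 200 if n_train >= 200 else int(round(0.5 * n_train))
    if subset_size > n_train:
        raise ValueError(
            f"subset_size {subset_size} exceeds training-set size {n_train}"
        )
    return subset_size


def within_panel_experiment(
    panel: Panel,
    y: np.ndarray,
    plan: CVPlan,
    subset_size: int | None = None,
    cdmean_iters: int = 3000,
    q: int = 7,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated CV comparison of four training strategies inside a panel.

    Per training fold: (i) RR-BLUP on all training individuals, (ii) on a
    random subset, (iii) on a CDmean-optimized subset (Algo1 with the
    training fold as calibration set), and (iv) the PC-only model on the
    whole training fold; all evaluated on the held-out fold.

    Returns a long-format DataFrame (method, rep, fold, r, n_train, seed).
    """
    X = code_markers(panel.genotypes)
    y = np.asarray(y, dtype=float)
    if len(y) != panel.n_individuals:
        raise ValueError("phenotypes not aligned to panel")
    A = kinship(X, panel.genotypes.individual_ids)
    rows = []
    child = spawn_seeds(seed, plan.n_reps * plan.k)
    si = 0
    for rep in range(plan.n_reps):
        for fold in range(plan.k):
            valid = plan.folds[rep][fold]
            train = np.setdiff1d(np.arange(len(y)), valid)
            m = _effective_subset_size(subset_size, len(train))
            seed_rnd, seed_cd = child[si].spawn(2)
            si += 1
            lam = lambda_from_phenotypes(y[train], A.values[np.ix_(train, train)])
            whole = RRBLUP().fit(X[train], y[train])
            rnd = random_subset(train, m=m, seed=seed_rnd)
            cd = algo1_exchange(
                A, train, m=m, n_iter=cdmean_iters, lmbda=lam, seed=seed_cd
            )
            preds = {
                "RRBLUP.Whole": whole.gebv(X[valid]),
                "RRBLUP.Random": RRBLUP().fit(X[rnd.selected], y[rnd.selected]).gebv(X[valid]),
                "RRBLUP.CDmean": RRBLUP().fit(X[cd.selected], y[cd.selected]).gebv(X[valid]),
                "PC.only": pca_fit_predict(X, y[train], train, valid, q=q),
            }
            for method, g in preds.items():
                rows.append(
                    {
                        "experiment": "within_panel",
                        "configuration": method,
                        "rep": rep,
                        "fold": fold,
                        "r": pearson_accuracy(y[valid], g),
                        "n_used": len(train) if "Whole" in method or method == "PC.only" else m,
                        "seed": si - 1,
                    }
                )
    return pd.DataFrame(rows)


def _config_predictor(
    config: str,
    X_a: np.ndarray,
    X_b: np.ndarray,
    y_a: np.ndarray,
    y_b: np.ndarray,
    subset_size: int | None,
    cdmean_iters: int,
    seed,
):
    """Train one cross-panel configuration; returns a GEBV function.

    Training (including any CDmean run) happens once here so that one
    fitted configuration can predict many target populations.
    """
    def fitted(X, y, idx):
        model = RRBLUP().fit(X[idx], y[idx])
        return model.gebv

    full_a = np.arange(X_a.shape[0])
    full_b = np.arange(X_b.shape[0])
    if config == "Msi.Whole":
        return fitted(X_a, y_a, full_a)
    if config == "Msa.Whole":
        return fitted(X_b, y_b, full_b)
    if config == "Whole.MsiMsa":
        ga = fitted(X_a, y_a, full_a)
        gb = fitted(X_b, y_b, full_b)
        return lambda X_t: sum_gebv(ga(X_t), gb(X_t))
    if config in ("Msi.Random", "Msa.Random"):
        X, y, full = (X_a, y_a, full_a) if config.startswith("Msi") else (X_b, y_b, full_b)
        m = _effective_subset_size(subset_size, len(full))
        sel = random_subset(full, m=m, seed=seed)
        return fitted(X, y, sel.selected)
    if config in ("Msi.CDmean", "Msa.CDmean"):
        X, y, full = (X_a, y_a, full_a) if config.startswith("Msi") else (X_b, y_b, full_b)
        m = _effective_subset_size(subset_size, len(full))
        A = kinship(X)
        lam = lambda_from_phenotypes(y, A)
        sel = algo1_exchange(A, full, m=m, n_iter=cdmean_iters, lmbda=lam, seed=seed)
        return fitted(X, y, sel.selected)
    raise ValueError(f"unknown configuration {config!r}; expected one of {CONFIGURATIONS}")


def _config_gebv(config, X_a, X_b, y_a, y_b, X_target, subset_size, cdmean_iters, seed):
    """GEBVs of one target under one cross-panel training configuration."""
    predict = _config_predictor(
        config, X_a, X_b, y_a, y_b, subset_size, cdmean_iters, seed
    )
    return predict(X_target)


def cross_panel_experiment(
    panel_a: Panel,
    panel_b: Panel,
    y_a: np.ndarray,
    y_b: np.ndarray,
    target: GenotypeMatrix,
    y_target: np.ndarray,
    configs=CONFIGURATIONS,
    subset_size: int | None = None,
    cdmean_iters: int = 3000,
    n_boot: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate cross-panel training configurations on a target population.

    With ``n_boot`` set, each configuration additionally reports the
    bootstrap accuracy distribution over resamples of the target.
    """
    X_a = code_markers(panel_a.genotypes)
    X_b = code_markers(panel_b.genotypes)
    X_t = code_markers(target)
    if X_a.shape[1] != X_b.shape[1] or X_a.shape[1] != X_t.shape[1]:
        raise ValueError("panels and target must share one marker universe")
    rows = []
    child = spawn_seeds(seed, len(configs))
    for config, s in zip(configs, child):
        gebv = _config_gebv(
            config, X_a, X_b, np.asarray(y_a, float), np.asarray(y_b, float),
            X_t, subset_size, cdmean_iters, s,
        )
        rows.append(
            {
                "experiment": "cross_panel",
                "configuration": config,
                "bootstrap": None,
                "r": pearson_accuracy(y_target, gebv),
                "n_used": len(y_target),
            }
        )
        if n_boot:
            rs, n_undef = bootstrap_accuracy(y_target, gebv, n_boot=n_boot, seed=s)
            for b, r in enumerate(rs):
                rows.append(
                    {
                        "experiment": "cross_panel",
                        "configuration": config,
                        "bootstrap": b,
                        "r": r,
                        "n_used": len(y_target),
                    }
                )
    return pd.DataFrame(rows)


def simulation_experiment(
    panel_a: Panel,
    panel_b: Panel,
    families: list[F2Family],
    scenarios=("S.QTN",),
    architectures=("A20D0E0",),
    configs=CONFIGURATIONS,
    subset_size: int | None = None,
    cdmean_iters: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy of the cross-panel configurations on simulated F2 families.

    For every scenario x architecture, one trait is simulated in both
    panels and all families; each configuration is trained on the panel
    phenotypes and evaluated per family against the family's simulated
    phenotypes.  The correlation with the true genetic values is emitted as
    a diagnostic column (``r_genetic``).
    """
    X_a = code_markers(panel_a.genotypes)
    X_b = code_markers(panel_b.genotypes)
    rows = []
    combos = [(sc, ar) for sc in scenarios for ar in architectures]
    child = spawn_seeds(seed, len(combos))
    for (scenario, architecture), s in zip(combos, child):
        s_trait, s_eval = s.spawn(2)
        suite = simulate_trait_suite(
            panel_a, panel_b, families, scenario, architecture, seed=s_trait
        )
        y_a = suite["panel_a"].phenotypes
        y_b = suite["panel_b"].phenotypes
        config_seeds = s_eval.spawn(len(configs))
        for config, cs in zip(configs, config_seeds):
            predict = _config_predictor(
                config, X_a, X_b, y_a, y_b, subset_size, cdmean_iters, cs
            )
            for fam, trait in zip(families, suite["families"]):
                gebv = predict(code_markers(fam.f2))
                rows.append(
                    {
                        "experiment": "simulation",
                        "scenario": scenario,
                        "architecture": architecture,
                        "configuration": config,
                        "family": fam.family_id,
                        "r": pearson_accuracy(trait.phenotypes, gebv),
                        "r_genetic": pearson_accuracy(trait.genetic_values, gebv),
                        "n_used": fam.f2.n_individuals,
                    }
                )
    return pd.DataFrame(rows)
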