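"""Replicated cross-validation and the experiment designs built on it.

All experiments share one engine: fit RR-BLUP on a training subset
(markers centered with training-set frequencies, ridge parameter
re-estimated by REML per training split) and score the Pearson
correlation between predicted and reference values on a validation set.

Seed policy: every experiment takes one integer seed and derives child
generators with ``numpy.random.SeedSequence.spawn``, so replicate r of
cell c is reproducible and independent of how many other cells run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import geno as geno_mod
from .geno import GenotypeMatrix, compute_qc, filter_markers, impute_mean
from .gblup import ModelError, accuracy, center_dosages, fit_rrblup, predict_gebv


class DesignError(ValueError):
    pass


@dataclass
class CVResult:
    """Replicate-level prediction accuracies for one experimental cell."""

    accuracies: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(len(self.accuracies))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"replicate": np.arange(1, len(self.accuracies) + 1),
             "accuracy": self.accuracies}
        )
        for k, v in self.metadata.items():
            df[k] = v
        return df


def _fit_and_score(
    y: np.ndarray,
    M: np.ndarray,
    marker_class: str,
    train_idx: np.ndarray,
    valid_idx: np.ndarray,
    y_ref: np.ndarray | None = None,
) -> float:
    """Train on ``train_idx`` rows of the raw (imputed) dosage matrix M,
    predict ``valid_idx`` rows, return the accuracy against ``y_ref``
    (defaults to y) on the validation rows."""
    mult = 2.0 if marker_class == "codominant" else 1.0
    M_train = M[train_idx]
    freqs = M_train.mean(axis=0) / mult
    Z_train = M_train - mult * freqs
    keep = Z_train.std(axis=0) > 0  # drop markers monomorphic in training
    if not keep.any():
        raise ModelError("no polymorphic markers in training set")
    fit = fit_rrblup(y[train_idx], Z_train[:, keep])
    Z_valid = (M[valid_idx] - mult * freqs)[:, keep]
    pred = predict_gebv(fit, Z_valid)
    ref = (y if y_ref is None else y_ref)[valid_idx]
    return accuracy(pred, ref)


def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into k near-equal disjoint folds."""
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def kfold_cv(
    y: np.ndarray,
    M: np.ndarray,
    k: int = 5,
    n_reps: int = 150,
    seed: int = 0,
    marker_class: str = "codominant",
    y_ref: np.ndarray | None = None,
    metadata: dict | None = None,
) -> CVResult:
    """Replicated k-fold cross-validation.

    Per replicate, lines are partitioned into k near-equal disjoint folds;
    each fold is predicted by a model trained on the remaining folds, with
    the REML ridge parameter re-estimated on every training split.  The
    replicate accuracy is the mean of the k per-fold accuracies.  ``M`` is
    the imputed lines x markers dosage matrix; ``y_ref`` (defaulting to
    ``y``) is the reference the predictions are correlated with, e.g. the
    simulated true breeding values.
    """
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    n = len(y)
    if k < 2 or n < k:
        raise DesignError(f"need n >= k >= 2, got n={n}, k={k}")
    if n // k < 3:
        raise DesignError(
            f"fold size {n // k} < 3; per-fold correlation undefined"
        )
    rng_streams = np.random.SeedSequence(seed).spawn(n_reps)
    accs = np.empty(n_reps)
    for r, ss in enumerate(rng_streams):
        rng = np.random.default_rng(ss)
        folds = _folds(n, k, rng)
        assert sum(len(f) for f in folds) == n
        fold_accs = []
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            fold_accs.append(
                _fit_and_score(y, M, marker_class, train, fold, y_ref)
            )
        accs[r] = np.nanmean(fold_accs)
    md = {"k": k, "n_reps": n_reps, "seed": seed}
    md.update(metadata or {})
    return CVResult(accuracies=accs, metadata=md)


def tps_sweep(
    y: np.ndarray,
    M: np.ndarray,
    fractions: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    n_reps: int = 100,
    seed: int = 0,
    marker_class: str = "codominant",
    y_ref: np.ndarray | None = None,
) -> list[CVResult]:
    """Training-population-size sweep: for each fraction, a random subset
    of that size trains a model that predicts the complement."""
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    n = len(y)
    results = []
    for f_i, frac in enumerate(fractions):
        if not 0.0 < frac < 1.0:
            raise DesignError(f"training fraction {frac} outside (0, 1)")
        n_train = int(round(frac * n))
        flagged = n_train < 10
        streams = np.random.SeedSequence((seed, f_i)).spawn(n_reps)
        accs = np.empty(n_reps)
        for r, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            perm = rng.permutation(n)
            train, valid = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            accs[r] = _fit_and_score(y, M, marker_class, train, valid, y_ref)
        results.append(
            CVResult(
                accuracies=accs,
                metadata={"fraction": float(frac), "n_train": n_train,
                          "small_training_set": flagged, "seed": seed},
            )
        )
    return results


def density_sweep(
    y: np.ndarray,
    M: np.ndarray,
    marker_counts: Sequence[int],
    n_reps: int = 100,
    k: int = 5,
    seed: int = 0,
    marker_class: str = "codominant",
    y_ref: np.ndarray | None = None,
) -> list[CVResult]:
    """Marker-density sweep: per replicate, a fresh random marker subset
    of the stated size feeds one full k-fold CV replicate."""
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    n, m = M.shape
    results = []
    for c_i, count in enumerate(marker_counts):
        if count > m:
            results.append(
                CVResult(
                    accuracies=np.array([]),
                    metadata={"n_markers": int(count), "skipped": True,
                              "warning": f"requested {count} of {m} markers"},
                )
            )
            continue
        streams = np.random.SeedSequence((seed, c_i)).spawn(n_reps)
        accs = np.empty(n_reps)
        for r, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            sub = np.sort(rng.choice(m, size=count, replace=False))
            folds = _folds(n, k, rng)
            fold_accs = []
            for fold in folds:
                train = np.setdiff1d(np.arange(n), fold)
                fold_accs.append(
                    _fit_and_score(y, M[:, sub], marker_class, train, fold, y_ref)
                )
            accs[r] = np.nanmean(fold_accs)
        results.append(
            CVResult(accuracies=accs,
                     metadata={"n_markers": int(count), "skipped": False,
                               "seed": seed})
        )
    return results


def quality_grid(
    geno_raw: GenotypeMatrix,
    y: np.ndarray,
    maf_levels: Sequence[float] = (0.10, 0.20, 0.30, 0.40),
    missing_levels: Sequence[float] | None = (0.0, 0.20, 0.40, 0.60, 0.80),
    n_reps: int = 150,
    k: int = 5,
    seed: int = 0,
    y_ref: np.ndarray | None = None,
) -> pd.DataFrame:
    """Marker-quality grid: filter raw genotypes at each (MAF, missing)
    combination, impute, run k-fold CV; one row per cell with marker
    count and accuracy summary.  Dominant platforms pass
    ``missing_levels=None`` for a MAF-only grid.
    """
    qc = compute_qc(geno_raw)
    miss_iter: Sequence[float | None] = (
        [None] if missing_levels is None else list(missing_levels)
    )
    rows = []
    for i, maf_t in enumerate(maf_levels):
        for j, miss_t in enumerate(miss_iter):
            sub = filter_markers(geno_raw, qc, maf_gt=maf_t,
                                 missing_lt=None if miss_t is None else miss_t)
            cell = {
                "maf_gt": maf_t,
                "missing_lt": np.nan if miss_t is None else miss_t,
                "n_markers": sub.n_markers,
            }
            if sub.n_markers == 0:
                cell.update(accuracy_mean=np.nan, accuracy_sd=np.nan, empty=True)
            else:
                M = impute_mean(sub).dosages
                res = kfold_cv(
                    y, M, k=k, n_reps=n_reps, seed=int(seed + 97 * i + j),
                    marker_class=geno_raw.marker_class, y_ref=y_ref,
                )
                cell.update(accuracy_mean=res.mean, accuracy_sd=res.sd, empty=False)
            rows.append(cell)
    return pd.DataFrame(rows)


SCENARIOS = ("random", "top", "bottom", "middle", "two_tails")


@dataclass
class ScenarioSpec:
    scenario: str
    fraction: float

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise DesignError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 < self.fraction <= 1.0:
            raise DesignError("fraction must lie in (0, 1]")


def _scenario_training_idx(
    lsmeans: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Select training lines by phenotype rank for one scenario.

    top/bottom take the extreme fraction; middle takes the central
    fraction around the median; two_tails takes fraction/2 from each
    extreme, the extra line (odd counts) going to the top tail.  Ranks
    tie-break by index; only 'random' is stochastic.
    """
    n = len(lsmeans)
    n_train = int(round(spec.fraction * n))
    n_train = max(1, min(n, n_train))
    order = np.argsort(lsmeans, kind="stable")  # ascending
    if spec.scenario == "random":
        return np.sort(rng.choice(n, size=n_train, replace=False))
    if spec.scenario == "top":
        return np.sort(order[-n_train:])
    if spec.scenario == "bottom":
        return np.sort(order[:n_train])
    if spec.scenario == "middle":
        lo = (n - n_train) // 2
        return np.sort(order[lo:lo + n_train])
    # two_tails
    n_bottom = n_train // 2
    n_top = n_train - n_bottom
    return np.sort(np.concatenate([order[:n_bottom], order[-n_top:]]))


def scenario_training(
    y: np.ndarray,
    M: np.ndarray,
    spec: ScenarioSpec,
    n_reps: int = 1,
    seed: int = 0,
    marker_class: str = "codominant",
    y_ref: np.ndarray | None = None,
    whole_population_validation: bool = True,
) -> CVResult:
    """Phenotype-stratified training-set design.

    The training set is chosen by lsmean rank under ``spec``; the model is
    evaluated on the whole population (training lines included) by
    default, or only on the held-out complement when
    ``whole_population_validation`` is False.  Deterministic scenarios run
    once regardless of ``n_reps``; 'random' is replicated.
    """
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    n = len(y)
    eff_reps = n_reps if spec.scenario == "random" else 1
    streams = np.random.SeedSequence(seed).spawn(eff_reps)
    accs = np.empty(eff_reps)
    n_train = int(round(spec.fraction * n))
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        train = _scenario_training_idx(y, spec, rng)
        valid = np.arange(n) if whole_population_validation \
            else np.setdiff1d(np.arange(n), train)
        if spec.fraction >= 1.0:
            valid = np.arange(n)
        accs[r] = _fit_and_score(y, M, marker_class, train, valid, y_ref)
    return CVResult(
        accuracies=accs,
        metadata={"scenario": spec.scenario, "fraction": spec.fraction,
                  "n_train": n_train, "small_training_set": n_train < 10,
                  "whole_population_validation": whole_population_validation,
                  "seed": seed},
    )


def cross_population(
    y_train: np.ndarray,
    geno_train: GenotypeMatrix,
    y_valid: np.ndarray,
    geno_valid: GenotypeMatrix,
    min_shared: int = 50,
) -> float:
    """Across-population prediction: train on one full population, predict
    the other.  Markers are intersected by id; centering frequencies come
    from the training population.  Returns the validation accuracy."""
    shared, ia, ib = np.intersect1d(
        geno_train.marker_ids.astype(str),
        geno_valid.marker_ids.astype(str),
        return_indices=True,
    )
    if len(shared) < min_shared:
        raise DesignError(
            f"only {len(shared)} shared markers (< {min_shared}); "
            "populations cannot be linked"
        )
    gt = impute_mean(geno_train.take_markers(np.sort(ia)))
    gv = impute_mean(geno_valid.take_markers(np.sort(ib)))
    # align by id, same order
    order_v = {m: i for i, m in enumerate(gv.marker_ids.astype(str))}
    gv = gv.take_markers(np.array([order_v[m] for m in gt.marker_ids.astype(str)]))

    mult = 2.0 if gt.marker_class == "codominant" else 1.0
    freqs = gt.dosages.mean(axis=0) / mult
    Z_train = gt.dosages - mult * freqs
    keep = Z_train.std(axis=0) > 0
    fit = fit_rrblup(np.asarray(y_train, dtype=float), Z_train[:, keep])
    Z_valid = (gv.dosages - mult * freqs)[:, keep]
    pred = predict_gebv(fit, Z_valid)
    return accuracy(pred, np.asarray(y_valid, dtype=float))


def mas_prediction(
    y: np.ndarray,
    geno: GenotypeMatrix,
    marker_subset: Sequence[str],
    k: int = 5,
    n_reps: int = 150,
    seed: int = 0,
    y_ref: np.ndarray | None = None,
) -> CVResult:
    """Marker-assisted-selection emulation: the k-fold CV machinery run on
    a small named subset of markers (e.g. trait-associated SNPs)."""
    ids = geno.marker_ids.astype(str)
    lookup = {m: i for i, m in enumerate(ids)}
    unknown = [m for m in marker_subset if str(m) not in lookup]
    if unknown:
        raise DesignError(f"unknown marker ids: {unknown[:5]}")
    idx = np.array([lookup[str(m)] for m in marker_subset])
    sub = impute_mean(geno.take_markers(np.sort(idx)))
    res = kfold_cv(
        np.asarray(y, dtype=float), sub.dosages, k=k, n_reps=n_reps, seed=seed,
        marker_class=geno.marker_class, y_ref=y_ref,
        metadata={"n_markers": len(idx), "design": "mas"},
    )
    return res


@dataclass
class TTestReport:
    t: float
    df: float
    p: float
    mean_diff: float


def compare_accuracies(res_a: CVResult, res_b: CVResult) -> TTestReport:
    """Welch two-sample t-test on the replicate accuracy lists."""
    a, b = res_a.accuracies, res_b.accuracies
    if len(a) < 2 or len(b) < 2:
        raise DesignError("need at least 2 replicates per side")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        return TTestReport(t=np.nan, df=np.nan, p=np.nan,
                           mean_diff=float(np.mean(a) - np.mean(b)))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return TTestReport(t=float(t), df=float(df), p=float(p),
                       mean_diff=float(np.mean(a) - np.mean(b)))
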