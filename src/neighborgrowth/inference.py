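"""Permutation tests of competitor identity and spatial block cross-validation.

The permutation test targets the null hypothesis that competition does not
depend on competitor identity (lambda_jk = lambda_j for all k): competitor
group labels are resampled without replacement *within each focal
neighborhood* — distances and explanatory values untouched — the model is
refit, and the in-sample RMSE is recompared to the observed one. Resampling
nested within neighborhoods preserves neighborhood structure, making the
statistic exchangeable under the null.

Spatial cross-validation holds out one contiguous fold at a time; a fold
buffer of width ``comp_dist`` around the test block is additionally removed
from the training set so training and test neighborhoods never overlap, and
the per-fold RMSEs are averaged (unweighted) into a single error estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seeding import child_rng
from .errors import DomainError
from .geometry import FoldPartition, fold_buffer_mask
from .model import ModelSpec, PriorSpec, build_design, fit_conjugate, posterior_predict, rmse
from .neighborhoods import FocalRecord, FocalTable

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed_rmse: float
    null_rmses: np.ndarray
    n_perm: int
    p_value: float
    seed: int


@dataclass
class CVResult:
    folds: pd.DataFrame        # fold_id, n_test, n_train, n_excluded_by_buffer, rmse, error
    overall_rmse: float

    def __post_init__(self):
        ok = self.folds["rmse"].notna()
        if ok.any():
            assert np.isclose(self.overall_rmse, self.folds.loc[ok, "rmse"].mean())


def _shuffled_record(record: FocalRecord, rng: np.random.Generator) -> FocalRecord:
    if record.n_competitors <= 1:
        return record
    codes = record.comp_group_codes[rng.permutation(record.n_competitors)]
    totals = np.bincount(codes, weights=record.comp_x,
                         minlength=len(record.comp_levels))
    return replace(record, comp_group_codes=codes, comp_totals=totals)


def shuffle_competitor_groups(table: FocalTable, rng_seed) -> FocalTable:
    """Permute competitor group labels within each neighborhood independently.

    Distances and explanatory values are untouched; per-group totals are
    recomputed from the permuted labels. Neighborhoods with a single
    competitor (or a single label) are unchanged by construction.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    return replace(table, records=[_shuffled_record(r, rng) for r in table.records])


def _fit_predict_rmse(table: FocalTable, prior: PriorSpec, spec: ModelSpec,
                      observed: np.ndarray | None = None) -> float:
    X, y = build_design(table, spec)
    post = fit_conjugate(X, y, prior, spec=spec)
    pred = posterior_predict(post, X)
    return rmse(y if observed is None else observed, pred)


def run_permutation_test(
    table: FocalTable, prior: PriorSpec, n_perm: int, rng_seed: int
) -> PermutationResult:
    """Observed vs permutation-null in-sample RMSE.

    Each null replicate refits the model on a freshly shuffled table and
    evaluates RMSE on the same records. Small RMSE is evidence that identity
    matters, so the one-sided p-value counts null replicates at or below the
    observed value, with the add-one convention:
    p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    spec = ModelSpec.from_focal_table(table)
    observed = _fit_predict_rmse(table, prior, spec)
    null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = shuffle_competitor_groups(table, child_rng(rng_seed, "perm", b))
        null[b] = _fit_predict_rmse(shuffled, prior, spec)
    p = (1.0 + np.sum(null <= observed)) / (n_perm + 1.0)
    return PermutationResult(observed, null, n_perm, float(p), int(rng_seed))


def run_cv(
    table: FocalTable,
    partition: FoldPartition,
    prior: PriorSpec,
    comp_dist: float | None = None,
    shuffle: bool = False,
    rng_seed: int = 0,
) -> CVResult:
    """Spatially blocked cross-validation with a fold buffer.

    For each fold f: the test set is the focal records with fold_id == f; the
    training set is all other records *except* those within ``comp_dist`` of
    the test block (the fold buffer). ``shuffle=True`` permutes competitor
    labels in both the training and test tables with a fresh per-fold
    permutation — under the null the identity labels are uninformative
    everywhere, not just in training. Folds with an empty training or test
    set are skipped with a warning and recorded, not fatal.
    """
    fold_ids = partition.fold_ids
    if len(fold_ids) < 2:
        raise DomainError("cross-validation needs >= 2 folds")
    if comp_dist is None:
        comp_dist = table.comp_dist
    spec = ModelSpec.from_focal_table(table)
    points = table.points
    rec_folds = table.fold_ids

    rows = []
    for f in fold_ids:
        test_mask = rec_folds == f
        buffered = fold_buffer_mask(points, partition, f, comp_dist)
        train_mask = (~test_mask) & (~buffered)
        n_excl = int(((~test_mask) & buffered).sum())
        if not test_mask.any() or not train_mask.any():
            warnings.warn(f"fold {f}: empty train or test set, skipped", stacklevel=2)
            rows.append((f, int(test_mask.sum()), int(train_mask.sum()),
                         n_excl, np.nan, "empty train or test set"))
            continue
        train = table.subset(train_mask)
        test = table.subset(test_mask)
        if shuffle:
            train = shuffle_competitor_groups(train, child_rng(rng_seed, "cv-train", f))
            test = shuffle_competitor_groups(test, child_rng(rng_seed, "cv-test", f))
        Xtr, ytr = build_design(train, spec)
        post = fit_conjugate(Xtr, ytr, prior, spec=spec)
        Xte, yte = build_design(test, spec)
        fold_rmse = rmse(yte, posterior_predict(post, Xte))
        rows.append((f, int(test_mask.sum()), int(train_mask.sum()),
                     n_excl, fold_rmse, ""))
        logger.info("run_cv: fold %d n_test=%d n_train=%d buffered=%d rmse=%.4f",
                    f, rows[-1][1], rows[-1][2], n_excl, fold_rmse)
    folds = pd.DataFrame(
        rows, columns=["fold_id", "n_test", "n_train",
                       "n_excluded_by_buffer", "rmse", "error"]
    )
    return CVResult(folds=folds, overall_rmse=float(folds["rmse"].mean()))


def comparison_experiment(
    table: FocalTable,
    partition: FoldPartition,
    prior: PriorSpec,
    n_perm: int,
    rng_seed: int,
    comp_dist: float | None = None,
) -> pd.DataFrame:
    """In-sample vs cross-validated RMSE, observed and under the permutation null.

    Produces the 2*(1 + n_perm) RMSE values contrasting the two error
    estimates: without CV an identity effect can look significant purely
    through spatial overfitting; blocked CV is the control. Columns:
    mode in {in_sample, cv}, kind in {observed, null}, replicate, rmse.
    """
    spec = ModelSpec.from_focal_table(table)
    rows = [("in_sample", "observed", 0,
             _fit_predict_rmse(table, prior, spec))]
    for b in range(n_perm):
        shuffled = shuffle_competitor_groups(table, child_rng(rng_seed, "cmp-perm", b))
        rows.append(("in_sample", "null", b + 1,
                     _fit_predict_rmse(shuffled, prior, spec)))
    rows.append(("cv", "observed", 0,
                 run_cv(table, partition, prior, comp_dist).overall_rmse))
    for b in range(n_perm):
        res = run_cv(table, partition, prior, comp_dist, shuffle=True,
                     rng_seed=int(child_rng(rng_seed, "cmp-cv", b).integers(2**31)))
        rows.append(("cv", "null", b + 1, res.overall_rmse))
    return pd.DataFrame(rows, columns=["mode", "kind", "replicate", "rmse"])


def sweep(
    table_builder,
    values,
    partition: FoldPartition,
    prior: PriorSpec,
    axis: str = "comp_dist",
) -> pd.DataFrame:
    """Cross-validated RMSE along one modeling axis.

    ``table_builder(value)`` rebuilds the focal table for each setting of the
    swept axis (competitive distance, explanatory variable, or grouping);
    values yielding an empty focal set produce a missing row with a warning.
    """
    if len(values) == 0:
        raise DomainError("sweep needs a nonempty value list")
    rows = []
    for v in values:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = table_builder(v)
        if len(t) == 0:
            warnings.warn(f"sweep: value {v!r} produced an empty focal set",
                          stacklevel=2)
            rows.append((v, np.nan))
            continue
        rows.append((v, run_cv(t, partition, prior).overall_rmse))
    return pd.DataFrame(rows, columns=[axis, "cv_rmse"])
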