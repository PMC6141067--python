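"""ROC/AUC analysis, adduct-subset cases, and repeated stratified holdout.

Two AUC estimates are computed for every score vector: the threshold-sweep
area (the ROC polygon traced by the same 0.01-step grid used for threshold
selection, integrated by trapezoids) and the exact rank-statistic area
(the Mann-Whitney probability that a random case outscores a random
control, ties counted one half).  On tie-free continuous scores the two
agree to within the grid resolution; the rank form is the exact quantity.

The five *cases* are the model-input subsets studied for the four-adduct
panel: the full panel, and the four three-adduct panels obtained by
dropping one adduct at a time.

Validation is repeated stratified holdout: each repeat draws, per class,
a fresh uniform train/test split (default 80% training, floor rounding
per class), trains the network on the training split only, selects the
operating threshold on training scores only, and evaluates the error rate
at that frozen threshold and the rank AUC on both splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort_io import (
    Adduct,
    AdductSubset,
    FULL_SUBSET,
    SubjectRecord,
    build_features,
)
from .decision import THRESHOLD_GRID, ThresholdScan, classify, error_rate, select_threshold
from .mlp_core import MLPParameters, TrainingConfig, forward, train

__all__ = [
    "ROCCurve",
    "CVConfig",
    "CVSummary",
    "compute_auc",
    "stratified_partition",
    "case_definitions",
    "run_case_full",
    "cross_validate",
    "full_data_report",
    "validation_report",
]


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC points plus the two AUC estimates.

    ``points`` lists (false-positive rate, true-positive rate) pairs in
    order of increasing threshold; ``auc_sweep`` integrates that polygon,
    ``auc_rank`` is the exact tie-corrected rank statistic.
    """

    points: tuple[tuple[float, float], ...]
    auc_sweep: float
    auc_rank: float


def _rank_auc(scores: np.ndarray, actual: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2, via midranks."""
    n_case = int(np.sum(actual == 1))
    n_control = actual.size - n_case
    ranks = rankdata(scores)
    u = ranks[actual == 1].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_control))


def compute_auc(scores: np.ndarray, actual: np.ndarray) -> ROCCurve:
    """ROC curve from the 101-threshold sweep plus both AUC estimates.

    Raises ``ValueError`` unless both classes are present.
    """
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual)
    if scores.shape != actual.shape:
        raise ValueError("scores and labels must have equal length")
    is_case = actual == 1
    n_case = int(is_case.sum())
    n_control = actual.size - n_case
    if n_case == 0 or n_control == 0:
        raise ValueError("AUC requires both classes")

    predictions = scores[None, :] >= THRESHOLD_GRID[:, None]  # (101, n)
    tpr = predictions[:, is_case].mean(axis=1)
    fpr = predictions[:, ~is_case].mean(axis=1)
    # The sweep runs threshold 0 -> 1, tracing (1,1) down to (0,0) for
    # scores inside (0,1); integrate over increasing FPR.
    order = np.argsort(fpr, kind="stable")
    auc_sweep = float(np.trapezoid(tpr[order], fpr[order]))
    points = tuple((float(f), float(t)) for f, t in zip(fpr, tpr))
    return ROCCurve(points=points, auc_sweep=auc_sweep,
                    auc_rank=_rank_auc(scores, actual))


def _stratified_indices(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class uniform split of indices; floor(train_fraction * n) train."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    train_parts, test_parts = [], []
    for label in (1, 0):
        idx = np.flatnonzero(y == label)
        if idx.size == 0:
            raise ValueError("both classes must be present")
        permuted = rng.permutation(idx)
        n_train = int(np.floor(train_fraction * idx.size))
        train_parts.append(permuted[:n_train])
        test_parts.append(permuted[n_train:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def stratified_partition(
    records: Sequence[SubjectRecord],
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Random per-class train/test split of a cohort.

    Each class contributes ``floor(train_fraction * n_class)`` uniformly
    drawn records to the training set and the remainder to the test set
    (e.g. 152 cases / 71 controls at 0.8 give 121 / 56 training records).
    """
    y = np.array([1 if r.is_case else 0 for r in records])
    train_idx, test_idx = _stratified_indices(y, train_fraction, rng)
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def case_definitions() -> list[tuple[int, AdductSubset]]:
    """The five studied input panels.

    Case 1 uses all four adducts; Cases 2-5 each drop exactly one
    (Hb 3,4-Q, Hb 2,3-Q, Alb 3,4-Q and Alb 2,3-Q respectively).
    """
    return [
        (1, FULL_SUBSET),
        (2, AdductSubset((Adduct.HB_23Q, Adduct.ALB_34Q, Adduct.ALB_23Q))),
        (3, AdductSubset((Adduct.HB_34Q, Adduct.ALB_34Q, Adduct.ALB_23Q))),
        (4, AdductSubset((Adduct.HB_34Q, Adduct.HB_23Q, Adduct.ALB_23Q))),
        (5, AdductSubset((Adduct.HB_34Q, Adduct.HB_23Q, Adduct.ALB_34Q))),
    ]


def run_case_full(
    records: Sequence[SubjectRecord],
    subset: AdductSubset,
    tconfig: TrainingConfig = TrainingConfig(),
) -> tuple[MLPParameters, ThresholdScan, ROCCurve]:
    """Train on the full cohort and report its training operating curve.

    The threshold scan and ROC are computed on the same samples the model
    was fitted to — apparent (training) operating characteristics.
    """
    features = build_features(records, subset)
    params, _ = train(features, tconfig)
    scores = forward(features.x, params)
    return params, select_threshold(scores, features.y), compute_auc(scores, features.y)


@dataclass(frozen=True)
class CVConfig:
    """Repeated-holdout settings: training fraction, repeats, master seed."""

    train_fraction: float = 0.8
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


_CV_COLUMNS = ("train_error", "test_error", "train_auc", "test_auc")


@dataclass(frozen=True)
class CVSummary:
    """Per-repeat holdout metrics and their mean/SD aggregates.

    ``per_repeat`` has one row per repeat with columns train error (at the
    training-selected threshold), test error (same frozen threshold),
    train rank-AUC and test rank-AUC.  Standard deviations use the sample
    (n-1) denominator and are 0 for a single repeat.
    """

    per_repeat: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @property
    def n_repeats(self) -> int:
        return self.per_repeat.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_repeat, columns=list(_CV_COLUMNS))

    def mean(self, column: str) -> float:
        return float(self.means[_CV_COLUMNS.index(column)])

    def sd(self, column: str) -> float:
        return float(self.sds[_CV_COLUMNS.index(column)])


def cross_validate(
    records: Sequence[SubjectRecord],
    subset: AdductSubset,
    tconfig: TrainingConfig = TrainingConfig(),
    cvconfig: CVConfig = CVConfig(),
) -> CVSummary:
    """Repeated stratified holdout validation of one input panel.

    For each repeat a fresh stratified partition is drawn, the network is
    trained on the training split alone, ``t_opt`` is selected from the
    training scores, and error (at that frozen threshold) and rank AUC are
    evaluated on both splits.  Partitions and per-repeat training seeds
    all derive from ``cvconfig.seed``, so the whole experiment reproduces
    from one integer.
    """
    features = build_features(records, subset)
    x, y = features.x, features.y
    master = np.random.default_rng(cvconfig.seed)
    rows = np.empty((cvconfig.n_repeats, 4))
    for repeat in range(cvconfig.n_repeats):
        train_idx, test_idx = _stratified_indices(y, cvconfig.train_fraction, master)
        train_seed = int(master.integers(2**31))
        sub_features = build_features(
            [records[i] for i in train_idx], subset
        )
        params, _ = train(sub_features, tconfig.with_seed(train_seed))

        train_scores = forward(x[train_idx], params)
        test_scores = forward(x[test_idx], params)
        scan = select_threshold(train_scores, y[train_idx])
        rows[repeat] = (
            error_rate(classify(train_scores, scan.t_opt), y[train_idx].astype(int)),
            error_rate(classify(test_scores, scan.t_opt), y[test_idx].astype(int)),
            _rank_auc(train_scores, y[train_idx]),
            _rank_auc(test_scores, y[test_idx]),
        )
    means = rows.mean(axis=0)
    sds = rows.std(axis=0, ddof=1) if cvconfig.n_repeats > 1 else np.zeros(4)
    return CVSummary(per_repeat=rows, means=means, sds=sds)


def full_data_report(
    records: Sequence[SubjectRecord],
    tconfig: TrainingConfig = TrainingConfig(),
    cases: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Full-cohort apparent performance for each requested case panel."""
    wanted = set(cases) if cases is not None else None
    rows = []
    for case_id, subset in case_definitions():
        if wanted is not None and case_id not in wanted:
            continue
        _, scan, roc = run_case_full(records, subset, tconfig)
        rows.append(
            {
                "case": case_id,
                "adducts": "+".join(subset.labels()),
                "auc_sweep": roc.auc_sweep,
                "auc_rank": roc.auc_rank,
                "train_error": scan.min_error,
                "t_opt": scan.t_opt,
            }
        )
    return pd.DataFrame(rows)


def validation_report(
    records: Sequence[SubjectRecord],
    tconfig: TrainingConfig = TrainingConfig(),
    cvconfig: CVConfig = CVConfig(),
    cases: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Repeated-holdout mean (SD) metrics for each requested case panel."""
    wanted = set(cases) if cases is not None else None
    rows = []
    for case_id, subset in case_definitions():
        if wanted is not None and case_id not in wanted:
            continue
        summary = cross_validate(records, subset, tconfig, cvconfig)
        row: dict[str, object] = {"case": case_id, "adducts": "+".join(subset.labels())}
        for column in _CV_COLUMNS:
            row[f"{column}_mean"] = summary.mean(column)
            row[f"{column}_sd"] = summary.sd(column)
        rows.append(row)
    return pd.DataFrame(rows)
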