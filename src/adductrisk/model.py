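"""Model/results front end for the adduct-panel risk classifier.

:class:`AdductRiskMLP` wraps a cohort (labels plus log-concentration
features) the way statistical modelling packages wrap endog/exog; its
:meth:`~AdductRiskMLP.fit` runs the gradient-descent training and returns
an :class:`AdductRiskResults` carrying the fitted parameters, the
threshold scan, the ROC, and a text ``summary()``.  Repeated-holdout
validation and plotting hang off the same two objects.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import __about__
from .cohort_io import (
    AdductSubset,
    FULL_SUBSET,
    FeatureMatrix,
    SubjectRecord,
    build_features,
)
from .decision import ThresholdScan, classify, select_threshold
from .evaluation import CVConfig, CVSummary, ROCCurve, compute_auc, cross_validate
from .mlp_core import (
    MLPParameters,
    TrainingConfig,
    TrainingTrace,
    forward,
    save_parameters,
    train,
)

__all__ = ["AdductRiskMLP", "AdductRiskResults"]


class AdductRiskMLP:
    """Sigmoid-MLP risk model over log adduct concentrations.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Class labels, 1 for cases.
    exog : array-like, shape (n, p)
        Natural-log adduct concentrations, columns ordered per ``subset``.
    subset : AdductSubset, optional
        Which adducts the columns represent (defaults to the full panel).
    records : sequence of SubjectRecord, optional
        The originating cohort; kept so validation can re-partition it.

    Examples
    --------
    >>> from adductrisk import synthetic_data, AdductRiskMLP
    >>> cohort = synthetic_data.generate_cohort(
    ...     synthetic_data.default_config(152, 71, seed=1))
    >>> results = AdductRiskMLP.from_records(cohort).fit()
    >>> round(results.auc, 3)
    1.0
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        subset: AdductSubset = FULL_SUBSET,
        records: Sequence[SubjectRecord] | None = None,
    ) -> None:
        self.features = FeatureMatrix(
            x=np.asarray(exog, dtype=float),
            y=np.asarray(endog, dtype=float),
            subject_ids=tuple(
                r.subject_id for r in records
            ) if records is not None else tuple(
                str(i) for i in range(np.asarray(endog).shape[0])
            ),
            adducts=subset,
        )
        self.records = list(records) if records is not None else None

    @classmethod
    def from_records(
        cls,
        records: Sequence[SubjectRecord],
        subset: AdductSubset = FULL_SUBSET,
    ) -> "AdductRiskMLP":
        """Build the model from a cohort of subject records."""
        features = build_features(records, subset)
        return cls(features.y, features.x, subset=features.adducts, records=records)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        subset: AdductSubset = FULL_SUBSET,
    ) -> "AdductRiskMLP":
        """Build the model from a cohort-schema DataFrame.

        The frame must carry ``subject_id``, ``group`` and the raw
        (un-logged) concentration columns named after the adducts.
        """
        records = [
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]).strip().lower(),
                conc_hb_34q=float(row["hb_e2_34q"]),
                conc_hb_23q=float(row["hb_e2_23q"]),
                conc_alb_34q=float(row["alb_e2_34q"]),
                conc_alb_23q=float(row["alb_e2_23q"]),
            )
            for _, row in frame.iterrows()
        ]
        return cls.from_records(records, subset)

    @property
    def nobs(self) -> int:
        return self.features.n_subjects

    def fit(self, config: TrainingConfig | None = None, **overrides) -> "AdductRiskResults":
        """Train the network and return the results wrapper.

        Keyword overrides (``alpha``, ``mu``, ``n_updates``, ``n_hidden``,
        ``init_scale``, ``seed``, ``trace_every``) are applied on top of
        ``config`` (or the defaults).
        """
        base = config if config is not None else TrainingConfig()
        if overrides:
            base = TrainingConfig(**{**base.__dict__, **overrides})
        params, trace = train(self.features, base)
        return AdductRiskResults(self, params, trace, base)

    def cross_validate(
        self,
        config: TrainingConfig | None = None,
        cvconfig: CVConfig | None = None,
    ) -> CVSummary:
        """Repeated stratified holdout validation of this model's panel.

        Requires the model to have been built from records (the cohort is
        re-partitioned per repeat).
        """
        if self.records is None:
            raise ValueError(
                "cross_validate needs the originating records; "
                "build the model with from_records/from_dataframe"
            )
        return cross_validate(
            self.records,
            self.features.adducts,
            config if config is not None else TrainingConfig(),
            cvconfig if cvconfig is not None else CVConfig(),
        )


class AdductRiskResults:
    """Fitted parameters plus training-set operating characteristics."""

    def __init__(
        self,
        model: AdductRiskMLP,
        params: MLPParameters,
        trace: TrainingTrace,
        config: TrainingConfig,
    ) -> None:
        self.model = model
        self.params = params
        self.trace = trace
        self.config = config
        self.fittedvalues: np.ndarray = forward(model.features.x, params)
        self.threshold_scan: ThresholdScan = select_threshold(
            self.fittedvalues, model.features.y
        )
        self.roc: ROCCurve = compute_auc(self.fittedvalues, model.features.y)

    # -- scalar conveniences -------------------------------------------------
    @property
    def auc(self) -> float:
        """Exact rank-statistic training AUC."""
        return self.roc.auc_rank

    @property
    def auc_sweep(self) -> float:
        """Threshold-sweep (ROC polygon) training AUC."""
        return self.roc.auc_sweep

    @property
    def t_opt(self) -> float:
        return self.threshold_scan.t_opt

    @property
    def training_error(self) -> float:
        """Training error rate at the selected threshold ``t_opt``."""
        return self.threshold_scan.min_error

    @property
    def training_error_at_half(self) -> float:
        return self.trace.final_error_rate_at_half

    def predict(self, exog: np.ndarray | None = None, threshold: float | None = None):
        """Risk scores for new log-feature rows (or the training data).

        With ``threshold`` given, returns hard 0/1 labels instead.
        """
        x = self.model.features.x if exog is None else np.asarray(exog, dtype=float)
        scores = forward(x, self.params)
        if threshold is None:
            return scores
        return classify(np.atleast_1d(scores), threshold)

    def save_params(self, path) -> None:
        save_parameters(self.params, path)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        """Plain-text fit summary (counts, hyperparameters, operating point)."""
        f = self.model.features
        n_cases = f.n_cases
        lines = [
            "Adduct-panel MLP risk model",
            "=" * 60,
            f"adductrisk version:   {__about__.__version__}",
            f"inputs (p):           {f.n_features}  [{', '.join(f.adducts.labels())}]",
            f"hidden nodes (m):     {self.config.n_hidden}",
            f"free parameters:      {self.params.size}",
            f"observations:         {f.n_subjects} ({n_cases} cases, "
            f"{f.n_subjects - n_cases} controls)",
            f"weight decay alpha:   {self.config.alpha:g}",
            f"step size mu:         {self.config.mu:g}",
            f"updates:              {self.config.n_updates}",
            f"init scale / seed:    {self.config.init_scale:g} / {self.config.seed}",
            "-" * 60,
            f"final objective V(w): {self.trace.final_objective:.6f}",
            f"train error @ t=0.5:  {self.training_error_at_half:.4f}",
            f"threshold scan:       t_min={self.threshold_scan.t_min:.2f} "
            f"t_max={self.threshold_scan.t_max:.2f} t_opt={self.t_opt:.4f}",
            f"train error @ t_opt:  {self.training_error:.4f}",
            f"AUC (rank / sweep):   {self.auc:.4f} / {self.auc_sweep:.4f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------------
    def plot_training(self, ax=None):
        """Objective value against update count (log-scaled y axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace.iterations, self.trace.objective_values)
        ax.set_yscale("log")
        ax.set_xlabel("update")
        ax.set_ylabel("objective V(w)")
        ax.set_title("training convergence")
        return ax

    def plot_roc(self, ax=None):
        """Threshold-sweep ROC polygon with both AUC estimates annotated."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr = zip(*sorted(self.roc.points))
        ax.plot(fpr, tpr, marker=".", lw=1)
        ax.plot([0, 1], [0, 1], ls=":", color="grey")
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.set_title(
            f"ROC  (AUC rank {self.auc:.3f}, sweep {self.auc_sweep:.3f})"
        )
        return ax
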