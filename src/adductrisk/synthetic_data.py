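"""Synthetic two-class cohorts with the adduct-panel structure.

The generator draws each group from a multivariate lognormal: the four
log-concentrations (Hb 3,4-Q, Hb 2,3-Q, Alb 3,4-Q, Alb 2,3-Q) are
multivariate normal within each group, and concentrations are their
exponentials, hence strictly positive.

The default configuration encodes the qualitative structure the analysis
assumes of real case/control panels:

* the median Alb 3,4-Q : 2,3-Q concentration ratio is 2:1 in cases and
  1:2 in controls (the log-mean difference is ``+/- ln 2``);
* the median Hb 3,4-Q : 2,3-Q ratio is 2:1 in both groups;
* cases have elevated adduct levels overall;
* a strong shared per-subject factor (cumulative estrogen exposure) makes
  the two groups overlap in each two-marker (3,4-Q vs 2,3-Q) scatter
  projection, while the full four-marker log space separates them almost
  perfectly — the exposure factor cancels out of cross-protein contrasts,
  leaving only small idiosyncratic noise.

With the default constants the four-dimensional Mahalanobis distance
between the group means is about 7.6 (two-class Bayes error below 1e-4),
while the Hb and Alb projections retain two-class Bayes errors of roughly
14% and 7%, so single-projection linear separators must err.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CASE, CONTROL, FULL_PANEL, SubjectRecord

__all__ = ["SyntheticCohortConfig", "default_config", "generate_cohort"]

_LN2 = math.log(2.0)

# Default log-scale geometry (see module docstring).  Shared-factor loading
# and idiosyncratic standard deviations per protein:
_LAMBDA = 1.0      # shared exposure factor, loads equally on all four markers
_SIGMA_HB = 0.18   # idiosyncratic log-sd of the two Hb markers
_SIGMA_ALB = 0.33  # idiosyncratic log-sd of the two Alb markers
_HB_SHIFT = 2.2    # case elevation of both Hb log-means
_ALB_SHIFT = 0.4   # case elevation common to both Alb log-means

#: Control log-means, order (Hb 3,4-Q, Hb 2,3-Q, Alb 3,4-Q, Alb 2,3-Q):
#: Hb ratio 2:1, Alb ratio 1:2.
_CONTROL_LOG_MEAN = np.array([_LN2 + 1.0, 1.0, 1.0, 1.0 + _LN2])
#: Case shift: Hb elevated with the 2:1 ratio kept; Alb elevated and the
#: ratio flipped from 1:2 to 2:1.
_CASE_SHIFT = np.array([_HB_SHIFT, _HB_SHIFT, _LN2 + _ALB_SHIFT, -_LN2 + _ALB_SHIFT])
_LOG_COV = _LAMBDA**2 * np.ones((4, 4)) + np.diag(
    [_SIGMA_HB**2, _SIGMA_HB**2, _SIGMA_ALB**2, _SIGMA_ALB**2]
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Group sizes, per-group log-scale moments and the simulation seed.

    Vectors follow the canonical adduct order Hb 3,4-Q, Hb 2,3-Q,
    Alb 3,4-Q, Alb 2,3-Q.  Both covariance matrices must be symmetric
    positive definite.
    """

    n_cases: int
    n_controls: int
    case_log_mean: np.ndarray
    control_log_mean: np.ndarray
    case_log_cov: np.ndarray
    control_log_cov: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must both be >= 1")
        for name in ("case_log_mean", "control_log_mean"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (4,):
                raise ValueError(f"{name} must have length 4")
            object.__setattr__(self, name, vec)
        for name in ("case_log_cov", "control_log_cov"):
            cov = np.asarray(getattr(self, name), dtype=float)
            if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
                raise ValueError(f"{name} must be a symmetric 4x4 matrix")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise ValueError(f"{name} is not positive definite") from None
            object.__setattr__(self, name, cov)


def default_config(n_cases: int, n_controls: int, seed: int) -> SyntheticCohortConfig:
    """The calibrated default generative configuration.

    Encodes the 2:1 / 1:2 Alb ratio contrast between cases and controls,
    the 2:1 Hb ratio in both groups, per-projection overlap and
    four-marker separability (see the module docstring for the constants).
    """
    return SyntheticCohortConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        case_log_mean=_CONTROL_LOG_MEAN + _CASE_SHIFT,
        control_log_mean=_CONTROL_LOG_MEAN.copy(),
        case_log_cov=_LOG_COV.copy(),
        control_log_cov=_LOG_COV.copy(),
        seed=seed,
    )


def generate_cohort(config: SyntheticCohortConfig) -> list[SubjectRecord]:
    """Draw a cohort of subject records from the configured lognormals.

    Cases are listed first.  All randomness flows from ``config.seed``;
    identical configurations produce bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    case_logs = rng.multivariate_normal(
        config.case_log_mean, config.case_log_cov, size=config.n_cases,
        method="cholesky",
    )
    control_logs = rng.multivariate_normal(
        config.control_log_mean, config.control_log_cov, size=config.n_controls,
        method="cholesky",
    )

    records: list[SubjectRecord] = []
    width_case = len(str(config.n_cases))
    width_ctrl = len(str(config.n_controls))
    for i, row in enumerate(np.exp(case_logs), start=1):
        records.append(_record(f"case-{i:0{width_case}d}", CASE, row))
    for i, row in enumerate(np.exp(control_logs), start=1):
        records.append(_record(f"ctrl-{i:0{width_ctrl}d}", CONTROL, row))
    return records


def _record(subject_id: str, group: str, concentrations: np.ndarray) -> SubjectRecord:
    values = dict(zip(FULL_PANEL, (float(c) for c in concentrations)))
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        conc_hb_34q=values[FULL_PANEL[0]],
        conc_hb_23q=values[FULL_PANEL[1]],
        conc_alb_34q=values[FULL_PANEL[2]],
        conc_alb_23q=values[FULL_PANEL[3]],
    )
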