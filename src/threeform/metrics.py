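"""Outcome statistics for design evaluation and the failure taxonomy.

Three statistics summarize how a planned missing data design performs
against a complete-data control:

* latent reliability ``rho(Y) = (sum lambda)^2 psi / [(sum lambda)^2 psi + sum theta]``,
  the squared correlation between a scale's sum score and its true score;
* relative efficiency ``RE = R^-1 sum_r SE(theta)_r / SE(theta_hat)_r``, the
  mean over replications of the ratio of complete-data to planned-missing
  standard errors (1.0 = no efficiency loss; smaller = greater loss);
* percent relative bias ``PRB = 100 (mean(theta_hat) - theta) / theta``, with
  |PRB| > 10 conventionally flagged as unacceptable bias.

RE is deliberately the mean of per-replication ratios, not the ratio of
means — the two differ and the former is the definition implemented here.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import InvalidInputError

#: conventional reporting threshold for |PRB|
DEFAULT_PRB_THRESHOLD = 10.0


def latent_reliability(
    loadings: Sequence[float],
    latent_variance: float,
    residual_variances: Sequence[float],
) -> float:
    """Reliability of a sum score under a one-factor model; bounded by [0, 1]."""
    lam = np.asarray(loadings, dtype=float)
    theta = np.asarray(residual_variances, dtype=float)
    if lam.size == 0 or lam.size != theta.size:
        raise InvalidInputError("loadings and residual variances must be equal-length, nonempty")
    if latent_variance <= 0:
        raise InvalidInputError("latent variance must be positive")
    if (theta < 0).any():
        raise InvalidInputError("residual variances must be nonnegative")
    true_var = lam.sum() ** 2 * latent_variance
    denom = true_var + theta.sum()
    if denom == 0:
        raise InvalidInputError("undefined reliability: zero total variance")
    return float(true_var / denom)


def relative_efficiency(
    se_complete: Sequence[float],
    se_missing: Sequence[float],
) -> float:
    """Mean over replications of SE(complete) / SE(planned-missing)."""
    a = np.asarray(se_complete, dtype=float)
    b = np.asarray(se_missing, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise InvalidInputError("SE series must be nonempty and of equal length")
    if (a <= 0).any() or (b <= 0).any():
        raise InvalidInputError("standard errors must be strictly positive")
    return float(np.mean(a / b))


def percent_relative_bias(estimates: Sequence[float], truth: float) -> float:
    """Signed bias of the replication-average estimate, as a percent of truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise InvalidInputError("estimate series must be nonempty")
    if truth == 0:
        raise InvalidInputError(
            "PRB undefined for a zero true value; report raw bias instead"
        )
    return float(100.0 * (est.mean() - truth) / truth)


def prb_flag(prb: float, threshold: float = DEFAULT_PRB_THRESHOLD) -> bool:
    """Whether |PRB| exceeds the (configurable) reporting threshold."""
    return abs(prb) > threshold


class FailureCategory(enum.IntEnum):
    """The four tracked failure types, in precedence order."""

    COMPLETE = 1      # the whole replication crashed
    IMPUTATION = 2    # missing-data treatment (EM / imputation) failed
    NONCONVERGENCE = 3  # the factor model did not converge
    INADMISSIBLE = 4  # converged to an inadmissible (Heywood) solution


@dataclass
class FailureTally:
    """Counts of the four failure categories over attempted replications."""

    attempted: int = 0
    counts: Counter = field(default_factory=Counter)

    def record(self, outcome: Optional[FailureCategory]) -> None:
        self.attempted += 1
        if outcome is not None:
            self.counts[FailureCategory(outcome)] += 1

    def count(self, category: FailureCategory) -> int:
        return self.counts.get(FailureCategory(category), 0)

    def rate(self, category: FailureCategory) -> float:
        if self.attempted == 0:
            return 0.0
        return self.count(category) / self.attempted

    @property
    def total_failures(self) -> int:
        return sum(self.counts.values())


def tally_failures(outcomes: Iterable[Optional[FailureCategory]]) -> FailureTally:
    """Aggregate per-replication outcomes (None = clean) into a tally.

    Each outcome carries at most one category; when several stages could
    claim a failure the caller should apply the precedence
    complete > imputation > non-convergence > inadmissible before recording.
    """
    tally = FailureTally()
    for outcome in outcomes:
        tally.record(outcome)
    return tally
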