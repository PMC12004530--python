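"""Combine member predictions: mixture moments for regression, votes for sites.

Each member predicts a Gaussian N(mu_i, sigma_i) per task.  The ensemble
prediction treats the members as an equal-weight mixture:

    mu_bar = (1/M) sum_i mu_i
    SD^2   = (1/M) sum_i (sigma_i^2 + mu_i^2) - mu_bar^2

i.e. the exact second moment of the mixture (law of total variance), so the
ensemble SD captures both member uncertainty and member disagreement.  The
alternative that averages member variances and ignores the mu spread is
available via ``variant="mean_variance"`` for comparison.

Site classification aggregates by majority voting at a probability threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import GaussianPrediction, N_TASKS


class AggregationError(ValueError):
    pass


@dataclass
class EnsemblePrediction:
    mu: np.ndarray       # (N_TASKS,)
    sd: np.ndarray       # (N_TASKS,)
    n_members: int


def aggregate_regression(member_predictions: list[GaussianPrediction],
                         variant: str = "mixture") -> EnsemblePrediction:
    if len(member_predictions) < 2:
        raise AggregationError("need at least 2 members")
    mus = np.stack([p.mu for p in member_predictions])      # (M, T)
    sigmas = np.stack([p.sigma for p in member_predictions])
    if mus.shape[1] != N_TASKS:
        raise AggregationError("inconsistent task sets across members")
    mu_bar = mus.mean(axis=0)
    if variant == "mixture":
        second = (sigmas ** 2 + mus ** 2).mean(axis=0)
        var = np.maximum(second - mu_bar ** 2, 0.0)
    elif variant == "mean_variance":
        var = (sigmas ** 2).mean(axis=0)
    else:
        raise AggregationError(f"unknown variant {variant!r}")
    return EnsemblePrediction(mu=mu_bar, sd=np.sqrt(var), n_members=len(member_predictions))


@dataclass
class VoteResult:
    labels: np.ndarray     # voted 0/1 per residue
    fractions: np.ndarray  # positive-vote fraction per residue


def aggregate_votes(member_site_probabilities: list[np.ndarray],
                    threshold: float = 0.5) -> VoteResult:
    """Majority vote per residue; even-M ties break toward negative (warned)."""
    M = len(member_site_probabilities)
    if M < 2:
        raise AggregationError("need at least 2 members")
    probs = np.stack([np.asarray(p, dtype=float) for p in member_site_probabilities])
    votes = (probs >= threshold).astype(int)
    fractions = votes.mean(axis=0)
    if M % 2 == 0:
        warnings.warn("even member count: vote ties break toward the negative class")
    labels = (fractions > 0.5).astype(int)
    return VoteResult(labels=labels, fractions=fractions)
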