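"""Censoring-aware outcome preprocessing.

Each regression engine sees the below-LOD phenotype through a different lens:

* linear  — rank-based inverse normal transform (INT) of the full vector with
  the censored block tied at the LOD and assigned its *average* rank;
* Tobit   — INT with the censored block assigned its *max* rank, whose common
  transformed value becomes the censoring threshold of the likelihood;
* Cox     — a left-to-right flip, y_cox = max(y_obs) - y_obs, with above-LOD
  samples as "events" (no rank transform);
* logistic — the binary above/below-LOD indicator.

The INT maps rank r to Phi^{-1}((r - k) / (n - 2k + 1)) with the Blom offset
k = 3/8 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .simulate import CensoredPhenotype

__all__ = [
    "TransformedOutcome",
    "CoxOutcome",
    "rank_inverse_normal",
    "prepare_linear_outcome",
    "prepare_tobit_outcome",
    "prepare_cox_outcome",
    "prepare_logistic_outcome",
]

BLOM_OFFSET = 0.375


@dataclass
class TransformedOutcome:
    """Phenotype on the normal-quantile scale plus transform provenance."""

    values: np.ndarray
    ties_policy: str
    offset: float = BLOM_OFFSET
    censor_threshold: float | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CoxOutcome:
    """Flipped pseudo-time with event indicators (above-LOD = event)."""

    pseudo_time: np.ndarray
    event: np.ndarray

    @property
    def n(self) -> int:
        return self.pseudo_time.shape[0]


def rank_inverse_normal(
    values: np.ndarray, ties_policy: str = "average", offset: float = BLOM_OFFSET
) -> TransformedOutcome:
    """Rank-based inverse normal transform with an explicit tie policy.

    value_i = Phi^{-1}((r_i - offset) / (n - 2*offset + 1)), where r_i is the
    rank of observation i; tied groups share the group's average or max rank
    according to ``ties_policy``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.shape[0] < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    if ties_policy not in ("average", "max"):
        raise ValueError(f"ties_policy must be 'average' or 'max', got {ties_policy!r}")
    if np.ptp(values) == 0:
        raise ValueError("all values identical: rank transform undefined")
    n = values.shape[0]
    ranks = rankdata(values, method=ties_policy)
    transformed = ndtri((ranks - offset) / (n - 2 * offset + 1))
    return TransformedOutcome(transformed, ties_policy, offset)


def prepare_linear_outcome(
    ph: CensoredPhenotype, offset: float = BLOM_OFFSET
) -> TransformedOutcome:
    """INT of the full observed vector, censored values tied at their average rank.

    The censored block all maps to one value: the average rank imputes a
    central tendency for the below-LOD group, which attenuates effect
    estimates less than the max rank would.
    """
    if ph.is_censored.all():
        raise ValueError("all observations censored")
    return rank_inverse_normal(ph.observed, "average", offset)


def prepare_tobit_outcome(
    ph: CensoredPhenotype, offset: float = BLOM_OFFSET
) -> TransformedOutcome:
    """INT with max-tied censored ranks plus the transformed-scale threshold.

    Censored observations share the largest rank of their tied group, so they
    sit at the transformed-scale LOD that the Tobit likelihood needs; all
    uncensored values lie strictly above it. With no censoring the threshold
    is placed below the minimum so the fit reduces to an uncensored MLE.
    """
    if ph.is_censored.all():
        raise ValueError("all observations censored")
    out = rank_inverse_normal(ph.observed, "max", offset)
    if ph.is_censored.any():
        threshold = float(out.values[ph.is_censored][0])
    else:
        threshold = float(out.values.min()) - 1.0
    out.censor_threshold = threshold
    return out


def prepare_cox_outcome(ph: CensoredPhenotype) -> CoxOutcome:
    """Flip left-censored data to right-censored pseudo-times.

    y_cox_i = max(y_obs) - y_obs_i; the maximum observation gets pseudo-time
    0, and above-LOD samples are events. No rank transform is applied.
    """
    if ph.n < 2:
        raise ValueError("need at least 2 observations")
    pseudo_time = ph.observed.max() - ph.observed
    return CoxOutcome(pseudo_time, ~ph.is_censored)


def prepare_logistic_outcome(ph: CensoredPhenotype) -> np.ndarray:
    """Binary indicator of being above the LOD (1 = detected)."""
    event = ~ph.is_censored
    if event.all() or not event.any():
        raise ValueError(
            "single-class outcome: logistic model undefined without both "
            "below- and above-LOD observations"
        )
    return event.astype(int)
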