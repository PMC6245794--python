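"""Closed-form squared-L2 geometry between gamma mixtures.

For gamma densities the squared L2 distance between an observed mixture
``f = p G(a1,b1) + (1-p) G(a2,b2)`` and a predicted mixture ``f_hat``
has a closed form built from two kernels:

* ``g(alpha, beta)  = int G(x; alpha, beta)^2 dx``
  ``               = 2^(1-2 alpha) / ((2 alpha - 1) beta B(alpha, alpha))``
  (finite only for ``alpha > 1/2``), and
* ``h(a1, a2, b1, b2) = 2 int G(x; a1, b1) G(x; a2, b2) dx``
  ``  = 2 b1^(a2-1) b2^(a1-1) / ((a1+a2-1) (b1+b2)^(a1+a2-1) B(a1, a2))``
  (finite only for ``a1 + a2 > 1``),

where ``B`` is the beta function. Expanding ``int (f - f_hat)^2 dx``
termwise gives nine signed g/h terms per cultivar pair: the two
self-energies contribute their within-mixture cross terms with a *plus*
sign and only the observed-predicted cross terms enter negatively. All
kernels are evaluated in log-space (fitted shapes near 100 overflow
naive powers).

Summing the squared distance over cultivars gives PRESS; normalising it
by the same sum against the population mean-parameter mixture gives the
shape-level skill score Q^2 (1 = perfect, 0 = no better than the mean
mixture, negative = worse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .errors import AlignmentError, DegenerateSampleError, DivergenceError
from .mixture import MixtureParams

__all__ = [
    "PredictionSet",
    "g_term",
    "h_term",
    "squared_l2_distance",
    "press",
    "q2_shape",
]


def g_term(alpha: float, beta: float) -> float:
    """Self-energy of a gamma density: ``int G(x; alpha, beta)^2 dx``."""
    if alpha <= 0.5:
        raise DivergenceError(
            f"g(alpha, beta) diverges for alpha <= 1/2 (got alpha={alpha}); "
            "a fitted shape this small indicates a degenerate fit upstream"
        )
    if beta <= 0:
        raise DivergenceError(f"scale must be > 0, got {beta}")
    log_g = (
        (1.0 - 2.0 * alpha) * math.log(2.0)
        - math.log(2.0 * alpha - 1.0)
        - math.log(beta)
        - special.betaln(alpha, alpha)
    )
    return math.exp(log_g)


def h_term(alpha1: float, alpha2: float, beta1: float, beta2: float) -> float:
    """Twice the cross-energy: ``2 int G(x;a1,b1) G(x;a2,b2) dx``."""
    if alpha1 <= 0 or alpha2 <= 0:
        raise DivergenceError("shapes must be > 0")
    if alpha1 + alpha2 <= 1.0:
        raise DivergenceError(
            f"h diverges for alpha1 + alpha2 <= 1 (got {alpha1} + {alpha2})"
        )
    if beta1 <= 0 or beta2 <= 0:
        raise DivergenceError("scales must be > 0")
    log_h = (
        math.log(2.0)
        + (alpha2 - 1.0) * math.log(beta1)
        + (alpha1 - 1.0) * math.log(beta2)
        - math.log(alpha1 + alpha2 - 1.0)
        - (alpha1 + alpha2 - 1.0) * math.log(beta1 + beta2)
        - special.betaln(alpha1, alpha2)
    )
    return math.exp(log_h)


def _self_energy(m: MixtureParams) -> float:
    """``int f^2`` for one mixture."""
    p, q = m.p, 1.0 - m.p
    total = 0.0
    if p > 0:
        total += p * p * g_term(m.a1, m.b1)
    if q > 0:
        total += q * q * g_term(m.a2, m.b2)
    if p > 0 and q > 0:
        total += p * q * h_term(m.a1, m.a2, m.b1, m.b2)
    return total


def _cross_energy(f: MixtureParams, f_hat: MixtureParams) -> float:
    """``2 int f f_hat`` between two mixtures."""
    terms = 0.0
    for w1, a1, b1 in ((f.p, f.a1, f.b1), (1.0 - f.p, f.a2, f.b2)):
        if w1 == 0:
            continue
        for w2, a2, b2 in ((f_hat.p, f_hat.a1, f_hat.b1), (1.0 - f_hat.p, f_hat.a2, f_hat.b2)):
            if w2 == 0:
                continue
            terms += w1 * w2 * h_term(a1, a2, b1, b2)
    return terms


def squared_l2_distance(f: MixtureParams, f_hat: MixtureParams) -> float:
    """``int (f - f_hat)^2 dx`` in closed form; clamped at 0."""
    d = _self_energy(f) + _self_energy(f_hat) - _cross_energy(f, f_hat)
    if d < -1e-9:
        raise ArithmeticError(f"squared distance evaluated to {d}; parameters pathological")
    return max(d, 0.0)


@dataclass(frozen=True)
class PredictionSet:
    """Aligned observed and predicted mixtures over a cultivar population."""

    cultivar_ids: tuple
    observed: tuple
    predicted: tuple

    def __post_init__(self) -> None:
        if not (len(self.cultivar_ids) == len(self.observed) == len(self.predicted)):
            raise AlignmentError("cultivar ids, observed and predicted must have equal length")
        if len(self.cultivar_ids) == 0:
            raise AlignmentError("empty prediction set")

    @classmethod
    def from_tables(cls, observed, predicted) -> "PredictionSet":
        """Build from two cultivar-indexed DataFrames with columns p,a1,b1,a2,b2."""
        obs_ids = list(observed.index)
        if set(obs_ids) != set(predicted.index):
            raise AlignmentError(
                "observed and predicted tables index different cultivars: "
                f"{sorted(set(obs_ids) ^ set(predicted.index))}"
            )
        pred = predicted.loc[obs_ids]
        cols = ["p", "a1", "b1", "a2", "b2"]
        obs = tuple(MixtureParams.from_values(*row) for row in observed[cols].to_numpy())
        prd = tuple(MixtureParams.from_values(*row) for row in pred[cols].to_numpy())
        return cls(cultivar_ids=tuple(obs_ids), observed=obs, predicted=prd)

    @property
    def reference_means(self) -> MixtureParams:
        """Mixture built from the per-parameter means of the observed set."""
        arr = np.array([m.as_array() for m in self.observed])
        return MixtureParams.from_values(*arr.mean(axis=0))

    def with_mean_predictor(self) -> "PredictionSet":
        ref = self.reference_means
        return PredictionSet(
            cultivar_ids=self.cultivar_ids,
            observed=self.observed,
            predicted=tuple(ref for _ in self.observed),
        )


def press(pset: PredictionSet) -> float:
    """Predicted residual error sum of squares over cultivars."""
    return float(sum(squared_l2_distance(o, p) for o, p in zip(pset.observed, pset.predicted)))


def q2_shape(pset: PredictionSet) -> float:
    """Shape-level skill score: ``1 - PRESS / PRESS(mean-parameter predictor)``."""
    denom = press(pset.with_mean_predictor())
    if denom <= 0:
        raise DegenerateSampleError(
            "all observed mixtures equal the mean-parameter mixture; Q^2 undefined"
        )
    return 1.0 - press(pset) / denom
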