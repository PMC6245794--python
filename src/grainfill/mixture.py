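"""Two-component gamma-mixture model of single-grain weight.

The dry weight ``x`` (mg) of a single rice grain within a cultivar is
modelled as a mixture of two gamma densities,

    f(x) = p * Gamma(x; a1, b1) + (1 - p) * Gamma(x; a2, b2),

where the *left* component (shape ``a1``, scale ``b1``) collects unfilled
and partially filled grains, the *right* component (``a2``, ``b2``) the
filled grains, and ``p`` is the mixing proportion of unfilled grains
(so ``1 - p`` is the filled-grain fraction). The five parameters are
genotype specific and are estimated per cultivar by maximum likelihood:
an EM algorithm whose M-step solves the weighted gamma MLE by Minka's
generalized-Newton fixed point, launched from many random initialisations
with the best converged log-likelihood kept.

Derived per-cultivar statistics implemented here:

* feature values ``mode1 = (a1-1) b1`` (clamped at 0), ``skewness1``
  (as-conventionally-printed ``2/sqrt(b1)`` or the standard gamma
  skewness ``2/sqrt(a1)``), ``mu2 = a2 b2`` and ``var2 = a2 b2**2``;
* the posterior probability that a grain of weight ``x`` is filled;
* the boundary analysis: the interior density minimum between the two
  component peaks, the probability mass within +-0.1 mg of it, the same
  mass around the right-component mode, and their ratio — a measure of
  how distinguishable filled and unfilled grains are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import (
    DegenerateSampleError,
    EMCollapseError,
    FitFailureError,
    ParameterDomainError,
)

__all__ = [
    "GammaComponent",
    "MixtureParams",
    "GrainWeightSample",
    "FitResult",
    "FeatureValues",
    "BoundaryAnalysis",
    "mixture_pdf",
    "mixture_logpdf",
    "mixture_cdf",
    "mixture_quantile",
    "log_likelihood",
    "init_parameters",
    "weighted_gamma_mle",
    "em_fit",
    "fit_with_restarts",
    "feature_values",
    "posterior_filled",
    "boundary_analysis",
]

#: weights at or below this floor (mg) are treated as empty husks /
#: measurement zeros and removed before fitting (gamma support excludes 0)
DEFAULT_WEIGHT_FLOOR = 0.1

#: minimum retained grains for a trustworthy five-parameter fit
DEFAULT_MIN_GRAINS = 50


@dataclass(frozen=True)
class GammaComponent:
    """One gamma component: shape (dimensionless) and scale (mg)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ParameterDomainError(f"gamma shape must be > 0, got {self.shape}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ParameterDomainError(f"gamma scale must be > 0, got {self.scale}")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2

    @property
    def mode(self) -> float:
        """Density mode, clamped to 0 when shape < 1."""
        return max((self.shape - 1.0) * self.scale, 0.0)

    def logpdf(self, x: np.ndarray, logx: Optional[np.ndarray] = None) -> np.ndarray:
        a, b = self.shape, self.scale
        if logx is None:
            logx = np.log(x)
        return (a - 1.0) * logx - x / b - special.gammaln(a) - a * math.log(b)


@dataclass(frozen=True)
class MixtureParams:
    """Five genotype-specific parameters of one cultivar's weight density."""

    p: float
    left: GammaComponent
    right: GammaComponent

    def __post_init__(self) -> None:
        if not (np.isfinite(self.p) and 0.0 <= self.p <= 1.0):
            raise ParameterDomainError(f"mixing proportion must be in [0, 1], got {self.p}")

    @classmethod
    def from_values(cls, p: float, a1: float, b1: float, a2: float, b2: float) -> "MixtureParams":
        return cls(p=float(p), left=GammaComponent(float(a1), float(b1)),
                   right=GammaComponent(float(a2), float(b2)))

    # short accessors mirroring the field's usual parameter names
    @property
    def a1(self) -> float:
        return self.left.shape

    @property
    def b1(self) -> float:
        return self.left.scale

    @property
    def a2(self) -> float:
        return self.right.shape

    @property
    def b2(self) -> float:
        return self.right.scale

    def as_array(self) -> np.ndarray:
        """[p, a1, b1, a2, b2]."""
        return np.array([self.p, self.a1, self.b1, self.a2, self.b2])

    def canonicalized(self) -> "MixtureParams":
        """Relabel so the left component has the smaller mean.

        EM is symmetric under component exchange; the unfilled-grain
        component is, by convention, the lighter one.
        """
        if self.left.mean <= self.right.mean:
            return self
        return MixtureParams(p=1.0 - self.p, left=self.right, right=self.left)

    @property
    def mean(self) -> float:
        return self.p * self.left.mean + (1.0 - self.p) * self.right.mean


@dataclass(frozen=True)
class GrainWeightSample:
    """Pooled single-grain dry weights (mg) of one cultivar."""

    cultivar_id: str
    weights: np.ndarray
    n_excluded_zero: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size == 0:
            raise DegenerateSampleError(f"{self.cultivar_id}: empty weight vector")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ParameterDomainError(
                f"{self.cultivar_id}: retained weights must be positive and finite"
            )

    @classmethod
    def from_raw(
        cls,
        cultivar_id: str,
        weights: Sequence[float],
        *,
        floor: float = DEFAULT_WEIGHT_FLOOR,
        min_grains: int = DEFAULT_MIN_GRAINS,
    ) -> "GrainWeightSample":
        """Drop weights at/below ``floor`` (empty husks) and count them."""
        w = np.asarray(weights, dtype=float)
        keep = w > floor
        n_excluded = int(w.size - keep.sum())
        w = w[keep]
        if w.size < min_grains:
            raise DegenerateSampleError(
                f"{cultivar_id}: only {w.size} grains above {floor} mg "
                f"(minimum {min_grains})"
            )
        return cls(cultivar_id=cultivar_id, weights=w, n_excluded_zero=n_excluded)

    def __len__(self) -> int:
        return int(self.weights.size)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one EM run (or the winner over restarts)."""

    params: MixtureParams
    loglik: float
    n_iterations: int
    converged: bool
    restart_index: int = -1
    loglik_history: tuple = field(default=(), repr=False)
    restart_logliks: tuple = field(default=(), repr=False)


@dataclass(frozen=True)
class FeatureValues:
    """Interpretable summaries of the two components."""

    mode1: float
    skewness1: float
    mu2: float
    var2: float


@dataclass(frozen=True)
class BoundaryAnalysis:
    """Distinguishability of the filled/unfilled components.

    ``boundary_point`` is the interior density minimum between the two
    component peaks; ``boundary_probability`` the mass within +-0.1 mg of
    it; ``mode_probability`` the same mass around the right-component
    mode; ``ratio`` their quotient. When the mixture density is monotone
    on the inter-peak interval (or the right component has no interior
    mode) the mixture is not bimodal and the fields are absent.
    """

    bimodal: bool
    boundary_point: Optional[float] = None
    boundary_probability: Optional[float] = None
    mode_probability: Optional[float] = None
    ratio: Optional[float] = None


# ---------------------------------------------------------------------------
# density, CDF, likelihood


def _component_logpdfs(params: MixtureParams, x: np.ndarray,
                       logx: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    return params.left.logpdf(x, logx), params.right.logpdf(x, logx)


def mixture_logpdf(params: MixtureParams, x) -> np.ndarray:
    """Log of the mixture density, computed in log-space throughout."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ParameterDomainError("grain weight must be > 0")
    l1, l2 = _component_logpdfs(params, x)
    with np.errstate(divide="ignore"):
        lp = np.log(params.p) + l1
        lq = np.log1p(-params.p) + l2
    return np.logaddexp(lp, lq)


def mixture_pdf(params: MixtureParams, x) -> np.ndarray:
    """Mixture density (per mg) at weight(s) ``x``."""
    return np.exp(mixture_logpdf(params, x))


def mixture_cdf(params: MixtureParams, x) -> np.ndarray:
    """Mixture CDF; 0 for x <= 0, -> 1 as x -> infinity."""
    x = np.asarray(x, dtype=float)
    c1 = stats.gamma.cdf(x, params.a1, scale=params.b1)
    c2 = stats.gamma.cdf(x, params.a2, scale=params.b2)
    out = params.p * c1 + (1.0 - params.p) * c2
    return np.where(x <= 0, 0.0, out)


def mixture_quantile(params: MixtureParams, q: float) -> float:
    """Inverse CDF by bracketing + Brent root finding."""
    if not 0.0 < q < 1.0:
        raise ParameterDomainError("quantile level must be in (0, 1)")
    hi = max(stats.gamma.ppf(q, params.a1, scale=params.b1),
             stats.gamma.ppf(q, params.a2, scale=params.b2)) + 1.0
    lo = 1e-12
    return float(optimize.brentq(lambda x: mixture_cdf(params, x) - q, lo, hi,
                                 xtol=1e-12, rtol=1e-12))


def log_likelihood(params: MixtureParams, sample: GrainWeightSample | np.ndarray) -> float:
    """Sum of log mixture densities over the sample."""
    w = sample.weights if isinstance(sample, GrainWeightSample) else np.asarray(sample, float)
    if w.size == 0:
        raise DegenerateSampleError("empty sample")
    return float(np.sum(mixture_logpdf(params, w)))


# ---------------------------------------------------------------------------
# estimation


def init_parameters(sample: GrainWeightSample, rng: np.random.Generator) -> MixtureParams:
    """Random EM initialisation.

    ``p`` starts at 0.5. Two grains are drawn without replacement; each
    draw ``x'`` seeds one component with ``a0 = x'^2 / Var(x)`` and
    ``b0 = Var(x) / x'`` (so the initial component mean is ``x'``), the
    lighter draw seeding the left component. Tied draws are redrawn.
    """
    w = sample.weights
    if w.size < 2:
        raise DegenerateSampleError(f"{sample.cultivar_id}: need >= 2 grains")
    var = float(np.var(w, ddof=1))
    if var <= 0:
        raise DegenerateSampleError(f"{sample.cultivar_id}: zero sample variance")
    for _ in range(100):
        x_lo, x_hi = rng.choice(w, size=2, replace=False)
        if x_lo != x_hi:
            break
    else:
        raise DegenerateSampleError(f"{sample.cultivar_id}: could not draw two distinct weights")
    if x_lo > x_hi:
        x_lo, x_hi = x_hi, x_lo
    return MixtureParams.from_values(
        0.5, x_lo**2 / var, var / x_lo, x_hi**2 / var, var / x_hi
    )


def _solve_gamma_shape(s: float, *, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Solve ``ln(a) - digamma(a) = s`` for ``a > 0`` (Minka's fixed point).

    Uses the generalized-Newton update in 1/a, started from the standard
    closed-form approximation; quadratically convergent.
    """
    if not (np.isfinite(s) and s > 0):
        raise DegenerateSampleError(f"log-moment gap must be > 0, got {s}")
    a = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        g = math.log(a) - special.digamma(a)
        denom = a * a * (1.0 / a - special.polygamma(1, a))
        inv_new = 1.0 / a + (g - s) / denom
        if inv_new <= 0:  # fall back to damped bisection-style step
            a_new = a * 0.5 if g < s else a * 2.0
        else:
            a_new = 1.0 / inv_new
        if abs(math.log(a_new) - math.log(a)) < tol:
            return a_new
        a = a_new
    return a


def _gamma_mle_from_stats(xbar: float, logxbar: float) -> tuple[float, float]:
    s = math.log(xbar) - logxbar
    a = _solve_gamma_shape(s)
    return a, xbar / a


def weighted_gamma_mle(values, weights) -> GammaComponent:
    """Weighted maximum-likelihood gamma fit (Minka's fixed point).

    Satisfies ``ln(a) - digamma(a) = ln(weighted mean) - weighted mean of
    logs`` and ``b = weighted mean / a``.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(x <= 0):
        raise ParameterDomainError("values must be positive")
    if np.any(w < 0) or w.sum() <= 0:
        raise DegenerateSampleError("weights must be non-negative with positive sum")
    sw = w.sum()
    xbar = float(np.dot(w, x) / sw)
    logxbar = float(np.dot(w, np.log(x)) / sw)
    # the gap is 0 for constant data up to rounding; treat near-zero as degenerate
    if math.log(xbar) - logxbar <= 1e-12:
        raise DegenerateSampleError("degenerate sample: weighted log-moment gap <= 0")
    a, b = _gamma_mle_from_stats(xbar, logxbar)
    return GammaComponent(a, b)


_COLLAPSE_EPS = 1e-10


def em_fit(
    sample: GrainWeightSample,
    init: MixtureParams,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FitResult:
    """EM for the two-component gamma mixture.

    E-step: responsibilities of the left component. M-step: ``p`` is the
    mean responsibility; each component is refit by the weighted gamma
    MLE. The log-likelihood is non-decreasing every iteration; iteration
    stops when its increase falls below ``tol``. The result is
    canonically labelled (left component mean <= right component mean).

    Raises :class:`EMCollapseError` when a component's responsibility
    mass vanishes or its weighted log-moment degenerates — the caller
    (restart loop) discards such runs.
    """
    x = sample.weights
    logx = np.log(x)
    p = init.p
    left, right = init.left, init.right
    prev_ll = -np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        l1 = left.logpdf(x, logx)
        l2 = right.logpdf(x, logx)
        with np.errstate(divide="ignore"):
            lp = np.log(p) + l1
            lq = np.log1p(-p) + l2
        norm = np.logaddexp(lp, lq)
        ll = float(norm.sum())
        history.append(ll)
        if ll - prev_ll < tol and it > 1:
            converged = True
            break
        prev_ll = ll
        r = np.exp(lp - norm)  # responsibility of the left component
        s1 = float(r.sum())
        s2 = float(x.size - s1)
        if s1 < _COLLAPSE_EPS or s2 < _COLLAPSE_EPS:
            raise EMCollapseError(f"{sample.cultivar_id}: component collapsed at iter {it}")
        p = s1 / x.size
        try:
            xbar1 = float(np.dot(r, x) / s1)
            lbar1 = float(np.dot(r, logx) / s1)
            xbar2 = float((x.sum() - np.dot(r, x)) / s2)
            lbar2 = float((logx.sum() - np.dot(r, logx)) / s2)
            a1, b1 = _gamma_mle_from_stats(xbar1, lbar1)
            a2, b2 = _gamma_mle_from_stats(xbar2, lbar2)
        except DegenerateSampleError as exc:
            raise EMCollapseError(f"{sample.cultivar_id}: M-step degenerate: {exc}") from exc
        left = GammaComponent(a1, b1)
        right = GammaComponent(a2, b2)
    params = MixtureParams(p=p, left=left, right=right).canonicalized()
    return FitResult(
        params=params,
        loglik=history[-1],
        n_iterations=it,
        converged=converged,
        loglik_history=tuple(history),
    )


def fit_with_restarts(
    sample: GrainWeightSample,
    n_restarts: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FitResult:
    """Run EM from ``n_restarts`` random initialisations; keep the best.

    The winner is the converged restart with the highest log-likelihood
    (``restart_index`` records which). ``restart_logliks`` holds every
    completed restart's log-likelihood (NaN for collapsed restarts) —
    the spread is the practical convergence diagnostic.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    best: Optional[FitResult] = None
    best_idx = -1
    logliks: list[float] = []
    failures: list[str] = []
    for idx in range(n_restarts):
        try:
            init = init_parameters(sample, rng)
            res = em_fit(sample, init, tol=tol, max_iter=max_iter)
        except (EMCollapseError, DegenerateSampleError, ParameterDomainError) as exc:
            logliks.append(float("nan"))
            failures.append(f"restart {idx}: {exc}")
            continue
        logliks.append(res.loglik)
        if res.converged and (best is None or res.loglik > best.loglik):
            best = res
            best_idx = idx
    if best is None:
        raise FitFailureError(
            f"{sample.cultivar_id}: all {n_restarts} restarts failed: "
            + "; ".join(failures[:5])
        )
    return replace(best, restart_index=best_idx, restart_logliks=tuple(logliks))


# ---------------------------------------------------------------------------
# derived statistics


def feature_values(params: MixtureParams, *, skewness_convention: str = "scale") -> FeatureValues:
    """The four interpretable feature values.

    ``skewness_convention="scale"`` (default) computes skewness1 as
    ``2 / sqrt(b1)``, the form conventionally reported for this trait;
    ``"shape"`` computes the standard gamma skewness ``2 / sqrt(a1)``.
    """
    if skewness_convention == "scale":
        skew = 2.0 / math.sqrt(params.b1)
    elif skewness_convention == "shape":
        skew = 2.0 / math.sqrt(params.a1)
    else:
        raise ValueError("skewness_convention must be 'scale' or 'shape'")
    return FeatureValues(
        mode1=params.left.mode,
        skewness1=skew,
        mu2=params.right.mean,
        var2=params.right.variance,
    )


def posterior_filled(params: MixtureParams, x) -> np.ndarray:
    """Posterior probability that a grain of weight ``x`` is filled.

    ``(1-p) f2(x) / f(x)``; a grain is classified as filled when this
    exceeds 0.5.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ParameterDomainError("grain weight must be > 0")
    if params.p == 0.0:
        return np.ones_like(x)
    if params.p == 1.0:
        return np.zeros_like(x)
    l1, l2 = _component_logpdfs(params, x)
    lp = math.log(params.p) + l1
    lq = math.log1p(-params.p) + l2
    return np.exp(lq - np.logaddexp(lp, lq))


def boundary_analysis(
    params: MixtureParams,
    *,
    n_grid: int = 10_000,
    halfwidth: float = 0.1,
) -> BoundaryAnalysis:
    """Locate the density minimum between the two component peaks.

    The mixture density is scanned on a dense grid over
    ``[max(mode1, eps), (a2-1) b2]`` and the grid minimum is refined by
    bounded scalar minimisation. The boundary probability is the mass
    within ``+-halfwidth`` mg of that point; the mode probability the
    same mass around the right-component mode. When the right component
    has no interior mode (a2 <= 1) or the density is monotone on the
    interval, the mixture is reported as not bimodal.
    """
    mode2 = params.right.mode
    if params.a2 <= 1.0 or params.p in (0.0, 1.0):
        return BoundaryAnalysis(bimodal=False)
    lo = max(params.left.mode, 1e-6)
    hi = mode2
    if not lo < hi:
        return BoundaryAnalysis(bimodal=False)
    grid = np.linspace(lo, hi, n_grid)
    dens = mixture_pdf(params, grid)
    i = int(np.argmin(dens))
    interior = 0 < i < n_grid - 1
    if not interior or not (dens[i] < dens[0] and dens[i] < dens[-1]):
        return BoundaryAnalysis(bimodal=False)
    res = optimize.minimize_scalar(
        lambda t: float(mixture_pdf(params, t)),
        bounds=(grid[i - 1], grid[i + 1]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    b = float(res.x)
    boundary_prob = float(mixture_cdf(params, b + halfwidth) - mixture_cdf(params, b - halfwidth))
    mode_prob = float(
        mixture_cdf(params, mode2 + halfwidth) - mixture_cdf(params, mode2 - halfwidth)
    )
    return BoundaryAnalysis(
        bimodal=True,
        boundary_point=b,
        boundary_probability=boundary_prob,
        mode_probability=mode_prob,
        ratio=boundary_prob / mode_prob if mode_prob > 0 else float("inf"),
    )
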