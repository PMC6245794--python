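"""Shared fixtures and the numerical-quadrature oracle.

The quadrature helpers integrate gamma-mixture expressions over (0, inf)
with adaptive quadrature split at the component means; they are the
independent ground truth for every closed-form identity in the package.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from grainfill import MixtureParams, mixture_pdf


def _upper_bound(*mixtures: MixtureParams) -> float:
    return max(
        stats.gamma.ppf(1.0 - 1e-13, c.shape, scale=c.scale)
        for m in mixtures
        for c in (m.left, m.right)
    )


def _breakpoints(*mixtures: MixtureParams) -> list:
    return sorted({c.mean for m in mixtures for c in (m.left, m.right)})


def quad_integral(fn, *mixtures: MixtureParams) -> float:
    """Adaptive quadrature of ``fn(x)`` over the mixtures' joint support."""
    hi = _upper_bound(*mixtures)
    val, _ = quad(fn, 1e-13, hi, points=_breakpoints(*mixtures),
                  limit=400, epsabs=0.0, epsrel=1e-12)
    return val


def quad_l2(f: MixtureParams, g: MixtureParams) -> float:
    """``int (f - g)^2`` by quadrature."""
    return quad_integral(lambda x: (mixture_pdf(f, x) - mixture_pdf(g, x)) ** 2, f, g)


def random_mixture(rng: np.random.Generator,
                   shape_range=(0.6, 200.0),
                   scale_range=(0.01, 10.0)) -> MixtureParams:
    """Random valid parameter set inside the closed-form kernels' domain."""
    return MixtureParams.from_values(
        rng.uniform(0.05, 0.95),
        rng.uniform(*shape_range), rng.uniform(*scale_range),
        rng.uniform(*shape_range), rng.uniform(*scale_range),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def field_regime_params() -> MixtureParams:
    """A realistic cultivar: right-skewed unfilled grains near 6 mg,
    sharp filled grains near 25 mg, 17.5 % unfilled."""
    return MixtureParams.from_values(0.175, 1.5, 4.0, 100.0, 0.25)
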