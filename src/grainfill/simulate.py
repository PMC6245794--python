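"""Synthetic rice panels with heritable grain-weight distributions.

The generator emulates the data structure the pipeline expects, end to
end: an inbred biallelic marker panel, five genotype-specific mixture
parameters with an additive genetic architecture of tunable
heritability, and per-cultivar single-grain weights drawn from each
cultivar's mixture (with component-membership labels retained for
oracle tests).

Defaults emulate the field regime the model targets: filled-grain mean
near 25 mg with a sharp right component (a2 = 100, b2 = 0.25), a
right-skewed unfilled component with mean near 6 mg (a1 = 1.5, b1 = 4),
and a population-centre unfilled proportion p = 0.175. Parameters vary
across cultivars on link scales (logit for p, log for shapes and
scales) as additive genetic value plus independent noise, so the
realized narrow-sense heritability on the link scale equals the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ParameterDomainError
from .mixture import GrainWeightSample, MixtureParams
from .prediction import PARAM_COLS, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedGrains",
    "SimulatedDataset",
    "simulate_markers",
    "simulate_distribution_params",
    "simulate_grain_weights",
    "make_dataset",
]

DEFAULT_BASELINES = MixtureParams.from_values(0.175, 1.5, 4.0, 100.0, 0.25)

#: total standard deviation of each parameter on its link scale
DEFAULT_LINK_SD = {"p": 0.45, "a1": 0.25, "b1": 0.25, "a2": 0.20, "b2": 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_cultivars: int = 150
    n_markers: int = 2000
    n_qtl: int = 100
    target_h2: Mapping[str, float] = dc_field(
        default_factory=lambda: {c: 0.5 for c in PARAM_COLS})
    n_grains_per_cultivar: int = 1500
    parameter_baselines: MixtureParams = DEFAULT_BASELINES
    link_sd: Mapping[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_LINK_SD))
    maf_range: tuple = (0.05, 0.5)
    het_fraction: float = 0.0
    n_duplicate_markers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ParameterDomainError("n_qtl must not exceed n_markers")
        for k, h2 in self.target_h2.items():
            if not 0.0 < h2 < 1.0:
                raise ParameterDomainError(f"target_h2[{k}] must be in (0, 1), got {h2}")
        base = self.parameter_baselines
        if base.left.mean >= base.right.mean:
            raise ParameterDomainError(
                "baseline left-component mean must be below the right-component mean"
            )


@dataclass(frozen=True)
class SimulatedGrains:
    """One cultivar's weights plus the true component memberships."""

    sample: GrainWeightSample
    is_left: np.ndarray  # True where the grain came from the unfilled component


@dataclass(frozen=True)
class SimulatedDataset:
    geno: GenotypeMatrix
    samples: Dict[str, GrainWeightSample]
    labels: Dict[str, np.ndarray]
    true_params: pd.DataFrame  # cultivar-indexed p, a1, b1, a2, b2
    genetic_values: pd.DataFrame  # additive genetic value per parameter (link scale)
    config: SimulationConfig


def simulate_markers(config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Inbred biallelic panel: codes in {-1, 1} (optionally a few hets).

    Per-marker alternate-allele frequencies are uniform on
    ``config.maf_range``; ``het_fraction`` flips that share of calls to
    heterozygous 0 codes; ``n_duplicate_markers`` appends exact copies
    of random columns (complete linkage, for exercising the filter).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_cultivars, config.n_markers
    freq = rng.uniform(*config.maf_range, size=m)
    codes = np.where(rng.random((n, m)) < freq, 1, -1).astype(np.int8)
    if config.het_fraction > 0:
        hets = rng.random((n, m)) < config.het_fraction
        codes[hets] = 0
    marker_ids = [f"M{j + 1:05d}" for j in range(m)]
    if config.n_duplicate_markers > 0:
        src = rng.choice(m, size=config.n_duplicate_markers, replace=False)
        codes = np.concatenate([codes, codes[:, src]], axis=1)
        marker_ids += [f"M{j + 1:05d}dup" for j in src]
    cultivar_ids = [f"C{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(tuple(cultivar_ids), tuple(marker_ids), codes)


def _link(base: float, t: np.ndarray, param: str) -> np.ndarray:
    if param == "p":
        return expit(logit(base) + t)
    return base * np.exp(t)


def simulate_distribution_params(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additively heritable mixture parameters per cultivar.

    For each parameter an additive genetic value ``u = Z_qtl beta`` is
    scaled to contribute ``target_h2`` of the link-scale variance
    ``link_sd**2``; independent Gaussian noise supplies the rest. Rows
    whose left-component mean would reach the right-component mean have
    their left-side deviations shrunk until the ordering holds.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    Z = geno.codes.astype(float)
    Z = Z - Z.mean(axis=0, keepdims=True)
    n = geno.n_cultivars
    base = config.parameter_baselines.as_array()
    t_cols, u_cols = {}, {}
    for j, name in enumerate(PARAM_COLS):
        sd = float(config.link_sd[name])
        h2 = float(config.target_h2[name])
        qtl = rng.choice(geno.n_markers, size=config.n_qtl, replace=False)
        beta = rng.standard_normal(config.n_qtl)
        u = Z[:, qtl] @ beta
        u_sd = float(np.std(u))
        if u_sd > 0:
            u = u * (np.sqrt(h2) * sd / u_sd)
        eps = rng.standard_normal(n) * np.sqrt(1.0 - h2) * sd
        t_cols[name] = u + eps
        u_cols[name] = u
    # ordering guard: shrink left-side deviations where means would cross
    for _ in range(40):
        mean_left = _link(base[1], t_cols["a1"], "a1") * _link(base[2], t_cols["b1"], "b1")
        mean_right = _link(base[3], t_cols["a2"], "a2") * _link(base[4], t_cols["b2"], "b2")
        bad = mean_left >= 0.95 * mean_right
        if not bad.any():
            break
        for name in ("a1", "b1"):
            t_cols[name] = np.where(bad, t_cols[name] * 0.5, t_cols[name])
    values = {name: _link(base[j], t_cols[name], name)
              for j, name in enumerate(PARAM_COLS)}
    params = pd.DataFrame(values, index=list(geno.cultivar_ids))
    genetic = pd.DataFrame(u_cols, index=list(geno.cultivar_ids))
    return params, genetic


def simulate_grain_weights(
    params: MixtureParams,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    cultivar_id: str = "sim",
) -> SimulatedGrains:
    """Draw ``n`` grains from the mixture, keeping membership labels."""
    if n < 1:
        raise ParameterDomainError("n must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    is_left = rng.random(n) < params.p
    weights = np.where(
        is_left,
        rng.gamma(params.a1, params.b1, size=n),
        rng.gamma(params.a2, params.b2, size=n),
    )
    # gamma draws are strictly positive almost surely; guard exact zeros
    weights = np.maximum(weights, np.finfo(float).tiny)
    sample = GrainWeightSample(cultivar_id=cultivar_id, weights=weights)
    return SimulatedGrains(sample=sample, is_left=is_left)


def make_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Compose markers, heritable parameters and grain weights."""
    rng = np.random.default_rng(config.seed)
    geno = simulate_markers(config, rng)
    params, genetic = simulate_distribution_params(geno, config, rng)
    samples: Dict[str, GrainWeightSample] = {}
    labels: Dict[str, np.ndarray] = {}
    for cid, row in params.iterrows():
        m = MixtureParams.from_values(*row[PARAM_COLS])
        sim = simulate_grain_weights(m, config.n_grains_per_cultivar,
                                     rng=rng, cultivar_id=cid)
        samples[cid] = sim.sample
        labels[cid] = sim.is_left
    return SimulatedDataset(
        geno=geno, samples=samples, labels=labels,
        true_params=params, genetic_values=genetic, config=config,
    )
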