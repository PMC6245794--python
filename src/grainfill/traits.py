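"""Conventionally measured grain-filling traits.

Three field-standard summaries of a cultivar's pooled single-grain
weights complement the mixture parameters:

* ``p.23mg`` — fraction of grains lighter than a fixed 23 mg threshold;
* ``p.90%`` — fraction lighter than 90 % of the 95th-percentile weight
  (a cultivar-relative unfilled-grain proportion);
* sink-filling rate — total grain weight over sink capacity, where the
  per-grain sink capacity is the 95th-percentile weight.

Percentiles use linear interpolation between order statistics (the
"type 7" rule of mainstream numeric stacks); "lighter than" is a strict
inequality. Both conventions are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError
from .mixture import MixtureParams, posterior_filled

__all__ = [
    "PanicleRecord",
    "ConventionalTraits",
    "rescale_weights",
    "p_23mg",
    "p_90pct",
    "sink_filling_rate",
    "conventional_traits",
    "positional_classification_summary",
]

DEFAULT_THRESHOLD_MG = 23.0


@dataclass(frozen=True)
class PanicleRecord:
    """One panicle's grains plus its independently weighed total."""

    cultivar_id: str
    panicle_id: str
    weights: np.ndarray
    total_dry_weight: float
    n_grains: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


@dataclass(frozen=True)
class ConventionalTraits:
    p23mg: float
    p90pct: float
    sink_filling_rate: float
    q95: float


def _quantile95(weights: np.ndarray) -> float:
    # numpy's default interpolation is the type-7 rule documented above
    return float(np.quantile(weights, 0.95))


def rescale_weights(measured_weights, total_dry_weight: float) -> np.ndarray:
    """Rescale counter-measured weights to sum to the oven-dry total.

    The automatic weighing system and the bulk dry-matter weighing have
    different calibrations; each grain weight is multiplied by
    ``total_dry_weight / sum(measured)``.
    """
    w = np.asarray(measured_weights, dtype=float)
    s = w.sum()
    if s <= 0:
        raise DegenerateSampleError("measured weights sum to zero")
    if total_dry_weight <= 0:
        raise DegenerateSampleError("total dry weight must be positive")
    return w * (total_dry_weight / s)


def _check_nonempty(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise DegenerateSampleError("empty weight vector")
    return w


def p_23mg(weights, *, threshold: float = DEFAULT_THRESHOLD_MG, strict: bool = True) -> float:
    """Fraction of grains lighter than the fixed filled-grain threshold."""
    w = _check_nonempty(weights)
    return float(np.mean(w < threshold) if strict else np.mean(w <= threshold))


def p_90pct(weights, *, strict: bool = True) -> float:
    """Fraction of grains lighter than 90 % of the 95th-percentile weight."""
    w = _check_nonempty(weights)
    thr = 0.9 * _quantile95(w)
    return float(np.mean(w < thr) if strict else np.mean(w <= thr))


def sink_filling_rate(weights, n_grains: int, total_weight: float) -> float:
    """Total grain weight over sink capacity (q95 x grain count)."""
    w = _check_nonempty(weights)
    if n_grains < 1:
        raise DegenerateSampleError("n_grains must be >= 1")
    if total_weight <= 0:
        raise DegenerateSampleError("total weight must be positive")
    q95 = _quantile95(w)
    if q95 <= 0:
        raise DegenerateSampleError("q95 of the weight distribution is zero")
    return float(total_weight / (q95 * n_grains))


def conventional_traits(
    weights,
    n_grains: Optional[int] = None,
    total_weight: Optional[float] = None,
    *,
    threshold: float = DEFAULT_THRESHOLD_MG,
    strict: bool = True,
) -> ConventionalTraits:
    """All three conventional traits from a pooled weight vector.

    When the independently counted grain number or weighed total are not
    supplied they default to the vector's own count and sum.
    """
    w = _check_nonempty(weights)
    n = int(n_grains) if n_grains is not None else w.size
    tot = float(total_weight) if total_weight is not None else float(w.sum())
    return ConventionalTraits(
        p23mg=p_23mg(w, threshold=threshold, strict=strict),
        p90pct=p_90pct(w, strict=strict),
        sink_filling_rate=sink_filling_rate(w, n, tot),
        q95=_quantile95(w),
    )


def positional_classification_summary(
    grains: pd.DataFrame,
    fits: Mapping[str, MixtureParams],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify position-tagged grains into the filled component.

    ``grains`` has columns ``cultivar_id``, ``position`` (e.g.
    ``superior`` / ``inferior``) and ``grain_weight_mg``; each grain is
    labelled filled when its posterior filled probability under the
    cultivar's fitted mixture exceeds 0.5.

    Returns ``(pooled, per_cultivar)``: the pooled table has one row per
    position label with grain counts and the filled fraction; the
    per-cultivar table carries counts for correlating unfilled-grain
    counts with the mixing proportion ``p``. Cultivars without a fit are
    skipped with a warning.
    """
    required = {"cultivar_id", "position", "grain_weight_mg"}
    missing = required - set(grains.columns)
    if missing:
        raise ValueError(f"grains table missing columns: {sorted(missing)}")
    rows = []
    skipped = []
    for (cid, pos), grp in grains.groupby(["cultivar_id", "position"], sort=True):
        params = fits.get(cid)
        if params is None:
            skipped.append(cid)
            continue
        post = posterior_filled(params, grp["grain_weight_mg"].to_numpy())
        filled = post > 0.5
        rows.append({
            "cultivar_id": cid,
            "position": pos,
            "n_grains": int(filled.size),
            "n_filled": int(filled.sum()),
            "p": params.p,
        })
    if skipped:
        warnings.warn(
            f"no mixture fit for cultivars {sorted(set(skipped))}; their positional "
            "grains were skipped",
            stacklevel=2,
        )
    if not rows:
        raise DegenerateSampleError("no positional grains with a matching fit")
    per_cultivar = pd.DataFrame(rows)
    pooled = (
        per_cultivar.groupby("position")[["n_grains", "n_filled"]]
        .sum()
        .assign(filled_fraction=lambda d: d["n_filled"] / d["n_grains"])
        .reset_index()
    )
    return pooled, per_cultivar
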