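"""End-to-end pipeline steps shared by the CLI and scripts.

Each step is a plain function over DataFrames so it can be driven from
Python or from the command line; every run directory gets a manifest
capturing the configuration, seed and package version so byte-identical
reruns are checkable.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import FitFailureError, GrainfillError
from .io import group_samples
from .mixture import (
    DEFAULT_MIN_GRAINS,
    DEFAULT_WEIGHT_FLOOR,
    boundary_analysis,
    feature_values,
    fit_with_restarts,
)
from .prediction import CVResult, GenotypeMatrix, filter_markers, run_prediction_experiment
from .traits import conventional_traits

__all__ = ["RunConfig", "fit_cultivars", "traits_table", "predict_report", "write_manifest"]


@dataclass
class RunConfig:
    """Reproducibility controls for a pipeline run."""

    seed: int = 0
    restarts: int = 100
    min_grains: int = DEFAULT_MIN_GRAINS
    weight_floor: float = DEFAULT_WEIGHT_FLOOR
    schemes: Sequence[str] = ("gblup", "pls1", "pls3", "plsE")
    maf_min: float = 0.025
    max_het: float = 0.05
    max_ncomp: int = 30
    select_per_fold: bool = True
    skewness_convention: str = "scale"
    strict: bool = False
    extra: dict = field(default_factory=dict)


def write_manifest(out_dir: Path, command: str, config: RunConfig) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def fit_cultivars(
    weights_df: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> tuple[pd.DataFrame, Dict[str, str]]:
    """Fit the mixture to every cultivar in a per-grain weight table.

    Returns (table, problems): the table has one row per cultivar that
    met the minimum-grains threshold, with parameters, diagnostics,
    feature values and boundary traits; ``problems`` maps cultivars that
    were skipped or whose fit did not converge to a reason (they are
    flagged, never dropped silently from the report).
    """
    config = config or RunConfig()
    samples, skipped = group_samples(
        weights_df, floor=config.weight_floor, min_grains=config.min_grains)
    problems: Dict[str, str] = dict(skipped)
    rows = []
    rng = np.random.default_rng(config.seed)
    for cid in sorted(samples):
        sample = samples[cid]
        sub_rng = np.random.default_rng(rng.integers(2**31))
        try:
            res = fit_with_restarts(sample, n_restarts=config.restarts, rng=sub_rng)
        except FitFailureError as exc:
            problems[cid] = str(exc)
            continue
        if not res.converged:
            problems[cid] = "EM did not converge within the iteration budget"
        params = res.params
        fv = feature_values(params, skewness_convention=config.skewness_convention)
        ba = boundary_analysis(params)
        rows.append({
            "cultivar_id": cid,
            "p": params.p, "a1": params.a1, "b1": params.b1,
            "a2": params.a2, "b2": params.b2,
            "loglik": res.loglik,
            "n_grains": len(sample),
            "n_excluded": sample.n_excluded_zero,
            "converged": res.converged,
            "n_iterations": res.n_iterations,
            "restart_index": res.restart_index,
            "mode1": fv.mode1, "skewness1": fv.skewness1,
            "mu2": fv.mu2, "var2": fv.var2,
            "bimodal": ba.bimodal,
            "boundary_point": ba.boundary_point,
            "boundary_probability": ba.boundary_probability,
            "mode_probability": ba.mode_probability,
            "ratio": ba.ratio,
        })
    table = pd.DataFrame(rows).set_index("cultivar_id") if rows else pd.DataFrame()
    return table, problems


def traits_table(
    weights_df: pd.DataFrame,
    config: Optional[RunConfig] = None,
    *,
    threshold: float = 23.0,
) -> pd.DataFrame:
    """Conventional traits per cultivar from pooled grain weights."""
    config = config or RunConfig()
    rows = []
    for cid, grp in weights_df.groupby("cultivar_id", sort=True):
        w = grp["grain_weight_mg"].to_numpy()
        w = w[w > config.weight_floor]
        if w.size == 0:
            continue
        ct = conventional_traits(w, threshold=threshold)
        rows.append({
            "cultivar_id": cid, "p23mg": ct.p23mg, "p90pct": ct.p90pct,
            "sink_filling_rate": ct.sink_filling_rate, "q95": ct.q95,
        })
    return pd.DataFrame(rows).set_index("cultivar_id")


def predict_report(
    params_table: pd.DataFrame,
    geno: GenotypeMatrix,
    config: Optional[RunConfig] = None,
    *,
    observed_traits: Optional[pd.DataFrame] = None,
) -> tuple[Dict[str, CVResult], dict]:
    """Filter markers and run every requested prediction scheme."""
    config = config or RunConfig()
    usable = params_table
    if "converged" in usable.columns:
        n_bad = int((~usable["converged"].astype(bool)).sum())
        if n_bad and config.strict:
            raise GrainfillError(f"{n_bad} cultivars have non-converged fits (--strict)")
        usable = usable[usable["converged"].astype(bool)]
    filtered, report = filter_markers(geno, maf_min=config.maf_min, max_het=config.max_het)
    results = run_prediction_experiment(
        filtered,
        usable,
        schemes=config.schemes,
        observed_traits=observed_traits,
        max_ncomp=config.max_ncomp,
        select_per_fold=config.select_per_fold,
        skewness_convention=config.skewness_convention,
    )
    meta = {
        "n_cultivars": len(usable),
        "marker_filter": asdict(report),
        "schemes": list(config.schemes),
        "select_per_fold": config.select_per_fold,
    }
    return results, meta
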