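"""Readers and writers for the pipeline's file formats.

* grain-weight CSV: one row per grain with columns ``cultivar_id``,
  ``panicle_id``, ``grain_weight_mg`` and an optional ``position``
  column (``superior|inferior|unknown``);
* fitted-parameters TSV: one row per cultivar with the five mixture
  parameters, fit diagnostics, feature values and boundary traits;
* genotype matrix CSV: cultivar rows, marker columns, codes {-1, 0, 1};
* genotype VCF: biallelic SNPs, genotypes mapped 0/0 -> -1, 1/1 -> 1,
  0/1 -> 0 (read through cyvcf2);
* prediction report JSON/TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .errors import GrainfillError, ParameterDomainError
from .mixture import (
    DEFAULT_MIN_GRAINS,
    DEFAULT_WEIGHT_FLOOR,
    GrainWeightSample,
    MixtureParams,
)
from .prediction import PARAM_COLS, CVResult, GenotypeMatrix

__all__ = [
    "read_weights_csv",
    "group_samples",
    "write_params_tsv",
    "read_params_tsv",
    "params_table_to_mixtures",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_genotype_vcf",
    "read_genotypes",
    "write_report_json",
    "write_report_tsv",
]

WEIGHT_COLUMNS = ["cultivar_id", "panicle_id", "grain_weight_mg"]


def read_weights_csv(path) -> pd.DataFrame:
    """Read and validate the per-grain weight table."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises many parser types
        raise GrainfillError(f"could not parse {path}: {exc}") from exc
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise GrainfillError(f"{path}: missing columns {sorted(missing)}")
    w = pd.to_numeric(df["grain_weight_mg"], errors="coerce")
    bad = df.index[w.isna()]
    if len(bad) > 0:
        raise GrainfillError(
            f"{path}: non-numeric grain_weight_mg at data line(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    df["grain_weight_mg"] = w
    if "position" not in df.columns:
        df["position"] = "unknown"
    return df


def group_samples(
    df: pd.DataFrame,
    *,
    floor: float = DEFAULT_WEIGHT_FLOOR,
    min_grains: int = DEFAULT_MIN_GRAINS,
) -> tuple[Dict[str, GrainWeightSample], Dict[str, str]]:
    """Pool each cultivar's grains (all panicles) into one sample.

    Returns (samples, skipped) where ``skipped`` maps cultivars that
    could not be pooled (too few retained grains) to the reason.
    """
    samples: Dict[str, GrainWeightSample] = {}
    skipped: Dict[str, str] = {}
    for cid, grp in df.groupby("cultivar_id", sort=True):
        try:
            samples[str(cid)] = GrainWeightSample.from_raw(
                str(cid), grp["grain_weight_mg"].to_numpy(),
                floor=floor, min_grains=min_grains,
            )
        except GrainfillError as exc:
            skipped[str(cid)] = str(exc)
    return samples, skipped


PARAMS_TSV_COLS = [
    "cultivar_id", "p", "a1", "b1", "a2", "b2", "loglik",
    "n_grains", "n_excluded", "converged", "n_iterations", "restart_index",
    "mode1", "skewness1", "mu2", "var2",
    "bimodal", "boundary_point", "boundary_probability", "mode_probability", "ratio",
]


def write_params_tsv(table: pd.DataFrame, path) -> None:
    cols = [c for c in PARAMS_TSV_COLS if c in table.columns]
    table = table.reset_index() if table.index.name == "cultivar_id" else table
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_params_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"cultivar_id", *PARAM_COLS} - set(df.columns)
    if missing:
        raise GrainfillError(f"{path}: missing columns {sorted(missing)}")
    return df.set_index("cultivar_id")


def params_table_to_mixtures(df: pd.DataFrame) -> Dict[str, MixtureParams]:
    return {
        str(cid): MixtureParams.from_values(*row[PARAM_COLS])
        for cid, row in df.iterrows()
    }


def read_genotype_csv(path) -> GenotypeMatrix:
    """Matrix CSV: first column cultivar IDs, header row marker IDs."""
    df = pd.read_csv(path, index_col=0)
    codes = df.to_numpy()
    if not np.isin(codes, (-1, 0, 1)).all():
        raise ParameterDomainError(f"{path}: genotype codes must be in {{-1, 0, 1}}")
    return GenotypeMatrix(
        tuple(str(c) for c in df.index),
        tuple(str(m) for m in df.columns),
        codes.astype(np.int8),
    )


def write_genotype_csv(geno: GenotypeMatrix, path) -> None:
    geno.to_dataframe().to_csv(path, index_label="cultivar_id")


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (plain or bgzipped).

    Genotypes are coded 0/0 -> -1, 1/1 -> 1, 0/1 -> 0; multi-allelic or
    non-SNP records and records with missing calls are skipped.
    """
    from cyvcf2 import VCF  # deferred: only VCF users need the htslib stack

    vcf = VCF(str(path), gts012=True)
    cultivars = tuple(vcf.samples)
    marker_ids = []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        if (gt == 3).any():
            continue
        columns.append(np.select([gt == 0, gt == 1, gt == 2], [-1, 0, 1]).astype(np.int8))
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not columns:
        raise GrainfillError(f"{path}: no usable biallelic SNPs")
    return GenotypeMatrix(cultivars, tuple(marker_ids), np.column_stack(columns))


def read_genotypes(path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf/.vcf.gz vs matrix CSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_genotype_vcf(path)
    return read_genotype_csv(path)


def write_report_json(results: Dict[str, CVResult], path, extra: Optional[dict] = None) -> None:
    payload = {name: res.to_dict() for name, res in results.items()}
    if extra:
        payload["run"] = extra
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def write_report_tsv(results: Dict[str, CVResult], path) -> None:
    """Spreadsheet twin of the JSON report: one accuracy row per trait/scheme."""
    frames = []
    for name, res in results.items():
        acc = res.accuracies.copy()
        acc.insert(0, "scheme", name)
        acc.insert(1, "trait", acc.index)
        frames.append(acc)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.6g")
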