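"""Genomic prediction of grain-weight-distribution parameters.

Cultivar genotypes are biallelic markers coded -1 (homozygous
reference), 1 (homozygous alternate), 0 (heterozygous). After filtering
(minor allele frequency, residual heterozygosity, monomorphic and
completely linked columns) two predictor families are supported:

* GBLUP — ``y = 1 mu + g + e`` with ``g ~ N(0, sigma_g^2 K)`` where K is
  the VanRaden genomic relationship matrix; variance components by REML
  on the spectral decomposition of K (one-dimensional search over the
  log variance ratio). Narrow-sense heritability is
  ``sigma_g^2 / (sigma_g^2 + sigma_e^2)``.
* Multi-response PLS (NIPALS) in three grouping schemes for the five
  parameters: one model for all five ("1 group"), three models for
  {p}, {a1, b1}, {a2, b2} ("3 groups"), or one model per parameter.
  Component counts (<= 30) are chosen by leave-one-out shape Q^2.

Prediction skill is evaluated by leave-one-out cross-validation: Pearson
correlation between observed and fitted/predicted values per trait, plus
PRESS and shape Q^2 on the predicted parameter sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    AlignmentError,
    DegenerateSampleError,
    EmptyPanelError,
    ParameterDomainError,
)
from .mixture import (
    MixtureParams,
    boundary_analysis,
    feature_values,
    mixture_cdf,
    mixture_quantile,
)
from .shape import PredictionSet, press, q2_shape

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "VarianceComponents",
    "PredictionScheme",
    "CVResult",
    "filter_markers",
    "genomic_relationship",
    "gblup_fit",
    "loo_gblup",
    "heritability",
    "PLSModel",
    "pls_fit",
    "loo_pls",
    "select_ncomp",
    "loo_cv",
    "run_prediction_experiment",
    "PARAM_COLS",
    "TABLE_ROWS",
]

PARAM_COLS = ["p", "a1", "b1", "a2", "b2"]
FEATURE_COLS = ["mode1", "skewness1", "mu2", "var2"]
BOUNDARY_COLS = ["boundary_point", "boundary_probability"]
CONVENTIONAL_COLS = ["p23mg", "p90pct", "sink_filling_rate"]
#: the full accuracy-report row set
TABLE_ROWS = PARAM_COLS + FEATURE_COLS + BOUNDARY_COLS + CONVENTIONAL_COLS

GROUPINGS = {
    "1-group": [PARAM_COLS],
    "3-group": [["p"], ["a1", "b1"], ["a2", "b2"]],
    "each-parameter": [[c] for c in PARAM_COLS],
}


# ---------------------------------------------------------------------------
# genotypes


@dataclass(frozen=True)
class GenotypeMatrix:
    """Cultivars x markers codes in {-1, 0, 1}."""

    cultivar_ids: tuple
    marker_ids: tuple
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        object.__setattr__(self, "codes", codes)
        if codes.shape != (len(self.cultivar_ids), len(self.marker_ids)):
            raise AlignmentError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.cultivar_ids)} cultivars x {len(self.marker_ids)} markers"
            )
        if not np.isin(codes, (-1, 0, 1)).all():
            raise ParameterDomainError("genotype codes must be in {-1, 0, 1}")

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivar_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def alt_allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker (heterozygotes count half)."""
        return (self.codes.astype(float) + 1.0).mean(axis=0) / 2.0

    def subset_cultivars(self, ids: Sequence) -> "GenotypeMatrix":
        index = {c: i for i, c in enumerate(self.cultivar_ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise AlignmentError(f"cultivars absent from genotype matrix: {missing}")
        rows = [index[c] for c in ids]
        return GenotypeMatrix(tuple(ids), self.marker_ids, self.codes[rows])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=list(self.cultivar_ids),
                            columns=list(self.marker_ids))


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_maf: int
    n_het: int
    n_monomorphic: int
    n_duplicate: int
    n_retained: int


def filter_markers(
    raw: GenotypeMatrix,
    maf_min: float = 0.025,
    max_het: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Standard marker QC.

    Drops markers with minor allele frequency below ``maf_min``
    (heterozygotes counted as half an alternate allele), heterozygote
    fraction at or above ``max_het``, monomorphic columns, and columns in
    complete linkage with an earlier column (identical or sign-flipped
    codes; the first occurrence is kept).
    """
    codes = raw.codes
    freq = raw.alt_allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    het = (codes == 0).mean(axis=0)
    mono = np.array([np.unique(col).size <= 1 for col in codes.T])

    keep = np.ones(raw.n_markers, dtype=bool)
    n_mono = int(mono.sum())
    keep &= ~mono
    n_maf = int((maf[keep] < maf_min).sum())
    keep &= maf >= maf_min
    n_het = int((het[keep] >= max_het).sum())
    keep &= het < max_het

    # complete-linkage removal: exact duplicates up to sign
    seen: dict[bytes, int] = {}
    n_dup = 0
    for j in np.flatnonzero(keep):
        col = codes[:, j]
        key_pos = col.astype(np.int8).tobytes()
        key_neg = (-col).astype(np.int8).tobytes()
        if key_pos in seen or key_neg in seen:
            keep[j] = False
            n_dup += 1
        else:
            seen[key_pos] = j

    if not keep.any():
        raise EmptyPanelError("marker filtering removed every marker")
    kept_idx = np.flatnonzero(keep)
    filtered = GenotypeMatrix(
        raw.cultivar_ids,
        tuple(raw.marker_ids[j] for j in kept_idx),
        codes[:, kept_idx],
    )
    report = FilterReport(
        n_input=raw.n_markers,
        n_maf=n_maf,
        n_het=n_het,
        n_monomorphic=n_mono,
        n_duplicate=n_dup,
        n_retained=filtered.n_markers,
    )
    return filtered, report


def genomic_relationship(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden (method 1) genomic relationship matrix.

    Column-centres the codes to Z and returns
    ``K = Z Z' / (2 sum_k p_k (1 - p_k))`` with ``p_k`` the
    alternate-allele frequency; symmetric and PSD by construction.
    """
    Z = geno.codes.astype(float)
    Z = Z - Z.mean(axis=0, keepdims=True)
    freq = geno.alt_allele_freq()
    denom = 2.0 * float(np.sum(freq * (1.0 - freq)))
    if denom <= 0:
        raise DegenerateSampleError("all markers monomorphic; relationship matrix undefined")
    return (Z @ Z.T) / denom


# ---------------------------------------------------------------------------
# GBLUP


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float

    @property
    def h2(self) -> float:
        total = self.sigma2_g + self.sigma2_e
        if total <= 0:
            raise DegenerateSampleError("both variance components are zero")
        return self.sigma2_g / total


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability from GBLUP variance components."""
    return vc.h2


@dataclass(frozen=True)
class GBLUPModel:
    """Fitted GBLUP: intercept, variance components and training state."""

    mu: float
    vc: VarianceComponents
    blups: np.ndarray
    fitted: np.ndarray
    _Hinv_resid: np.ndarray = field(repr=False)  # (sg2 K + se2 I)^-1 (y - mu)
    _ratio: float = field(repr=False, default=float("nan"))

    def predict_from_cross(self, K_cross: np.ndarray) -> np.ndarray:
        """BLUP for new cultivars given their kinship rows to the training set."""
        return self.mu + self.vc.sigma2_g * (K_cross @ self._Hinv_resid)


_LOG_RATIO_GRID = np.linspace(-20.0, 20.0, 81)


def _reml_profile(loglam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    """Negative restricted log-likelihood, profiled over mu and sigma_e^2.

    ``d`` are eigenvalues of K, ``yt``/``xt`` the response and intercept
    rotated into the eigenbasis; ``loglam`` is log(sigma_g^2/sigma_e^2).
    """
    lam = math.exp(loglam)
    w = 1.0 / (lam * d + 1.0)
    xwx = float(np.sum(w * xt * xt))
    xwy = float(np.sum(w * xt * yt))
    ywy = float(np.sum(w * yt * yt))
    ypy = ywy - xwy * xwy / xwx
    n = d.size
    if ypy <= 0:
        return float("inf")
    sigma2_e = ypy / (n - 1)
    ll = -0.5 * (
        (n - 1) * (math.log(2.0 * math.pi * sigma2_e) + 1.0)
        + float(np.sum(np.log(lam * d + 1.0)))
        + math.log(xwx)
    )
    return -ll


def _gblup_from_eig(
    y: np.ndarray,
    K: np.ndarray,
    d: np.ndarray,
    U: np.ndarray,
    ratio: Optional[float] = None,
) -> GBLUPModel:
    n = y.size
    x = np.ones(n)
    yt = U.T @ y
    xt = U.T @ x
    if ratio is None:
        if float(np.var(y)) <= 0:
            ratio = math.exp(_LOG_RATIO_GRID[0])
        else:
            vals = np.array([_reml_profile(ll, d, yt, xt) for ll in _LOG_RATIO_GRID])
            i = int(np.argmin(vals))
            lo = _LOG_RATIO_GRID[max(i - 1, 0)]
            hi = _LOG_RATIO_GRID[min(i + 1, _LOG_RATIO_GRID.size - 1)]
            res = optimize.minimize_scalar(
                _reml_profile, bounds=(lo, hi), args=(d, yt, xt),
                method="bounded", options={"xatol": 1e-10},
            )
            ratio = math.exp(float(res.x))
    lam = float(ratio)
    w = 1.0 / (lam * d + 1.0)
    xwx = float(np.sum(w * xt * xt))
    xwy = float(np.sum(w * xt * yt))
    mu = xwy / xwx
    resid_t = yt - mu * xt
    ypy = float(np.sum(w * resid_t * resid_t))
    sigma2_e = ypy / (n - 1)
    sigma2_g = lam * sigma2_e
    # (sg2 K + se2 I)^-1 (y - mu) = U diag(1/(sg2 d + se2)) U' (y - mu)
    denom_eig = sigma2_g * d + sigma2_e
    denom_eig = np.where(denom_eig <= 0, np.finfo(float).tiny, denom_eig)
    hinv_resid = U @ (resid_t / denom_eig)
    blups = sigma2_g * (K @ hinv_resid)
    return GBLUPModel(
        mu=mu,
        vc=VarianceComponents(sigma2_g=sigma2_g, sigma2_e=sigma2_e),
        blups=blups,
        fitted=mu + blups,
        _Hinv_resid=hinv_resid,
        _ratio=lam,
    )


def gblup_fit(y, K: np.ndarray, *, ratio: Optional[float] = None) -> GBLUPModel:
    """Fit GBLUP by REML (spectral decomposition of K).

    ``ratio`` fixes the variance ratio sigma_g^2/sigma_e^2 instead of
    estimating it (useful for closed-form checks).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ParameterDomainError("trait values must be finite")
    K = np.asarray(K, dtype=float)
    if K.shape != (y.size, y.size):
        raise AlignmentError(f"K shape {K.shape} does not match {y.size} cultivars")
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    return _gblup_from_eig(y, K, d, U, ratio=ratio)


def loo_gblup(Y, K: np.ndarray) -> np.ndarray:
    """Leave-one-out GBLUP predictions for one or more traits.

    Each fold re-estimates the intercept and variance components on the
    remaining cultivars (the held-out phenotype enters nothing) and
    predicts the held-out cultivar from its kinship row. ``Y`` may be a
    vector or an (n, t) matrix sharing the per-fold decomposition.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, t = Y.shape
    if n < 3:
        raise DegenerateSampleError("need >= 3 cultivars for leave-one-out")
    preds = np.empty_like(Y)
    idx = np.arange(n)
    for l in range(n):
        tr = idx != l
        K_tt = K[np.ix_(tr, tr)]
        d, U = np.linalg.eigh(K_tt)
        d = np.clip(d, 0.0, None)
        K_cross = K[l, tr]
        for j in range(t):
            model = _gblup_from_eig(Y[tr, j], K_tt, d, U)
            preds[l, j] = model.predict_from_cross(K_cross[None, :])[0]
    return preds[:, 0] if squeeze else preds


# ---------------------------------------------------------------------------
# PLS (NIPALS, multi-response)


@dataclass(frozen=True)
class PLSModel:
    """NIPALS PLS2 fit with per-component-count coefficients."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # (m, A) X weights
    P: np.ndarray  # (m, A) X loadings
    Q: np.ndarray  # (t, A) Y loadings
    n_components: int

    def coef(self, n_components: Optional[int] = None) -> np.ndarray:
        """(m, t) coefficient matrix using the first ``n_components`` scores."""
        k = self.n_components if n_components is None else n_components
        if not 1 <= k <= self.n_components:
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        W, P, Q = self.W[:, :k], self.P[:, :k], self.Q[:, :k]
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, X: np.ndarray, n_components: Optional[int] = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef(n_components) + self.y_mean


def pls_fit(
    X,
    Y,
    n_components: int,
    *,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> PLSModel:
    """Multi-response PLS regression by NIPALS.

    Predictors and responses are centred (not scaled). Successive score
    vectors ``t = X w`` maximise covariance with the response block and
    are mutually orthogonal; both blocks are deflated by the X-scores.
    Deterministic for a fixed input order. If the X block is exhausted
    before ``n_components`` (rank deficiency) the component count is
    reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise AlignmentError("X and Y must have the same number of rows")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    n, m = Xc.shape
    t_dim = Yc.shape[1]
    A = min(n_components, n - 1, m)
    W = np.zeros((m, A))
    P = np.zeros((m, A))
    Q = np.zeros((t_dim, A))
    x_norm0 = float(np.sum(Xc * Xc))
    a = 0
    for a in range(A):
        if float(np.sum(Xc * Xc)) <= max(x_norm0, 1.0) * 1e-14:
            break
        # start from the response column with the largest remaining variance
        u = Yc[:, int(np.argmax(np.sum(Yc * Yc, axis=0)))].copy()
        if float(u @ u) <= 0:
            break
        w = np.zeros(m)
        for _ in range(max_iter):
            w_new = Xc.T @ u
            norm = float(np.linalg.norm(w_new))
            if norm <= 0:
                break
            w_new /= norm
            t_vec = Xc @ w_new
            tt = float(t_vec @ t_vec)
            if tt <= 0:
                break
            q = Yc.T @ t_vec / tt
            u_new = Yc @ q / float(q @ q) if float(q @ q) > 0 else u
            if float(np.linalg.norm(w_new - w)) < tol:
                w = w_new
                u = u_new
                break
            w = w_new
            u = u_new
        t_vec = Xc @ w
        tt = float(t_vec @ t_vec)
        if tt <= 0:
            break
        p_load = Xc.T @ t_vec / tt
        q_load = Yc.T @ t_vec / tt
        W[:, a] = w
        P[:, a] = p_load
        Q[:, a] = q_load
        Xc = Xc - np.outer(t_vec, p_load)
        Yc = Yc - np.outer(t_vec, q_load)
    else:
        a = A
    n_eff = a if a > 0 else 1
    if n_eff < n_components:
        warnings.warn(
            f"X block exhausted after {n_eff} components (requested {n_components})",
            stacklevel=2,
        )
        W, P, Q = W[:, :n_eff], P[:, :n_eff], Q[:, :n_eff]
    return PLSModel(x_mean=x_mean, y_mean=y_mean, W=W, P=P, Q=Q, n_components=W.shape[1])


def loo_cv(predict_fold: Callable[[np.ndarray, int], np.ndarray], n: int) -> list:
    """Generic leave-one-out loop.

    ``predict_fold(train_idx, test_idx)`` must fit on the training
    cultivars only and return the held-out prediction. Returns one entry
    per cultivar, in input order; fold failures are recorded as None.
    """
    if n < 3:
        raise DegenerateSampleError("need >= 3 cultivars for leave-one-out")
    out = []
    idx = np.arange(n)
    for l in range(n):
        try:
            out.append(predict_fold(idx[idx != l], l))
        except (DegenerateSampleError, ParameterDomainError) as exc:
            warnings.warn(f"LOO fold {l} failed: {exc}", stacklevel=2)
            out.append(None)
    return out


def loo_pls(X, Y, n_components: int) -> np.ndarray:
    """Leave-one-out PLS predictions (refit per fold; centring included)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n = X.shape[0]
    preds = np.empty_like(Y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for l in range(n):
            tr = np.arange(n) != l
            model = pls_fit(X[tr], Y[tr], n_components)
            preds[l] = model.predict(X[l][None, :])
    return preds[:, 0] if squeeze else preds


def _loo_pls_all_ncomp(X: np.ndarray, Y: np.ndarray, max_components: int) -> np.ndarray:
    """(max_components, n, t) LOO predictions for every component count.

    One fit per fold at the maximal count serves every smaller count.
    """
    n, t = Y.shape
    out = np.empty((max_components, n, t))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for l in range(n):
            tr = np.arange(n) != l
            model = pls_fit(X[tr], Y[tr], max_components)
            for k in range(1, max_components + 1):
                out[k - 1, l] = model.predict(X[l][None, :], min(k, model.n_components))
    return out


def _sanitize_params_row(row: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip a predicted (p, a1, b1, a2, b2) row into the valid domain.

    Linear predictors can leave the parameter space; shapes are floored
    just above 1/2 (where the L2 self-energy diverges) and p clipped to
    [0, 1]. Returns the row and whether clipping occurred.
    """
    p, a1, b1, a2, b2 = row
    clipped = False
    p2 = min(max(p, 0.0), 1.0)
    a1c, a2c = max(a1, 0.501), max(a2, 0.501)
    b1c, b2c = max(b1, 1e-6), max(b2, 1e-6)
    if (p2, a1c, b1c, a2c, b2c) != (p, a1, b1, a2, b2):
        clipped = True
    return np.array([p2, a1c, b1c, a2c, b2c]), clipped


def _params_frame_to_set(observed: pd.DataFrame, predicted: pd.DataFrame) -> tuple[PredictionSet, int]:
    n_clipped = 0
    pred = predicted.copy()
    rows = []
    for _, row in pred[PARAM_COLS].iterrows():
        fixed, clipped = _sanitize_params_row(row.to_numpy())
        n_clipped += clipped
        rows.append(fixed)
    pred.loc[:, PARAM_COLS] = np.array(rows)
    return PredictionSet.from_tables(observed[PARAM_COLS], pred[PARAM_COLS]), n_clipped


def select_ncomp(
    X,
    observed_params: pd.DataFrame,
    group_cols: Sequence[str],
    max_components: int = 30,
) -> int:
    """Choose the PLS component count for one grouped model.

    Criterion: shape Q^2 of leave-one-out predictions, with the model's
    predicted columns substituted into the observed parameter table (the
    remaining parameters stay at their observed values, isolating this
    model's contribution). Ties break toward fewer components.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    max_eff = max(1, min(max_components, n - 2, X.shape[1]))
    Y = observed_params[list(group_cols)].to_numpy()
    preds = _loo_pls_all_ncomp(X, Y, max_eff)
    best_k, best_q2 = 1, -np.inf
    for k in range(1, max_eff + 1):
        pred_tab = observed_params[PARAM_COLS].copy()
        pred_tab.loc[:, list(group_cols)] = preds[k - 1]
        pset, _ = _params_frame_to_set(observed_params, pred_tab)
        q2 = q2_shape(pset)
        if q2 > best_q2 + 1e-12:
            best_q2, best_k = q2, k
    return best_k


# ---------------------------------------------------------------------------
# experiment runner


@dataclass(frozen=True)
class PredictionScheme:
    """One prediction configuration."""

    name: str
    method: str  # "GBLUP" or "PLS"
    grouping: Optional[str] = None  # PLS only


SCHEMES = {
    "gblup": PredictionScheme("gblup", "GBLUP"),
    "pls1": PredictionScheme("pls1", "PLS", "1-group"),
    "pls3": PredictionScheme("pls3", "PLS", "3-group"),
    "plsE": PredictionScheme("plsE", "PLS", "each-parameter"),
}


@dataclass
class CVResult:
    """Per-scheme fitting and leave-one-out prediction report."""

    scheme: PredictionScheme
    fitted_params: pd.DataFrame
    predicted_params: pd.DataFrame
    accuracies: pd.DataFrame  # rows TABLE_ROWS, cols fitting/prediction (+direct)
    press_fit: float
    q2_fit: float
    press_pred: float
    q2_pred: float
    variance_components: dict = field(default_factory=dict)
    heritabilities: dict = field(default_factory=dict)
    ncomp: dict = field(default_factory=dict)
    n_clipped: int = 0

    def to_dict(self) -> dict:
        acc = self.accuracies.where(pd.notna(self.accuracies), None)
        return {
            "scheme": self.scheme.name,
            "method": self.scheme.method,
            "grouping": self.scheme.grouping,
            "accuracies_fitting": acc["fitting"].to_dict(),
            "accuracies_prediction": acc["prediction"].to_dict(),
            "accuracies_fitting_direct": acc["fitting_direct"].to_dict()
            if "fitting_direct" in acc else {},
            "accuracies_prediction_direct": acc["prediction_direct"].to_dict()
            if "prediction_direct" in acc else {},
            "press": {"fitting": self.press_fit, "prediction": self.press_pred},
            "q2": {"fitting": self.q2_fit, "prediction": self.q2_pred},
            "variance_components": {
                k: {"sigma2_g": v.sigma2_g, "sigma2_e": v.sigma2_e, "h2": v.h2}
                for k, v in self.variance_components.items()
            },
            "heritabilities": dict(self.heritabilities),
            "n_components": dict(self.ncomp),
            "n_clipped_predictions": self.n_clipped,
        }


def _derived_traits_from_params(params_df: pd.DataFrame, *,
                                skewness_convention: str = "scale") -> pd.DataFrame:
    """Feature values, boundary traits and model-based conventional traits.

    Conventional traits are the mixture-model analogues: p23mg is the
    mixture CDF at 23 mg, p90pct the CDF at 0.9 x the mixture 95th
    percentile, and the sink-filling rate the mixture mean over that
    percentile.
    """
    rows = {}
    for cid, row in params_df[PARAM_COLS].iterrows():
        arr, _ = _sanitize_params_row(row.to_numpy())
        m = MixtureParams.from_values(*arr)
        fv = feature_values(m, skewness_convention=skewness_convention)
        ba = boundary_analysis(m)
        q95 = mixture_quantile(m, 0.95)
        rows[cid] = {
            "mode1": fv.mode1,
            "skewness1": fv.skewness1,
            "mu2": fv.mu2,
            "var2": fv.var2,
            "boundary_point": ba.boundary_point if ba.bimodal else np.nan,
            "boundary_probability": ba.boundary_probability if ba.bimodal else np.nan,
            "p23mg": float(mixture_cdf(m, 23.0)),
            "p90pct": float(mixture_cdf(m, 0.9 * q95)),
            "sink_filling_rate": m.mean / q95,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[params_df.index]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return float("nan")
    a, b = a[mask], b[mask]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _evaluate_predictions(
    observed_params: pd.DataFrame,
    fitted_params: pd.DataFrame,
    predicted_params: pd.DataFrame,
    observed_traits: pd.DataFrame,
    *,
    skewness_convention: str = "scale",
) -> tuple[pd.DataFrame, float, float, float, float, int]:
    """Accuracy table plus PRESS/Q^2 for fitted and LOO-predicted tables."""
    fit_traits = _derived_traits_from_params(fitted_params,
                                             skewness_convention=skewness_convention)
    pred_traits = _derived_traits_from_params(predicted_params,
                                              skewness_convention=skewness_convention)
    acc = pd.DataFrame(index=TABLE_ROWS, columns=["fitting", "prediction"], dtype=float)
    for col in PARAM_COLS:
        obs = observed_params[col].to_numpy()
        acc.loc[col, "fitting"] = _pearson(obs, fitted_params[col].to_numpy())
        acc.loc[col, "prediction"] = _pearson(obs, predicted_params[col].to_numpy())
    for col in FEATURE_COLS + BOUNDARY_COLS + CONVENTIONAL_COLS:
        obs = observed_traits[col].to_numpy()
        acc.loc[col, "fitting"] = _pearson(obs, fit_traits[col].to_numpy())
        acc.loc[col, "prediction"] = _pearson(obs, pred_traits[col].to_numpy())
    pset_fit, nclip_f = _params_frame_to_set(observed_params, fitted_params)
    pset_pred, nclip_p = _params_frame_to_set(observed_params, predicted_params)
    return (
        acc,
        press(pset_fit),
        q2_shape(pset_fit),
        press(pset_pred),
        q2_shape(pset_pred),
        nclip_f + nclip_p,
    )


def run_prediction_experiment(
    geno: GenotypeMatrix,
    params_df: pd.DataFrame,
    schemes: Sequence[str] = ("gblup", "pls1", "pls3", "plsE"),
    *,
    observed_traits: Optional[pd.DataFrame] = None,
    max_ncomp: int = 30,
    select_per_fold: bool = True,
    skewness_convention: str = "scale",
    direct_traits: bool = True,
) -> dict[str, CVResult]:
    """Fit and cross-validate every requested scheme.

    ``params_df`` is cultivar-indexed with columns p, a1, b1, a2, b2
    (the per-cultivar mixture fits). ``observed_traits``, if given, must
    carry the derived-trait columns (feature values, boundary traits,
    conventional traits) measured from the data; otherwise the
    model-based analogues computed from the observed parameters are
    used. ``select_per_fold`` re-selects PLS component counts inside
    every LOO fold from the training cultivars only; with ``False`` the
    count is selected once on the full set (the literal historical
    protocol, which lets fold selection see the held-out phenotype).
    """
    shared = [c for c in geno.cultivar_ids if c in set(params_df.index)]
    if len(shared) < 10:
        raise AlignmentError(
            f"only {len(shared)} cultivars shared between genotypes and fits (need >= 10); "
            f"genotype-only: {sorted(set(geno.cultivar_ids) - set(params_df.index))[:5]}, "
            f"fit-only: {sorted(set(params_df.index) - set(geno.cultivar_ids))[:5]}"
        )
    geno = geno.subset_cultivars(shared)
    params_df = params_df.loc[shared]
    if observed_traits is None:
        observed_traits = _derived_traits_from_params(
            params_df, skewness_convention=skewness_convention)
    else:
        missing = set(FEATURE_COLS + BOUNDARY_COLS + CONVENTIONAL_COLS) - set(observed_traits.columns)
        if missing:
            raise AlignmentError(f"observed_traits missing columns: {sorted(missing)}")
        observed_traits = observed_traits.loc[shared]

    K = genomic_relationship(geno)
    X = geno.codes.astype(float)
    n = len(shared)
    results: dict[str, CVResult] = {}

    for name in schemes:
        scheme = SCHEMES[name]
        if scheme.method == "GBLUP":
            results[name] = _run_gblup_scheme(
                scheme, K, params_df, observed_traits, skewness_convention,
                direct_traits=direct_traits,
            )
        else:
            results[name] = _run_pls_scheme(
                scheme, X, params_df, observed_traits, max_ncomp,
                select_per_fold, skewness_convention,
            )
    return results


def _run_gblup_scheme(scheme, K, params_df, observed_traits, skewness_convention,
                      *, direct_traits: bool) -> CVResult:
    ids = params_df.index
    Y = params_df[PARAM_COLS].to_numpy()
    fitted = np.empty_like(Y)
    vcs = {}
    for j, col in enumerate(PARAM_COLS):
        model = gblup_fit(Y[:, j], K)
        fitted[:, j] = model.fitted
        vcs[col] = model.vc
    predicted = loo_gblup(Y, K)
    fitted_df = pd.DataFrame(fitted, index=ids, columns=PARAM_COLS)
    predicted_df = pd.DataFrame(predicted, index=ids, columns=PARAM_COLS)
    acc, press_f, q2_f, press_p, q2_p, nclip = _evaluate_predictions(
        params_df, fitted_df, predicted_df, observed_traits,
        skewness_convention=skewness_convention,
    )
    if direct_traits:
        # direct route: a GBLUP model per derived trait itself
        acc["fitting_direct"] = np.nan
        acc["prediction_direct"] = np.nan
        trait_cols = [c for c in FEATURE_COLS + BOUNDARY_COLS + CONVENTIONAL_COLS
                      if np.isfinite(observed_traits[c]).sum() == len(ids)]
        if trait_cols:
            T = observed_traits[trait_cols].to_numpy()
            t_pred = loo_gblup(T, K)
            for j, col in enumerate(trait_cols):
                model = gblup_fit(T[:, j], K)
                acc.loc[col, "fitting_direct"] = _pearson(T[:, j], model.fitted)
                acc.loc[col, "prediction_direct"] = _pearson(T[:, j], t_pred[:, j])
                vcs[col] = model.vc
    return CVResult(
        scheme=scheme,
        fitted_params=fitted_df,
        predicted_params=predicted_df,
        accuracies=acc,
        press_fit=press_f,
        q2_fit=q2_f,
        press_pred=press_p,
        q2_pred=q2_p,
        variance_components=vcs,
        heritabilities={k: v.h2 for k, v in vcs.items()},
        n_clipped=nclip,
    )


def _run_pls_scheme(scheme, X, params_df, observed_traits, max_ncomp,
                    select_per_fold, skewness_convention) -> CVResult:
    ids = params_df.index
    n = len(ids)
    groups = GROUPINGS[scheme.grouping]
    fitted_df = params_df[PARAM_COLS].copy()
    predicted_df = params_df[PARAM_COLS].copy()
    ncomp_report: dict[str, object] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for group in groups:
            key = "+".join(group)
            Y = params_df[group].to_numpy()
            k_global = select_ncomp(X, params_df, group, max_components=max_ncomp)
            model = pls_fit(X, Y, k_global)
            fitted_df.loc[:, group] = model.predict(X)
            if select_per_fold:
                fold_ks = []
                preds = np.empty_like(Y)
                for l in range(n):
                    tr = np.arange(n) != l
                    k_fold = select_ncomp(
                        X[tr], params_df.iloc[tr], group, max_components=max_ncomp)
                    fold_ks.append(k_fold)
                    fold_model = pls_fit(X[tr], Y[tr], k_fold)
                    preds[l] = fold_model.predict(X[l][None, :])
                predicted_df.loc[:, group] = preds
                ncomp_report[key] = {"global": k_global, "per_fold": fold_ks}
            else:
                predicted_df.loc[:, group] = loo_pls(X, Y, k_global)
                ncomp_report[key] = {"global": k_global}
    acc, press_f, q2_f, press_p, q2_p, nclip = _evaluate_predictions(
        params_df, fitted_df, predicted_df, observed_traits,
        skewness_convention=skewness_convention,
    )
    return CVResult(
        scheme=scheme,
        fitted_params=fitted_df,
        predicted_params=predicted_df,
        accuracies=acc,
        press_fit=press_f,
        q2_fit=q2_f,
        press_pred=press_p,
        q2_pred=q2_p,
        ncomp=ncomp_report,
        n_clipped=nclip,
    )
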