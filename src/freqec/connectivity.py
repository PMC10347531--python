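"""Multivariate (conditional) Granger causality on component time courses.

A vector autoregressive (VAR) model of order p is fit to the component set
S(t) by per-target ordinary least squares; the directed influence j -> k is
the Geweke log-variance-ratio

    GC(j -> k) = ln( sigma^2_reduced(j, k) / sigma^2_full(k) ),

where sigma^2_full(k) is target k's residual variance under the full model and
sigma^2_reduced(j, k) the residual variance when all lags of component j are
omitted while every other component is retained (conditional Granger
causality). The statistic is non-negative by construction (clamped at zero
against sampling noise) and invariant to per-component affine rescaling.

Under the null of no j -> k influence, T_eff * GC is asymptotically
chi-square with p degrees of freedom, which provides per-subject edge
significance with Benjamini-Hochberg control across the n(n-1) edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "VARModel",
    "ECMatrix",
    "select_order",
    "fit_var",
    "conditional_gc",
    "subject_significance",
    "network_mean_ec",
    "ec_long_frame",
]

_RIDGE = 1e-10


@dataclass
class VARModel:
    """Fitted VAR(p): s_k(t) = c_k + sum_m C_k(m) S(t-m) + R_k(t)."""

    order: int
    coefficients: np.ndarray  # (n_targets, n_sources, p)
    intercept: np.ndarray  # (n_targets,)
    residual_covariance: np.ndarray  # (n, n), MLE normalisation
    n_obs: int  # effective sample count T - p

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        sym_err = np.max(np.abs(self.residual_covariance - self.residual_covariance.T))
        if sym_err > 1e-8:
            raise ValueError("residual covariance must be symmetric")


@dataclass
class ECMatrix:
    """Directed causality strengths for one subject in one band.

    ``values[j, k]`` is the influence of component j on component k; the
    diagonal is zero. ``significance_mask`` marks FDR-surviving edges when
    `subject_significance` has been applied.
    """

    values: np.ndarray
    band_id: str = ""
    subject_id: str = ""
    significance_mask: np.ndarray | None = None
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        finite = v[np.isfinite(v)]
        if np.any(finite < 0):
            raise ValueError("entries must be non-negative (log-variance-ratio form)")
        self.values = v


def _design(S: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix [1, S(t-1), ..., S(t-p)] and targets S(t)."""
    n, T = S.shape
    T_eff = T - p
    X = np.empty((T_eff, 1 + n * p))
    X[:, 0] = 1.0
    for m in range(1, p + 1):
        X[:, 1 + (m - 1) * n : 1 + m * n] = S[:, p - m : T - m].T
    Y = S[:, p:].T
    return X, Y


def _check_length(S: np.ndarray, p: int) -> None:
    n, T = S.shape
    need = n * p + 2
    if T <= need - 1:
        raise ValueError(
            f"need more than {n * p + 1} time points for n={n}, p={p}; got {T}"
        )


def _standardize(S: np.ndarray) -> np.ndarray:
    mu = S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant component series — VAR undefined")
    return (S - mu) / sd


def fit_var(S: np.ndarray, p: int) -> VARModel:
    """Per-target OLS fit of a VAR(p) with intercept.

    Collinear predictor sets trigger a small ridge fallback with a warning.
    The residual covariance uses the MLE normalisation (divide by T_eff).
    """
    S = np.asarray(S, dtype=float)
    _check_length(S, p)
    n, T = S.shape
    X, Y = _design(S, p)
    G = X.T @ X
    C = X.T @ Y
    try:
        B = np.linalg.solve(G, C)
        if not np.all(np.isfinite(B)):
            raise np.linalg.LinAlgError
        cond = np.linalg.cond(G)
        if cond > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("collinear predictors — using ridge-regularised fit")
        lam = _RIDGE * np.trace(G) / G.shape[0] + _RIDGE
        B = np.linalg.solve(G + lam * np.eye(G.shape[0]), C)
    E = Y - X @ B
    T_eff = T - p
    Sigma = E.T @ E / T_eff
    coeffs = np.empty((n, n, p))
    for m in range(p):
        coeffs[:, :, m] = B[1 + m * n : 1 + (m + 1) * n, :].T
    return VARModel(
        order=p,
        coefficients=coeffs,
        intercept=B[0, :].copy(),
        residual_covariance=0.5 * (Sigma + Sigma.T),
        n_obs=T_eff,
    )


def select_order(S: np.ndarray, p_max: int = 5) -> int:
    """AIC order selection over p in [1, p_max], ties toward smaller p.

    AIC(p) = ln det(Sigma_p) + 2 p n^2 / T_eff with T_eff = T - p.
    """
    S = np.asarray(S, dtype=float)
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    _check_length(S, p_max)
    n, T = S.shape
    best_p, best_aic = 1, np.inf
    for p in range(1, p_max + 1):
        model = fit_var(S, p)
        sign, logdet = np.linalg.slogdet(model.residual_covariance)
        if sign <= 0:
            continue
        aic = logdet + 2.0 * p * n * n / model.n_obs
        if aic < best_aic - 1e-12:
            best_aic, best_p = aic, p
    return best_p


def conditional_gc(
    S: np.ndarray,
    p: int,
    band_id: str = "",
    subject_id: str = "",
) -> ECMatrix:
    """Pairwise-conditional Granger causality matrix from one VAR fit.

    Component series are standardised internally (the statistic is scale
    invariant). Reduced models reuse the full Gram matrix, so each omitted
    source requires only a small linear solve per target set.
    """
    S = _standardize(np.asarray(S, dtype=float))
    _check_length(S, p)
    n, T = S.shape
    X, Y = _design(S, p)
    G = X.T @ X
    C = X.T @ Y
    yty = np.einsum("ij,ij->j", Y, Y)
    lam = _RIDGE * np.trace(G) / G.shape[0] + _RIDGE
    Greg = G + lam * np.eye(G.shape[0])

    def rss(idx: np.ndarray) -> np.ndarray:
        B = np.linalg.solve(Greg[np.ix_(idx, idx)], C[idx])
        return yty - np.einsum("ij,ij->j", C[idx], B)

    all_idx = np.arange(1 + n * p)
    rss_full = rss(all_idx)
    values = np.zeros((n, n))
    invalid = np.zeros((n, n), dtype=bool)
    for j in range(n):
        drop = 1 + j + n * np.arange(p)
        keep = np.setdiff1d(all_idx, drop)
        rss_red = rss(keep)
        with np.errstate(divide="ignore", invalid="ignore"):
            gc_row = np.log(rss_red / rss_full)
        bad = ~np.isfinite(gc_row) | (rss_full <= 0)
        gc_row = np.where(bad, np.nan, np.maximum(gc_row, 0.0))
        values[j, :] = gc_row
        invalid[j, :] = bad
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(invalid, False)
    if invalid.any():
        warnings.warn(f"{int(invalid.sum())} GC entries non-finite; flagged invalid")
        values[invalid] = np.nan
    return ECMatrix(values=values, band_id=band_id, subject_id=subject_id)


def subject_significance(ec: ECMatrix, model: VARModel, alpha: float = 0.05) -> ECMatrix:
    """Per-edge asymptotic significance with Benjamini-Hochberg control.

    Under the null, T_eff * GC ~ chi-square(p). The mask marks edges whose
    BH-adjusted p-value over the n(n-1) off-diagonal edges is below ``alpha``.
    ``alpha = 0`` yields an empty mask.
    """
    from .groupstats import fdr_bh

    n = ec.values.shape[0]
    off = ~np.eye(n, dtype=bool)
    stat = model.n_obs * ec.values[off]
    p_raw = np.where(np.isfinite(stat), sstats.chi2.sf(stat, df=model.order), 1.0)
    if alpha <= 0:
        reject = np.zeros_like(p_raw, dtype=bool)
        p_adj = np.ones_like(p_raw)
    else:
        reject, p_adj = fdr_bh(p_raw, q=alpha)
    mask = np.zeros((n, n), dtype=bool)
    mask[off] = reject
    pmat = np.ones((n, n))
    pmat[off] = p_adj
    return ECMatrix(
        values=ec.values,
        band_id=ec.band_id,
        subject_id=ec.subject_id,
        significance_mask=mask,
        p_values=pmat,
    )


def network_mean_ec(
    values: np.ndarray,
    labels: dict[int, str],
    networks: tuple[str, ...] = ("DMN", "SN", "CEN"),
) -> pd.DataFrame:
    """Network-block means of a directed EC matrix.

    Block (A, B) averages values[j, k] over j in A, k in B; within-network
    blocks exclude the diagonal. Empty networks yield NaN with a warning.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if set(labels) != set(range(n)):
        raise ValueError("labels must cover every component index exactly once")
    idx = {net: [i for i in range(n) if labels[i] == net] for net in networks}
    out = np.full((len(networks), len(networks)), np.nan)
    for a, A in enumerate(networks):
        for b, B in enumerate(networks):
            ia, ib = idx[A], idx[B]
            if not ia or not ib:
                warnings.warn(f"network {A if not ia else B} has no members")
                continue
            block = v[np.ix_(ia, ib)]
            if A == B:
                m = len(ia)
                mask = ~np.eye(m, dtype=bool)
                out[a, b] = np.nanmean(block[mask]) if m > 1 else np.nan
            else:
                out[a, b] = np.nanmean(block)
    return pd.DataFrame(out, index=list(networks), columns=list(networks))


def ec_long_frame(ecs: list[ECMatrix]) -> pd.DataFrame:
    """Long-format table (subject, band, source, target, value, significant)."""
    rows = []
    for ec in ecs:
        n = ec.values.shape[0]
        for j in range(n):
            for k in range(n):
                if j == k:
                    continue
                rows.append(
                    {
                        "subject_id": ec.subject_id,
                        "band": ec.band_id,
                        "source": j,
                        "target": k,
                        "value": ec.values[j, k],
                        "significant": bool(ec.significance_mask[j, k])
                        if ec.significance_mask is not None
                        else None,
                    }
                )
    return pd.DataFrame(rows)
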