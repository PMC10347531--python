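"""Group inference: permutation tests, FDR control, symptom correlation.

Group differences in effective-connectivity metrics are assessed by label
permutation on the mean difference (patients minus controls), two-sided, with
the add-one estimator p = (1 + #{|perm| >= |obs|}) / (n_perm + 1). When the
number of distinct group relabelings is small enough, the exact tail over all
relabelings is computed instead. Benjamini-Hochberg correction is applied
within each frequency band, separately for edge-level and network-block-level
families. Symptom association uses a partial Spearman correlation controlling
for age, gender and mean framewise displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .connectivity import network_mean_ec

__all__ = [
    "permutation_test",
    "fdr_bh",
    "partial_spearman",
    "GroupAnalysisResult",
    "run_group_analysis",
]

_TIE_EPS = 1e-12


def _perm_pvalues(
    values: np.ndarray, is_a: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided permutation p-values for many variables at once.

    ``values`` is (n_subjects, m); the statistic per variable is
    mean(A) - mean(B). Returns (observed stats, p-values).
    """
    n = len(is_a)
    n_a = int(is_a.sum())
    n_b = n - n_a
    obs = values[is_a].mean(axis=0) - values[~is_a].mean(axis=0)
    total = values.sum(axis=0)
    # each row of P selects a permuted group A
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
    sum_a = np.zeros((n_perm, values.shape[1]))
    for i in range(n_perm):  # gather is memory-friendly; matmul would be n_perm x n dense
        sum_a[i] = values[order[i]].sum(axis=0)
    perm_stat = sum_a / n_a - (total[None, :] - sum_a) / n_b
    exceed = (np.abs(perm_stat) >= np.abs(obs)[None, :] - _TIE_EPS).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return obs, p


def permutation_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided permutation test of the mean difference mean(x) - mean(y).

    Labels are permuted without replacement. If the number of distinct
    relabelings C(n, n_x) does not exceed ``n_perm``, the exact tail
    probability over all relabelings is returned (identity included);
    otherwise the add-one Monte-Carlo estimator with ``seed`` is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value resolution")
    pooled = np.concatenate([x, y])
    n, n_x = len(pooled), len(x)
    obs = float(x.mean() - y.mean())
    n_comb = comb(n, n_x)
    if n_comb <= n_perm:
        csum = pooled.sum()
        count = 0
        for idx in combinations(range(n), n_x):
            sa = pooled[list(idx)].sum()
            stat = sa / n_x - (csum - sa) / (n - n_x)
            if abs(stat) >= abs(obs) - _TIE_EPS:
                count += 1
        return obs, count / n_comb
    rng = np.random.default_rng(seed)
    is_a = np.zeros(n, dtype=bool)
    is_a[:n_x] = True
    _, p = _perm_pvalues(pooled[:, None], is_a, n_perm, rng)
    return obs, float(p[0])


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection flags and adjusted p-values.

    Rejects every p(i) with rank i <= max{i : p(i) <= i q / m}; adjusted
    p-values follow the monotone cumulative-minimum construction. Empty input
    yields empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    thresh = ranked <= q * np.arange(1, m + 1) / m
    reject = np.zeros(m, dtype=bool)
    if thresh.any():
        k = int(np.max(np.where(thresh)[0]))
        reject[order[: k + 1]] = True
    return reject, p_adj


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Spearman correlation of x and y with covariates partialled out.

    Both variables are rank-transformed; the covariates (plus intercept) are
    regressed out of each rank vector and the Pearson correlation of the
    residuals is returned with its t-approximation p-value on
    n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("partial Spearman undefined for zero-variance input")
    n = len(x)
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
    if n <= k + 3:
        raise ValueError("need n > k + 3 observations")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    ex = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ey = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom == 0:
        raise ValueError("ranks fully explained by covariates")
    rho = float(np.dot(ex, ey) / denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return rho, float(p)


@dataclass
class GroupAnalysisResult:
    """Edge- and block-level group tests plus symptom correlations."""

    edges: pd.DataFrame
    blocks: pd.DataFrame
    correlations: pd.DataFrame
    networks: tuple[str, ...] = ("DMN", "SN", "CEN")

    def summary(self) -> dict:
        sig_blocks = self.blocks[self.blocks["significant"]]
        return {
            "n_significant_edges": int(self.edges["significant"].sum()),
            "n_significant_blocks": int(len(sig_blocks)),
            "significant_blocks": sig_blocks[
                ["band", "source", "target", "stat", "p_fdr"]
            ].to_dict("records"),
            "correlations": self.correlations.to_dict("records"),
        }


def _block_values(ec_array: np.ndarray, labels: dict[int, str], networks) -> np.ndarray:
    """Per-subject 3x3 block means, vectorised over subjects -> (n_subj, 9)."""
    n_subj = ec_array.shape[0]
    out = np.empty((n_subj, len(networks) ** 2))
    for s in range(n_subj):
        out[s] = network_mean_ec(ec_array[s], labels, networks).to_numpy().ravel()
    return out


def run_group_analysis(
    ec_by_band: dict[str, np.ndarray],
    metadata: pd.DataFrame,
    labels: dict[int, str],
    q: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
    networks: tuple[str, ...] = ("DMN", "SN", "CEN"),
    symptom_col: str = "symptom_score",
) -> GroupAnalysisResult:
    """Band-wise group comparison of EC with FDR control and symptom correlation.

    ``ec_by_band`` maps a band name to a (n_subjects, n, n) stack of EC
    matrices in metadata row order. Per band, edge-level permutation tests are
    BH-corrected across the n(n-1) edges and block-level tests across the nine
    network blocks. Network blocks that survive FDR in any band are then
    correlated (partial Spearman, controlling age, gender, mean FD) with the
    patients' symptom scores, BH-corrected across the tested correlations.
    Fully deterministic given the data and ``seed``.
    """
    is_patient = (metadata["group"] == "patient").to_numpy()
    rng = np.random.default_rng(seed)
    n_names = list(networks)

    edge_rows, block_rows = [], []
    block_store: dict[str, np.ndarray] = {}
    for band, ec in ec_by_band.items():
        n_subj, n, _ = ec.shape
        if n_subj != len(metadata):
            raise ValueError(f"band {band}: subject count mismatch with metadata")
        off = ~np.eye(n, dtype=bool)
        src, tgt = np.where(off)
        edge_vals = np.nan_to_num(ec[:, src, tgt])
        stat, p = _perm_pvalues(edge_vals, is_patient, n_perm, rng)
        reject, p_adj = fdr_bh(p, q)
        for i in range(len(src)):
            edge_rows.append(
                {
                    "band": band,
                    "level": "edge",
                    "source": int(src[i]),
                    "target": int(tgt[i]),
                    "stat": stat[i],
                    "p_raw": p[i],
                    "p_fdr": p_adj[i],
                    "significant": bool(reject[i]),
                }
            )
        bvals = _block_values(ec, labels, networks)
        block_store[band] = bvals
        bstat, bp = _perm_pvalues(bvals, is_patient, n_perm, rng)
        breject, bp_adj = fdr_bh(bp, q)
        for i in range(bvals.shape[1]):
            block_rows.append(
                {
                    "band": band,
                    "level": "block",
                    "source": n_names[i // len(networks)],
                    "target": n_names[i % len(networks)],
                    "stat": bstat[i],
                    "p_raw": bp[i],
                    "p_fdr": bp_adj[i],
                    "significant": bool(breject[i]),
                }
            )

    edges = pd.DataFrame(edge_rows)
    blocks = pd.DataFrame(block_rows)

    corr_rows = []
    have_symptoms = (
        symptom_col in metadata.columns
        and metadata.loc[is_patient, symptom_col].notna().all()
        and is_patient.sum() > 6
    )
    sig_blocks = blocks[blocks["significant"]]
    if not have_symptoms and len(sig_blocks):
        warnings.warn("symptom scores missing — correlation step skipped")
    elif have_symptoms:
        cov_cols = [c for c in ("age", "gender", "mean_fd") if c in metadata.columns]
        cov = None
        if cov_cols:
            C = metadata.loc[is_patient, cov_cols].copy()
            if "gender" in cov_cols and C["gender"].dtype == object:
                C["gender"] = (C["gender"] == "F").astype(float)
            cov = C.to_numpy(float)
        scores = metadata.loc[is_patient, symptom_col].to_numpy(float)
        tested = []
        for _, row in sig_blocks.iterrows():
            bvals = block_store[row["band"]]
            col = n_names.index(row["source"]) * len(networks) + n_names.index(row["target"])
            x = bvals[is_patient, col]
            try:
                rho, p = partial_spearman(x, scores, cov)
            except ValueError:
                continue
            tested.append((row["band"], row["source"], row["target"], rho, p))
        if tested:
            rej, p_adj = fdr_bh(np.array([t[4] for t in tested]), q)
            for (band, s, t_, rho, p), pa, rj in zip(tested, p_adj, rej):
                corr_rows.append(
                    {
                        "band": band,
                        "source": s,
                        "target": t_,
                        "rho": rho,
                        "p_raw": p,
                        "p_fdr": pa,
                        "significant": bool(rj),
                    }
                )
    correlations = pd.DataFrame(
        corr_rows,
        columns=["band", "source", "target", "rho", "p_raw", "p_fdr", "significant"],
    )
    return GroupAnalysisResult(
        edges=edges, blocks=blocks, correlations=correlations, networks=networks
    )
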