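"""Post-processing of component time courses before connectivity analysis.

The cleaning chain is fixed: polynomial detrending (up to cubic), nuisance
regression (e.g., six motion parameters and their first differences),
despiking of robust outliers, and a zero-phase low-pass at 0.15 Hz. The order
matters — nuisance regressors are fit to detrended data, spikes are judged
after slow trends and nuisance structure are gone, and filtering last avoids
smearing spikes — so `postprocess` applies the steps in exactly this order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "NuisanceSet",
    "detrend_poly",
    "regress_nuisance",
    "despike",
    "lowpass",
    "postprocess",
]


@dataclass
class NuisanceSet:
    """Time x k nuisance regressor matrix with column labels."""

    regressors: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a time x k matrix")
        if not self.labels:
            self.labels = [f"reg{i}" for i in range(self.regressors.shape[1])]


def detrend_poly(series: np.ndarray, max_order: int = 3) -> np.ndarray:
    """Remove the least-squares polynomial fit up to ``max_order``.

    ``max_order=0`` demeans. The residual is orthogonal to the polynomial
    basis. A constant series comes back as zeros.
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= max_order + 1:
        raise ValueError("series must be longer than max_order + 1")
    t = np.linspace(-1.0, 1.0, len(x))
    # Legendre-like Vandermonde on [-1, 1] keeps the fit well conditioned
    basis = np.polynomial.legendre.legvander(t, max_order)
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ coef


def regress_nuisance(series: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """OLS residual of ``series`` on the demeaned nuisance set plus intercept.

    Rank-deficient regressor matrices are repaired by dropping the offending
    columns (detected by pivoted QR) with a warning.
    """
    x = np.asarray(series, dtype=float)
    R = nuisance.regressors
    if R.shape[0] != len(x):
        raise ValueError("nuisance regressors must match the series length")
    R = R - R.mean(axis=0)
    # drop near-collinear columns
    q, r, piv = _pivoted_qr(R)
    diag = np.abs(np.diag(r))
    tol = max(R.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 1.0)
    rank = int(np.sum(diag > max(tol, 1e-12)))
    if rank < R.shape[1]:
        dropped = sorted(piv[rank:])
        names = [nuisance.labels[i] for i in dropped]
        warnings.warn(f"dropping rank-deficient nuisance columns: {names}")
        R = R[:, sorted(piv[:rank])]
    X = np.column_stack([np.ones(len(x)), R])
    coef, *_ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ coef


def _pivoted_qr(A: np.ndarray):
    from scipy.linalg import qr

    if A.shape[1] == 0:
        return None, np.zeros((0, 0)), np.array([], dtype=int)
    q, r, piv = qr(A, mode="economic", pivoting=True)
    return q, r, piv


def despike(series: np.ndarray, z_thresh: float = 4.0) -> tuple[np.ndarray, int]:
    """Replace robust outliers by cubic interpolation from clean neighbours.

    Outliers are samples whose median/MAD z-score exceeds ``z_thresh``.
    Returns the cleaned series and the number of replaced samples. When more
    than 20% of samples are flagged a warning is issued but despiking still
    proceeds.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("series must have at least 10 samples")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = mad / 0.6744897501960817 if mad > 0 else np.std(x)
    if scale == 0:
        return x.copy(), 0
    z = np.abs(x - med) / scale
    bad = z > z_thresh
    n_bad = int(bad.sum())
    if n_bad == 0:
        return x.copy(), 0
    if n_bad > 0.2 * len(x):
        warnings.warn(f"{n_bad}/{len(x)} samples flagged as spikes (> 20%)")
    good = ~bad
    t = np.arange(len(x), dtype=float)
    out = x.copy()
    if good.sum() >= 4:
        interp = CubicSpline(t[good], x[good])
        out[bad] = interp(t[bad])
    else:
        out[bad] = np.interp(t[bad], t[good], x[good])
    return out, n_bad


def lowpass(series: np.ndarray, cutoff: float, sampling_interval: float) -> np.ndarray:
    """Zero-phase ideal (frequency-domain) low-pass.

    The series is mirror-extended (even extension) to suppress wrap-around
    leakage, transformed, components above ``cutoff`` zeroed, and inverted.
    The ideal response is exactly zero-phase, leaves the passband untouched,
    attenuates the stopband completely, and — unlike any finite-order IIR
    design — is exactly idempotent, which keeps the cleaning chain stable
    under reapplication. Rejects cutoffs at or above Nyquist.
    """
    x = np.asarray(series, dtype=float)
    nyq = 0.5 / sampling_interval
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    n = len(x)
    ext = np.concatenate([x, x[::-1]])
    spec = np.fft.rfft(ext)
    freqs = np.fft.rfftfreq(2 * n, d=sampling_interval)
    spec[freqs > cutoff] = 0.0
    return np.fft.irfft(spec, 2 * n)[:n]


def postprocess(
    series: np.ndarray,
    sampling_interval: float,
    nuisance: NuisanceSet | None = None,
    detrend_order: int = 3,
    despike_z: float = 4.0,
    lowpass_cutoff: float | None = 0.15,
) -> tuple[np.ndarray, dict]:
    """Fixed-order cleaning chain: detrend -> nuisance -> despike -> low-pass.

    ``lowpass_cutoff=None`` skips the filter (used when a band-specific
    decomposition follows and applies its own band limits). Returns the
    cleaned series and a small log dict (steps applied, spike count).
    """
    x = detrend_poly(series, detrend_order)
    log: dict = {"detrend_order": detrend_order}
    if nuisance is not None:
        x = regress_nuisance(x, nuisance)
        log["nuisance_columns"] = len(nuisance.labels)
    x, n_spikes = despike(x, despike_z)
    log["n_spikes_replaced"] = n_spikes
    if lowpass_cutoff is not None:
        x = lowpass(x, lowpass_cutoff, sampling_interval)
        # discarding stopband noise perturbs the polynomial projection; re-project
        # onto the detrended subspace so the chain is idempotent
        x = detrend_poly(x, detrend_order)
        log["lowpass_cutoff_hz"] = lowpass_cutoff
    return x, log
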