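"""Empirical mode decomposition and frequency-band derivation.

This module provides the data-driven band machinery: classic EMD (Huang-style
sifting with cubic-spline envelopes and mirrored boundary extrema), the
complete ensemble EMD with adaptive noise (CEEMDAN, Torres-style stage-wise
noise), the Hilbert weighted frequency (HWF) summarising the mean oscillation
frequency of an intrinsic mode function, and the derivation of frequencies of
interest (FOIs) as confidence intervals of per-order HWF distributions.

Resting-state BOLD component signals sampled at TR = 2 s occupy 0-0.25 Hz;
their first IMF orders form an approximately dyadic filter bank, which is the
property the FOI construction exploits: each IMF order's pooled HWF
distribution defines one band. The conventional low-frequency band
(0.01-0.08 Hz) is carried alongside as a fixed reference band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from ._filters import zero_phase_bandpass

logger = logging.getLogger(__name__)

__all__ = [
    "IMFSet",
    "FOIBand",
    "FOIBandSet",
    "ConstantSignalError",
    "emd",
    "ceemdan",
    "hilbert_weighted_frequency",
    "build_hwf_table",
    "derive_fois",
    "extract_band_signal",
    "CONVENTIONAL_BAND",
]

#: conventional low-frequency band of resting-state analyses, Hz
CONVENTIONAL_BAND = (0.01, 0.08)


class ConstantSignalError(ValueError):
    """Raised when an operation is undefined on a (near-)constant series."""


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the monotonic residue.

    ``imfs[0]`` is the highest-frequency mode. ``sum(imfs) + residue``
    reconstructs the analysed signal exactly (the residue is defined as the
    remainder), so completeness is structural.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        for imf in self.imfs:
            if len(imf) != self.source_length:
                raise ValueError("all IMFs must share the source length")
        if len(self.residue) != self.source_length:
            raise ValueError("residue must share the source length")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass(frozen=True)
class FOIBand:
    """One frequency interval. ``imf_order`` is None for the fixed band."""

    low: float
    high: float
    imf_order: int | None = None
    ci_level: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"band low {self.low} exceeds high {self.high}")
        if self.ci_level is not None and not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class FOIBandSet:
    """Data-driven bands in descending frequency order plus the fixed band."""

    bands: list[FOIBand]
    conventional: FOIBand = field(
        default_factory=lambda: FOIBand(*CONVENTIONAL_BAND, name="FOI-N")
    )

    def all_bands(self) -> list[FOIBand]:
        """Fixed conventional band first, then data-driven bands high to low."""
        return [self.conventional, *self.bands]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": b.name,
                "low_hz": b.low,
                "high_hz": b.high,
                "imf_order": b.imf_order,
                "ci_level": b.ci_level,
            }
            for b in self.all_bands()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EMD internals
# ---------------------------------------------------------------------------


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior maxima/minima indices; plateaus resolved to a single extremum."""
    dx = np.diff(x)
    s = np.sign(dx)
    nz = s != 0
    if not nz.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    # carry the previous non-zero sign across flat runs
    idx = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    s = s[idx]
    ds = np.diff(s)
    maxima = np.where(ds < 0)[0] + 1
    minima = np.where(ds > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, boundaries handled by mirroring
    up to two extrema beyond each end of the series."""
    n = len(x)
    t = ext.astype(float)
    v = x[ext]
    k = min(2, len(ext))
    lt = -t[:k][::-1]
    lv = v[:k][::-1]
    rt = 2.0 * (n - 1) - t[-k:][::-1]
    rv = v[-k:][::-1]
    tt = np.concatenate([lt, t, rt])
    vv = np.concatenate([lv, v, rv])
    # mirrored knots can coincide with boundary extrema at the ends
    tt, uniq = np.unique(tt, return_index=True)
    vv = vv[uniq]
    grid = np.arange(n, dtype=float)
    if len(tt) < 4:
        return np.interp(grid, tt, vv)
    return CubicSpline(tt, vv)(grid)


def _imf_criterion_ok(h: np.ndarray) -> bool:
    maxima, minima = _extrema_indices(h)
    zc = int(np.sum(np.diff(np.signbit(h)) != 0))
    return abs(len(maxima) + len(minima) - zc) <= 1


def _sift(x: np.ndarray, sd_threshold: float, max_siftings: int) -> np.ndarray | None:
    """Extract one IMF from ``x``; None when too few extrema remain.

    Sifting stops once the Cauchy criterion is met *and* the candidate
    satisfies the IMF extrema/zero-crossing condition, or at ``max_siftings``.
    """
    h = x
    for _ in range(max_siftings):
        maxima, minima = _extrema_indices(h)
        if len(maxima) < 2 or len(minima) < 2:
            return None if h is x else h
        mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
        h_new = h - mean_env
        denom = float(np.sum(h * h))
        if denom <= 0:
            return h_new
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < sd_threshold and _imf_criterion_ok(h):
            break
    return h


def emd(
    signal: np.ndarray,
    max_imfs: int | None = None,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
) -> IMFSet:
    """Empirical mode decomposition by iterated sifting.

    Each sift subtracts the mean of the upper and lower cubic-spline extrema
    envelopes; sifting of one mode stops when the Cauchy-type criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2)`` falls below ``sd_threshold`` (or
    after ``max_siftings`` passes). Mode extraction stops when the residue has
    too few extrema to envelope (a monotonic or near-monotonic remainder) or
    when ``max_imfs`` modes have been extracted.

    A signal with fewer than two interior extrema yields zero IMFs with the
    signal itself as residue.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(x) < 16:
        raise ValueError("signal must have at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")

    imfs: list[np.ndarray] = []
    residue = x.copy()
    while max_imfs is None or len(imfs) < max_imfs:
        maxima, minima = _extrema_indices(residue)
        if len(maxima) + len(minima) < 2:
            break
        imf = _sift(residue, sd_threshold, max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, source_length=len(x))


def ceemdan(
    signal: np.ndarray,
    ensemble_size: int = 100,
    noise_sd: float = 0.2,
    max_imfs: int | None = 5,
    seed: int = 0,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
) -> IMFSet:
    """Complete ensemble EMD with adaptive noise (stage-wise scheme).

    At stage ``k`` the k-th EMD mode of each stored unit-noise realization,
    scaled by ``noise_sd`` times the current residue's standard deviation, is
    added to the residue; the stage IMF is the ensemble average of the first
    sifted mode of those perturbed residues. The final residue is defined as
    ``signal - sum(imfs)`` so reconstruction is exact. Deterministic given
    ``seed``.

    With ``noise_sd == 0`` the ensemble members coincide and the procedure
    collapses to plain EMD (a notice is logged when ``ensemble_size > 1``).
    """
    x = np.asarray(signal, dtype=float)
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0.0:
        if ensemble_size > 1:
            logger.info("ceemdan with noise_sd=0 collapses to plain EMD")
        return emd(x, max_imfs=max_imfs, sd_threshold=sd_threshold, max_siftings=max_siftings)

    sd_x = float(np.std(x))
    if sd_x == 0:
        return IMFSet(imfs=[], residue=x.copy(), source_length=len(x))
    xn = x / sd_x

    rng = np.random.default_rng(seed)
    # noise bank: full EMD of each unit-variance realization, computed once
    cap = None if max_imfs is None else max_imfs + 2
    noise_modes: list[list[np.ndarray]] = []
    for _ in range(ensemble_size):
        w = rng.standard_normal(len(x))
        noise_modes.append(emd(w, max_imfs=cap, sd_threshold=sd_threshold,
                               max_siftings=max_siftings).imfs)

    def first_mode(y: np.ndarray) -> np.ndarray:
        dec = emd(y, max_imfs=1, sd_threshold=sd_threshold, max_siftings=max_siftings)
        return dec.imfs[0] if dec.imfs else np.zeros_like(y)

    imfs: list[np.ndarray] = []
    stage = np.zeros(len(x))
    for modes in noise_modes:
        if modes:
            stage += first_mode(xn + noise_sd * modes[0])
        else:
            stage += first_mode(xn)
    imfs.append(stage / ensemble_size)
    residue = xn - imfs[0]

    k = 1
    while max_imfs is None or len(imfs) < max_imfs:
        maxima, minima = _extrema_indices(residue)
        if len(maxima) + len(minima) < 2:
            break
        eps_k = noise_sd * float(np.std(residue))
        stage = np.zeros(len(x))
        for modes in noise_modes:
            if len(modes) > k and eps_k > 0:
                stage += first_mode(residue + eps_k * modes[k])
            else:
                stage += first_mode(residue)
        imf = stage / ensemble_size
        if float(np.std(imf)) < 1e-12:
            break
        imfs.append(imf)
        residue = residue - imf
        k += 1

    imfs = [imf * sd_x for imf in imfs]
    residue = x - np.sum(imfs, axis=0)
    return IMFSet(imfs=imfs, residue=residue, source_length=len(x))


# ---------------------------------------------------------------------------
# Hilbert weighted frequency and FOI derivation
# ---------------------------------------------------------------------------


def hilbert_weighted_frequency(
    imf: np.ndarray,
    sampling_interval: float,
    weighting: str = "power",
    edge_fraction: float = 0.05,
) -> float:
    """Amplitude-weighted mean instantaneous frequency of a mode, in Hz.

    The analytic signal provides amplitude ``a(t)`` and unwrapped phase whose
    discrete derivative divided by 2*pi is the instantaneous frequency. The
    weighted mean uses squared amplitude by default (``weighting='power'``;
    ``'amplitude'`` for linear weights). The first and last ``edge_fraction``
    of samples are excluded to suppress Hilbert end effects. The result is
    clipped to [0, Nyquist].
    """
    y = np.asarray(imf, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("imf must be finite")
    if np.ptp(y) == 0:
        raise ConstantSignalError("HWF is undefined for a constant series")
    analytic = hilbert(y)
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    freq = np.diff(phase) / (2.0 * np.pi * sampling_interval)
    a_mid = 0.5 * (amp[:-1] + amp[1:])
    w = a_mid**2 if weighting == "power" else a_mid
    m = len(freq)
    k = int(edge_fraction * m)
    sl = slice(k, m - k) if k > 0 else slice(None)
    wsum = float(np.sum(w[sl]))
    if wsum <= 0:
        raise ConstantSignalError("zero amplitude — HWF undefined")
    hwf = float(np.sum(w[sl] * freq[sl]) / wsum)
    nyquist = 0.5 / sampling_interval
    return float(np.clip(hwf, 0.0, nyquist))


def build_hwf_table(
    imfsets: dict[tuple[str, str], IMFSet],
    sampling_interval: float,
    weighting: str = "power",
) -> pd.DataFrame:
    """HWF of every mode of every (subject, component) decomposition.

    Returns a tidy frame with columns subject_id, component_id, imf_order
    (1-based, 1 = highest frequency) and hwf in Hz. Constant modes are skipped.
    """
    rows = []
    for (subject_id, component_id), imfset in imfsets.items():
        for order, imf in enumerate(imfset.imfs, start=1):
            try:
                hwf = hilbert_weighted_frequency(imf, sampling_interval, weighting)
            except ConstantSignalError:
                continue
            rows.append(
                {
                    "subject_id": subject_id,
                    "component_id": component_id,
                    "imf_order": order,
                    "hwf": hwf,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "component_id", "imf_order", "hwf"])


def derive_fois(
    hwf_table: pd.DataFrame,
    ci_level: float = 0.95,
    max_order: int = 5,
) -> FOIBandSet:
    """Bands as central ``ci_level`` intervals of per-order HWF distributions.

    For each IMF order up to ``max_order`` the band is
    [percentile (1-ci)/2, percentile (1+ci)/2] of the pooled HWF samples of
    that order, trimming extreme values. Bands are returned in descending
    frequency order and named FOI-1 (highest) onward; the conventional
    0.01-0.08 Hz band rides along as FOI-N.
    """
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must lie in (0, 1)")
    lo_q = 100.0 * (1.0 - ci_level) / 2.0
    hi_q = 100.0 * (1.0 + ci_level) / 2.0
    entries = []
    for order in range(1, max_order + 1):
        vals = hwf_table.loc[hwf_table["imf_order"] == order, "hwf"].to_numpy(float)
        if len(vals) == 0:
            warnings.warn(f"no HWF samples for IMF order {order}; order omitted")
            continue
        if len(vals) < 20:
            warnings.warn(f"only {len(vals)} HWF samples for IMF order {order}")
        low, high = np.percentile(vals, [lo_q, hi_q])
        entries.append((float(low), float(high), order))
    entries.sort(key=lambda e: -(e[0] + e[1]) / 2.0)
    bands = [
        FOIBand(low, high, imf_order=order, ci_level=ci_level, name=f"FOI-{i}")
        for i, (low, high, order) in enumerate(entries, start=1)
    ]
    return FOIBandSet(bands=bands)


def extract_band_signal(
    signal: np.ndarray,
    imfset: IMFSet | None,
    band: FOIBand,
    sampling_interval: float,
    mode: str = "imf",
    hwf_weighting: str = "power",
) -> np.ndarray:
    """Band-limited version of ``signal`` for one FOI.

    ``mode='imf'`` (default) sums the IMFs whose HWF falls inside the band —
    typically a single mode; when no mode qualifies, a zero series is returned
    with a warning. The conventional fixed band (``imf_order is None``) and
    ``mode='filter'`` use a zero-phase 4th-order Butterworth band-pass at the
    band's cutoffs instead.
    """
    x = np.asarray(signal, dtype=float)
    fs = 1.0 / sampling_interval
    if band.imf_order is None or mode == "filter":
        if band.high <= 0:
            warnings.warn("degenerate band [0, 0]; returning zero series")
            return np.zeros_like(x)
        return zero_phase_bandpass(x, band.low, band.high, fs, order=4)
    if imfset is None:
        raise ValueError("imf mode requires the signal's IMFSet")
    members = []
    for imf in imfset.imfs:
        try:
            hwf = hilbert_weighted_frequency(imf, sampling_interval, hwf_weighting)
        except ConstantSignalError:
            continue
        if band.low <= hwf <= band.high:
            members.append(imf)
    if not members:
        warnings.warn(
            f"no IMF with HWF inside [{band.low:.4g}, {band.high:.4g}] Hz; zero series returned"
        )
        return np.zeros_like(x)
    return np.sum(members, axis=0)
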