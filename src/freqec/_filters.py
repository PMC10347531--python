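"""Zero-phase Butterworth band-pass shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def zero_phase_bandpass(
    x: np.ndarray, low: float, high: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase band-pass; degenerates to low-/high-pass at the band edges.

    ``low <= 0`` selects everything below ``high``; ``high >= Nyquist``
    selects everything above ``low``.
    """
    nyq = fs / 2.0
    if not (0.0 <= low < high):
        raise ValueError(f"invalid band [{low}, {high}] Hz")
    if high > nyq + 1e-12:
        raise ValueError(f"band [{low}, {high}] Hz exceeds Nyquist {nyq} Hz")
    eps = 1e-9
    if low <= eps:
        sos = sps.butter(order, min(high, nyq * (1 - 1e-6)) / nyq, btype="low", output="sos")
    elif high >= nyq * (1 - 1e-6):
        sos = sps.butter(order, low / nyq, btype="high", output="sos")
    else:
        sos = sps.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)
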