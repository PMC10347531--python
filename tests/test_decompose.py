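"""Band decomposition: EMD sifting, CEEMDAN, HWF, FOI derivation."""

import numpy as np
import pandas as pd
import pytest

from freqec import (
    FOIBand,
    build_hwf_table,
    ceemdan,
    derive_fois,
    emd,
    extract_band_signal,
    hilbert_weighted_frequency,
)
from freqec.decompose import ConstantSignalError, _extrema_indices

DT = 2.0  # TR in seconds, fs = 0.5 Hz
T = np.arange(512) * DT


def _dominant_freq(x: np.ndarray, fs: float = 0.5) -> float:
    from scipy.signal import periodogram

    f, p = periodogram(x, fs=fs)
    return float(f[np.argmax(p)])


class TestEMD:
    def test_monocomponent_sine_gives_one_dominant_imf(self):
        x = np.sin(2 * np.pi * 0.1 * T)
        dec = emd(x)
        rms = np.std(x)
        strong = [imf for imf in dec.imfs if np.std(imf) > 0.1 * rms]
        assert len(strong) == 1
        assert np.std(dec.residue) < 0.05 * rms

    def test_linear_ramp_returns_zero_imfs(self):
        x = np.linspace(0.0, 3.0, 128)
        dec = emd(x)
        assert dec.n_imfs == 0
        np.testing.assert_array_equal(dec.residue, x)

    def test_two_tone_separation(self):
        x = np.sin(2 * np.pi * 0.15 * T) + np.sin(2 * np.pi * 0.02 * T)
        dec = emd(x)
        assert _dominant_freq(dec.imfs[0]) == pytest.approx(0.15, rel=0.15)
        assert _dominant_freq(dec.imfs[1]) == pytest.approx(0.02, rel=0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_completeness_and_imf_criterion(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(512)
        dec = emd(x)
        err = np.max(np.abs(dec.reconstruct() - x))
        assert err < 1e-8 * np.ptp(x)
        for imf in dec.imfs:
            mx, mn = _extrema_indices(imf)
            zc = int(np.sum(np.diff(np.signbit(imf)) != 0))
            assert abs(len(mx) + len(mn) - zc) <= 1

    def test_short_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            emd(np.ones(8))
        with pytest.raises(ValueError):
            emd(np.r_[np.ones(100), np.nan])


class TestCEEMDAN:
    def test_degenerate_ensemble_equals_emd(self):
        rng = np.random.default_rng(3)
        x = np.sin(2 * np.pi * 0.05 * T) + 0.2 * rng.standard_normal(len(T))
        a = ceemdan(x, ensemble_size=1, noise_sd=0.0, max_imfs=4)
        b = emd(x, max_imfs=4)
        assert a.n_imfs == b.n_imfs
        for ia, ib in zip(a.imfs, b.imfs):
            np.testing.assert_allclose(ia, ib)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(256)
        a = ceemdan(x, ensemble_size=20, noise_sd=0.2, seed=11)
        b = ceemdan(x, ensemble_size=20, noise_sd=0.2, seed=11)
        for ia, ib in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(ia, ib)

    def test_reconstruction_bounded(self):
        rng = np.random.default_rng(5)
        x = np.sin(2 * np.pi * 0.08 * T) + 0.5 * rng.standard_normal(len(T))
        dec = ceemdan(x, ensemble_size=50, noise_sd=0.2, max_imfs=5, seed=1)
        assert np.max(np.abs(dec.reconstruct() - x)) < 0.02 * np.std(x)

    def test_imf_order_frequency_decreases(self):
        """HWF of successive orders decreases on a white-noise ensemble."""
        rng = np.random.default_rng(6)
        meds = []
        for _ in range(10):
            x = rng.standard_normal(1024)
            dec = emd(x, max_imfs=4)
            meds.append([hilbert_weighted_frequency(i, DT) for i in dec.imfs[:4]])
        med = np.median(np.array(meds), axis=0)
        assert np.all(np.diff(med) < 0)


class TestHWF:
    @pytest.mark.parametrize("f", [0.02, 0.05, 0.10, 0.15])
    def test_pure_sinusoid(self, f):
        x = np.sin(2 * np.pi * f * T)
        assert hilbert_weighted_frequency(x, DT) == pytest.approx(f, rel=0.02)

    def test_am_carrier(self):
        x = (1 + 0.5 * np.sin(2 * np.pi * 0.01 * T)) * np.sin(2 * np.pi * 0.10 * T)
        assert hilbert_weighted_frequency(x, DT) == pytest.approx(0.10, rel=0.05)

    def test_linear_chirp_time_average(self):
        phase = 2 * np.pi * (0.02 * T + (0.06 - 0.02) / (2 * T[-1]) * T**2)
        assert hilbert_weighted_frequency(np.sin(phase), DT) == pytest.approx(0.04, rel=0.10)

    def test_constant_series_signalled(self):
        with pytest.raises(ConstantSignalError):
            hilbert_weighted_frequency(np.ones(100), DT)


class TestFOIs:
    def _table(self, values, order=1):
        return pd.DataFrame(
            {
                "subject_id": "s0",
                "component_id": "C00",
                "imf_order": order,
                "hwf": values,
            }
        )

    def test_degenerate_distribution(self):
        bs = derive_fois(self._table(np.full(30, 0.05)), ci_level=0.95, max_order=1)
        band = bs.bands[0]
        assert band.low == band.high == pytest.approx(0.05)

    def test_uniform_order_statistics(self):
        rng = np.random.default_rng(0)
        bs = derive_fois(self._table(rng.uniform(0, 1, 10000)), ci_level=0.95, max_order=1)
        assert bs.bands[0].low == pytest.approx(0.025, abs=0.01)
        assert bs.bands[0].high == pytest.approx(0.975, abs=0.01)

    def test_conventional_band_appended(self):
        bs = derive_fois(self._table(np.linspace(0.1, 0.2, 50)), max_order=1)
        names = [b.name for b in bs.all_bands()]
        assert names[0] == "FOI-N"
        assert (bs.conventional.low, bs.conventional.high) == (0.01, 0.08)

    def test_permutation_invariance_and_rescaling_equivariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.01, 0.2, 500)
        a = derive_fois(self._table(vals), max_order=1).bands[0]
        b = derive_fois(self._table(rng.permutation(vals)), max_order=1).bands[0]
        assert (a.low, a.high) == (b.low, b.high)
        c = derive_fois(self._table(2.0 * vals), max_order=1).bands[0]
        assert c.low == pytest.approx(2 * a.low)
        assert c.high == pytest.approx(2 * a.high)

    def test_empty_order_omitted_with_warning(self):
        table = self._table(np.linspace(0.1, 0.2, 30), order=2)
        with pytest.warns(UserWarning):
            bs = derive_fois(table, max_order=3)
        assert len(bs.bands) == 1

    def test_pipeline_orders_do_not_overlap(self, small_cohort):
        """Data-driven bands from a cohort: order-1 midpoint above order-2."""
        _, _, tcs, _ = small_cohort
        imfsets = {}
        for s in range(4):
            for c in range(3):
                imfsets[(f"s{s}", f"C{c:02d}")] = emd(tcs.data[s, c], max_imfs=4)
        table = build_hwf_table(imfsets, tcs.sampling_interval)
        bs = derive_fois(table, max_order=2)
        mids = [(b.low + b.high) / 2 for b in bs.bands]
        assert mids[0] > mids[1]


class TestBandExtraction:
    def test_single_member_selection_is_exact(self):
        x = np.sin(2 * np.pi * 0.1 * T) + np.sin(2 * np.pi * 0.02 * T)
        dec = emd(x)
        hwf1 = hilbert_weighted_frequency(dec.imfs[0], DT)
        band = FOIBand(hwf1 - 0.01, hwf1 + 0.01, imf_order=1, name="FOI-1")
        out = extract_band_signal(x, dec, band, DT)
        np.testing.assert_array_equal(out, dec.imfs[0])

    def test_conventional_band_filter_response(self):
        rng = np.random.default_rng(2)
        from scipy.signal import periodogram

        x = rng.standard_normal(4096)
        out = extract_band_signal(x, None, FOIBand(0.01, 0.08, name="FOI-N"), DT)
        f, p = periodogram(out, fs=0.5)
        outside = (f < 0.005) | (f > 0.10)
        assert p[outside].sum() < 0.10 * p.sum()

    def test_empty_band_warns_and_zeroes(self):
        x = np.sin(2 * np.pi * 0.1 * T)
        dec = emd(x)
        with pytest.warns(UserWarning):
            out = extract_band_signal(x, dec, FOIBand(0.0, 0.0, imf_order=3), DT)
        assert not out.any()
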