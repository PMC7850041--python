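"""Preprocessing, Morlet decomposition and SME contrasts."""

import numpy as np
import pandas as pd
import pytest

from memsme import spectral as spe
from memsme.datatypes import EpochTensor, SchemaError

FS = 500.0


def tensor_from(data, buffer=1.0, tmin=None):
    data = np.asarray(data, dtype=float)
    if tmin is None:
        tmin = -buffer
    return EpochTensor(data=data, fs=FS, tmin=tmin, buffer=buffer)


def electrode_table(n, regions=("frontal", "MTL", "LTC", "parietal"), excluded=()):
    return pd.DataFrame({
        "channel": [f"ch{i}" for i in range(n)],
        "region": [regions[i % len(regions)] for i in range(n)],
        "excluded": [i in excluded for i in range(n)],
    })


class TestPreprocess:
    def test_60hz_sinusoid_attenuated(self):
        t = np.arange(int(3.0 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)[None, None, :]
        ep, _ = spe.preprocess(tensor_from(x), electrode_table(1))
        mid = ep.data[0, 0, 250:-250]  # ignore filter edges
        assert np.abs(mid).max() < 0.05

    def test_nearby_frequency_preserved(self):
        t = np.arange(int(3.0 * FS)) / FS
        x = np.sin(2 * np.pi * 20.0 * t)[None, None, :]
        ep, _ = spe.preprocess(tensor_from(x), electrode_table(1))
        mid = ep.data[0, 0, 250:-250]
        assert np.abs(mid).max() > 0.95

    def test_zero_in_zero_out_and_bipolar_identity(self):
        x = np.zeros((2, 3, 1000))
        ep, elec = spe.preprocess(tensor_from(x), electrode_table(3))
        assert np.allclose(ep.data, 0.0)
        assert ep.n_channels == 3 and len(elec) == 3

    def test_monopolar_rereferencing_is_neighbor_difference(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 3, 800))
        ep, elec = spe.preprocess(tensor_from(x), electrode_table(3),
                                  montage="monopolar", notch_hz=60.0)
        assert ep.n_channels == 2
        assert list(elec["channel"]) == ["ch0-ch1", "ch1-ch2"]

    def test_excluded_channels_dropped(self):
        x = np.zeros((2, 4, 800))
        ep, elec = spe.preprocess(tensor_from(x), electrode_table(4, excluded=(2,)))
        assert ep.n_channels == 3
        assert "ch2" not in list(elec["channel"])

    def test_low_sampling_rate_rejected_for_hfa(self):
        x = np.zeros((1, 1, 500))
        ep = EpochTensor(x, fs=250.0, tmin=-1.0, buffer=1.0)
        with pytest.raises(SchemaError):
            spe.preprocess(ep, electrode_table(1))


class TestMorlet:
    def _sinusoid(self, freq, amp=1.0, dur=3.7):
        t = np.arange(int(dur * FS)) / FS
        return amp * np.sin(2 * np.pi * freq * t)[None, None, :]

    def test_power_peaks_at_matching_frequency(self):
        ep = tensor_from(self._sinusoid(10.0))
        power, _ = spe.morlet_power(ep, np.array([5.0, 10.0, 20.0]))
        mean_p = power.mean(axis=-1)[0, 0]
        assert np.argmax(mean_p) == 1

    def test_quadratic_amplitude_scaling(self):
        p1, _ = spe.morlet_power(tensor_from(self._sinusoid(10.0, 1.0)),
                                 np.array([10.0]))
        p2, _ = spe.morlet_power(tensor_from(self._sinusoid(10.0, 2.0)),
                                 np.array([10.0]))
        assert np.allclose(p2, 4.0 * p1, rtol=1e-10)

    def test_zero_signal_zero_power(self):
        p, _ = spe.morlet_power(tensor_from(np.zeros((1, 1, 1850))), np.array([8.0]))
        assert np.allclose(p, 0.0)

    def test_buffer_trimmed_to_analysis_window(self):
        ep = tensor_from(np.zeros((1, 1, 1850)), buffer=1.0, tmin=-1.2)
        _, times = spe.morlet_power(ep, np.array([10.0]))
        assert times[0] == pytest.approx(-0.2, abs=1e-9)
        assert len(times) == 1850 - 2 * 500

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(SchemaError):
            spe.morlet_power(tensor_from(np.zeros((1, 1, 1850))), np.array([300.0]))

    def test_insufficient_buffer_rejected(self):
        ep = tensor_from(np.zeros((1, 1, 1000)), buffer=0.2, tmin=-0.2)
        with pytest.raises(SchemaError):
            spe.morlet_power(ep, np.array([3.0]))

    def test_agrees_with_mne_implementation(self):
        """Cross-check the wavelet power against MNE's Morlet transform
        (normalizations differ; log powers must be affinely identical)."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 2, 1850))
        ep = tensor_from(x, buffer=1.0, tmin=-1.2)
        freqs = [6.0, 40.0]
        p_ours, _ = spe.morlet_power(ep, np.array(freqs))
        p_mne = mne.time_frequency.tfr_array_morlet(
            x, FS, freqs, n_cycles=5, output="power", zero_mean=False,
            verbose=False)[:, :, :, 500:-500]
        for k in range(2):
            a = np.log(p_ours[:, :, k, :]).ravel()
            b = np.log(p_mne[:, :, k, :]).ravel()
            assert np.corrcoef(a, b)[0, 1] > 0.9999


class TestFeatures:
    def test_session_zscore_exact(self, null_subject):
        ds = null_subject
        power, times = spe.morlet_power(ds.epochs, np.array([5.0, 50.0]))
        feats = spe.encoding_power_features(
            power, times, ds.events["session"].to_numpy())
        assert np.allclose(feats.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(feats.std(axis=0), 1.0, atol=1e-6)

    def test_constant_power_maps_to_zero_with_warning(self):
        power = np.ones((4, 1, 1, 100))
        times = np.linspace(0.0, 1.2, 100)
        with pytest.warns(UserWarning):
            feats = spe.encoding_power_features(power, times, np.zeros(4))
        assert np.allclose(feats, 0.0)

    def test_single_item_session_rejected(self):
        power = np.ones((1, 1, 1, 100))
        times = np.linspace(0.0, 1.2, 100)
        with pytest.raises(SchemaError):
            spe.encoding_power_features(power, times, np.zeros(1))


class TestPowerSme:
    def test_identical_classes_give_zero(self):
        feats = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])[:, None, None]
        t = spe.power_sme(feats, np.array([1, 1, 1, 0, 0, 0], dtype=bool))
        assert t[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_welch(self):
        a, b = np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0])
        feats = np.concatenate([a, b])[:, None, None]
        t = spe.power_sme(feats, np.array([1, 1, 1, 0, 0, 0], dtype=bool))
        expected = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert t[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_empty_class_rejected(self):
        feats = np.zeros((4, 1, 1))
        with pytest.raises(SchemaError):
            spe.power_sme(feats, np.array([1, 1, 1, 1], dtype=bool))


class TestAggregation:
    def test_uniform_t_gives_uniform_cells(self):
        elec = electrode_table(8)
        t = np.ones((8, 20))
        cells = spe.band_region_sme(t, spe.DEFAULT_SME_FREQS, elec)
        assert np.allclose(cells.to_numpy(), 1.0)

    def test_band_membership_closed_interval(self):
        freqs = np.array([3.9, 4.0, 8.0, 8.1, 45.0, 170.0])
        elec = electrode_table(1, regions=("frontal",))
        t = np.arange(6, dtype=float)[None, :]
        cells = spe.band_region_sme(t, freqs, elec)
        assert cells.loc["frontal", "theta"] == pytest.approx((1 + 2) / 2)
        assert cells.loc["frontal", "hfa"] == pytest.approx((4 + 5) / 2)

    def test_single_region_leaves_other_cells_missing(self):
        elec = electrode_table(2, regions=("frontal",))
        t = np.ones((2, 20))
        cells = spe.band_region_sme(t, spe.DEFAULT_SME_FREQS, elec)
        assert list(cells.index) == ["frontal"]


def bh_stepup_oracle(pvals):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestGroupContrast:
    def _cells(self, values_by_subject):
        idx = ["frontal", "MTL", "LTC", "parietal"]
        return {s: pd.DataFrame(v, index=idx, columns=["theta", "hfa"])
                for s, v in values_by_subject.items()}

    def test_bh_matches_oracle(self):
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.2, 0.5, 0.9])
        assert np.allclose(multipletests(p, method="fdr_bh")[1],
                           bh_stepup_oracle(p), atol=1e-10)

    def test_bh_fixed_point(self):
        from statsmodels.stats.multitest import multipletests
        p = np.full(8, 0.001)
        assert np.allclose(multipletests(p, method="fdr_bh")[1], 0.001)

    def test_group_difference_detected_and_corrected(self):
        rng = np.random.default_rng(0)
        cells = {}
        groups = {}
        for i in range(10):
            base = rng.normal(0, 0.1, (4, 2))
            base[:, 1] += 1.0 if i < 5 else 0.0  # hfa differs between groups
            cells[f"S{i}"] = pd.DataFrame(
                base, index=["frontal", "MTL", "LTC", "parietal"],
                columns=["theta", "hfa"])
            groups[f"S{i}"] = "case" if i < 5 else "control"
        res = spe.group_sme_contrast(cells, pd.Series(groups))
        assert len(res) == 8
        hfa_q = res[res.band == "hfa"]["q"]
        theta_q = res[res.band == "theta"]["q"]
        assert (hfa_q < 0.05).all() and (theta_q > 0.05).all()

    def test_small_group_rejected(self):
        cells = self._cells({"a": np.zeros((4, 2)), "b": np.zeros((4, 2))})
        groups = pd.Series({"a": "x", "b": "y"})
        with pytest.raises(ValueError):
            spe.group_sme_contrast(cells, groups)
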