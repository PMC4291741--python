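"""IPD extraction, circular statistics, and the cue maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import circstd as scipy_circstd
from scipy.stats import spearmanr

from owlrel.binaural import filter_binaural, make_flat_noise, render_binaural
from owlrel.cues import (
    ZeroEnergyError,
    _steady_window,
    band_edges,
    build_cue_maps,
    build_reliability_map,
    build_reliability_map_three_sources,
    circular_mean,
    circular_std,
    extract_ipd,
    gain_normalizations,
    build_gain_map,
    interaural_correlation_at,
    ipd_distractor_ensemble,
    single_source_channel_cues,
)


def _channel_pair(wave, bank, k, duration_s=0.1):
    win = _steady_window(wave.left.size, wave.fs_hz, duration_s)
    ch_l, ch_r = filter_binaural(wave, bank, channels=[k])
    return ch_l[0, win], ch_r[0, win]


class TestExtractIPD:
    def test_identical_signals_give_zero(self):
        x = make_flat_noise((500.0, 9000.0), 0.05, 48000.0, seed=0).samples
        assert extract_ipd(x, x.copy(), 4000.0, 48000.0) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("fc", [1000.0, 3000.0, 6000.0, 8000.0])
    def test_quarter_period_delay_gives_quarter_cycle(self, fc, bank36):
        """Analytic tone-phase oracle: right = left delayed by 1/(4 fc)
        must read +0.25 cycles (right lag positive)."""
        fs = 48000.0
        t = np.arange(int(0.1 * fs)) / fs
        d = 1.0 / (4.0 * fc)
        k = int(np.argmin(np.abs(bank36.center_freqs_hz - fc)))
        tau = bank36.time_constants_s[k]
        from owlrel.binaural import gammatone_filter

        l = gammatone_filter(np.sin(2 * np.pi * fc * t), fc, tau, fs)[2000:4500]
        r = gammatone_filter(np.sin(2 * np.pi * fc * (t - d)), fc, tau, fs)[2000:4500]
        assert extract_ipd(l, r, fc, fs) == pytest.approx(0.25, abs=0.01)

    def test_silent_channel_rejected(self):
        with pytest.raises(ZeroEnergyError):
            extract_ipd(np.zeros(1000), np.ones(1000), 4000.0, 48000.0)

    def test_two_equal_sources_mix_to_circular_mean(self, hrir_isotropic, bank36):
        """Equal-intensity mixing rule: with the same token played from
        two directions through a delay-only head, the per-channel
        resultant IPD is the circular mean of the single-source IPDs."""
        st = make_flat_noise((500.0, 9000.0), 0.1, 48000.0, seed=21)
        el = 0.0
        w1 = render_binaural([(0.0, el, st)], hrir_isotropic)
        w2 = render_binaural([(10.0, el, st)], hrir_isotropic)
        w12 = render_binaural([(0.0, el, st), (10.0, el, st)], hrir_isotropic)
        for k in range(0, bank36.n_channels, 7):
            fc = bank36.center_freqs_hz[k]
            ipd1 = extract_ipd(*_channel_pair(w1, bank36, k), fc, 48000.0)
            ipd2 = extract_ipd(*_channel_pair(w2, bank36, k), fc, 48000.0)
            mixed = extract_ipd(*_channel_pair(w12, bank36, k), fc, 48000.0)
            expect = circular_mean([ipd1, ipd2])
            err = abs((mixed - expect + 0.5) % 1.0 - 0.5)
            assert err < 0.02

    def test_colocated_duplicate_source_matches_single(self, hrir_default, bank36):
        """Superposing an identical token at the same location only
        scales the signals; the IPD must not move."""
        st = make_flat_noise((500.0, 9000.0), 0.1, 48000.0, seed=8)
        w1 = render_binaural([(20.0, 0.0, st)], hrir_default)
        w2 = render_binaural([(20.0, 0.0, st), (20.0, 0.0, st)], hrir_default)
        k = 15
        fc = bank36.center_freqs_hz[k]
        a = extract_ipd(*_channel_pair(w1, bank36, k), fc, 48000.0)
        b = extract_ipd(*_channel_pair(w2, bank36, k), fc, 48000.0)
        assert a == pytest.approx(b, abs=1e-9)


class TestCircularStd:
    def test_equal_samples_give_zero(self):
        assert circular_std([0.3, 0.3, 0.3]) == pytest.approx(0.0, abs=1e-3)

    def test_quarter_cycle_pair_closed_form(self):
        """{0, 0.25} cycles: R = sqrt(2)/2, SD = sqrt(-2 ln R) rad."""
        expect = 100.0 * np.sqrt(-2.0 * np.log(np.sqrt(2.0) / 2.0)) / (2.0 * np.pi)
        assert circular_std([0.0, 0.25]) == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(13.25, abs=0.01)

    def test_full_cycle_shifts_are_invisible(self):
        x = [0.1, 0.3, 0.45]
        shifted = [0.1 + 1.0, 0.3, 0.45 - 2.0]
        assert circular_std(x) == pytest.approx(circular_std(shifted), rel=1e-12)

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-0.5, 0.5, size=40)
        for rot in (0.13, 0.37, 0.5):
            assert circular_std(x + rot) == pytest.approx(circular_std(x), rel=1e-9)

    def test_matches_scipy_circular_std(self):
        rng = np.random.default_rng(7)
        x = rng.vonmises(0.0, 4.0, size=200) / (2.0 * np.pi)
        expect = 100.0 * scipy_circstd(x, high=1.0)
        assert circular_std(x) == pytest.approx(expect, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            circular_std([])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-0.5, 0.5), min_size=2, max_size=30),
        st.floats(-3.0, 3.0),
    )
    def test_rotation_and_wrap_invariance_property(self, samples, rotation):
        """Circular SD is finite, non-negative, and unchanged by any
        global phase rotation or integer-cycle shifts."""
        base = circular_std(samples)
        assert np.isfinite(base) and base >= 0.0
        rotated = circular_std(np.asarray(samples) + rotation)
        assert rotated == pytest.approx(base, abs=1e-6)


class TestEnsemble:
    def test_default_grid_gives_37_configs(self, hrir_isotropic, bank_small):
        mat = ipd_distractor_ensemble(0.0, hrir_isotropic, bank_small, seed=3)
        assert mat.shape == (bank_small.n_channels, 37)

    def test_delay_only_head_low_channels_least_spread(self, hrir_isotropic, bank36):
        """Without directional gain, IPD spread in percent of cycle is
        set by phase geometry alone: bounded small at the lowest
        channels, rising to a broad wrapped-phase plateau above."""
        mat = ipd_distractor_ensemble(
            0.0,
            hrir_isotropic,
            bank36,
            distractor_azimuths=np.arange(-90.0, 91.0, 15.0),
            seed=3,
        )
        sds = np.array([circular_std(mat[k]) for k in range(bank36.n_channels)])
        assert sds[0] < 0.6 * np.median(sds[4:])
        assert np.all(sds > 1.0) and np.all(sds < 40.0)


@pytest.fixture(scope="module")
def tiny_maps(hrir_default, bank_small):
    return build_cue_maps(
        hrir_default,
        bank_small,
        target_azimuths=[-60.0, 0.0, 60.0],
        distractor_azimuths=np.arange(-90.0, 91.0, 30.0),
        seed=13,
    )


class TestMaps:
    def test_reliability_normalization_contract(self, tiny_maps):
        rmap, _ = tiny_maps
        assert np.allclose(rmap.reliability_norm.max(axis=1), 1.0)
        assert np.all(rmap.reliability_norm >= 0.0)
        assert np.all(np.isfinite(rmap.circ_std_pct_cycle))

    def test_lower_spread_means_higher_reliability(self, tiny_maps):
        rmap, _ = tiny_maps
        for row_sd, row_rel in zip(rmap.circ_std_pct_cycle, rmap.reliability_norm):
            order = np.argsort(row_sd)
            assert np.all(np.diff(row_rel[order]) <= 1e-12)

    def test_maps_reproducible_with_seed(self, hrir_default, bank_small, tiny_maps):
        rmap2, imap2 = build_cue_maps(
            hrir_default,
            bank_small,
            target_azimuths=[-60.0, 0.0, 60.0],
            distractor_azimuths=np.arange(-90.0, 91.0, 30.0),
            seed=13,
        )
        rmap, imap = tiny_maps
        assert np.array_equal(rmap.circ_std_pct_cycle, rmap2.circ_std_pct_cycle)
        assert np.array_equal(imap.mean_iac, imap2.mean_iac)

    def test_single_source_interaural_correlation_near_one(self, tiny_maps):
        _, imap = tiny_maps
        assert np.all(imap.single_source_iac > 0.9)
        assert np.all(imap.mean_iac <= 1.0) and np.all(imap.mean_iac >= -1.0)

    def test_concurrent_sound_decorrelates_ears(self, tiny_maps):
        _, imap = tiny_maps
        assert np.all(imap.mean_iac < imap.single_source_iac)

    def test_map_export_roundtrip(self, tiny_maps, tmp_path):
        import h5py

        from owlrel.cues import save_maps_h5

        rmap, imap = tiny_maps
        tidy = rmap.to_tidy()
        assert set(tidy.columns) == {"target_azimuth", "channel_fc", "statistic", "value"}
        assert len(tidy) == 2 * rmap.circ_std_pct_cycle.size
        path = tmp_path / "maps.h5"
        save_maps_h5(path, reliability=rmap, iac=imap)
        with h5py.File(path) as f:
            assert np.array_equal(
                f["reliability/reliability_norm"][...], rmap.reliability_norm
            )
            assert np.array_equal(f["iac/mean_iac"][...], imap.mean_iac)

    def test_three_source_map_contract_and_structure(self, hrir_default, bank_small):
        targets = [-60.0, 0.0, 60.0]
        pairs = [(-60.0, 0.0), (-60.0, 60.0), (0.0, 60.0)]
        m3 = build_reliability_map_three_sources(
            hrir_default, bank_small, targets, pairs, seed=4
        )
        assert np.allclose(m3.reliability_norm.max(axis=1), 1.0)
        m2 = build_reliability_map(
            hrir_default,
            bank_small,
            targets,
            distractor_azimuths=[-60.0, 0.0, 60.0],
            seed=4,
        )
        rho, _ = spearmanr(m2.circ_std_pct_cycle.ravel(), m3.circ_std_pct_cycle.ravel())
        assert rho > 0.5


class TestGainMap:
    def test_per_location_normalization_contract(self, hrir_default, bank_small):
        gmap = build_gain_map(
            hrir_default, bank_small.center_freqs_hz, [-60.0, -20.0, 0.0, 30.0, 60.0]
        )
        assert np.allclose(gmap.gain_norm_per_location.max(axis=1), 1.0)
        assert np.all(gmap.gain_norm_per_location >= 0.0)
        assert np.all(
            (gmap.gain_norm_freq_then_location >= 0.0)
            & (gmap.gain_norm_freq_then_location <= 1.0)
        )
        assert np.all(np.isfinite(gmap.gain_db))

    def test_two_normalizations_differ_on_toy_table(self):
        """When the across-location gain range differs by frequency the
        relative-gain normalization reorders the profile."""
        gain_db = np.array(
            [
                [0.0, 10.0],
                [-1.0, -10.0],
            ]
        )
        per_loc, freq_then_loc = gain_normalizations(gain_db)
        assert np.allclose(per_loc.max(axis=1), 1.0)
        assert not np.allclose(per_loc, freq_then_loc)

    def test_symmetric_head_equal_ear_gain(self, hrir_isotropic, bank_small):
        gmap = build_gain_map(hrir_isotropic, bank_small.center_freqs_hz, [0.0])
        # delay-only head: gain ~0 dB everywhere
        assert np.allclose(gmap.gain_db, 0.0, atol=0.5)


class TestBandEdges:
    def test_delta_profile(self):
        freqs = [1000.0, 2000.0, 3000.0, 4000.0, 5000.0]
        profile = [0.0, 0.0, 0.0, 1.0, 0.0]
        assert band_edges(freqs, profile) == (4000.0, 4000.0)

    def test_threshold_scan(self):
        freqs = [1000.0, 2000.0, 3000.0, 4000.0, 5000.0]
        profile = [0.2, 0.6, 1.0, 0.6, 0.2]
        assert band_edges(freqs, profile, 0.5) == (2000.0, 4000.0)

    def test_zero_threshold_full_support(self):
        freqs = [1000.0, 2000.0, 3000.0, 4000.0]
        profile = [0.0, 0.5, 0.1, 0.0]
        assert band_edges(freqs, profile, 0.0) == (2000.0, 3000.0)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            band_edges([1.0, 2.0], [0.0, 0.0])


class TestCorrelationAtLag:
    def test_matches_peak_for_aligned_signals(self):
        x = make_flat_noise((500.0, 9000.0), 0.05, 48000.0, seed=2).samples
        assert interaural_correlation_at(x, x.copy(), 0.0, 48000.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_single_source_cues_consistency(self, hrir_default, bank_small):
        ipd, lag, corr = single_source_channel_cues(
            30.0, hrir_default, bank_small, elevation=0.0, seed=6
        )
        assert np.all(corr > 0.9)
        wrapped = -((0.5 - lag * bank_small.center_freqs_hz) % 1.0) + 0.5
        assert np.allclose(ipd, wrapped, atol=1e-6)
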