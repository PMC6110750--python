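"""Cleaning, interpolation, epoching and artifact rejection."""

import numpy as np
import pandas as pd
import pytest

from interbrain import montage
from interbrain.containers import EventTable, Recording
from interbrain.preprocess import (apply_baseline, detect_bad_channels,
                                   detrend_and_rereference, epoch,
                                   interpolate_spherical,
                                   reject_artifact_epochs,
                                   remove_blink_component,
                                   synchronize_rejections)
from interbrain.simulate import simulate_pair_session

from conftest import make_epochs

FS = 500.0
CH = list(montage.DEFAULT_CHANNELS)


def make_recording(data, channels=CH):
    return Recording(np.asarray(data, dtype=float), FS, list(channels))


def simple_events(onsets, conditions=None):
    n = len(onsets)
    conditions = conditions or ["expected"] * n
    return EventTable(pd.DataFrame({
        "trial": range(n), "condition": conditions,
        "prompt_onset": onsets,
        "sentence_onset": [o + 1000 for o in onsets],
        "go_onset": [o + 3000 for o in onsets],
        "word_onset": [o + 3250 for o in onsets]}))


class TestDetrendRereference:
    def test_linear_ramp_removed(self):
        ramp = np.outer(np.ones(24), np.linspace(0, 10, 5000))
        out = detrend_and_rereference(make_recording(ramp))
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_channel_equal_to_mastoids_becomes_zero(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal(5000)
        data = rng.standard_normal((24, 5000))
        for ch in ("Pz", "M1", "M2"):
            data[CH.index(ch)] = sig
        out = detrend_and_rereference(make_recording(data))
        assert np.allclose(out.data[CH.index("Pz")], 0.0, atol=1e-9)

    def test_mastoid_average_is_zero_after_rereference(self):
        rng = np.random.default_rng(1)
        out = detrend_and_rereference(
            make_recording(rng.standard_normal((24, 5000))))
        m = out.data[[CH.index("M1"), CH.index("M2")]].mean(axis=0)
        assert np.allclose(m, 0.0, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        rec = make_recording(rng.standard_normal((24, 5000)))
        once = detrend_and_rereference(rec)
        twice = detrend_and_rereference(once)
        assert np.allclose(once.data, twice.data, atol=1e-8)

    def test_missing_mastoid_named(self):
        rec = Recording(np.zeros((2, 100)), FS, ["Pz", "Cz"])
        with pytest.raises(KeyError, match="M1"):
            detrend_and_rereference(rec)


class TestBadChannelDetection:
    def test_inflated_variance_channel_flagged_exactly(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((24, 20000))
        data[CH.index("C3")] *= 10.0            # variance x100
        assert detect_bad_channels(make_recording(data)) == ["C3"]

    def test_homogeneous_channels_pass(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((24, 20000))
        assert detect_bad_channels(make_recording(data)) == []

    def test_injected_bad_channels_recovered(self, tiny_config):
        # sensitivity over injected variance-inflated channels
        import dataclasses
        cfg = dataclasses.replace(tiny_config, bad_channel_prob=0.1,
                                  blink_rate_per_min=0.0,
                                  artifact_rate_per_min=0.0)
        injected, found = 0, 0
        for seed in (11, 12, 13, 14):
            blk = simulate_pair_session(cfg, seed=seed)
            for rec in (blk.speaker, blk.listener):
                clean = detrend_and_rereference(rec)
                flagged = set(detect_bad_channels(clean))
                inj = set(rec.meta["injected_bad_channels"])
                injected += len(inj)
                found += len(inj & flagged)
        assert injected >= 5
        assert found / injected >= 0.9


class TestSphericalInterpolation:
    def test_constant_field_reproduced(self):
        data = np.full((24, 100), 3.7)
        out = interpolate_spherical(make_recording(data), ["Pz"])
        assert np.allclose(out.data[CH.index("Pz")], 3.7, atol=1e-6)

    def test_empty_bad_list_is_identity(self):
        rng = np.random.default_rng(5)
        rec = make_recording(rng.standard_normal((24, 100)))
        out = interpolate_spherical(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_good_channels_bit_identical(self):
        rng = np.random.default_rng(6)
        rec = make_recording(rng.standard_normal((24, 200)))
        out = interpolate_spherical(rec, ["Cz", "P3"])
        for i, ch in enumerate(CH):
            if ch not in ("Cz", "P3"):
                assert np.array_equal(out.data[i], rec.data[i]), ch

    def test_smooth_dipolar_field_recovered(self):
        # leave one channel out of a smooth dipolar potential and compare the
        # spline estimate against the held-out truth
        rng = np.random.default_rng(7)
        pos = montage.positions_for(CH)
        moments = rng.standard_normal((3, 300))
        field = pos @ moments          # linear-in-position potential
        rec = make_recording(field)
        out = interpolate_spherical(rec, ["Pz"])
        i = CH.index("Pz")
        r = np.corrcoef(out.data[i], field[i])[0, 1]
        assert r >= 0.95

    def test_missing_position_errors(self):
        rec = Recording(np.zeros((5, 10)), FS,
                        ["Pz", "Cz", "P3", "P4", "XX"])
        with pytest.raises(KeyError, match="XX"):
            interpolate_spherical(rec, ["XX"])


class TestBlinkRemoval:
    @staticmethod
    def _record_with_blinks(n_blinks, seed=8, heavy_tails=True):
        rng = np.random.default_rng(seed)
        n = int(120 * FS)
        # heavy-tailed background gives the ICA non-Gaussian structure
        base = rng.standard_t(5, size=(24, n)) if heavy_tails else \
            rng.standard_normal((24, n))
        data = 2.0 * base
        width = 100
        template = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
        pos = montage.positions_for(CH)
        front = pos[[CH.index("Fp1"), CH.index("Fp2")]].mean(axis=0)
        gains = np.exp(-np.linalg.norm(pos - front, axis=1) / 0.5)
        gains /= gains.max()
        starts = rng.integers(0, n - width, size=n_blinks)
        for s in starts:
            data[:, s:s + width] += 100.0 * np.outer(gains, template)
        return make_recording(data), starts, width

    @pytest.mark.parametrize("method", ["ica", "template_regression"])
    def test_injected_blinks_attenuated(self, method):
        rec, starts, width = self._record_with_blinks(24)
        out, n_removed = remove_blink_component(rec, method)
        fp = CH.index("Fp1")
        sel = np.zeros(rec.n_samples, dtype=bool)
        for s in starts:
            sel[s:s + width] = True
        before = np.abs(rec.data[fp, sel]).mean()
        after = np.abs(out.data[fp, sel]).mean()
        assert after <= 0.2 * before
        assert n_removed >= 1

    def test_clean_record_nearly_untouched(self):
        rec, _, _ = self._record_with_blinks(0)
        out, n_removed = remove_blink_component(rec, "ica")
        rms_change = np.sqrt(np.mean((out.data - rec.data) ** 2))
        rms = np.sqrt(np.mean(rec.data ** 2))
        assert rms_change < 0.01 * rms
        assert n_removed == 0

    def test_short_record_rejected_for_ica(self):
        rec = make_recording(np.zeros((24, int(10 * FS))))
        with pytest.raises(ValueError, match="60 s"):
            remove_blink_component(rec, "ica")


class TestEpoching:
    def test_event_at_10000_cuts_9900_to_10499(self):
        rng = np.random.default_rng(9)
        rec = make_recording(rng.standard_normal((24, 20000)))
        ep = epoch(rec, simple_events([10000]), "prompt")
        assert ep.n_samples == 600
        assert np.array_equal(ep.data[0], rec.data[:, 9900:10500])

    def test_all_epochs_kept_without_packet_loss(self):
        rec = make_recording(np.zeros((24, 400000)))
        onsets = [1000 + 4000 * i for i in range(80)]
        ep = epoch(rec, simple_events(onsets), "prompt")
        assert ep.n_trials == 80 and ep.keep_mask.all()
        assert ep.n_samples == 600

    def test_epoch_overlapping_lost_packet_unkept(self):
        rec = make_recording(np.zeros((24, 20000)))
        rec.validity_mask[10400] = False
        ep = epoch(rec, simple_events([5000, 10000]), "prompt")
        assert ep.keep_mask.tolist() == [True, False]

    def test_event_outside_record_unkept(self):
        rec = make_recording(np.zeros((24, 5000)))
        ep = epoch(rec, simple_events([60, 3000]), "prompt")
        assert ep.keep_mask.tolist() == [False, True]

    def test_baseline_subtracts_prestim_mean(self):
        ep = make_epochs(np.ones((2, 3, 600)) * 5.0)
        out = apply_baseline(ep)
        assert np.allclose(out.data, 0.0)


class TestEpochRejection:
    def test_all_zero_epochs_survive(self):
        ep = make_epochs(np.zeros((10, 3, 600)))
        out = reject_artifact_epochs(ep)
        assert out.keep_mask.all()

    def test_amplitude_spike_rejected(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((10, 3, 600))
        data[4, 1, 300] = 2000.0
        out = reject_artifact_epochs(make_epochs(data))
        assert not out.keep_mask[4]
        assert out.keep_mask.sum() == 9

    def test_deviant_epoch_rejected_iteratively(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((30, 3, 600))
        data[7] *= 20.0
        out = reject_artifact_epochs(make_epochs(data))
        assert not out.keep_mask[7]

    def test_keep_count_never_increases(self):
        rng = np.random.default_rng(12)
        ep = make_epochs(rng.standard_normal((20, 3, 600)))
        ep.keep_mask[3] = False
        out = reject_artifact_epochs(ep)
        assert out.keep_mask.sum() <= 19
        assert not out.keep_mask[3]

    def test_all_rejected_is_error(self):
        data = np.full((3, 2, 600), 5000.0)
        with pytest.raises(ValueError, match="all epochs rejected"):
            reject_artifact_epochs(make_epochs(data))


class TestSynchronizeRejections:
    def _pair(self, keep_a, keep_b):
        a = make_epochs(np.zeros((3, 2, 600)), keep=np.array(keep_a))
        b = make_epochs(np.zeros((3, 2, 600)), keep=np.array(keep_b))
        return a, b

    def test_joint_mask_is_elementwise_and(self):
        a, b = self._pair([True, True, False], [True, False, True])
        oa, ob = synchronize_rejections(a, b)
        assert oa.keep_mask.tolist() == [True, False, False]
        assert ob.keep_mask.tolist() == [True, False, False]

    def test_identical_masks_unchanged(self):
        a, b = self._pair([True, False, True], [True, False, True])
        oa, ob = synchronize_rejections(a, b)
        assert oa.keep_mask.tolist() == [True, False, True]

    def test_commutative_and_idempotent(self):
        a, b = self._pair([True, True, False], [False, True, True])
        oa, ob = synchronize_rejections(a, b)
        ob2, oa2 = synchronize_rejections(b, a)
        assert np.array_equal(oa.keep_mask, oa2.keep_mask)
        oa3, ob3 = synchronize_rejections(oa, ob)
        assert np.array_equal(oa3.keep_mask, oa.keep_mask)

    def test_trial_count_mismatch_errors(self):
        a = make_epochs(np.zeros((3, 2, 600)))
        b = make_epochs(np.zeros((4, 2, 600)))
        with pytest.raises(ValueError, match="trial counts"):
            synchronize_rejections(a, b)

    def test_joint_removals_at_least_max_of_individual(self, tiny_block,
                                                       analysis_config):
        from interbrain.preprocess import preprocess_recording
        cfg = analysis_config.preprocess
        sp, _ = preprocess_recording(tiny_block.speaker, tiny_block.events,
                                     "prompt", cfg, baseline=False)
        ls, _ = preprocess_recording(tiny_block.listener, tiny_block.events,
                                     "word", cfg)
        ja, jb = synchronize_rejections(sp, ls)
        removed_joint = (~ja.keep_mask).sum()
        assert removed_joint >= max((~sp.keep_mask).sum(),
                                    (~ls.keep_mask).sum())
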