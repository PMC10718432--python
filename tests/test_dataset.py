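import warnings

import numpy as np
import pytest

from reachdyn.dataset import (
    MovementDataset,
    NormalizationStats,
    add_peak_to_peak_noise,
    apply_zscore,
    channel_ranges,
    fit_zscore,
    invert_zscore,
    make_sequence_windows,
    split_dataset,
)


class TestAssembly:
    def test_reduced_feature_count(self, small_corpus):
        # 23 q + q'/q'' of the 3 dynamic DOFs = 29
        assert small_corpus.n_features == 29
        rec = small_corpus.trajectories[0]
        assert small_corpus.reduced_features(rec).shape == (rec.n_samples, 29)

    def test_reduction_excludes_only_zero_channels(self, small_corpus):
        rec = small_corpus.trajectories[0]
        feats = small_corpus.reduced_features(rec)
        # dropped channels are exactly the identically-zero static q'/q''
        dropped = 3 * 23 - 29
        assert dropped == 40
        stat = np.setdiff1d(np.arange(23), small_corpus.dynamic_dofs)
        assert np.all(rec.qd[:, stat] == 0.0)
        assert np.all(rec.qdd[:, stat] == 0.0)

    def test_all_dynamic_reduction_keeps_69(self, small_corpus):
        full = MovementDataset(
            trajectories=small_corpus.trajectories,
            dynamic_dofs=np.arange(23),
        )
        rec = full.trajectories[0]
        assert full.n_features == 69
        assert full.reduced_features(rec).shape[1] == 69

    def test_sample_count_per_duration(self, small_corpus):
        for rec in small_corpus.trajectories:
            assert rec.n_samples == round(rec.duration / rec.dt) + 1

    def test_manifest_counts(self, small_corpus):
        m = small_corpus.manifest
        assert m["n_trajectories"] == len(small_corpus.trajectories)
        assert m["n_state_vectors"] == sum(t.n_samples for t in small_corpus.trajectories)
        assert len(m["feature_layout"]) == 29

    def test_roundtrip_bit_identical(self, split_small_corpus, tmp_path):
        h5 = tmp_path / "ds.h5"
        mf = tmp_path / "manifest.json"
        split_small_corpus.save(h5, mf)
        clone = MovementDataset.load(h5, mf)
        for a, b in zip(split_small_corpus.trajectories, clone.trajectories):
            assert a.traj_id == b.traj_id and a.split == b.split
            for name in ("times", "q", "qd", "qdd", "tau"):
                assert np.array_equal(getattr(a, name), getattr(b, name))


def _copy_dataset(ds):
    import dataclasses

    return MovementDataset(
        trajectories=[dataclasses.replace(t) for t in ds.trajectories],
        dynamic_dofs=ds.dynamic_dofs,
        manifest=dict(ds.manifest),
    )


class TestSplit:
    def test_no_leakage_and_full_partition(self, split_small_corpus):
        ids = {s: {t.traj_id for t in split_small_corpus.records(s)}
               for s in ("train", "val", "test")}
        assert not (ids["train"] & ids["val"]) and not (ids["train"] & ids["test"])
        assert not (ids["val"] & ids["test"])
        assert sum(map(len, ids.values())) == len(split_small_corpus.trajectories)

    def test_every_duration_in_every_split(self, split_small_corpus):
        durations = {t.duration for t in split_small_corpus.trajectories}
        for s in ("train", "val", "test"):
            assert {t.duration for t in split_small_corpus.records(s)} == durations

    def test_stratified_counts_balanced(self, small_corpus):
        ds = split_dataset(_copy_dataset(small_corpus), seed=3)
        for dur in (0.5, 1.0):
            counts = [
                sum(1 for t in ds.records(s) if t.duration == dur)
                for s in ("train", "val", "test")
            ]
            n = sum(counts)
            quota = np.array([0.71, 0.15, 0.14]) * n
            assert all(abs(c - q) <= 1.0 for c, q in zip(counts, quota))

    def test_deterministic_given_seed(self, small_corpus):
        a = split_dataset(_copy_dataset(small_corpus), seed=11)
        assign_a = [t.split for t in a.trajectories]
        b = split_dataset(_copy_dataset(small_corpus), seed=11)
        assert assign_a == [t.split for t in b.trajectories]

    def test_degenerate_fractions(self, small_corpus):
        ds = split_dataset(_copy_dataset(small_corpus), fractions=(1.0, 0.0, 0.0), seed=0)
        assert all(t.split == "train" for t in ds.trajectories)

    def test_invalid_fractions_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            split_dataset(_copy_dataset(small_corpus), fractions=(0.5, 0.2, 0.2), seed=0)


class TestZScore:
    def test_roundtrip_identity(self, rng):
        stats = NormalizationStats.fit(rng.normal(2.0, 3.0, size=(500, 6)))
        x = rng.normal(size=(40, 6))
        np.testing.assert_allclose(invert_zscore(apply_zscore(x, stats), stats), x, atol=1e-12)

    def test_training_split_standardized(self, split_small_corpus):
        stats = fit_zscore(split_small_corpus, "tau")
        tau = np.concatenate([t.tau for t in split_small_corpus.records("train")])
        z = apply_zscore(tau, stats)
        live = ~stats.constant
        assert np.abs(z[:, live].mean(axis=0)).max() < 1e-10
        assert np.abs(z[:, live].std(axis=0) - 1).max() < 1e-10

    def test_constant_channel_flagged_and_passed_through(self):
        x = np.column_stack([np.random.default_rng(0).normal(size=100), np.full(100, 5.0)])
        with pytest.warns(UserWarning, match="constant"):
            stats = NormalizationStats.fit(x)
        assert stats.constant.tolist() == [False, True]
        z = apply_zscore(x, stats)
        np.testing.assert_array_equal(z[:, 1], x[:, 1])

    def test_stats_require_training_split(self, small_corpus):
        import dataclasses

        plain = MovementDataset(
            trajectories=[dataclasses.replace(t, split=None) for t in small_corpus.trajectories],
            dynamic_dofs=small_corpus.dynamic_dofs,
        )
        with pytest.raises(ValueError):
            fit_zscore(plain, "tau")


class TestWindows:
    def test_window_count_conservation(self, split_small_corpus):
        L = 100
        X, Y, meta = make_sequence_windows(split_small_corpus, L, split="test")
        expected = sum(
            max(t.n_samples - L + 1, 0) for t in split_small_corpus.records("test")
        )
        assert X.shape == (expected, L, 29)
        assert Y.shape == (expected, 23)
        assert len(meta) == expected

    def test_single_sample_windows(self, split_small_corpus):
        X, Y, _ = make_sequence_windows(split_small_corpus, 1, split="val")
        total = sum(t.n_samples for t in split_small_corpus.records("val"))
        assert X.shape[0] == total

    def test_windows_never_cross_trajectories(self, split_small_corpus):
        _, _, meta = make_sequence_windows(split_small_corpus, 100, split="test")
        by_traj = {}
        for tid, end in meta:
            by_traj.setdefault(tid, []).append(end)
        for tid, ends in by_traj.items():
            rec = next(t for t in split_small_corpus.records("test") if t.traj_id == tid)
            assert min(ends) == 99 and max(ends) == rec.n_samples - 1

    def test_target_is_final_sample_torque(self, split_small_corpus):
        rec = split_small_corpus.records("test")[0]
        X, Y, meta = make_sequence_windows(split_small_corpus, 50, split="test")
        idx = next(i for i, (tid, end) in enumerate(meta) if tid == rec.traj_id and end == 49)
        np.testing.assert_allclose(Y[idx], rec.tau[49], rtol=1e-5, atol=1e-5)

    def test_too_long_window_warns_and_skips(self, split_small_corpus):
        with pytest.warns(UserWarning, match="shorter"):
            X, _, _ = make_sequence_windows(split_small_corpus, 10_000, split="test")
        assert X.shape[0] == 0

    def test_invalid_length_rejected(self, split_small_corpus):
        with pytest.raises(ValueError):
            make_sequence_windows(split_small_corpus, 0)


class TestNoise:
    def test_zero_fraction_bit_identical(self, rng):
        x = rng.normal(size=(200, 5))
        assert add_peak_to_peak_noise(x, 0.0, np.ones(5), seed=0) is x

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(size=(200, 5))
        a = add_peak_to_peak_noise(x, 0.01, np.ones(5), seed=42)
        b = add_peak_to_peak_noise(x, 0.01, np.ones(5), seed=42)
        assert np.array_equal(a, b)

    def test_noise_sd_scales_with_channel_range(self):
        x = np.zeros((100_000, 2))
        ranges = np.array([2.0, 0.0])
        noisy = add_peak_to_peak_noise(x, 0.01, ranges, seed=7)
        sd = (noisy - x).std(axis=0)
        assert sd[0] == pytest.approx(0.02, rel=0.05)
        assert sd[1] == 0.0  # constant channels receive no noise

    def test_negative_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            add_peak_to_peak_noise(rng.normal(size=(5, 2)), -0.1, np.ones(2), seed=0)

    def test_channel_ranges_match_split_extremes(self, split_small_corpus):
        ranges = channel_ranges(split_small_corpus, split="test")
        feats = np.concatenate(
            [split_small_corpus.reduced_features(t) for t in split_small_corpus.records("test")]
        )
        np.testing.assert_allclose(ranges, np.ptp(feats, axis=0))
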