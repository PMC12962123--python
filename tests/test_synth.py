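"""Generator contracts: schedules, ratings, images, epochs, determinism."""

import numpy as np
import pytest
from scipy import stats

import facedecode as fd
from facedecode.synth import ConfigError, CoverageError, null_config, response_gate


class TestSchedule:
    def test_full_scale_design_counts(self):
        cfg = fd.SimConfig(seed=1)
        sched = fd.build_schedule(cfg)
        assert len(sched) == 10_800
        assert sched["sequence"].nunique() == 72
        assert sched["block"].nunique() == 12
        per_block = sched.groupby("block")["stimulus_id"].nunique()
        assert (per_block == 900).all()
        # every block is a permutation: each stimulus exactly once
        counts = sched.groupby(["block", "stimulus_id"]).size()
        assert (counts == 1).all()

    def test_miniature_design(self):
        cfg = fd.SimConfig.desk_scale(
            n_stimuli=6, n_human=6, trials_per_sequence=3, sequences_per_block=2, n_blocks=2
        )
        sched = fd.build_schedule(cfg)
        assert len(sched) == 12
        assert (sched.groupby("stimulus_id").size() == 2).all()

    def test_per_block_multiset_equals_catalog(self, tiny_cfg):
        sched = fd.build_schedule(tiny_cfg)
        for _, blk in sched.groupby("block"):
            assert sorted(blk["stimulus_id"]) == list(range(tiny_cfg.n_stimuli))

    def test_inconsistent_counts_rejected(self):
        cfg = fd.SimConfig.desk_scale(n_stimuli=7)
        with pytest.raises(ConfigError):
            fd.build_schedule(cfg)


class TestRatings:
    def test_default_row_count(self):
        cfg = fd.SimConfig(seed=2)
        table = fd.simulate_ratings(fd.make_catalog(cfg), cfg, "valence")
        assert len(table) == 60 * 300
        assert table["stimulus_id"].nunique() == 900  # full coverage
        assert table["rating"].between(1, 9).all()

    def test_each_rater_exact_quota(self, tiny_cfg):
        table = fd.simulate_ratings(fd.make_catalog(tiny_cfg), tiny_cfg, "sex")
        per_rater = table.groupby("rater_id").size()
        assert (per_rater == tiny_cfg.ratings_per_rater).all()
        # subsets without replacement: no duplicate stimulus within a rater
        assert not table.duplicated(["rater_id", "stimulus_id"]).any()

    def test_noiseless_ratings_monotone_in_latent(self):
        cfg = fd.SimConfig.desk_scale(rater_noise_sd=0.0, n_raters_valence=4, ratings_per_rater=20, seed=5)
        catalog = fd.make_catalog(cfg)
        table = fd.simulate_ratings(catalog, cfg, "valence")
        means = table.groupby("stimulus_id")["rating"].mean()
        latent = catalog.set_index("stimulus_id")["latent_valence"].loc[means.index].to_numpy()
        order = np.argsort(latent)
        assert np.all(np.diff(means.to_numpy()[order]) >= 0)  # weakly monotone
        # exact oracle: without rater noise the mean rating is the
        # deterministic scale transform of the latent, ties and all
        expected = np.floor(np.clip(5.0 + cfg.latent_scale * latent, 1, 9) + 0.5)  # half-away rounding
        assert stats.spearmanr(means, latent).statistic == pytest.approx(
            stats.spearmanr(expected, latent).statistic
        )

    def test_negative_latent_correlation_recovered(self):
        cfg = fd.SimConfig(
            n_stimuli=300, n_human=280, trials_per_sequence=150, sequences_per_block=2,
            n_raters_valence=80, n_raters_sex=80, ratings_per_rater=150,
            latent_correlation=-0.3, rater_noise_sd=0.5, seed=11,
        )
        catalog = fd.make_catalog(cfg)
        v = fd.simulate_ratings(catalog, cfg, "valence").groupby("stimulus_id")["rating"].mean()
        s = fd.simulate_ratings(catalog, cfg, "sex").groupby("stimulus_id")["rating"].mean()
        assert stats.spearmanr(v, s).statistic < 0

    def test_impossible_coverage_raises(self):
        cfg = fd.SimConfig.desk_scale(n_raters_valence=1, ratings_per_rater=5)
        with pytest.raises(CoverageError):
            fd.simulate_ratings(fd.make_catalog(cfg), cfg, "valence")


class TestImages:
    def test_class_luminance_offset_round_trip(self):
        from facedecode.image_stats import basic_stats

        cfg = fd.SimConfig.desk_scale(seed=9, n_stimuli=40, n_human=20, trials_per_sequence=20)
        cfg.images.class_luminance = {"human": 140.0, "nonhuman": 110.0}
        cfg.images.class_contrast = {"human": 10.0, "nonhuman": 10.0}
        catalog = fd.make_catalog(cfg)
        images = fd.simulate_images(catalog, cfg)
        lums = {cat: [] for cat in ("human", "nonhuman")}
        for _, row in catalog.iterrows():
            lums[row["category"]].append(basic_stats(images[row["stimulus_id"]])[0])
        measured_delta = np.mean(lums["human"]) - np.mean(lums["nonhuman"])
        assert measured_delta == pytest.approx(30.0, abs=3.0)

    def test_constant_image_config_zero_contrast(self):
        from facedecode.image_stats import basic_stats

        cfg = fd.SimConfig.desk_scale(n_stimuli=4, n_human=4, trials_per_sequence=2)
        cfg.images.class_luminance = {"human": 128.0, "nonhuman": 128.0}
        cfg.images.class_contrast = {"human": 0.0, "nonhuman": 0.0}
        images = fd.simulate_images(fd.make_catalog(cfg), cfg)
        lum, con = basic_stats(images[0])
        assert (lum, con) == (128.0, 0.0)

    def test_lowfreq_class_elevates_low_band(self):
        from facedecode.image_stats import radial_sf_bands

        cfg = fd.SimConfig.desk_scale(seed=13, n_stimuli=20, n_human=10, trials_per_sequence=10)
        cfg.images.class_lowfreq_amplitude = {"human": 60.0, "nonhuman": 0.0}
        cfg.images.class_contrast = {"human": 5.0, "nonhuman": 5.0}
        catalog = fd.make_catalog(cfg)
        images = fd.simulate_images(catalog, cfg)
        low = {cat: [] for cat in ("human", "nonhuman")}
        for _, row in catalog.iterrows():
            low[row["category"]].append(radial_sf_bands(images[row["stimulus_id"]])[0])
        assert np.mean(low["human"]) > 2 * np.mean(low["nonhuman"])

    def test_small_image_rejected(self):
        cfg = fd.SimConfig.desk_scale()
        cfg.images.size = 16
        with pytest.raises(ConfigError):
            fd.simulate_images(fd.make_catalog(fd.SimConfig.desk_scale()), cfg)


class TestEpochs:
    def test_prestimulus_is_noise_only(self, tiny_world):
        """Mean over many trials of the pre-stimulus window shrinks toward 0."""
        epochs = tiny_world["epochs"]
        pre = epochs.data[:, :, epochs.times < 0]
        grand = np.abs(pre.mean(axis=0)).mean()
        assert grand < 4 * pre.std() / np.sqrt(epochs.n_trials)

    def test_signal_starts_at_injected_onset(self, tiny_cfg):
        from dataclasses import replace

        cfg = replace(
            tiny_cfg,
            class_effect={"valence": fd.ClassEffect(80.0, 120.0, amplitude=4.0)},
            image_effect_amplitude=0.0,
        )
        catalog = fd.make_catalog(cfg)
        epochs, truth = fd.simulate_epochs(catalog, fd.build_schedule(cfg), cfg, subject_seed=21)
        # variance across per-stimulus mean patterns isolates the evoked signal
        stim = epochs.events["stimulus_id"].to_numpy()
        cond = np.stack([epochs.data[stim == s].mean(axis=0) for s in np.unique(stim)])
        var = cond.var(axis=0).mean(axis=0)
        pre = epochs.times < 0
        post = (epochs.times > 100) & (epochs.times < 140)
        assert var[post].mean() > 5 * var[pre].mean()
        # nothing before the injected onset
        before_onset = (epochs.times > 0) & (epochs.times < truth.onset_ms["valence"] - 5)
        assert var[before_onset].mean() < 2 * var[pre].mean()

    def test_bit_identical_under_same_seed(self, tiny_world):
        cfg, catalog, schedule = tiny_world["cfg"], tiny_world["catalog"], tiny_world["schedule"]
        a, _ = fd.simulate_epochs(catalog, schedule, cfg, subject_seed=99)
        assert np.array_equal(a.data, tiny_world["epochs"].data)
        b, _ = fd.simulate_epochs(catalog, schedule, cfg, subject_seed=100)
        assert not np.array_equal(a.data, b.data)

    def test_ground_truth_serializes(self, tiny_world, tmp_path):
        import json

        tiny_world["truth"].save(tmp_path / "gt.json")
        gt = json.loads((tmp_path / "gt.json").read_text())
        assert gt["onset_ms"]["valence"] == tiny_world["cfg"].class_effect["valence"].onset_ms

    def test_invalid_class_effect_timing_rejected(self):
        with pytest.raises(ConfigError):
            fd.SimConfig.desk_scale(class_effect={"valence": fd.ClassEffect(onset_ms=120, peak_ms=100)}).validate()
        with pytest.raises(ConfigError):
            fd.SimConfig.desk_scale(class_effect={"valence": fd.ClassEffect(onset_ms=-5, peak_ms=100)}).validate()

    def test_gate_shape(self):
        t = np.linspace(-100, 500, 601)
        g = response_gate(t, 80.0, 120.0, decay_tau_ms=100.0)
        assert g[t < 80].max() == 0.0
        assert g[np.searchsorted(t, 120)] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(g[(t >= 80) & (t <= 120)]) >= 0)
        assert g[t > 120][-1] < 0.05  # decays away

    def test_null_config_zeroes_all_amplitudes(self, tiny_cfg):
        cfg = null_config(tiny_cfg)
        assert cfg.image_effect_amplitude == 0.0
        assert all(e.amplitude == 0.0 for e in cfg.class_effect.values())
        # and the original is untouched
        assert any(e.amplitude != 0.0 for e in tiny_cfg.class_effect.values())
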