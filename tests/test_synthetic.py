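import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from concertsync import (
    AudienceSpec,
    Channel,
    ROI,
    generate_audience,
    generate_frames,
    generate_traits,
    generate_zeitgeber,
    motion_energy_series,
)
from concertsync.synthetic import BASE_RATE, TRAIT_COLUMNS, write_audience


class TestZeitgeber:
    def test_same_seed_identical(self):
        z1 = generate_zeitgeber(120, seed=9)
        z2 = generate_zeitgeber(120, seed=9)
        np.testing.assert_array_equal(z1.values, z2.values)

    def test_standardized(self):
        z = generate_zeitgeber(300, seed=1)
        assert abs(z.values.mean()) < 1e-6
        assert abs(z.values.var() - 1.0) < 1e-6

    def test_slow_autocorrelation(self):
        z = generate_zeitgeber(600, seed=2).values
        lag = int(BASE_RATE)  # 1 s
        r = pearsonr(z[:-lag], z[lag:]).statistic
        assert r > 0.5

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_zeitgeber(30, seed=0)


class TestAudience:
    def test_deterministic_under_seed(self, tmp_path):
        spec = lambda: AudienceSpec(m=4, duration_s=120, seed=13, missing_rate=0.05)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_audience(d1, spec())
        write_audience(d2, spec())
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_uncoupled_audience_uncorrelated(self):
        corr = []
        for seed in range(3):
            spec = AudienceSpec(m=15, duration_s=300, seed=seed,
                                gains=np.zeros(15), channels=(Channel.HR,))
            channels, _ = generate_audience(spec)
            hr = channels[Channel.HR]
            for i in range(15):
                for j in range(i + 1, 15):
                    corr.append(
                        pearsonr(hr[i].values, hr[j].values).statistic
                    )
        assert -0.1 < float(np.mean(corr)) < 0.1

    def test_perfect_coupling_identical_channels(self):
        spec = AudienceSpec(
            m=2, duration_s=120, seed=3,
            gains=np.ones(2), lags_s=np.zeros(2),
            channels=(Channel.HR,),
        )
        channels, _ = generate_audience(spec)
        a, b = channels[Channel.HR]
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_lag_recovered_by_cross_correlation(self):
        spec = AudienceSpec(
            m=2, duration_s=600, seed=4,
            gains=np.array([0.8, 0.8]), lags_s=np.array([0.0, 2.0]),
            channels=(Channel.HR,),
        )
        channels, _ = generate_audience(spec)
        a, b = (s.values for s in channels[Channel.HR])
        best_lag, best_r = None, -np.inf
        for tau in range(-5, 6):
            if tau >= 0:
                r = pearsonr(a[: len(a) - tau], b[tau:]).statistic
            else:
                r = pearsonr(a[-tau:], b[: len(a) + tau]).statistic
            if r > best_r:
                best_lag, best_r = tau, r
        # b lags a by 2 s: a(t) aligns with b(t + 2)
        assert best_lag == 2

    def test_variance_budget_constant_in_gain(self):
        sds = []
        for g in (0.0, 0.8):
            spec = AudienceSpec(m=3, duration_s=300, seed=6,
                                gains=np.full(3, g), channels=(Channel.HR,))
            channels, _ = generate_audience(spec)
            sds.append(np.mean([s.values.std() for s in channels[Channel.HR]]))
        assert sds[1] == pytest.approx(sds[0], rel=0.1)

    def test_channel_ranges(self):
        spec = AudienceSpec(m=3, duration_s=300, seed=7)
        channels, _ = generate_audience(spec)
        for s in channels[Channel.HR]:
            assert 40 < np.nanmin(s.values) and np.nanmax(s.values) < 120
        for s in channels[Channel.SCR]:
            assert np.nanmin(s.values) >= 0
        for s in channels[Channel.MOVE]:
            assert np.nanmin(s.values) >= 0
        for s in channels[Channel.RESP]:
            assert abs(np.nanmean(s.values)) < 0.2
        assert channels[Channel.RESP][0].rate == 10.0
        assert channels[Channel.MOVE][0].rate == 15.0

    def test_missingness_in_contiguous_blocks(self):
        spec = AudienceSpec(m=2, duration_s=300, seed=8, missing_rate=0.2)
        channels, _ = generate_audience(spec)
        s = channels[Channel.HR][0]
        frac = np.isnan(s.values).mean()
        assert 0.1 < frac < 0.35
        # contiguity: few transitions relative to missing count
        miss = np.isnan(s.values).astype(int)
        transitions = np.abs(np.diff(miss)).sum()
        assert transitions <= 2 * max(1, round(miss.sum() / (10 * s.rate)) + 1) + 2

    def test_piece_outside_duration_rejected(self):
        from concertsync import SessionLayout

        layout = SessionLayout("c", [("a", 0, 400)])
        with pytest.raises(ValueError, match="outside duration"):
            AudienceSpec(m=3, duration_s=300, layout=layout)


class TestTraits:
    def test_perfect_target_gives_rank_one(self):
        gains = np.random.default_rng(0).uniform(0, 1, 40)
        traits = generate_traits(gains, target_r=1.0, seed=1)
        rho = spearmanr(gains, traits["openness"]).statistic
        assert rho == pytest.approx(1.0)

    def test_zero_target_weak_correlation(self):
        gains = np.random.default_rng(1).uniform(0, 1, 40)
        traits = generate_traits(gains, target_r=0.0, seed=2)
        assert abs(pearsonr(gains, traits["openness"]).statistic) < 0.3

    def test_moderate_target_mean_correlation(self):
        rs = []
        for seed in range(30):
            gains = np.random.default_rng(seed).uniform(0, 1, 40)
            traits = generate_traits(gains, target_r=0.4, seed=seed)
            rs.append(pearsonr(gains, traits["openness"]).statistic)
        assert 0.25 < float(np.mean(rs)) < 0.55

    def test_scale_bounds(self):
        gains = np.random.default_rng(3).uniform(0, 1, 25)
        traits = generate_traits(gains, target_r=0.4, seed=4)
        for col in TRAIT_COLUMNS:
            assert traits[col].between(1, 5).all()
        for col in ("positive_activation", "negative_activation", "valence"):
            assert traits[col].between(1, 7).all()


class TestFrames:
    def _move(self, values, pid="p0"):
        from concertsync import UniformSeries

        return UniformSeries(pid, Channel.MOVE, 15.0, np.asarray(values, dtype=float))

    def test_zero_motion_gives_static_stack(self):
        rois = [ROI("p0", 10, 10, 40, 40)]
        stack = generate_frames([self._move(np.zeros(50))], rois)
        series = motion_energy_series(stack, rois, threshold=5)[0]
        assert np.all(series.values == 0)

    def test_motion_confined_to_own_roi(self):
        rois = [ROI("p0", 0, 0, 60, 60), ROI("p1", 70, 0, 130, 60)]
        moves = [self._move(np.abs(np.sin(np.arange(50))) * 30, "p0"),
                 self._move(np.zeros(50), "p1")]
        stack = generate_frames(moves, rois, image_size=(80, 140))
        series = motion_energy_series(stack, rois, threshold=5)
        assert series[0].values.sum() > 0
        assert np.all(series[1].values == 0)

    def test_round_trip_rank_correlation(self):
        rng = np.random.default_rng(11)
        move = np.abs(rng.normal(0, 1, 150)) * 20
        rois = [ROI("p0", 10, 20, 90, 70)]
        stack = generate_frames([self._move(move)], rois, image_size=(100, 110))
        recovered = motion_energy_series(stack, rois, threshold=5)[0]
        rho = spearmanr(move, recovered.values).statistic
        assert rho >= 0.8

    def test_overlapping_rois_rejected(self):
        rois = [ROI("a", 0, 0, 50, 50), ROI("b", 40, 40, 90, 90)]
        with pytest.raises(ValueError, match="overlap"):
            generate_frames([self._move(np.zeros(10), "a"),
                             self._move(np.zeros(10), "b")], rois)
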