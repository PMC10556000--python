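import math

import numpy as np
import pytest

from concertsync import (
    Channel,
    SessionLayout,
    SusyConfig,
    UniformSeries,
    audience_susy,
    segment_cross_z,
    segment_series,
    susy_dyad,
)

from _reference import susy_es_bruteforce


def _series(values, rate=1.0, pid="p", channel=Channel.HR):
    return UniformSeries(pid, channel, rate, np.asarray(values, dtype=float))


class TestSegmentation:
    def test_trailing_partial_dropped(self):
        segs = segment_series(_series(np.arange(95)), 30.0)
        assert len(segs) == 3
        assert all(len(s.values) == 30 for s in segs)

    def test_missing_invalidates_segment(self):
        x = np.arange(60.0)
        x[10] = np.nan
        segs = segment_series(_series(x), 30.0)
        assert not segs[0].valid
        assert segs[1].valid

    def test_high_rate_segments(self):
        segs = segment_series(_series(np.zeros(900), rate=10.0), 30.0)
        assert len(segs) == 3
        assert all(len(s.values) == 300 for s in segs)

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="shorter than one segment"):
            segment_series(_series(np.arange(20)), 30.0)


class TestSegmentCrossZ:
    def test_perfect_correlation_clipped(self):
        ramp = np.arange(1.0, 31.0)
        z = segment_cross_z(ramp, ramp, max_lag_samples=0)
        assert z == pytest.approx(math.atanh(1 - 1e-6))
        assert z == pytest.approx(7.2543, abs=1e-3)

    def test_known_half_correlation(self):
        # construct y with exact lag-0 Pearson correlation 0.5 to x
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        x = (x - x.mean()) / x.std()
        e = rng.normal(size=30)
        e -= e.mean()
        e -= (e @ x) / (x @ x) * x  # orthogonalize against x
        e /= e.std()
        y = 0.5 * x + math.sqrt(1 - 0.25) * e
        z = segment_cross_z(x, y, max_lag_samples=0)
        assert z == pytest.approx(math.atanh(0.5), abs=1e-12)
        assert z == pytest.approx(0.5493, abs=1e-4)

    def test_matches_double_loop_oracle(self, rng):
        from scipy.stats import pearsonr

        for _ in range(10):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            expected = []
            for tau in range(-5, 6):
                if tau >= 0:
                    r = pearsonr(a[: 30 - tau], b[tau:]).statistic
                else:
                    r = pearsonr(a[-tau:], b[: 30 + tau]).statistic
                r = np.clip(r, -(1 - 1e-6), 1 - 1e-6)
                expected.append(math.atanh(r))
            assert segment_cross_z(a, b, 5) == pytest.approx(
                np.mean(expected), abs=1e-12
            )

    def test_zero_variance_overlap_flagged_nan(self):
        a = np.ones(30)
        b = np.arange(30.0)
        assert math.isnan(segment_cross_z(a, b, 2))


class TestSusyDyad:
    def test_constant_members_flagged_missing(self):
        a = _series(np.ones(300), pid="a")
        b = _series(np.ones(300), pid="b")
        res = susy_dyad(a, b)
        assert res.missing

    def test_symmetry(self, rng):
        a = _series(rng.normal(size=300), pid="a")
        b = _series(rng.normal(size=300), pid="b")
        r_ab = susy_dyad(a, b)
        r_ba = susy_dyad(b, a)
        assert r_ab.es == pytest.approx(r_ba.es, abs=1e-12)
        assert r_ab.z_real == pytest.approx(r_ba.z_real, abs=1e-12)

    def test_es_zero_when_real_equals_surrogate_mean(self):
        # definition check via the components returned
        rng = np.random.default_rng(2)
        a = _series(rng.normal(size=300), pid="a")
        b = _series(rng.normal(size=300), pid="b")
        res = susy_dyad(a, b)
        assert res.es == pytest.approx(
            (res.z_real - res.z_surr_mean) / res.z_surr_sd, abs=1e-12
        )

    def test_surrogate_stats_invariant_to_joint_segment_shuffle(self, rng):
        vals_a = rng.normal(size=300)
        vals_b = rng.normal(size=300)
        res = susy_dyad(_series(vals_a, pid="a"), _series(vals_b, pid="b"))
        perm = rng.permutation(10)
        shuf_a = np.concatenate([vals_a[i * 30 : (i + 1) * 30] for i in perm])
        shuf_b = np.concatenate([vals_b[i * 30 : (i + 1) * 30] for i in perm])
        res_shuf = susy_dyad(_series(shuf_a, pid="a"), _series(shuf_b, pid="b"))
        assert res_shuf.z_surr_mean == pytest.approx(res.z_surr_mean, abs=1e-12)
        assert res_shuf.z_real == pytest.approx(res.z_real, abs=1e-12)

    def test_white_noise_null_mean_es_near_zero(self):
        # 100 independent dyads: the mean effect size under no coupling
        es = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = _series(rng.normal(size=300), pid="a")
            b = _series(rng.normal(size=300), pid="b")
            r = susy_dyad(a, b)
            assert not r.missing
            es.append(r.es)
        assert -0.15 < float(np.mean(es)) < 0.15

    def test_missing_segments_excluded(self, rng):
        vals_a = rng.normal(size=300)
        vals_b = rng.normal(size=300)
        vals_a[5] = np.nan  # invalidates segment 0 of a
        res = susy_dyad(_series(vals_a, pid="a"), _series(vals_b, pid="b"))
        assert res.n_valid_segments == 9
        assert not res.missing

    def test_matches_bruteforce_reference(self, rng):
        a_vals = rng.normal(size=300)
        b_vals = rng.normal(size=300)
        res = susy_dyad(_series(a_vals, pid="a"), _series(b_vals, pid="b"))
        z, sm, sd, es = susy_es_bruteforce(a_vals, b_vals, 1.0, 30.0, 5.0)
        assert res.z_real == pytest.approx(z, abs=1e-10)
        assert res.es == pytest.approx(es, abs=1e-10)


class TestAudienceSusy:
    def test_two_participants_single_dyad(self, rng):
        a = _series(rng.normal(size=300), pid="a")
        b = _series(rng.normal(size=300), pid="b")
        res = audience_susy([a, b])
        assert set(res) == {"all", "concert"}
        assert list(res["concert"]) == [("a", "b")]
        assert res["concert"][("a", "b")].es == pytest.approx(susy_dyad(a, b).es)

    def test_compositional_equality_with_dyad_calls(self, small_coupled_audience):
        channels, _ = small_coupled_audience
        hr = channels[Channel.HR]
        res = audience_susy(hr)["concert"]
        for (ia, ib), d in res.items():
            sa = next(s for s in hr if s.participant_id == ia)
            sb = next(s for s in hr if s.participant_id == ib)
            assert d.es == pytest.approx(susy_dyad(sa, sb).es, abs=1e-12)

    def test_participant_order_irrelevant(self, small_coupled_audience):
        channels, _ = small_coupled_audience
        hr = channels[Channel.HR]
        res_fwd = audience_susy(hr)["concert"]
        res_rev = audience_susy(hr[::-1])["concert"]
        assert set(res_fwd) == set(res_rev)
        for key in res_fwd:
            assert res_fwd[key].es == pytest.approx(res_rev[key].es, abs=1e-12)

    def test_piece_scopes_use_piece_segments(self, rng):
        layout = SessionLayout("c", [("p1", 0, 120), ("p2", 150, 300)])
        a = _series(rng.normal(size=300), pid="a")
        b = _series(rng.normal(size=300), pid="b")
        res = audience_susy([a, b], layout=layout)
        assert set(res) == {"p1", "p2", "concert"}
        assert res["p1"][("a", "b")].n_segments == 4
        assert res["p2"][("a", "b")].n_segments == 5
        assert res["concert"][("a", "b")].n_segments == 9

    def test_config_validation(self):
        with pytest.raises(ValueError, match="segment_s"):
            SusyConfig(segment_s=8.0, max_lag_s=5.0)
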