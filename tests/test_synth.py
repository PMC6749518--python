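"""The synthetic-data generators: cohorts, streams, features, SAQ,
noiseless window datasets."""

import numpy as np
import pytest

from audass.decision import SignatureRules
from audass.levels import (
    AU_INDEX,
    INTENSITY_VALUES,
    SCALES,
    SeverityBand,
)
from audass.matrix import windows_from_frames
from audass.network import BAND_MIDPOINTS
from audass.saq import band_raw_score, score_scale
from audass.synth import (
    DISORDER_SCALE,
    GeneratorConfig,
    SubjectProfile,
    generate_au_stream,
    generate_cohort,
    generate_cohort_samples,
    generate_saq,
    generate_window_dataset,
    signature_burst_probability,
    walk_session_bands,
)

SIG = SignatureRules().signatures


def _uniform_profile(band):
    return SubjectProfile(subject_id="t", bands={s: band for s in SCALES})


class TestCohort:
    def test_fixed_seed_reproduces_cohort(self):
        a = generate_cohort(32, seed=4)
        b = generate_cohort(32, seed=4)
        assert a == b

    def test_single_subject_is_valid(self):
        (p,) = generate_cohort(1, seed=0)
        assert set(p.bands) == set(SCALES)

    def test_requested_marginal_fraction_within_sampling_error(self):
        dist = [0.2, 0.2, 0.2, 0.2, 0.2]
        n = 10_000
        cohort = generate_cohort(n, band_distribution=dist, seed=1,
                                 disorder_rates={"MDD": 0, "GAD": 0,
                                                 "PTSD": 0})
        frac = np.mean([p.bands["depression"] == SeverityBand.EXTREMELY_SEVERE
                        for p in cohort])
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * se

    def test_disorders_mutually_exclusive_and_band_consistent(self):
        cohort = generate_cohort(400, seed=7)
        n_disorder = 0
        for p in cohort:
            if p.disorder is not None:
                n_disorder += 1
                assert p.bands[DISORDER_SCALE[p.disorder]] >= SeverityBand.SEVERE
        # expected prevalence (20+19+17)/128 = 43.75%
        assert 0.3 < n_disorder / 400 < 0.6

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError, match="band_distribution"):
            generate_cohort(5, band_distribution=[0.5, 0.5, 0.5, 0, 0])


class TestSessionWalk:
    def test_mean_absolute_step_matches_walk_probability(self):
        profile = _uniform_profile(SeverityBand.MODERATE)
        steps = []
        for seed in range(200):
            s = walk_session_bands(profile, 2, seed=seed)
            steps.extend(abs(int(s[1][sc]) - int(s[0][sc])) for sc in SCALES)
        # one +/-1 step with probability 0.4 (minus clipping at the edges)
        assert 0.3 < np.mean(steps) < 0.5

    def test_first_session_equals_profile(self):
        profile = _uniform_profile(SeverityBand.MILD)
        s = walk_session_bands(profile, 3, seed=0)
        assert s[0] == profile.bands


class TestAUStream:
    def test_frame_count_is_duration_times_fps(self):
        frames = generate_au_stream(
            _uniform_profile(SeverityBand.NORMAL), None,
            GeneratorConfig(duration=60.0), seed=0)
        assert len(frames) == 1800
        assert frames[-1].timestamp == pytest.approx(1799 / 30)

    def test_same_seed_reproduces_stream(self):
        cfg = GeneratorConfig(duration=2.0)
        p = _uniform_profile(SeverityBand.SEVERE)
        a = generate_au_stream(p, "fear", cfg, seed=3)
        b = generate_au_stream(p, "fear", cfg, seed=3)
        assert all(x.levels == y.levels for x, y in zip(a, b))

    def test_unknown_emotion_rejected(self):
        with pytest.raises(ValueError, match="unknown emotion"):
            generate_au_stream(_uniform_profile(SeverityBand.NORMAL),
                               "boredom", GeneratorConfig(), seed=0)

    def test_burst_probability_monotone_in_rank(self):
        cfg = GeneratorConfig()
        probs = [signature_burst_probability(r, cfg) for r in range(5)]
        assert probs[0] == 0.0
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert probs[4] >= 0.9

    def _full_signature_window_rate(self, band, scale, n_streams, seed0):
        cfg = GeneratorConfig(duration=4.0)
        rows = [AU_INDEX[au] for au in SIG[scale]]
        hits = total = 0
        for k in range(n_streams):
            frames = generate_au_stream(_uniform_profile(band), None, cfg,
                                        seed=seed0 + k)
            for w in windows_from_frames(frames):
                total += 1
                hits += all((w.values[r] >= 0.8).any() for r in rows)
        return hits / total

    def test_severe_profiles_show_signature_more_than_normal(self):
        r_es = self._full_signature_window_rate(
            SeverityBand.EXTREMELY_SEVERE, "depression", 50, 0)
        r_no = self._full_signature_window_rate(
            SeverityBand.NORMAL, "depression", 50, 900)
        assert r_es > 0.8
        assert r_no < 0.05
        assert r_es > r_no

    def test_normal_profile_co_occurrence_matches_independence(self):
        # under a Normal profile the four signature AUs only reach D/E via
        # independent baseline flicker; the all-four-in-window rate should
        # match the independence prediction within binomial error
        cfg = GeneratorConfig(duration=4.0)
        p_frame = cfg.baseline_activation * 0.15  # P(level >= D | baseline)
        p_au = 1 - (1 - p_frame) ** 30
        expected = p_au ** 4
        rate = self._full_signature_window_rate(
            SeverityBand.NORMAL, "stress", 200, 5000)
        n = 200 * 4
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 4 * se + 1e-4

    def test_signal_monotone_in_severity_rank(self):
        rates = [
            self._full_signature_window_rate(band, "stress", 30, 100 * int(band))
            for band in SeverityBand
        ]
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))


class TestSAQGeneration:
    @pytest.mark.parametrize("band,scale,check", [
        (SeverityBand.EXTREMELY_SEVERE, "depression", lambda r: r >= 28),
        (SeverityBand.NORMAL, "anxiety", lambda r: r <= 7),
    ])
    def test_band_interval_respected(self, band, scale, check):
        for seed in range(10):
            resp = generate_saq(_uniform_profile(band), seed=seed)
            assert check(score_scale(resp, scale))

    def test_round_trip_rebands_to_profile(self, rng):
        for seed in range(30):
            r = np.random.default_rng(seed)
            bands = {s: SeverityBand(int(r.integers(1, 6))) for s in SCALES}
            resp = generate_saq(bands, seed=seed)
            for s in SCALES:
                assert band_raw_score(s, score_scale(resp, s)) == bands[s]

    def test_deterministic(self):
        p = _uniform_profile(SeverityBand.SEVERE)
        assert generate_saq(p, seed=3) == generate_saq(p, seed=3)


class TestWindowDataset:
    def test_values_stay_on_the_normalized_grid(self):
        windows, _, _ = generate_window_dataset(20, seed=0)
        allowed = set(INTENSITY_VALUES)
        for w in windows:
            assert set(np.unique(w.values)) <= allowed

    def test_targets_are_band_midpoints(self):
        _, targets, triples = generate_window_dataset(50, seed=1)
        for t, triple in zip(targets, triples):
            assert t.tolist() == [BAND_MIDPOINTS[b] for b in triple]

    def test_signature_mean_affine_in_target(self):
        # the window mean of each scale's distinctive signature AU is an
        # affine function of the band-midpoint target
        windows, targets, _ = generate_window_dataset(100, seed=2)
        unique_au = {"depression": "AU26", "anxiety": "AU2", "stress": "AU1"}
        for k, scale in enumerate(SCALES):
            row = AU_INDEX[unique_au[scale]]
            means = np.array([w.values[row].mean() for w in windows])
            assert np.allclose(targets[:, k], 0.075 + 7.5 * means)

    def test_deterministic_and_distinct(self):
        w1, t1, _ = generate_window_dataset(10, seed=3)
        w2, t2, _ = generate_window_dataset(10, seed=3)
        assert np.array_equal(t1, t2)
        for a, b in zip(w1, w2):
            assert np.array_equal(a.values, b.values)


class TestCohortSamples:
    def test_sample_inventory_and_truth_alignment(self):
        cohort, samples = generate_cohort_samples(
            2, n_sessions=2, cfg=GeneratorConfig(duration=1.0), seed=0,
            emotions=("sadness",), n_dsr=1)
        assert len(samples) == 2 * 2 * (1 + 1)
        by_subject = {p.subject_id: p for p in cohort}
        for s in samples:
            assert s.subject_id in by_subject
            assert len(s.truth) == 3
            assert s.dataset in ("DSC", "DSR")
            assert (s.emotion is None) == (s.dataset == "DSR")
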