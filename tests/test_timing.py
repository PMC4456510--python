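"""Response times, shuffled nulls, distribution summaries, KS and KL."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virduet import (Bout, DuetParams, DistributionSummary, ResponseTimeSet,
                     assemble_bouts, kl_divergence, ks_compare, response_times,
                     shuffle_null, simulate_duet, summarize_distribution)


def male_bouts(onsets, n=5, ipi=0.0212):
    return [Bout(o, o + (n - 1) * ipi, "M", o + np.arange(n) * ipi)
            for o in onsets]


class TestResponseTimes:
    def test_female_latency_after_bout_onset(self):
        bouts = male_bouts([1.0, 3.0])
        rts = response_times(bouts, np.array([1.409, 3.409]),
                             "female_after_male_onset")
        assert np.allclose(rts.latencies, [0.409, 0.409])

    def test_male_latency_back_to_last_female_pulse(self):
        bouts = male_bouts([5.0])
        female = np.array([4.70, 4.76, 4.82, 4.890])
        rts = response_times(bouts, female, "male_onset_after_female_pulse",
                             reference_pulse="last")
        assert np.allclose(rts.latencies, [0.110])

    def test_reference_pulse_selection(self):
        bouts = male_bouts([5.0])
        female = np.array([4.70, 4.76, 4.82, 4.890])
        for ref, expect in (("first", 0.30), ("second", 0.24),
                            ("penultimate", 0.18), ("last", 0.110)):
            rts = response_times(bouts, female, "male_onset_after_female_pulse",
                                 reference_pulse=ref)
            assert np.allclose(rts.latencies, [expect]), ref

    def test_event_beyond_window_not_emitted(self):
        bouts = male_bouts([1.0])
        rts = response_times(bouts, np.array([2.6]), "female_after_male_onset")
        assert rts.n == 0

    def test_bout_without_preceding_train_skipped(self):
        bouts = male_bouts([0.5])
        rts = response_times(bouts, np.array([2.0]),
                             "male_onset_after_female_pulse")
        assert rts.n == 0

    def test_offset_direction_ignores_overlaps(self):
        bouts = male_bouts([1.0])
        off = bouts[0].offset
        # one pulse inside the bout (overlap), one after the offset
        female = np.array([1.02, off + 0.2])
        rts = response_times(bouts, female, "female_after_male_offset")
        assert np.allclose(rts.latencies, [0.2])

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            response_times([], np.array([]), "sideways")


class TestShuffleNull:
    def test_identical_intervals_are_invariant(self):
        times = np.arange(10) * 0.5
        out = shuffle_null(times, "female_ipis", seed=3)
        assert np.allclose(out, times)

    def test_total_span_preserved(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.exponential(0.3, 50))
        out = shuffle_null(times, "female_ipis", seed=1)
        assert out[0] == pytest.approx(times[0])
        assert out[-1] == pytest.approx(times[-1])
        assert np.allclose(np.sort(np.diff(out)), np.sort(np.diff(times)))

    def test_male_ibi_shuffle_keeps_bout_structure(self):
        bouts = male_bouts([1.0, 3.0, 6.0, 10.0])
        out = shuffle_null(bouts, "male_ibis", seed=2)
        for o in out:
            assert np.allclose(np.diff(o.pulse_centers), 0.0212)
        gaps = sorted(round(out[i + 1].onset - out[i].offset, 6)
                      for i in range(3))
        expect = sorted(round(bouts[i + 1].onset - bouts[i].offset, 6)
                        for i in range(3))
        assert gaps == expect

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            shuffle_null(np.array([1.0, 2.0]), "female_ipis", 0)

    def test_shuffling_destroys_coordination(self):
        reject, null_ps = [], []
        for seed in range(1, 11):
            _, truth = simulate_duet(DuetParams(duration=120.0), seed=seed)
            mb = assemble_bouts(truth.pulse_times("M"), "M")
            fp = truth.pulse_times("F")
            real = response_times(mb, fp, "female_after_male_onset")
            n1 = response_times(mb, shuffle_null(fp, "female_ipis", seed),
                                "female_after_male_onset")
            n2 = response_times(mb, shuffle_null(fp, "female_ipis", seed + 100),
                                "female_after_male_onset")
            reject.append(ks_compare(real, n1)["p"] < 0.001)
            null_ps.append(ks_compare(n1, n2)["p"])
        assert np.mean(reject) >= 0.9
        assert np.median(null_ps) > 0.05


class TestSummarizeDistribution:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        rts = ResponseTimeSet(rng.uniform(0.01, 1.4, 300),
                              "female_after_male_onset")
        s = summarize_distribution(rts, seed=0)
        width = np.diff(s.bin_edges)
        assert np.sum(s.density * width) == pytest.approx(1.0, abs=1e-9)
        assert np.all(s.ci_lo <= s.ci_hi + 1e-12)

    def test_identical_latencies_single_bin_zero_ci_width(self):
        rts = ResponseTimeSet(np.full(50, 0.409), "female_after_male_onset")
        s = summarize_distribution(rts, seed=0)
        assert (s.density > 0).sum() == 1
        assert s.peak_latency_ms == pytest.approx(409.0, abs=1.0)
        occupied = s.density > 0
        assert np.allclose(s.ci_lo[occupied], s.ci_hi[occupied])

    def test_mode_recovered_at_reported_sample_size(self):
        # latencies with a 409-ms density mode at n ~ 1000
        rng = np.random.default_rng(7)
        mode, sigma = 0.409, 0.2
        x = np.exp(rng.normal(np.log(mode) + sigma**2, sigma, 970))
        x = x[(x > 0) & (x <= 1.5)]
        s = summarize_distribution(
            ResponseTimeSet(x, "female_after_male_onset"), seed=0)
        assert abs(s.peak_latency_ms - 409.0) <= 25.0

    def test_low_n_flagged(self):
        rts = ResponseTimeSet(np.full(5, 0.2), "female_after_male_onset")
        assert summarize_distribution(rts, seed=0).low_n


class TestKsCompare:
    def test_identical_sets_do_not_differ(self):
        a = ResponseTimeSet(np.linspace(0.01, 1.0, 40), "female_after_male_onset")
        res = ks_compare(a, a)
        assert res["statistic"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_statistic_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(1)
        a = ResponseTimeSet(rng.uniform(0.01, 1.4, 37), "female_after_male_onset")
        b = ResponseTimeSet(rng.uniform(0.01, 1.4, 43), "female_after_male_onset")
        res = ks_compare(a, b)
        grid = np.concatenate([a.latencies, b.latencies])
        brute = max(abs((a.latencies <= x).mean() - (b.latencies <= x).mean())
                    for x in grid)
        assert res["statistic"] == pytest.approx(brute, abs=1e-12)

    def test_shifted_uniforms_detected(self):
        rng = np.random.default_rng(2)
        a = ResponseTimeSet(rng.uniform(0.0001, 1.0, 500),
                            "female_after_male_onset", window=1.5)
        b = ResponseTimeSet(rng.uniform(0.5, 1.5, 500),
                            "female_after_male_onset", window=1.5)
        assert ks_compare(a, b)["p"] < 0.001

    def test_empty_set_rejected(self):
        a = ResponseTimeSet(np.array([]), "female_after_male_onset")
        b = ResponseTimeSet(np.array([0.3]), "female_after_male_onset")
        with pytest.raises(ValueError):
            ks_compare(a, b)


def summary_from_probs(probs, window=1.5):
    probs = np.asarray(probs, dtype=float)
    edges = np.linspace(0.0, window, probs.size + 1)
    width = np.diff(edges)
    dens = probs / probs.sum() / width
    z = np.zeros_like(dens)
    return DistributionSummary(edges, dens, z, z, 0.0, 100)


class TestKlDivergence:
    def test_self_divergence_is_zero(self):
        a = summary_from_probs([0.2, 0.5, 0.3])
        assert kl_divergence(a, a)["kl_nats"] == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_hand_arithmetic(self):
        a = summary_from_probs([0.9, 0.1])
        b = summary_from_probs([0.5, 0.5])
        expect = 0.9 * np.log(0.9 / 0.5) + 0.1 * np.log(0.1 / 0.5)
        got = kl_divergence(a, b, eps=0.0)
        assert got["kl_nats"] == pytest.approx(expect)
        assert got["kl_nats"] == pytest.approx(0.368, abs=0.001)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 10_000))
    def test_nonnegative_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = summary_from_probs(rng.dirichlet(np.ones(10)))
        b = summary_from_probs(rng.dirichlet(np.ones(10)))
        assert kl_divergence(a, b)["kl_nats"] >= -1e-12

    def test_invariant_to_consistent_bin_permutation(self):
        rng = np.random.default_rng(4)
        pa, pb = rng.dirichlet(np.ones(8)), rng.dirichlet(np.ones(8))
        perm = rng.permutation(8)
        base = kl_divergence(summary_from_probs(pa), summary_from_probs(pb))
        permuted = kl_divergence(summary_from_probs(pa[perm]),
                                 summary_from_probs(pb[perm]))
        assert base["kl_nats"] == pytest.approx(permuted["kl_nats"], abs=1e-12)

    def test_mismatched_grids_rejected(self):
        a = summary_from_probs([0.5, 0.5])
        b = summary_from_probs([0.3, 0.3, 0.4])
        with pytest.raises(ValueError, match="grid"):
            kl_divergence(a, b)
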