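"""Core quantification: event screening, histograms, constrained fits."""
import numpy as np
import pytest

from tonicquant import (
    CurrentTrace,
    QuantParams,
    SimConfig,
    all_point_histogram,
    detect_events,
    fit_gaussian_constrained,
    holding_current,
    quantify_trace,
    select_epochs,
    simulate_trace,
    tonic_current,
)
from tonicquant.errors import (
    FitError,
    InsufficientDataError,
    ValidationError,
)
from tonicquant.quantify import EpochSelection, Segment

FS = 10_000.0


def _trace(samples, **kw):
    kw.setdefault("sampling_rate_hz", FS)
    return CurrentTrace(samples=np.asarray(samples, dtype=float), **kw)


class TestDetectEvents:
    def test_constant_trace_has_no_events(self):
        events = detect_events(_trace(np.full(30_000, -45.0)))
        assert events.shape == (0, 2)

    def test_injected_event_found_at_injection_time(self):
        # one kernel, peak 10x the noise SD, at t = 30 s
        cfg = SimConfig(duration_s=60.0, noise_sd_pa=1.0, event_rate_hz=0.0)
        trace, _ = simulate_trace(cfg)
        from tonicquant import ipsc_kernel
        k = ipsc_kernel(1.0, 10.0, FS)
        i0 = int(30.0 * FS)
        trace.samples[i0:i0 + k.size] -= 10.0 * k
        events = detect_events(trace, threshold_sd=5.0)
        assert len(events) == 1
        start_s, stop_s = events[0] / FS
        assert start_s <= 30.0 + 0.002 and stop_s >= 30.0 + 0.002

    def test_false_positive_rate_bounded_on_pure_noise(self):
        # 5-SD criterion on pure noise: no events in >= 99% of seeds
        clean = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimConfig(duration_s=5.0, noise_sd_pa=3.0,
                            event_rate_hz=0.0, seed=seed)
            trace, _ = simulate_trace(cfg)
            if len(detect_events(trace, threshold_sd=5.0)) == 0:
                clean += 1
        assert clean >= 0.99 * n_seeds

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            detect_events(_trace(np.zeros(500)))

    def test_robust_sd_not_inflated_by_events(self):
        # heavy contamination must not mask a clear event
        cfg = SimConfig(duration_s=30.0, noise_sd_pa=2.0, event_rate_hz=5.0,
                        event_amp_mean_pa=40.0, seed=4)
        trace, truth = simulate_trace(cfg)
        events = detect_events(trace)
        # at 5 Hz over 30 s, the detector should flag a sizeable fraction
        assert len(events) > 0.5 * truth.event_times_s.size


class TestSelectEpochs:
    def test_event_free_trace_yields_clean_epochs(self):
        trace = _trace(np.full(1_200_000, -50.0), t_drug_s=60.0)
        sel = select_epochs(trace, np.empty((0, 2), dtype=int),
                            post_delay_s=10.0)
        assert len(sel.for_phase("pre")) == 3
        assert len(sel.for_phase("post")) == 3
        assert all(s.clean for s in sel.segments)
        for phase, lo, hi in [("pre", 0, 600_000), ("post", 700_000, 1_200_000)]:
            for s in sel.for_phase(phase):
                assert lo <= s.start_index and s.stop_index <= hi

    def test_epochs_do_not_overlap(self):
        trace = _trace(np.full(1_200_000, -50.0), t_drug_s=60.0)
        sel = select_epochs(trace, np.empty((0, 2), dtype=int), post_delay_s=10.0)
        spans = sorted((s.start_index, s.stop_index) for s in sel.segments)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b <= c

    def test_short_phase_raises_insufficient_data(self):
        trace = _trace(np.full(300_000, -50.0), t_drug_s=12.0)
        with pytest.raises(InsufficientDataError, match="pre"):
            select_epochs(trace, np.empty((0, 2), dtype=int), post_delay_s=0.0)

    def test_fallback_matches_brute_force_minimum_density_scan(self):
        # contaminated 1-s toy problem at low rate: check the fallback
        # selection against an exhaustive per-start window scan
        rng = np.random.default_rng(9)
        n = 240_000  # 24 s
        trace = _trace(np.full(n, -50.0), t_drug_s=12.0)
        starts = rng.choice(n - 600, size=60, replace=False)
        events = np.sort(np.stack([starts, starts + 500], axis=1), axis=0)
        events = events[np.argsort(events[:, 0])]
        L = 20_000  # 2-s epochs
        with pytest.warns(UserWarning, match="event-free"):
            sel = select_epochs(trace, events, epoch_len_s=2.0,
                                n_per_phase=2, post_delay_s=0.0)

        # brute-force oracle: greedy lowest-count, earliest-start,
        # non-overlapping selection per phase, skipping picks that would
        # make placing the remaining epochs infeasible
        def oracle(lo, hi):
            cand = []
            for s in range(lo, hi - L + 1):
                c = sum(1 for b, e in events if b < s + L and e > s)
                cand.append((c, s))
            cand.sort()

            def capacity(intervals):
                cap, prev = 0, lo
                for b, e in sorted(intervals):
                    cap += (b - prev) // L
                    prev = max(prev, e)
                return cap + (hi - prev) // L

            picked = []
            for c, s in cand:
                if any(s < e and s + L > b for b, e in picked):
                    continue
                if capacity(picked + [(s, s + L)]) < 2 - len(picked) - 1:
                    continue
                picked.append((s, s + L))
                if len(picked) == 2:
                    break
            return sorted(b for b, _ in picked)

        assert [s.start_index for s in sel.for_phase("pre")] == oracle(0, 120_000)
        assert [s.start_index for s in sel.for_phase("post")] == oracle(120_000, n)
        assert not all(s.clean for s in sel.segments)

    def test_requires_drug_time(self):
        with pytest.raises(ValidationError, match="t_drug_s"):
            select_epochs(_trace(np.zeros(100_000)), np.empty((0, 2), dtype=int))


class TestAllPointHistogram:
    def test_constant_segment_is_single_degenerate_bin(self):
        hist = all_point_histogram(np.full(5000, -45.25))
        assert hist.degenerate
        assert hist.counts.sum() == 5000
        assert hist.counts.size == 1

    def test_counts_conserved_for_5s_epoch(self, gaussian_trace):
        seg = Segment(0, 50_000, "pre", True, 0.0)
        hist = all_point_histogram(gaussian_trace, seg)
        assert hist.counts.sum() == 50_000
        assert hist.n_samples == 50_000

    def test_edges_on_bin_width_grid(self, gaussian_trace):
        hist = all_point_histogram(gaussian_trace, bin_width_pa=0.5)
        np.testing.assert_allclose(hist.bin_edges % 0.5, 0.0, atol=1e-9)
        widths = np.diff(hist.bin_edges)
        np.testing.assert_allclose(widths, 0.5, atol=1e-9)

    def test_mode_bin_near_true_mean(self):
        # Gaussian noise at -50 pA: the mode bin center lands within one
        # bin of -50 in each of several seeds
        for seed in range(10):
            rng = np.random.default_rng(seed)
            hist = all_point_histogram(rng.normal(-50, 3, 50_000))
            center = hist.centers()[hist.mode_bin]
            assert abs(center - (-50.0)) <= 1.0

    def test_invalid_bin_width(self):
        with pytest.raises(ValidationError, match="bin_width"):
            all_point_histogram(np.zeros(10), bin_width_pa=0.0)


class TestConstrainedGaussianFit:
    def test_recovers_known_gaussian_parameters(self):
        rng = np.random.default_rng(3)
        x = rng.normal(-50.0, 3.0, 50_000)
        fit = fit_gaussian_constrained(all_point_histogram(x))
        assert fit.converged
        assert fit.mu_pa == pytest.approx(np.mean(x), abs=0.1)
        assert fit.sigma_pa == pytest.approx(3.0, rel=0.10)

    def test_fit_window_excludes_deep_negative_tail(self):
        rng = np.random.default_rng(3)
        hist = all_point_histogram(rng.normal(-50.0, 3.0, 50_000))
        fit = fit_gaussian_constrained(hist, peak_offset_bins=2)
        first, last = fit.fit_window
        assert first == hist.mode_bin - 2
        assert last == hist.counts.size - 1

    def test_positive_tail_side_mirrors_window(self):
        rng = np.random.default_rng(3)
        hist = all_point_histogram(rng.normal(-50.0, 3.0, 50_000))
        fit = fit_gaussian_constrained(hist, tail_side="positive")
        assert fit.fit_window == (0, hist.mode_bin + 2)

    def test_less_biased_than_naive_mean_under_contamination(self):
        # the entire point of the constrained fit: with inward sIPSCs the
        # naive segment mean is pulled negative, the fit is not
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimConfig(duration_s=5.0, noise_sd_pa=3.0, event_rate_hz=3.0,
                            event_amp_mean_pa=30.0, seed=seed)
            trace, _ = simulate_trace(cfg)
            fit = fit_gaussian_constrained(all_point_histogram(trace.samples))
            err_fit = abs(fit.mu_pa - cfg.i_hold_pa)
            err_mean = abs(trace.samples.mean() - cfg.i_hold_pa)
            wins += err_fit < err_mean
        assert wins >= 0.9 * n_seeds

    def test_degenerate_histogram_raises(self):
        hist = all_point_histogram(np.full(100, -45.25))
        with pytest.raises(FitError, match="degenerate"):
            fit_gaussian_constrained(hist)

    def test_too_few_bins_raises(self):
        hist = all_point_histogram(np.array([-50.1, -50.2, -49.9, -50.0]),
                                   bin_width_pa=0.25)
        with pytest.raises(FitError):
            fit_gaussian_constrained(hist, tail_side="positive",
                                     peak_offset_bins=0)


class TestHoldingCurrent:
    def test_mean_of_segment_mus(self):
        # three constant-noise segments engineered at known levels:
        # the phase holding current is the arithmetic mean of the mus
        rng = np.random.default_rng(5)
        parts = [rng.normal(m, 2.0, 50_000) for m in (-50.0, -51.0, -49.0)]
        trace = _trace(np.concatenate(parts), t_drug_s=15.0)
        sel = EpochSelection(
            segments=[Segment(i * 50_000, 50_000, "pre", True, 0.0)
                      for i in range(3)],
            epoch_len_s=5.0, n_per_phase=3,
        )
        mean_mu, mus = holding_current(trace, sel, "pre")
        assert len(mus) == 3
        assert mean_mu == pytest.approx(np.mean(mus))
        assert mean_mu == pytest.approx(-50.0, abs=0.2)

    def test_recovers_simulated_holding_current(self):
        errs = []
        for seed in range(10):
            cfg = SimConfig(duration_s=40.0, t_drug_s=39.0, noise_sd_pa=3.0,
                            event_rate_hz=2.0, seed=seed)
            trace, _ = simulate_trace(cfg)
            events = detect_events(trace)
            trace2 = CurrentTrace(samples=trace.samples, sampling_rate_hz=FS,
                                  t_drug_s=20.0)
            sel = select_epochs(trace2, events, post_delay_s=0.0)
            mean_mu, _ = holding_current(trace2, sel, "pre")
            errs.append(abs(mean_mu - cfg.i_hold_pa))
        assert np.mean(errs) < 0.5

    def test_missing_phase_rejected(self):
        sel = EpochSelection(segments=[], epoch_len_s=5.0, n_per_phase=3)
        with pytest.raises(ValidationError, match="phase"):
            holding_current(_trace(np.zeros(100)), sel, "pre")


class TestTonicCurrent:
    def test_agonist_worked_example(self):
        # THIP on an SST cell: -56.0 -> -99.1 pA gives 43.1 pA of tonic
        # current, inward (negative signed shift)
        r = tonic_current(-56.0, -99.1, "agonist")
        assert r.tonic_current_pa == pytest.approx(43.1, abs=1e-9)
        assert r.tonic_signed_pa == pytest.approx(-43.1, abs=1e-9)

    def test_no_shift_gives_zero(self):
        assert tonic_current(-50.0, -50.0, "antagonist").tonic_current_pa == 0.0

    def test_density_is_magnitude_over_capacitance(self):
        r = tonic_current(-56.0, -99.1, "agonist", capacitance_pf=100.0)
        assert r.current_density_pa_per_pf == pytest.approx(0.431)
        # identity: density x capacitance reproduces the magnitude exactly
        assert r.current_density_pa_per_pf * 100.0 == r.tonic_current_pa

    def test_density_absent_without_capacitance(self):
        assert tonic_current(-1.0, -2.0, "agonist").current_density_pa_per_pf is None

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValidationError, match="mode"):
            tonic_current(-1.0, -2.0, "blocker")


class TestEndToEnd:
    def test_quantify_recovers_simulated_shift(self):
        cfg = SimConfig(duration_s=175.0, t_drug_s=30.0, tonic_shift_pa=22.5,
                        seed=17)
        trace, truth = simulate_trace(cfg)
        with pytest.warns(UserWarning):
            result = quantify_trace(trace, "antagonist")
        assert result.tonic_current_pa == pytest.approx(22.5, abs=2.0)
        assert result.tonic_signed_pa > 0

    def test_round_trip_through_file_leaves_result_unchanged(self, tmp_path):
        from tonicquant import read_trace, write_trace
        cfg = SimConfig(duration_s=175.0, t_drug_s=30.0, tonic_shift_pa=-43.1,
                        seed=23)
        trace, _ = simulate_trace(cfg)
        path = tmp_path / "t.txt"
        write_trace(trace, path, precision=9)
        with pytest.warns(UserWarning):
            direct = quantify_trace(trace, "agonist")
        with pytest.warns(UserWarning):
            loaded = quantify_trace(read_trace(path), "agonist")
        assert loaded.tonic_current_pa == pytest.approx(
            direct.tonic_current_pa, abs=1e-6)
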