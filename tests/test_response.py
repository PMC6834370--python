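import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from icfra import build_default_protocol
from icfra.core_io import RoiSession
from icfra.response import (
    TrialSegmentSet,
    WindowMeans,
    background_subtract,
    bootstrap_null,
    classify_fra,
    classify_stimulus_response,
    determine_cf,
    extract_segments,
    fit_decay_kinetics,
    fit_onset_kinetics,
    gate_for_classification,
    grid_neighbors,
    holm_bonferroni,
    p_value,
    pixelwise_correlation_map,
    qc_trials,
    signal_autocorrelation,
    signal_crosscorrelation,
    window_means,
)
from icfra.synthetic import render_pixel_stack

DT = 0.1144


def _pairwise_mean_r(segs):
    """Independent oracle: direct pairwise Pearson via np.corrcoef."""
    rs = [np.corrcoef(a, b)[0, 1] for a, b in itertools.combinations(segs, 2)]
    return float(np.mean(rs))


class TestSignalCorrelation:
    def test_identical_segments_give_one(self):
        seg = np.tile([1.0, 2.0, 4.0, 3.0], (5, 1))
        assert signal_autocorrelation(seg) == pytest.approx(1.0)

    def test_hand_computed_three_trials(self):
        seg = np.array([[1, 2, 3], [2, 4, 6], [3, 2, 1]], float)
        assert signal_autocorrelation(seg) == pytest.approx(-1.0 / 3.0)

    def test_matches_pairwise_corrcoef_oracle(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(size=(10, 26))
        assert signal_autocorrelation(seg) == pytest.approx(
            _pairwise_mean_r(seg), abs=1e-12
        )

    def test_constant_segment_pairs_count_as_zero(self):
        seg = np.array([[1, 2, 3], [1, 1, 1], [2, 4, 6]], float)
        # pairs: (0,2) -> 1; pairs with the flat trial -> 0
        assert signal_autocorrelation(seg) == pytest.approx(1.0 / 3.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            signal_autocorrelation(np.ones((1, 5)))

    def test_cross_correlation_identical_sets(self):
        a = np.tile([1.0, 3.0, 2.0], (2, 1))
        assert signal_crosscorrelation(a, a) == pytest.approx(1.0)

    def test_cross_correlation_matches_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 26)), rng.normal(size=(3, 26))
        expected = np.mean(
            [np.corrcoef(x, y)[0, 1] for x in a for y in b]  # 2 x 3 = 6 pairs
        )
        assert signal_crosscorrelation(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(
        seg=arrays(
            np.float64, (4, 12),
            elements=st.floats(-50, 50).map(lambda v: round(v, 2)),
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_affine_and_permutation_invariance(self, seg, a, b):
        """Pearson-based, so rho-auto ignores per-trial gain/offset and
        repetition order."""
        base = signal_autocorrelation(seg)
        assert signal_autocorrelation(a * seg + b) == pytest.approx(base, abs=1e-9)
        perm = seg[::-1]
        assert signal_autocorrelation(perm) == pytest.approx(base, abs=1e-9)


class TestBootstrap:
    def test_observed_above_all_null_reports_below_1_over_b(self):
        null = np.linspace(-0.5, 0.5, 2000)
        p = p_value(0.9, null)
        assert 0 < p < 1.0 / 2000

    def test_observed_at_minimum_gives_p_near_one(self):
        null = np.linspace(-0.5, 0.5, 2000)
        assert p_value(-1.0, null) == pytest.approx(1.0, abs=1e-3)

    def test_segment_longer_than_session_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_null(np.zeros(10), 26, 6, B=1000, seed=0)

    def test_null_statistic_matches_direct_computation(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(size=400)
        null = bootstrap_null(trace, 20, 4, B=1000, seed=5)
        # recompute one draw by hand with the same RNG stream
        rng2 = np.random.default_rng(5)
        starts = rng2.integers(0, len(trace) - 20 + 1, size=(1000, 4))
        segs = np.stack([trace[s: s + 20] for s in starts[0]])
        assert null[0] == pytest.approx(_pairwise_mean_r(segs), abs=1e-12)

    def test_type_one_error_single_stimulus(self):
        """On white noise with m=1 at alpha=0.05 the bootstrap test is
        calibrated: rejection rate ~5% over many ROIs."""
        rng = np.random.default_rng(11)
        n_roi, hits = 2000, 0
        for i in range(n_roi):
            trace = rng.normal(size=700)
            null = bootstrap_null(trace, 26, 6, B=3000, seed=i)
            starts = rng.integers(0, 700 - 26, size=6)
            obs = signal_autocorrelation(
                np.stack([trace[s: s + 26] for s in starts])
            )
            hits += p_value(obs, null) <= 0.05
        assert hits / n_roi == pytest.approx(0.05, abs=0.02)


class TestHolm:
    def test_all_ones_nothing_significant(self):
        assert not holm_bonferroni(np.ones(114)).any()

    def test_m114_smallest_p_below_first_threshold(self):
        p = np.ones(114)
        p[57] = 1e-5  # < 0.05/114 ~ 4.39e-4
        sig = holm_bonferroni(p)
        assert sig[57] and sig.sum() == 1

    def test_step_down_example_m2(self):
        assert holm_bonferroni(np.array([0.01, 0.04])).all()

    def test_matches_manual_step_down(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40) ** 3
        sig = holm_bonferroni(p, alpha=0.05)
        order = np.argsort(p)
        manual = np.zeros(40, bool)
        for rank, idx in enumerate(order):
            if p[idx] <= 0.05 / (40 - rank):
                manual[idx] = True
            else:
                break
        assert (sig == manual).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni(np.array([0.5, 1.2]))

    @settings(max_examples=25, derandomize=True)
    @given(p=arrays(np.float64, 20, elements=st.floats(0, 1)))
    def test_flags_monotone_in_p(self, p):
        sig = holm_bonferroni(p)
        if sig.any() and (~sig).any():
            assert p[sig].max() <= p[~sig].min() + 1e-12


class TestTrialQC:
    def _segset(self, baselines):
        b = np.asarray(baselines, float)
        return TrialSegmentSet(
            segments=np.zeros((len(b), 2)),
            baselines=b,
            excluded=np.zeros(len(b), bool),
            stim_index=np.zeros(len(b), int),
            pre_frames=1,
            frame_interval_s=DT,
        )

    def test_outlier_trial_excluded(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=50)
        b[7] = 5.0
        out = qc_trials(self._segset(b))
        assert out.excluded[7]

    def test_identical_baselines_no_exclusions(self):
        out = qc_trials(self._segset(np.ones(20)))
        assert not out.excluded.any()

    def test_exclusion_fraction_matches_gaussian_tail(self):
        # P(|z| > 3) = 2*Phi(-3) ~ 0.27%
        rng = np.random.default_rng(1)
        out = qc_trials(self._segset(rng.normal(size=200_000)))
        assert out.excluded.mean() == pytest.approx(0.0027, abs=0.001)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            qc_trials(self._segset(np.arange(5)))


class TestWindowsAndClassification:
    def test_default_window_frame_counts(self):
        """Half-open floor windows at 114.4 ms: 500 ms -> 4 frames,
        the 1 s tone -> 8 frames, full segment 26 frames."""
        onsets = np.array([20])
        sess = RoiSession("r", np.arange(60.0), DT, onsets, np.array([0]))
        segset = extract_segments(sess)
        assert segset.segments.shape == (1, 26)
        assert segset.pre_frames == 9
        w = window_means(
            segset.segments, segset.baselines, segset.pre_frames, DT,
            baseline_sd_mode="frames",
        )
        seg = segset.segments[0]
        assert w.f_baseline == pytest.approx(seg[:9].mean())
        assert w.f_onset == pytest.approx(seg[9:13].mean())      # 4 frames
        assert w.f_steady == pytest.approx(seg[13:17].mean())    # 4 frames
        assert w.f_offset == pytest.approx(seg[17:22].mean())
        assert w.f_offlate == pytest.approx(seg[22:26].mean())

    @pytest.mark.parametrize(
        "deltas, expected",
        [
            # (onset, steady, offset, offlate) deltas in units of sigma
            ((3, 0, 0, 0), {"excitation"}),
            ((0, 3, 0, 0), {"excitation"}),
            ((0, -3, 0, 3), {"inhibition", "offset"}),  # offlate>baseline rebound
            ((0, -3, -3, -3), {"inhibition"}),
            ((0.5, 0.5, -0.5, 0.9), set()),
            ((0, 0, 3, 3), {"offset"}),  # rise after the tone only
            ((3, 3, 0, 3), {"excitation", "offset"}),
        ],
    )
    def test_classification_table(self, deltas, expected):
        d_on, d_st, d_off, d_late = deltas
        w = WindowMeans(
            f_baseline=10.0,
            f_onset=10.0 + d_on,
            f_steady=10.0 + d_st,
            f_offset=10.0 + d_off,
            f_offlate=10.0 + d_late,
            baseline_sd=1.0,
        )
        assert set(classify_stimulus_response(w)) == expected

    def test_zero_sigma_unclassified(self):
        w = WindowMeans(10, 20, 20, 10, 10, baseline_sd=0.0)
        assert classify_stimulus_response(w) == frozenset()

    def test_fra_mixed_when_two_classes_reach_quarter(self):
        sets = [frozenset({"excitation"})] * 6 + [frozenset({"inhibition"})] * 4
        cls, frac = classify_fra(sets)
        assert cls == "mixed"

    def test_fra_single_class(self):
        sets = [frozenset({"excitation"})] * 7
        cls, frac = classify_fra(sets)
        assert cls == "excitation" and frac == 1.0

    def test_fra_minority_class_below_quarter_ignored(self):
        sets = [frozenset({"inhibition"})] * 9 + [frozenset({"offset"})]
        cls, _ = classify_fra(sets)
        assert cls == "inhibition"

    def test_fra_order_invariant(self):
        rng = np.random.default_rng(4)
        sets = [frozenset({"excitation"})] * 3 + [frozenset({"offset"})] * 3 + [
            frozenset()
        ] * 2
        for _ in range(5):
            rng.shuffle(sets)
            assert classify_fra(sets)[0] == "mixed"

    def test_no_significant_responses_is_none(self):
        assert classify_fra([]) == ("none", 0.0)


class TestCharacteristicFrequency:
    def _grid(self, protocol, entries):
        sig = np.zeros((19, 6), bool)
        for f_khz, i_db in entries:
            fi = int(round(3 * np.log2(f_khz)))
            ii = int((i_db - 30) // 10)
            sig[fi, ii] = True
        return sig.ravel()

    def test_single_stimulus(self, protocol6):
        sig = self._grid(protocol6, [(8.0, 30)])
        assert determine_cf(sig, protocol6) == pytest.approx(8.0)

    def test_geometric_mean_at_lowest_intensity(self, protocol6):
        sig = self._grid(protocol6, [(4.0, 30), (16.0, 30)])
        assert determine_cf(sig, protocol6) == pytest.approx(8.0)

    def test_lowest_intensity_wins(self, protocol6):
        sig = self._grid(protocol6, [(4.0, 40), (16.0, 30)])
        assert determine_cf(sig, protocol6) == pytest.approx(16.0)

    def test_neighbor_lists_include_diagonals(self, protocol6):
        nbs = grid_neighbors(protocol6)
        assert len(nbs[0]) == 3          # corner
        assert len(nbs[1]) == 5          # edge
        assert len(nbs[7]) == 8          # interior
        assert all(len(n) <= 8 for n in nbs)

    def test_gate_excludes_isolated_stimulus(self, protocol6):
        rng = np.random.default_rng(5)
        T = 26
        shared = rng.normal(size=T)
        segs = [rng.normal(size=(4, T)) * 0.1 for _ in range(114)]
        # stimuli 30 and 31 (grid neighbours) share a waveform; 80 does not
        segs[30] = shared + rng.normal(size=(4, T)) * 0.05
        segs[31] = shared + rng.normal(size=(4, T)) * 0.05
        included = gate_for_classification(segs, protocol6)
        assert included[30] and included[31]
        assert not included[80]


class TestKinetics:
    def test_onset_tau_recovery(self):
        t = np.arange(0, 1.0, DT)
        rng = np.random.default_rng(0)
        y = 5.0 * (1 - np.exp(-t / 0.3)) + rng.normal(0, 0.05, len(t))
        tau, cls = fit_onset_kinetics(t, y)
        assert tau == pytest.approx(300, rel=0.1)
        assert cls == "onset"

    def test_slow_rise_designated_sustained(self):
        t = np.arange(0, 1.0, DT)
        y = 5.0 * (1 - np.exp(-t / 1.5))
        tau, cls = fit_onset_kinetics(t, y)
        assert cls == "sustained" and tau > 1000

    def test_decay_tau_recovery(self):
        t = np.arange(0.5, 4.0, DT)
        y = 10.2 * np.exp(-t / 1.0)
        tau = fit_decay_kinetics(t, y)
        assert tau == pytest.approx(1000, rel=0.05)


class TestPixelOps:
    def test_background_invariance_and_neighbor_exclusion(self):
        rng = np.random.default_rng(6)
        T = 40
        trace_a = np.sin(np.linspace(0, 6, T)) + 4
        trace_b = rng.normal(5, 2, T)  # flashing neighbour
        stack, masks = render_pixel_stack(
            np.stack([trace_a, trace_b]), [(10, 10), (10, 16)], 2, (24, 24)
        )
        bg = rng.normal(1.0, 0.5, T)
        stack_bg = stack + bg[:, None, None]
        out = background_subtract(stack_bg, masks[0], masks)
        out_nobg = background_subtract(stack, masks[0], masks)
        np.testing.assert_allclose(out, out_nobg, atol=1e-9)
        # neighbour exclusion: trace_b leaks nowhere into ROI A's estimate
        np.testing.assert_allclose(out - out.mean(), trace_a - trace_a.mean(),
                                   atol=1e-9)

    def test_zero_noise_recovers_generating_trace(self):
        trace = np.cos(np.linspace(0, 8, 30)) + 3
        bg = np.linspace(0, 2, 30)
        stack, masks = render_pixel_stack(
            trace[None], [(8, 8)], 2, (16, 16), background=bg
        )
        out = background_subtract(stack, masks[0], masks)
        # the shared background component cancels exactly
        np.testing.assert_allclose(out, trace, atol=1e-9)

    def test_correlation_map_extremes(self):
        rng = np.random.default_rng(7)
        soma = rng.normal(size=1200)
        stack = np.zeros((1200, 1, 3))
        stack[:, 0, 0] = soma
        stack[:, 0, 1] = -(soma - soma.mean()) + 2.0
        stack[:, 0, 2] = rng.normal(size=1200)
        rmap, valid = pixelwise_correlation_map(stack, soma)
        assert rmap[0, 0] == pytest.approx(1.0)
        assert rmap[0, 1] == pytest.approx(-1.0)
        assert abs(rmap[0, 2]) < 0.1
        assert valid.all()

    def test_constant_pixel_flagged_zero(self):
        stack = np.ones((50, 1, 1))
        rmap, valid = pixelwise_correlation_map(stack, np.arange(50.0))
        assert rmap[0, 0] == 0.0 and not valid[0, 0]
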