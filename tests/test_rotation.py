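"""Two-state idealization, kymograph rotation analysis and energetics."""
import numpy as np
import pandas as pd
import pytest

import hsafm as H
from conftest import gt_plateau_dwells, map_idealization_labels


class TestIdealization:
    def test_noiseless_telegraph_recovered_exactly(self):
        cfg = H.TelegraphConfig(seed=3, noise=None, jitter=(0.0, 0.0),
                                transition_duration=0.0)
        tr = H.simulate_telegraph_trace(cfg, 5.0)
        ideal = H.idealize_two_state(tr, filter_width=1)
        rec = map_idealization_labels(ideal, tr)
        assert np.array_equal(rec, tr.states)

    def test_recovery_against_ground_truth(self, telegraph_no_jitter):
        """On the noisy benchmark telegraph, >= 95% of ground-truth dwells
        >= 1 ms carry the correct label and the mean dwell is within 10%."""
        tr = telegraph_no_jitter
        ideal = H.idealize_two_state(tr)
        rec = map_idealization_labels(ideal, tr)
        dwells, states, starts, ends = gt_plateau_dwells(tr)
        good = total = 0
        for d, s, a, b in zip(dwells, states, starts, ends):
            if d < 1e-3:
                continue
            total += 1
            good += np.bincount(rec[a:b], minlength=2).argmax() == s
        assert total > 300
        assert good / total >= 0.95
        stats = H.dwell_statistics(ideal)
        assert abs(stats.mean - dwells.mean()) / dwells.mean() < 0.10

    def test_short_dwells_resolved_to_hundreds_of_us(self):
        """With sharp state changes the idealizer resolves dwells down to
        the few-hundred-µs scale (floor: five filter widths, 240 µs)."""
        cfg = H.TelegraphConfig(seed=29, jitter=(0.0, 0.0),
                                transition_duration=0.0)
        tr = H.simulate_telegraph_trace(cfg, 12.0)
        ideal = H.idealize_two_state(tr)
        shortest = ideal.segments["dwell"].iloc[1:-1].min()
        assert shortest < 1.5e-3
        assert shortest >= 150 / tr.sampling_rate

    def test_unimodal_trace_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 0.17, 100_000)
        with pytest.raises(H.NotTwoStateError):
            H.idealize_two_state(x, sampling_rate=625_000.0)

    def test_states_alternate_and_tile_trace(self, telegraph_no_jitter):
        ideal = H.idealize_two_state(telegraph_no_jitter)
        seg = ideal.segments
        assert np.all(np.abs(np.diff(seg["state"])) == 1)
        assert seg["start"].iloc[0] == 0
        assert seg["end"].iloc[-1] == telegraph_no_jitter.n_samples
        assert np.all(seg["start"].iloc[1:].to_numpy()
                      == seg["end"].iloc[:-1].to_numpy())

    def test_state_occupancy_symmetric_for_symmetric_generator(self,
                                                               telegraph_no_jitter):
        """With equal mean dwells neither orientation is preferred: state
        occupancies agree within 3 binomial s.d."""
        ideal = H.idealize_two_state(telegraph_no_jitter)
        seg = ideal.segments.iloc[1:-1]
        n = len(seg)
        k = int((seg["state"] == 0).sum())
        assert abs(k - n / 2) <= 3 * np.sqrt(n) / 2

    @pytest.mark.parametrize("snr", [3.0, 5.0, 10.0])
    def test_dwell_mean_bias_across_snr(self, snr):
        """Across filtered-signal SNR of 3-10, the recovered mean dwell is
        biased by < 10% for dwells well above the filter width."""
        sep = 0.28
        sigma = sep / snr * np.sqrt(30)
        cfg = H.TelegraphConfig(seed=17, jitter=(0.0, 0.0),
                                noise=H.NoiseModel(sigma),
                                transition_duration=0.0,
                                mean_dwells=(0.03, 0.03))
        tr = H.simulate_telegraph_trace(cfg, 15.0)
        ideal = H.idealize_two_state(tr)
        dwells, *_ = gt_plateau_dwells(tr)
        stats = H.dwell_statistics(ideal)
        assert abs(stats.mean - dwells.mean()) / dwells.mean() < 0.10


class TestDwellStatistics:
    def test_exponential_dwell_mean_recovered(self):
        """~2000 exponential dwells of mean 35 ms: the estimate lands
        within 3 s.e.m. of the generator mean."""
        cfg = H.TelegraphConfig(seed=23, jitter=(0.0, 0.0), noise=None,
                                transition_duration=0.0,
                                mean_dwells=(0.035, 0.035))
        tr = H.simulate_telegraph_trace(cfg, 72.0)
        ideal = H.idealize_two_state(tr, filter_width=1)
        stats = H.dwell_statistics(ideal)
        assert stats.n > 1500
        assert abs(stats.mean - 0.035) <= 3 * stats.sem

    def test_too_few_dwells_rejected(self):
        seg = pd.DataFrame({"state": [0, 1, 0], "start": [0, 10, 20],
                            "end": [10, 20, 30], "dwell": [1.0, 1.0, 1.0]})
        ideal = H.TwoStateIdealization(segments=seg, levels=(0.0, 1.0),
                                       filter_width=1, sampling_rate=10.0)
        with pytest.raises(ValueError):
            H.dwell_statistics(ideal)

    def test_dwell_mixture_deviates_from_single_exponential(self):
        """A 13/41/96 ms mixture of exponentials is over-dispersed relative
        to a single exponential: its dwell coefficient of variation clearly
        exceeds 1, while a matched single exponential sits at 1."""
        rng = np.random.default_rng(9)
        n = 3000
        means = rng.choice([0.013, 0.041, 0.096], n, p=[1 / 3, 1 / 3, 1 / 3])
        dwells = rng.exponential(means)
        mono = rng.exponential(dwells.mean(), n)
        cv = lambda d: d.std() / d.mean()
        assert cv(dwells) > 1.2
        assert 0.9 < cv(mono) < 1.1


class TestKymographTraces:
    def test_position_traces_anticorrelate(self, rotation_kymograph):
        prof = rotation_kymograph.meta["profile"]
        x0, x60 = prof.state_positions()
        st = H.extract_position_traces(rotation_kymograph, x0, x60)
        assert st.anticorrelation < -0.5

    def test_difference_idealization_matches_schedule(self, rotation_kymograph):
        """The two-state fit of the difference trace reproduces the
        scheduled state sequence at line resolution."""
        kym = rotation_kymograph
        prof = kym.meta["profile"]
        st = H.extract_position_traces(kym, *prof.state_positions())
        rec = st.idealization.sample_states(kym.n_lines)
        # ground truth: plateau angle mod 120 == 0 -> lobe at the x0 side
        ang = kym.orientation
        plateau = np.isin(np.mod(ang, 120.0), [0.0])
        state60 = np.mod(ang, 120.0) == 60.0
        # difference = h(x0) - h(x60) is high in the 0-deg state (state 1)
        agree = (rec[plateau] == 1).mean(), (rec[state60] == 0).mean()
        assert agree[0] > 0.9 and agree[1] > 0.9

    def test_static_object_rejected_as_two_state(self):
        kym = H.simulate_rotation_kymograph([(0.0, 0.3)], noise=H.NoiseModel(0.05),
                                            seed=2)
        prof = kym.meta["profile"]
        with pytest.raises(H.NotTwoStateError):
            H.extract_position_traces(kym, *prof.state_positions())

    def test_common_mode_noise_cancels_in_difference(self):
        """Baseline wobble shared by all rows cancels in the difference
        trace: its plateau spread stays below either single trace's."""
        sched = [(0, 0.08), (60, 0.09), (0, 0.08), (60, 0.09)]
        kym = H.simulate_rotation_kymograph(sched, noise=H.NoiseModel(0.03), seed=4)
        rng = np.random.default_rng(5)
        wobble = rng.normal(0.0, 0.2, kym.n_lines)
        kym.data += wobble[None, :]
        prof = kym.meta["profile"]
        st = H.extract_position_traces(kym, *prof.state_positions())
        # compare spreads within one plateau type so the two-state swing
        # itself does not enter
        plateau_a = np.mod(kym.orientation, 120.0) == 0.0
        assert st.trace0[plateau_a].std() > 0.15  # single trace carries the wobble
        assert st.difference[plateau_a].std() < 0.5 * st.trace0[plateau_a].std()

    def test_out_of_range_position_rejected(self, rotation_kymograph):
        with pytest.raises(ValueError):
            H.extract_position_traces(rotation_kymograph, -5.0, 8.5)


class TestRotationTransitions:
    def test_scheduled_durations_recovered(self, rotation_kymograph):
        """18 ms scheduled rotations at 2.4 ms per line are measured at
        18 ms within about one line period."""
        tr = H.measure_rotation_transitions(rotation_kymograph)
        d = tr.durations
        assert len(d) >= 5
        assert np.all(np.abs(d - 0.018) <= 1.3 * rotation_kymograph.line_period)

    def test_directions_match_schedule(self, rotation_kymograph):
        tr = H.measure_rotation_transitions(rotation_kymograph)
        gt = rotation_kymograph.transitions["direction"].tolist()
        got = tr.table["direction"].tolist()
        assert got == gt

    def test_noiseless_directions_perfect(self):
        sched = [(0, 0.06), (60, 0.06), (120, 0.06), (60, 0.06), (0, 0.06),
                 (-60, 0.06), (0, 0.06)]
        kym = H.simulate_rotation_kymograph(sched, noise=None, seed=0)
        tr = H.measure_rotation_transitions(kym)
        assert tr.table["direction"].tolist() == \
            kym.transitions["direction"].tolist()

    def test_instantaneous_transitions_flagged_unresolvable(self):
        sched = [(0, 0.06), (60, 0.06), (0, 0.06), (60, 0.06)]
        kym = H.simulate_rotation_kymograph(sched, transition_duration=0.0,
                                            noise=None, seed=0)
        tr = H.measure_rotation_transitions(kym)
        assert len(tr.table) == 3
        assert not tr.table["resolvable"].any()


class TestRotationEnergetics:
    def test_published_barrier_and_velocity(self):
        """tau_rotation = 18 ms against the line-scan tau_state = 35 ms
        gives the ~0.7 kBT barrier and ~3300 deg/s (~550 rpm)."""
        st = H.rotation_energetics(tau_state=0.035, tau_rotation=0.018)
        assert st.delta_g == pytest.approx(0.665, abs=0.001)
        assert round(st.delta_g, 1) == 0.7
        assert st.angular_velocity == pytest.approx(3333.3, rel=1e-3)
        assert st.rpm == pytest.approx(555.6, rel=1e-3)

    def test_height_spectroscopy_dwell_variant(self):
        st = H.rotation_energetics(tau_state=0.026, tau_rotation=0.018)
        assert st.delta_g == pytest.approx(0.368, abs=0.001)

    def test_symmetric_case_zero_barrier(self):
        assert H.rotation_energetics(0.02, 0.02).delta_g == 0.0

    def test_antisymmetric_under_time_exchange(self):
        a = H.rotation_energetics(0.04, 0.01).delta_g
        b = H.rotation_energetics(0.01, 0.04).delta_g
        assert a == pytest.approx(-b, rel=1e-12)

    def test_invalid_times(self):
        with pytest.raises(ValueError):
            H.rotation_energetics(0.0, 0.01)
        with pytest.raises(ValueError):
            H.rotation_energetics(0.01, -1.0)
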