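"""Spike selection, segment search, alignment-averaging and the final
similarity score — checked against exhaustive enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tcrelay as tr
from tcrelay.detect import SpikeEvent
from tcrelay.errors import (ParameterError, SelectionInfeasibleError,
                            UndefinedCorrelationError)
from tcrelay.similarity import AlignmentParams, best_correlated_segments

FS = 100000.0


def spike_from(waveform, trial, trough_ms=10.0):
    waveform = np.asarray(waveform, dtype=float)
    return SpikeEvent(
        subject_id="s1", trial_id=trial, site="cortex", mode="TS",
        trough_time_ms=trough_ms, window_start_ms=trough_ms - 0.3,
        descending_mv=1.0, ascending_mv=1.0, threshold_mv=0.1,
        trough_index=int(trough_ms * 100), window_start_index=0,
        waveform=waveform)


def embedded_template(position, n=2000, amplitude=1.0, width=0.3, noise=0.0,
                      rng=None):
    """A trace with one template trough at the given sample index."""
    template = tr.generate_template(amplitude, width, FS)
    trough = int(np.argmin(template))
    x = np.zeros(n)
    start = position - trough
    x[start:start + template.size] += template
    if noise:
        x += rng.normal(0, noise, n)
    return x


class TestPearson:
    def test_exact_values(self):
        assert tr.pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0, abs=1e-12)
        assert tr.pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0, abs=1e-12)
        assert tr.pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_errors_rather_than_zero(self):
        with pytest.raises(UndefinedCorrelationError):
            tr.pearson_r([1.0, 1.0, 1.0], [1, 2, 3])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            tr.pearson_r([1, 2], [1, 2, 3])

    @given(scale=st.floats(0.01, 100), offset=st.floats(-50, 50))
    def test_invariant_under_positive_affine_transform(self, scale, offset):
        x = np.array([0.1, -0.4, 0.9, 0.2, -0.7])
        y = np.array([0.3, -0.1, 0.5, 0.0, -0.9])
        base = tr.pearson_r(x, y)
        assert tr.pearson_r(scale * x + offset, y) == pytest.approx(base, abs=1e-9)


def oracle_select(spikes):
    """Literal enumeration of the selection rule, on canonical order."""
    spikes = sorted(spikes, key=lambda e: (e.trial_id, e.trough_time_ms))
    n = len(spikes)

    def r(i, j):
        return tr.pearson_r(spikes[i].waveform, spikes[j].waveform)

    best, pair = -2.0, None
    for i in range(n):
        for j in range(i + 1, n):
            if spikes[i].trial_id == spikes[j].trial_id:
                continue
            if r(i, j) > best + 1e-12:
                best, pair = r(i, j), (i, j)
    s1, s2 = pair
    used = {spikes[s1].trial_id, spikes[s2].trial_id}
    cands = [k for k in range(n)
             if k not in pair and spikes[k].trial_id not in used]

    def argmax(anchor, pool):
        top, out = -2.0, None
        for k in pool:
            if r(k, anchor) > top + 1e-12:
                top, out = r(k, anchor), k
        return out, top

    c1, r1 = argmax(s1, cands)
    c2, r2 = argmax(s2, cands)
    if spikes[c1].trial_id != spikes[c2].trial_id:
        s3, s4 = c1, c2
    elif r1 >= r2:
        s3 = c1
        s4, _ = argmax(s2, [k for k in cands
                            if spikes[k].trial_id != spikes[c1].trial_id])
    else:
        s4 = c2
        s3, _ = argmax(s1, [k for k in cands
                            if spikes[k].trial_id != spikes[c2].trial_id])
    return tuple(spikes[k].trial_id for k in (s1, s2, s3, s4))


class TestSelection:
    def _spike_set(self, rng, n_spikes=6):
        base = tr.generate_template(0.5, 0.35, FS)  # 70-sample window
        return [spike_from(base + rng.normal(0, 0.05, base.size), trial=f"t{k}")
                for k in range(n_spikes)]

    def test_constructed_example_selects_best_pair_and_companions(self, rng):
        base = np.sin(np.linspace(0, 2 * np.pi, 70))
        spikes = [
            spike_from(base + 0.001 * rng.normal(size=70), "A"),
            spike_from(base + 0.001 * rng.normal(size=70), "B"),
            spike_from(base + 0.2 * rng.normal(size=70), "C"),
            spike_from(base + 0.5 * rng.normal(size=70), "D"),
        ]
        sel = tr.select_representative_spikes(spikes)
        trials = [s.trial_id for s in sel.spikes]
        assert set(trials[:2]) == {"A", "B"}  # the near-identical pair
        assert set(trials) == {"A", "B", "C", "D"}
        assert trials == list(oracle_select(spikes))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spikes = self._spike_set(rng)
        sel = tr.select_representative_spikes(spikes)
        assert tuple(s.trial_id for s in sel.spikes) == oracle_select(spikes)

    def test_all_four_from_distinct_traces(self, rng):
        spikes = self._spike_set(rng, n_spikes=8)
        # add second spikes in already-used traces
        spikes += [spike_from(spikes[0].waveform + rng.normal(0, 0.01, 70),
                              trial=f"t{k}", trough_ms=30.0) for k in range(3)]
        sel = tr.select_representative_spikes(spikes)
        assert len({s.trial_id for s in sel.spikes}) == 4

    def test_identical_spikes_tie_flagged_and_deterministic(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 70))
        spikes = [spike_from(w.copy(), trial=f"t{k}") for k in range(4)]
        sel = tr.select_representative_spikes(spikes)
        assert sel.tied
        assert [s.trial_id for s in sel.spikes] == ["t0", "t1", "t2", "t3"]

    def test_three_spikes_infeasible(self, rng):
        with pytest.raises(SelectionInfeasibleError):
            tr.select_representative_spikes(self._spike_set(rng, n_spikes=3))

    def test_four_spikes_in_three_traces_infeasible(self, rng):
        spikes = self._spike_set(rng, n_spikes=3)
        spikes.append(spike_from(spikes[0].waveform, trial="t0", trough_ms=30))
        with pytest.raises(SelectionInfeasibleError):
            tr.select_representative_spikes(spikes)


def oracle_segments(a, b, peak_a, peak_b, seg, half):
    """Brute force over every candidate center pair."""
    left = seg // 2
    best = (-2.0, None)
    for ca in range(peak_a - half, peak_a + half + 1):
        for cb in range(peak_b - half, peak_b + half + 1):
            r = tr.pearson_r(a[ca - left:ca - left + seg],
                             b[cb - left:cb - left + seg])
            if r > best[0] + 1e-12:
                best = (r, (ca, cb))
    return best


class TestBestCorrelatedSegments:
    def test_identical_traces_zero_relative_offset(self):
        a = embedded_template(1000)
        m = best_correlated_segments(a, a, 1000, 1000, FS, 0.5, 0.1)
        assert m.r == pytest.approx(1.0, abs=1e-12)
        assert m.center_a == m.center_b

    def test_pure_delay_recovered_with_perfect_correlation(self):
        a = embedded_template(1000)
        b = np.roll(a, 3)
        m = best_correlated_segments(a, b, 1000, 1003, FS, 0.5, 0.1)
        assert m.r == pytest.approx(1.0, abs=1e-12)
        assert m.center_b - m.center_a == 3

    def test_misreported_peak_compensated_within_search(self):
        a = embedded_template(1000)
        m = best_correlated_segments(a, a, 1000, 1003, FS, 0.5, 0.1)
        assert m.r == pytest.approx(1.0, abs=1e-12)
        assert m.center_b == m.center_a  # search undoes the 3-sample error

    def test_zero_search_yields_single_candidate(self):
        a = embedded_template(1000)
        b = embedded_template(1010)
        m = best_correlated_segments(a, b, 1000, 1010, FS, 0.5, 0.0)
        assert (m.offset_a, m.offset_b) == (0, 0)

    def test_segment_out_of_bounds_rejected(self):
        a = np.sin(np.linspace(0, 3, 55))  # too short for centers at 27 +/- 5
        with pytest.raises(ParameterError):
            best_correlated_segments(a, a, 27, 27, FS, 0.5, 0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = embedded_template(300, n=600, noise=0.05, rng=rng)
        b = embedded_template(305, n=600, noise=0.05, rng=rng)
        m = best_correlated_segments(a, b, 300, 305, FS, 0.5, 0.1)
        r, (ca, cb) = oracle_segments(a, b, 300, 305, 50, 5)
        assert m.r == pytest.approx(r, abs=1e-12)
        assert (m.center_a, m.center_b) == (ca, cb)


class TestAlignAverage:
    def test_average_of_identical_traces_is_identity(self):
        a = embedded_template(1000)
        out = tr.align_average_pair(a, 1000, a, 1000, FS)
        np.testing.assert_allclose(out.samples, a, atol=1e-15)
        assert out.shift_samples == 0

    def test_noiseless_shift_fully_recovered(self):
        a = embedded_template(1000)
        b = embedded_template(1004)
        out = tr.align_average_pair(a, 1000, b, 1004, FS)
        assert out.shift_samples == 1000 - 1004
        # averaged spike equals the template exactly on the common support
        seg = out.samples[out.peak_index - 30:out.peak_index + 30]
        ref = a[1000 - 30:1000 + 30]
        np.testing.assert_allclose(seg, ref, atol=1e-12)

    def test_noise_reduced_by_sqrt2(self):
        """Averaging two independent noise realizations of one template
        leaves residual SD ~ sigma / sqrt(2) (measured on the spike-free
        stretch, where alignment jitter cannot leak template error in)."""
        rng = np.random.default_rng(99)
        sigma = 0.01
        sds = []
        for _ in range(40):
            a = embedded_template(1000, noise=sigma, rng=rng)
            b = embedded_template(1000, noise=sigma, rng=rng)
            out = tr.align_average_pair(a, 1000, b, 1000, FS)
            p = out.peak_index
            sds.append(np.std(out.samples[p + 300:p + 900]))
        assert np.mean(sds) == pytest.approx(sigma / np.sqrt(2), rel=0.10)


class TestHierarchicalAverage:
    def test_four_identical_traces_return_the_input(self):
        a = embedded_template(1000)
        out = tr.hierarchical_average([a, a.copy(), a.copy(), a.copy()],
                                      [1000] * 4, FS)
        np.testing.assert_allclose(out.samples, a, atol=1e-15)
        assert out.stage_shifts_ms == (0.0, 0.0, 0.0)

    def test_four_shifted_copies_recover_the_template(self):
        positions = [1000, 1003, 998, 1005]
        traces = [embedded_template(p) for p in positions]
        out = tr.hierarchical_average(traces, positions, FS)
        template = tr.generate_template(1.0, 0.3, FS)
        trough = int(np.argmin(template))
        seg = out.samples[out.peak_index - trough:
                          out.peak_index - trough + template.size]
        np.testing.assert_allclose(seg, template, atol=1e-12)

    def test_four_noisy_copies_halve_the_noise(self):
        rng = np.random.default_rng(7)
        sigma = 0.01
        sds = []
        for _ in range(30):
            traces = [embedded_template(1000, noise=sigma, rng=rng)
                      for _ in range(4)]
            out = tr.hierarchical_average(traces, [1000] * 4, FS)
            p = out.peak_index
            sds.append(np.std(out.samples[p + 300:p + 900]))
        assert np.mean(sds) == pytest.approx(sigma / 2.0, rel=0.10)

    def test_sequential_pairing_switch(self):
        positions = [1000, 1002, 999, 1001]
        traces = [embedded_template(p) for p in positions]
        out = tr.hierarchical_average(
            traces, positions, FS, AlignmentParams(pairing="sequential"))
        template = tr.generate_template(1.0, 0.3, FS)
        trough = int(np.argmin(template))
        seg = out.samples[out.peak_index - trough:
                          out.peak_index - trough + template.size]
        np.testing.assert_allclose(seg, template, atol=1e-12)


def averaged(samples, peak, mode, subject="s1"):
    return tr.AveragedWaveform(
        subject_id=subject, mode=mode, spike_trials=("a", "b", "c", "d"),
        samples=np.asarray(samples, dtype=float), peak_index=peak,
        sampling_rate=FS, stage_shifts_ms=(0.0, 0.0, 0.0))


class TestFinalSimilarity:
    def test_identical_averages_give_r_one(self):
        a = embedded_template(1000)
        rep = tr.final_similarity(averaged(a, 1000, "TS"),
                                  averaged(a, 1000, "ES"))
        assert rep.r == pytest.approx(1.0, abs=1e-12)
        assert rep.ts_segment.size == rep.es_segment.size == 100

    def test_sign_flip_gives_minus_one(self):
        # with a degenerate center search the matched segments are compared
        # directly; a free search would instead maximize r over alignments
        a = embedded_template(1000)
        rep = tr.final_similarity(averaged(a, 1000, "TS"),
                                  averaged(-a, 1000, "ES"),
                                  tr.AlignmentParams(center_search_ms=0.0))
        assert rep.r == pytest.approx(-1.0, abs=1e-12)
        free = tr.final_similarity(averaged(a, 1000, "TS"),
                                   averaged(-a, 1000, "ES"))
        assert free.r < 0.0

    def test_shared_template_with_residual_noise_highly_similar(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            a = embedded_template(1000, amplitude=0.5, noise=0.01, rng=rng)
            b = embedded_template(1000, amplitude=0.5, noise=0.01, rng=rng)
            rep = tr.final_similarity(averaged(a, 1000, "TS"),
                                      averaged(b, 1000, "ES"))
            hits += rep.r > 0.9
        assert hits >= 19

    def test_r_invariant_to_scaling_and_offset(self):
        rng = np.random.default_rng(3)
        a = embedded_template(1000, noise=0.02, rng=rng)
        b = embedded_template(1000, noise=0.02, rng=rng)
        base = tr.final_similarity(averaged(a, 1000, "TS"),
                                   averaged(b, 1000, "ES")).r
        scaled = tr.final_similarity(averaged(a, 1000, "TS"),
                                     averaged(3.0 * b + 0.5, 1000, "ES")).r
        assert scaled == pytest.approx(base, abs=1e-9)
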