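"""Local-peak filter, ion tracing, averagine envelopes, monoisotopic correction."""

import numpy as np
import pytest

from glycoridge.constants import (
    AVERAGINE_COMPOSITION,
    AVERAGINE_MASS,
    ISOTOPE_ABUNDANCES,
    ISOTOPE_SPACING,
    PROTON_MASS,
)
from glycoridge.formats_io import MS1Signal
from glycoridge.peak_detection import (
    IsotopeEnvelope,
    RangeSetting,
    assign_monoisotopic,
    averagine_envelope,
    detect_local_peaks,
    envelope_fit_score,
    filter_signals,
    integrate_envelope,
    trace_ion_group,
)


def _random_signals(rng, n, scan_hi=20, mass_lo=900.0, mass_hi=1100.0):
    return [
        MS1Signal(
            int(rng.integers(1, scan_hi)),
            0.0,
            float(rng.uniform(mass_lo, mass_hi)),
            float(rng.uniform(1, 1000)),
        )
        for _ in range(n)
    ]


def _local_peak_oracle(signals):
    """Exhaustive O(n^2) window-maximum dominance check."""
    peaks = []
    for s in signals:
        beaten = False
        for o in signals:
            if o is s:
                continue
            if abs(o.scan_index - s.scan_index) <= 2 and abs(o.mass - s.mass) <= 2.5:
                if (o.intensity, -o.scan_index, -o.mass) > (s.intensity, -s.scan_index, -s.mass):
                    beaten = True
                    break
        if not beaten:
            peaks.append(s)
    return sorted(peaks, key=lambda s: (s.scan_index, s.mass))


class TestFilter:
    def test_identity_with_open_ranges(self):
        rng = np.random.default_rng(0)
        signals = _random_signals(rng, 30)
        setting = RangeSetting(0, 100, 0, 10000, 0)
        assert filter_signals(signals, setting) == signals

    def test_all_below_threshold(self):
        signals = [MS1Signal(1, 0.5, 1000.0, 10.0)]
        assert filter_signals(signals, RangeSetting(min_intensity=11.0)) == []

    def test_matches_brute_force_at_median_threshold(self):
        rng = np.random.default_rng(1)
        signals = _random_signals(rng, 101)
        thr = float(np.median([s.intensity for s in signals]))
        setting = RangeSetting(0, 100, 950, 1050, thr)
        expect = [
            s for s in signals
            if 950 <= s.mass <= 1050 and 0 <= s.rt <= 100 and s.intensity >= thr
        ]
        assert filter_signals(signals, setting) == expect

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            RangeSetting(rt_min=10, rt_max=5)


class TestLocalPeaks:
    def test_isolated_signal_is_a_peak(self):
        s = MS1Signal(5, 1.0, 1000.0, 10.0)
        assert detect_local_peaks([s]) == [s]

    def test_isotope_neighbour_suppressed(self):
        a = MS1Signal(3, 1.0, 1000.0, 100.0)
        b = MS1Signal(3, 1.0, 1001.0033, 60.0)
        assert detect_local_peaks([a, b]) == [a]

    @pytest.mark.parametrize("seed", [0, 1, 7, 42])
    def test_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        signals = _random_signals(rng, 50, scan_hi=8, mass_lo=995.0, mass_hi=1010.0)
        assert detect_local_peaks(signals) == _local_peak_oracle(signals)

    def test_oracle_equivalence_on_larger_instances(self):
        rng = np.random.default_rng(11)
        signals = _random_signals(rng, 200, scan_hi=15, mass_lo=990.0, mass_hi=1020.0)
        assert detect_local_peaks(signals) == _local_peak_oracle(signals)


class TestTracing:
    def _trace_signals(self, scans, mass=1500.0):
        return [MS1Signal(s, s * 0.01, mass, 100.0 - abs(s - 12)) for s in scans]

    def test_trace_spans_contiguous_scans(self):
        signals = self._trace_signals(range(10, 16))
        peak = max(signals, key=lambda s: s.intensity)
        group = trace_ion_group(peak, signals)
        assert group.scan_span == (10, 15)

    def test_trace_stops_before_large_gap(self):
        signals = self._trace_signals([10, 11]) + self._trace_signals([14, 15])
        peak = signals[1]  # scan 11
        group = trace_ion_group(peak, signals, max_gap_scans=1)
        assert group.scan_span == (10, 11)

    def test_gap_of_one_scan_is_bridged(self):
        signals = self._trace_signals([10, 11, 13])
        group = trace_ion_group(signals[1], signals, max_gap_scans=1)
        assert group.scan_span == (10, 13)


class TestIntegration:
    def _ladder(self, scan, mono=2000.0, rels=(1.0, 0.8, 0.4), scale=100.0):
        return [
            MS1Signal(scan, scan * 0.01, mono + m * ISOTOPE_SPACING, scale * r)
            for m, r in enumerate(rels)
        ]

    def test_single_scan_group(self):
        signals = self._ladder(10)
        group = trace_ion_group(signals[0], signals)
        env = integrate_envelope(group, signals)
        assert [i for _, i in env.peaks] == pytest.approx([100.0, 80.0, 40.0])

    def test_three_scan_symmetric_profile_triples_envelope(self):
        signals = []
        for scan in (9, 10, 11):
            signals.extend(self._ladder(scan))
        apex = [s for s in signals if s.scan_index == 10][0]
        group = trace_ion_group(apex, signals)
        env = integrate_envelope(group, signals, n_flank_scans=2)
        assert [i for _, i in env.peaks] == pytest.approx([300.0, 240.0, 120.0])


def _averagine_direct_oracle(neutral_mass):
    """Atom-by-atom convolution (independent of squaring exponentiation)."""
    n_units = neutral_mass / AVERAGINE_MASS
    dist = np.array([1.0])
    for el, per_unit in AVERAGINE_COMPOSITION.items():
        count = max(0, round(per_unit * n_units))
        iso = ISOTOPE_ABUNDANCES[el]
        base = np.zeros(max(d for d, _ in iso) + 1)
        for d, p in iso:
            base[d] = p
        for _ in range(count):
            dist = np.convolve(dist, base)
    return dist / dist.max()


class TestAveragine:
    def test_distribution_sums_to_one_after_total_normalisation(self):
        env = averagine_envelope(2500.0)
        rels = env.intensities()
        assert rels.sum() > 0
        assert (rels / rels.sum()).sum() == pytest.approx(1.0)

    def test_small_mass_mono_is_most_intense(self):
        env = averagine_envelope(500.0)
        assert int(np.argmax(env.intensities())) == 0

    def test_large_mass_mono_is_not_most_intense(self):
        env = averagine_envelope(5000.0)
        assert int(np.argmax(env.intensities())) > 0

    @pytest.mark.parametrize("mass", [800.0, 2500.0, 5000.0])
    def test_matches_direct_convolution_oracle(self, mass):
        env = averagine_envelope(mass, min_rel_intensity=1e-6)
        oracle = _averagine_direct_oracle(mass)
        got = env.intensities()
        assert np.allclose(got, oracle[: len(got)], atol=1e-9)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            averagine_envelope(0.0)


def _observed_at(mono_mh, noise_sigma=0.0, rng=None, drop_mono=False):
    env = averagine_envelope(mono_mh - PROTON_MASS)
    peaks = [(mono_mh + m * ISOTOPE_SPACING, rel) for m, (_, rel) in enumerate(env.peaks)]
    if drop_mono:
        peaks = peaks[1:]
    if noise_sigma and rng is not None:
        peaks = [(m, rel * (1 + noise_sigma * rng.standard_normal())) for m, rel in peaks]
        peaks = [(m, max(rel, 1e-6)) for m, rel in peaks]
    return IsotopeEnvelope(peaks)


class TestMonoisotopicCorrection:
    def test_exact_envelope_needs_no_correction(self):
        mono = 3000.0
        mono_out, flag = assign_monoisotopic(_observed_at(mono), mono)
        assert flag == 0
        assert mono_out == pytest.approx(mono)

    def test_deleted_mono_peak_corrected_down_one_isotope(self):
        """A 5 kDa envelope missing its mono rung, anchored at the 2nd
        isotope, is corrected one isotope down with the update flag set."""
        mono = 5000.0
        observed = _observed_at(mono, drop_mono=True)
        initial = observed.peaks[0][0]
        assert initial == pytest.approx(mono + ISOTOPE_SPACING)
        mono_out, flag = assign_monoisotopic(observed, initial)
        assert flag == 1
        assert mono_out == pytest.approx(initial - ISOTOPE_SPACING)

    def test_scale_invariance(self):
        mono = 4200.0
        observed = _observed_at(mono, drop_mono=True)
        initial = observed.peaks[0][0]
        scaled = IsotopeEnvelope([(m, i * 1234.5) for m, i in observed.peaks])
        assert assign_monoisotopic(observed, initial) == assign_monoisotopic(scaled, initial)

    def test_idempotent_after_correction(self):
        mono = 5000.0
        observed = _observed_at(mono, drop_mono=True)
        corrected, flag = assign_monoisotopic(observed, observed.peaks[0][0])
        assert flag == 1
        _, flag2 = assign_monoisotopic(_observed_at(corrected), corrected)
        assert flag2 == 0

    def test_planted_offset_recovery_rate(self):
        """>=95% of 200 noisy envelopes with planted offsets are recovered."""
        rng = np.random.default_rng(7)
        recovered = 0
        n = 200
        for _ in range(n):
            mono = float(rng.uniform(1500.0, 5500.0))
            offset = int(rng.integers(-1, 2))
            observed = _observed_at(mono, noise_sigma=0.05, rng=rng)
            initial = mono + offset * ISOTOPE_SPACING
            mono_out, flag = assign_monoisotopic(observed, initial)
            if abs(mono_out - mono) < 0.5 * ISOTOPE_SPACING and flag == (offset != 0):
                recovered += 1
        assert recovered / n >= 0.95

    def test_single_rung_envelope_left_alone(self):
        env = IsotopeEnvelope([(2000.0, 1.0)])
        assert assign_monoisotopic(env, 2000.0) == (2000.0, 0)

    def test_fit_score_is_cosine_bounded(self):
        a = _observed_at(3000.0)
        assert 0.999 <= envelope_fit_score(a, a, anchor=3000.0) <= 1.0
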