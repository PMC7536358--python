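"""Comparator sampling, deadtime logic, threshold scans and E1/2."""

import numpy as np
import pytest

from pcdsim.counting import (
    ComparatorBank,
    ExtractionError,
    ThresholdScan,
    build_pulse_train,
    count_frame,
    count_rate_curve,
    deadtime_for,
    extract_e_half,
    shaped_kernels,
    simulate_threshold_scan,
)
from pcdsim.readout import VoltagePulse, pulse_length


@pytest.fixture(scope="module")
def kernels_40ns(ideal_config):
    """keV-calibrated shaped kernels of the 40-ns ideal channel."""
    kernels, gain = shaped_kernels(ideal_config, energy_kev=60.0, seed=0)
    return [k / gain for k in kernels]


def make_waveform(kernels, energies, times_ns, n_samples, rng=None):
    wf = np.zeros(n_samples)
    for e, t in zip(energies, times_ns):
        k = kernels[0]
        i0 = int(round(t / 2.0))
        seg = min(len(k), n_samples - i0)
        wf[i0:i0 + seg] += e * k[:seg]
    return wf


class TestBankValidation:
    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            ComparatorBank((10.0, 5.0), deadtime_ns=100.0)

    def test_deadtime_clock_multiple(self):
        with pytest.raises(ValueError):
            ComparatorBank((5.0,), deadtime_ns=55.0, clock_ns=10.0)

    def test_at_most_eight_thresholds(self):
        with pytest.raises(ValueError):
            ComparatorBank(tuple(range(1, 10)), deadtime_ns=100.0)


class TestCountFrame:
    def test_empty_train_zero_counts(self, rng):
        bank = ComparatorBank((5.0,), deadtime_ns=100.0)
        counts = count_frame(np.zeros(50_000), 2.0, bank, rng)
        assert counts.sum() == 0

    def test_single_pulse_binned_by_peak(self, kernels_40ns, rng):
        """One isolated 60-keV pulse with thresholds {5,30,50,70} keV gives
        exactly one count, in the 50-70 keV bin."""
        wf = make_waveform(kernels_40ns, [60.0], [20_000.0], 30_000)
        bank = ComparatorBank((5.0, 30.0, 50.0, 70.0), deadtime_ns=200.0)
        counts = count_frame(wf, 2.0, bank, rng)
        assert counts.tolist() == [0, 0, 1, 0]

    def test_long_pulse_double_counted(self, kernels_40ns, rng):
        """A pulse whose length at the lowest threshold exceeds deadtime +
        clock re-triggers after deadtime expiry: two counts."""
        wf = make_waveform(kernels_40ns, [60.0], [20_000.0], 30_000)
        pulse = VoltagePulse(wf, 2.0)
        thr = 10.0
        length = pulse_length(pulse, thr)
        deadtime = 70.0
        assert length > deadtime + 10.0
        bank = ComparatorBank((thr,), deadtime_ns=deadtime)
        counts = count_frame(wf, 2.0, bank, rng)
        assert counts.sum() == 2

    def test_deadtime_hard_bound(self, kernels_40ns):
        """Registered counts never exceed ceil(T / deadtime): with retrigger
        allowed on the first clock edge at deadtime expiry (the semantics
        behind the deadtime + clock/2 pulse-length identity), one count per
        deadtime is the non-paralyzable ceiling."""
        rng = np.random.default_rng(0)
        n = 50_000  # 100 us
        wf = 100.0 * np.ones(n)  # pathological always-high signal
        bank = ComparatorBank((5.0,), deadtime_ns=100.0)
        counts = count_frame(wf, 2.0, bank, rng)
        assert counts.sum() <= int(np.ceil(n * 2.0 / 100.0)) + 1

    def test_registered_spectrum_matches_input_histogram(self, kernels_40ns, rng):
        """Well-separated noise-free pulses land exactly in the threshold
        bins of their deposited energies."""
        energies = [12.0, 35.0, 35.0, 55.0, 75.0, 75.0, 75.0]
        times = [4000.0 * (i + 1) for i in range(len(energies))]
        wf = make_waveform(kernels_40ns, energies, times, 40_000)
        bank = ComparatorBank((5.0, 20.0, 45.0, 65.0), deadtime_ns=200.0)
        counts = count_frame(wf, 2.0, bank, rng)
        assert counts.tolist() == [1, 2, 1, 3]


@pytest.fixture(scope="module")
def scans(ideal_config):
    return simulate_threshold_scan(
        60.0, [70.0, 90.0, 400.0], ideal_config, n_pulses=400, seed=1)


class TestThresholdScan:
    def test_long_deadtime_plateau_at_one(self, scans):
        """Deadtime far beyond the pulse length counts every pulse once."""
        scan = scans[2]
        plateau = scan.normalized[(scan.thresholds_kev > 20)
                                  & (scan.thresholds_kev < 50)]
        np.testing.assert_allclose(plateau, 1.0, atol=0.02)

    def test_two_to_one_structure_matches_pulse_length(self, scans, ideal_config):
        """Normalized counts are 2 where the pulse outlives deadtime + clock
        and 1 where it is shorter (waveform oracle via pulse_length)."""
        kernels, gain = shaped_kernels(ideal_config, energy_kev=60.0, seed=0)
        mean = np.mean(np.array(kernels), axis=0) * 60.0 / gain
        pulse = VoltagePulse(mean, 2.0)
        scan = scans[0]  # deadtime 70 ns
        for thr, norm in zip(scan.thresholds_kev, scan.normalized):
            if not 16.0 < thr < 55.0:
                continue
            length = pulse_length(pulse, thr)
            if length > scan.deadtime_ns + 12.0:
                assert norm == pytest.approx(2.0, abs=0.1)
            elif length < scan.deadtime_ns - 2.0:
                assert norm == pytest.approx(1.0, abs=0.1)

    def test_noise_region_exceeds_two(self, scans):
        """Below ~4 sigma the electronic noise adds false counts on top of
        the double-counted pulses."""
        scan = scans[0]
        low = scan.normalized[scan.thresholds_kev < 6.0]
        assert low.max() > 2.0

    def test_e_half_decreases_with_deadtime(self, scans):
        e1 = extract_e_half(scans[0])
        e2 = extract_e_half(scans[1])
        assert e1 > e2  # longer deadtime -> transition at lower threshold

    def test_csv_roundtrip(self, scans, tmp_path):
        path = tmp_path / "scan.csv"
        scans[0].to_csv(path)
        back = ThresholdScan.from_csv(path)
        np.testing.assert_allclose(back.thresholds_kev, scans[0].thresholds_kev)
        np.testing.assert_allclose(back.counts, scans[0].counts)
        assert back.deadtime_ns == scans[0].deadtime_ns


class TestExtractEHalf:
    def test_exact_step_recovered(self):
        thr = np.arange(16.0, 50.0, 0.5)
        counts = np.where(thr < 30.0, 200.0, 100.0)
        scan = ThresholdScan(thr, counts, 100, 60.0, 70.0)
        assert extract_e_half(scan) == pytest.approx(30.0, abs=0.26)

    def test_no_transition_raises(self):
        thr = np.arange(16.0, 50.0, 0.5)
        scan = ThresholdScan(thr, np.full(thr.size, 100.0), 100, 60.0, 400.0)
        with pytest.raises(ExtractionError):
            extract_e_half(scan)

    def test_noise_region_excluded(self):
        """A spurious crossing below the exclusion threshold is ignored."""
        thr = np.arange(2.0, 50.0, 0.5)
        counts = np.where(thr < 10.0, 500.0, np.where(thr < 30.0, 200.0, 100.0))
        scan = ThresholdScan(thr, counts, 100, 60.0, 70.0)
        assert extract_e_half(scan) == pytest.approx(30.0, abs=0.26)


class TestOperatingPoint:
    def test_threshold_is_four_sigma(self, sources):
        from pcdsim.noise import sigma_ideal_kev

        op = deadtime_for(100.0, sources)
        assert op.threshold_kev == pytest.approx(4 * sigma_ideal_kev(100.0), rel=1e-9)

    def test_deadtime_is_clock_multiple_covering_length(self, sources):
        op = deadtime_for(40.0, sources)
        assert op.deadtime_ns % 10.0 == 0
        assert 0 <= op.deadtime_ns - op.pulse_length_ns < 10.0


class TestCountRate:
    def test_monotone_then_saturating(self, sources):
        """Output rate rises with input rate; the 40-ns channel saturates
        above the 200-ns channel's bound 1/(deadtime + clock)."""
        rng_dep = lambda rng, n: np.full(n, 60.0)
        fluxes = [2e5, 2e6, 2e7]
        inp, out40 = count_rate_curve(fluxes, 40.0, rng_dep, n_frames=3,
                                      frame_us=100.0, sources=sources, seed=2)
        _, out200 = count_rate_curve(fluxes, 200.0, rng_dep, n_frames=3,
                                     frame_us=100.0, sources=sources, seed=2)
        assert out40[0] < out40[1] < out40[2]
        op40 = deadtime_for(40.0, sources)
        op200 = deadtime_for(200.0, sources)
        assert out40[2] <= 1.0 / (op40.deadtime_ns * 1e-9)
        assert out200[2] <= 1.0 / (op200.deadtime_ns * 1e-9)
        # shorter shaping time -> higher saturated rate
        assert out40[2] > out200[2]

    def test_poisson_arrivals(self, kernels_40ns):
        rng = np.random.default_rng(9)
        sampler = lambda r, n: np.full(n, 60.0)
        train = build_pulse_train(1e6, 150.0, sampler, kernels_40ns, 2.0, rng)
        assert train.photon_times_ns.size == train.photon_energies_kev.size
        assert np.all(np.diff(train.photon_times_ns) >= 0)
        assert train.photon_times_ns.max() <= 150_000.0
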