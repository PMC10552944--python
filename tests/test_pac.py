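"""Phase-amplitude coupling: KL modulation index, surrogates, comodulograms."""
import numpy as np
import pytest

from speechosc import (
    BandPair,
    PacSpec,
    SimulationSpec,
    comodulogram_conditions,
    extract_phase_amp,
    gen_eeg,
    gen_envelope,
    mi_analytic_profile,
    modulation_index,
    trial_mi_with_surrogates,
)
from speechosc.pac import phase_bin_indices

RATE = 500.0


def _dense_phase(n_per_bin=4000, n_bins=18):
    """Deterministic uniform phase sampling, n_per_bin points per bin."""
    return np.linspace(-np.pi, np.pi, n_bins * n_per_bin, endpoint=False)


class TestBandPair:
    def test_variable_bandwidth_rule(self):
        pair = BandPair(fp_center=6.0, fa_center=36.0)
        assert pair.phase_band == (5.0, 7.0)
        assert pair.amp_band == (30.0, 42.0)

    @pytest.mark.parametrize("fp,fa", [(6.0, 6.5), (10.0, 9.0), (20.0, 18.0)])
    def test_amplitude_band_must_clear_phase_band(self, fp, fa):
        with pytest.raises(ValueError):
            BandPair(fp_center=fp, fa_center=fa)


class TestExtractPhaseAmp:
    def test_phase_advances_one_cycle_per_period(self):
        t = np.arange(int(6 * RATE)) / RATE
        x = np.sin(2 * np.pi * 6 * t)
        phase, _ = extract_phase_amp(x, RATE, BandPair(6.0, 36.0))
        # 6 Hz: 2*pi per 166.7 ms = 83.3 samples at 500 Hz
        dphi = np.diff(np.unwrap(phase[500:-500]))
        cycles_per_s = np.mean(dphi) * RATE / (2 * np.pi)
        assert cycles_per_s == pytest.approx(6.0, abs=0.05)

    def test_pure_fast_tone_has_constant_amplitude(self):
        t = np.arange(int(6 * RATE)) / RATE
        x = np.sin(2 * np.pi * 36 * t)
        _, amp = extract_phase_amp(x, RATE, BandPair(6.0, 36.0))
        interior = amp[500:-500]
        assert interior.std() / interior.mean() < 0.02

    def test_depth_one_amplitude_peaks_at_phase_zero(self):
        spec = SimulationSpec(n_trials=12, trial_ms=2000.0, n_channels=2, seed=3,
                              snr=0.0, embed_channels=("E1",), rate=RATE,
                              pac=(PacSpec(6.0, 36.0, 1.0, channels=("E1",),
                                           fast_amp=2.0),))
        env = gen_envelope(spec)
        eeg, _ = gen_eeg(spec, env)
        post = eeg.time_window(100.0, 1900.0)
        x = eeg.data[:, 0, post]
        phase, amp = extract_phase_amp(x, RATE, BandPair(6.0, 36.0))
        bins = phase_bin_indices(phase.ravel())
        means = np.array([amp.ravel()[bins == b].mean() for b in range(18)])
        # bin 9 starts at phase 0
        assert means.argmax() in (8, 9, 10)


class TestModulationIndex:
    def test_uniform_amplitude_gives_zero(self):
        phase = _dense_phase()
        assert modulation_index(phase, np.ones_like(phase)) < 1e-12

    def test_single_bin_concentration_gives_one(self):
        phase = _dense_phase(100)
        amp = np.zeros_like(phase)
        amp[phase_bin_indices(phase) == 4] = 3.3
        assert modulation_index(phase, amp) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("depth", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    def test_cosine_profile_matches_bin_mean_oracle(self, depth):
        phase = _dense_phase()
        amp = 1.0 + depth * np.cos(phase)
        assert modulation_index(phase, amp) == pytest.approx(
            mi_analytic_profile(depth), abs=1e-6
        )

    def test_monotone_in_depth(self):
        mis = [mi_analytic_profile(d) for d in np.arange(0, 1.01, 0.2)]
        assert np.all(np.diff(mis) > 0)

    def test_invariant_to_amplitude_rescaling(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        assert modulation_index(phase, amp) == pytest.approx(
            modulation_index(phase, 17.3 * amp), abs=1e-12
        )

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            modulation_index(np.zeros(10), np.full(10, -1.0))

    def test_sparse_phase_sampling_warns_on_empty_bins(self):
        with pytest.warns(UserWarning, match="empty"):
            modulation_index(np.zeros(5), np.ones(5))


class TestSurrogates:
    def _phase_amp(self, n_trials=12, T=400, coupled=True, seed=0):
        rng = np.random.default_rng(seed)
        phase = rng.uniform(-np.pi, np.pi, (n_trials, T))
        if coupled:
            amp = 1 + 0.8 * np.cos(phase) + 0.1 * rng.standard_normal((n_trials, T))
        else:
            amp = 1 + 0.1 * rng.standard_normal((n_trials, T))
        return phase, np.clip(amp, 0, None)

    def test_coupled_trials_give_large_z(self):
        phase, amp = self._phase_amp(coupled=True)
        mi, z, mu, sd = trial_mi_with_surrogates(
            phase, amp, 200, np.random.default_rng(1)
        )
        assert z > 5 and mi > mu

    def test_uncoupled_trials_give_standard_normal_z(self):
        zs = []
        for seed in range(60):
            phase, amp = self._phase_amp(coupled=False, seed=seed)
            _, z, _, _ = trial_mi_with_surrogates(
                phase, amp, 100, np.random.default_rng(seed + 500)
            )
            zs.append(z)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.35
        assert 0.7 < zs.std() < 1.4

    def test_seeded_surrogates_are_reproducible(self):
        phase, amp = self._phase_amp()
        out1 = trial_mi_with_surrogates(phase, amp, 50, np.random.default_rng(7))
        out2 = trial_mi_with_surrogates(phase, amp, 50, np.random.default_rng(7))
        assert out1 == out2

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 trials"):
            trial_mi_with_surrogates(np.zeros((1, 100)), np.ones((1, 100)), 10)


@pytest.fixture(scope="module")
def coupled_run():
    cluster = ("E1", "E2", "E3", "E4", "E5", "E6")
    spec = SimulationSpec(
        n_trials=40, trial_ms=2000.0, pre_ms=1000.0, rate=RATE, n_channels=8,
        seed=1, snr=0.0, embed_channels=("E1",),
        pac=(PacSpec(6.0, 36.0, 0.8, channels=cluster),),
    )
    env = gen_envelope(spec)
    eeg, _ = gen_eeg(spec, env)
    return comodulogram_conditions(
        eeg, channels=list(cluster), n_surrogates=200,
        rng=np.random.default_rng(0),
    )


class TestComodulogram:

    def test_grid_dimensions(self, coupled_run):
        sp = coupled_run["speech"]
        assert sp.mi.shape == (14, 18)
        assert sp.phase_freqs[0] == 2.0 and sp.phase_freqs[-1] == 15.0
        assert sp.amp_freqs[0] == 16.0 and sp.amp_freqs[-1] == 50.0

    def test_speech_coupling_centroid_recovers_planted_pair(self, coupled_run):
        assert coupled_run["speech"].coupling_centroid() == (6.0, 36.0)

    def test_speech_argmax_within_analysis_bandwidth(self, coupled_run):
        fp, fa = coupled_run["speech"].argmax_cell()
        assert fp == 6.0
        assert abs(fa - 36.0) <= 6.0  # the +/- f_p structural resolution

    def test_baseline_without_coupling_stays_null(self, coupled_run):
        base = coupled_run["baseline"]
        frac = np.nanmean(np.abs(base.z) > 1.96)
        assert frac < 0.15
        assert np.nanmax(base.z) < np.nanmax(coupled_run["speech"].z) / 2

    def test_mi_within_unit_interval(self, coupled_run):
        for c in coupled_run.values():
            finite = c.mi[np.isfinite(c.mi)]
            assert np.all((finite >= 0) & (finite <= 1))

    def test_screening_confirms_slow_spectral_peak(self, coupled_run):
        sp = coupled_run["speech"]
        assert sp.screening[list(sp.phase_freqs).index(6.0)]
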