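"""Phase response curves: protocol, aggregation and feature extraction."""

import numpy as np
import pytest

from thetanet.cell import (
    DEFAULT_DT,
    PYR_DEFAULTS,
    CurrentProtocol,
    integrate_cell,
    resting_state,
)
from thetanet.prc import (
    MeanPRC,
    NotOscillatingError,
    PRCResult,
    compute_prc,
    extract_prc_features,
    mean_prc,
    prc_population_study,
)


@pytest.fixture(scope="module")
def default_prc():
    return compute_prc(PYR_DEFAULTS, 20.0)


def synthetic_prc(shifts, I_tonic=20.0):
    shifts = np.asarray(shifts, dtype=float)
    n = len(shifts)
    return PRCResult(lam=100.0, phases=np.arange(1, n + 1) / n,
                     shifts=shifts, I_tonic=I_tonic,
                     pulse_amp=-500.0, pulse_dur=1.0)


class TestProtocol:
    def test_null_perturbation_gives_exactly_zero_prc(self):
        r = compute_prc(PYR_DEFAULTS, 20.0, pulse_amp=0.0)
        assert np.all(r.shifts == 0.0)

    def test_shifts_match_trace_differencing_oracle(self, default_prc):
        """Recompute perturbed periods for a few phases by building the
        pulse protocol explicitly and differencing raw spike times."""
        r = default_prc
        # unperturbed spike times via the public integrator
        trace = integrate_cell(PYR_DEFAULTS, resting_state(PYR_DEFAULTS),
                               CurrentProtocol.constant(20.0, 6000.0))
        s = trace.spike_times
        t10, lam_ref = s[9], s[10] - s[9]
        assert r.lam == pytest.approx(s[9] - s[8])
        for i in (10, 30, 55, 90):
            t_pulse = t10 + i * r.lam / 100.0
            n_steps = int(round(6000.0 / DEFAULT_DT))
            I = np.full(n_steps, 20.0)
            start = int(round(t_pulse / DEFAULT_DT))
            I[start:start + int(round(1.0 / DEFAULT_DT))] += -500.0
            proto = CurrentProtocol([(6000.0, 0.0)], noise=I)
            pert = integrate_cell(PYR_DEFAULTS, resting_state(PYR_DEFAULTS),
                                  proto)
            after = pert.spike_times[pert.spike_times > t10 + DEFAULT_DT / 2]
            lam_p = after[0] - t10
            assert r.shifts[i - 1] == pytest.approx(
                (lam_ref - lam_p) / r.lam, abs=1e-12)

    def test_sign_convention_depolarizing_pulse_advances(self):
        r = compute_prc(PYR_DEFAULTS, 20.0, pulse_amp=500.0)
        assert r.shifts[49] > 0  # mid-phase depolarization -> advance

    def test_intrinsic_frequency_monotone_over_current_sweep(self):
        freqs = [compute_prc(PYR_DEFAULTS, I).intrinsic_frequency
                 for I in range(20, 31, 2)]
        assert all(f2 >= f1 for f1, f2 in zip(freqs, freqs[1:]))

    def test_determinism_bit_identical(self, default_prc):
        again = compute_prc(PYR_DEFAULTS, 20.0)
        assert np.array_equal(default_prc.shifts, again.shifts)
        assert default_prc.lam == again.lam

    def test_non_oscillating_cell_raises(self):
        with pytest.raises(NotOscillatingError):
            compute_prc(PYR_DEFAULTS, 0.0)

    def test_period_settled_by_ninth_spike(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            compute_prc(PYR_DEFAULTS, 24.0, pulse_amp=0.0)


class TestMeanPRC:
    def test_singleton_population_mean_is_identity_sd_zero(self,
                                                           default_prc):
        m = mean_prc([default_prc])
        assert np.array_equal(m.mean_shift, default_prc.shifts)
        assert np.all(m.sd_shift == 0.0)
        assert m.n_models == 1

    def test_mirror_image_population_averages_to_zero(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=100)
        m = mean_prc([synthetic_prc(s), synthetic_prc(-s)])
        assert np.allclose(m.mean_shift, 0.0)

    def test_mean_and_sd_match_bruteforce_recomputation(self):
        rng = np.random.default_rng(4)
        pop = [synthetic_prc(rng.normal(size=100)) for _ in range(7)]
        m = mean_prc(pop)
        stack = np.vstack([p.shifts for p in pop])
        for j in range(100):
            col = stack[:, j]
            assert m.mean_shift[j] == pytest.approx(col.sum() / len(col))
            mu = col.sum() / len(col)
            assert m.sd_shift[j] == pytest.approx(
                np.sqrt(((col - mu) ** 2).sum() / len(col)))

    def test_mixed_tonic_currents_rejected(self):
        with pytest.raises(ValueError, match="tonic"):
            mean_prc([synthetic_prc(np.zeros(100), I_tonic=20.0),
                      synthetic_prc(np.zeros(100), I_tonic=22.0)])


class TestFeatures:
    def test_constant_mean_prc_has_zero_derivative_variance(self):
        m = mean_prc([synthetic_prc(np.full(100, 0.3))])
        feats = extract_prc_features(m)
        assert feats.deriv_variance == 0.0
        assert feats.shift_at_0p3 == pytest.approx(0.3)

    def test_linear_mean_prc_has_zero_derivative_variance(self):
        m = mean_prc([synthetic_prc(0.5 * np.arange(1, 101) / 100 - 0.2)])
        assert extract_prc_features(m).deriv_variance == pytest.approx(
            0.0, abs=1e-18)

    def test_derivative_variance_matches_two_pass_oracle(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=100)
        m = mean_prc([synthetic_prc(s)])
        feats = extract_prc_features(m)
        q = (s[1:] - s[:-1]) / (1.0 / 100)
        assert len(q) == 99
        mu = sum(q) / len(q)
        var = sum((x - mu) ** 2 for x in q) / (len(q) - 1)
        assert feats.deriv_variance == pytest.approx(var)

    def test_grid_without_phase_0p3_rejected(self):
        m = mean_prc([synthetic_prc(np.zeros(7))])
        with pytest.raises(ValueError, match="0.3"):
            extract_prc_features(m)

    def test_derivative_variance_stable_across_phase_grid_refinement(self):
        r100 = compute_prc(PYR_DEFAULTS, 30.0)
        r200 = compute_prc(PYR_DEFAULTS, 30.0, n_phases=200)
        v100 = extract_prc_features(mean_prc([r100])).deriv_variance
        q = np.diff(r200.shifts) / np.diff(r200.phases)
        v200 = float(np.var(q, ddof=1))
        assert v200 == pytest.approx(v100, rel=0.5)


class TestPopulationStudy:
    def test_single_population_single_current_single_row(self):
        table = prc_population_study({"base": [PYR_DEFAULTS]}, [20.0])
        assert len(table) == 1
        assert table.iloc[0].n_models == 1

    def test_six_current_sweep_monotone_frequency(self):
        table = prc_population_study({"base": [PYR_DEFAULTS]},
                                     list(range(20, 31, 2)))
        assert len(table) == 6
        freqs = table.sort_values("I_tonic_pA").mean_freq_Hz.to_numpy()
        assert np.all(np.diff(freqs) >= 0)

    def test_rows_match_independent_composition(self):
        cells = [PYR_DEFAULTS, PYR_DEFAULTS.with_(d=12.0), PYR_DEFAULTS]
        table = prc_population_study({"pop": cells}, [22.0])
        # oracle: compose the three stages by hand over distinct models
        results = [compute_prc(p, 22.0)
                   for p in (PYR_DEFAULTS, PYR_DEFAULTS.with_(d=12.0))]
        m = mean_prc(results)
        feats = extract_prc_features(m)
        row = table.iloc[0]
        assert row.n_models == 2
        assert row.shift_at_0p3 == pytest.approx(feats.shift_at_0p3)
        assert row.deriv_variance == pytest.approx(feats.deriv_variance)
        freqs = [r.intrinsic_frequency for r in results]
        assert row.mean_freq_Hz == pytest.approx(np.mean(freqs))
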