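"""Bingham and von Mises tuning models, orientation ANOVA."""

import math

import numpy as np
import pytest

from neuropose import synth, tuning
from neuropose.design import TaskDesign, enumerate_conditions
from neuropose.separability import angular_deviation

ORIENTS = [(t if s > 0 else None, s)
           for t, s in [(c.tilt, c.slant) for c in enumerate_conditions(TaskDesign())
                        if c.distance == 37.0]]


def scalar_bingham(tilt, slant, mu_t, mu_s, l1, l2, phi, gain, offset):
    """Independent scalar evaluation of the Bingham rate formula."""
    def normal(T, S):
        t, s = math.radians(T), math.radians(S)
        return np.array([math.sin(s) * math.cos(t), math.sin(s) * math.sin(t),
                         math.cos(s)])
    mu = normal(mu_t, mu_s)
    t, s = math.radians(mu_t), math.radians(mu_s)
    u1 = np.array([math.cos(s) * math.cos(t), math.cos(s) * math.sin(t),
                   -math.sin(s)])
    u2 = np.cross(mu, u1)
    p = math.radians(phi)
    u1r = math.cos(p) * u1 + math.sin(p) * u2
    u2r = -math.sin(p) * u1 + math.cos(p) * u2
    n = normal(tilt, slant)
    return offset + gain * math.exp(l1 * float(n @ u1r) ** 2
                                    + l2 * float(n @ u2r) ** 2)


class TestNormals:
    @pytest.mark.parametrize("tilt,slant,expected", [
        (123.0, 0.0, (0.0, 0.0, 1.0)),
        (0.0, 90.0, (1.0, 0.0, 0.0)),
        (90.0, 45.0, (0.0, math.sqrt(0.5), math.sqrt(0.5))),
    ])
    def test_known_normals(self, tilt, slant, expected):
        n = tuning.tilt_slant_to_normal(tilt, slant)
        assert np.allclose(n, expected, atol=1e-12)
        assert np.linalg.norm(n) == pytest.approx(1.0)

    def test_roundtrip(self):
        for t, s in [(10.0, 20.0), (200.0, 75.0), (359.0, 5.0)]:
            n = tuning.tilt_slant_to_normal(t, s)
            t2, s2 = tuning.normal_to_tilt_slant(n)
            assert t2 == pytest.approx(t, abs=1e-9)
            assert s2 == pytest.approx(s, abs=1e-9)

    def test_slant_range_enforced(self):
        with pytest.raises(ValueError):
            tuning.tilt_slant_to_normal(0.0, 91.0)


class TestBinghamPredict:
    FIT = tuning.BinghamFit(mu_tilt=120.0, mu_slant=40.0, lambda1=-2.5,
                            lambda2_mag=1.2, phi=30.0, gain=35.0, offset=8.0,
                            goodness_r=1.0)

    def test_maximum_at_preferred(self):
        r = tuning.bingham_predict(self.FIT, [(120.0, 40.0)])
        assert r[0] == pytest.approx(8.0 + 35.0)
        # dense hemisphere grid never exceeds the preferred-rate value
        grid = [(t, s) for t in range(0, 360, 5) for s in range(0, 91, 5)]
        assert tuning.bingham_predict(self.FIT, grid).max() <= r[0] + 1e-9

    def test_flat_when_concentrations_zero(self):
        flat = tuning.BinghamFit(120.0, 40.0, 0.0, 0.0, 30.0, 35.0, 8.0, 1.0)
        r = tuning.bingham_predict(flat, [(0.0, 10.0), (180.0, 60.0), (None, 0.0)])
        assert np.allclose(r, 43.0)

    def test_matches_scalar_oracle(self):
        probes = [(0.0, 15.0), (45.0, 60.0), (200.0, 30.0), (318.0, 52.0),
                  (None, 0.0)]
        got = tuning.bingham_predict(self.FIT, probes)
        want = [scalar_bingham(t if t is not None else 0.0, s, 120.0, 40.0,
                               -2.5, -1.2, 30.0, 35.0, 8.0) for t, s in probes]
        assert np.allclose(got, want, atol=1e-12)


class TestFitBingham:
    def test_noiseless_parameter_recovery(self):
        truth = tuning.BinghamFit(75.0, 35.0, -2.0, 0.8, 110.0, 30.0, 10.0, 1.0)
        rates = tuning.bingham_predict(truth, ORIENTS)
        fit = tuning.fit_bingham(ORIENTS, rates)
        dev = angular_deviation((truth.mu_tilt, truth.mu_slant),
                                (fit.mu_tilt, fit.mu_slant))
        assert dev < 3.0
        assert fit.lambda1 == pytest.approx(-2.0, rel=0.05)
        assert fit.lambda2_mag == pytest.approx(0.8, rel=0.05)
        assert fit.goodness_r == pytest.approx(1.0, abs=1e-6)

    def test_isotropic_truth_flags_phi(self):
        truth = tuning.BinghamFit(75.0, 35.0, -1.5, 1.5, 0.0, 30.0, 10.0, 1.0)
        rates = tuning.bingham_predict(truth, ORIENTS)
        fit = tuning.fit_bingham(ORIENTS, rates)
        assert fit.phi_unidentifiable
        assert angular_deviation((75.0, 35.0), (fit.mu_tilt, fit.mu_slant)) < 3.0

    def test_flat_surface_flagged(self):
        fit = tuning.fit_bingham(ORIENTS, np.full(33, 12.0))
        assert fit.flat
        assert fit.gain < 0.01 * max(fit.offset, 1.0)

    def test_offset_and_gain_covariance(self):
        """Affine response transforms map onto offset/gain alone."""
        truth = tuning.BinghamFit(260.0, 50.0, -2.2, 1.0, 90.0, 20.0, 5.0, 1.0)
        base = tuning.bingham_predict(truth, ORIENTS)
        fit = tuning.fit_bingham(ORIENTS, 3.0 * base + 7.0)
        assert fit.gain == pytest.approx(60.0, rel=0.02)
        assert fit.offset == pytest.approx(22.0, rel=0.05)


class TestOrientationAnova:
    def test_constant_rates_give_p_one(self, design):
        from conftest import make_tilt_dataset
        rows = []
        for c in enumerate_conditions(design):
            for _ in range(2):
                rows.append((np.nan if c.tilt is None else c.tilt, c.slant,
                             c.distance, 10, np.nan))
        data = make_tilt_dataset(rows, design)
        assert tuning.orientation_anova(data, 57.0) == 1.0

    def test_strong_tuning_is_significant_after_holm(self, tuned_neuron):
        _, data = tuned_neuron
        sig = tuning.orientation_significance(data)
        assert sig[57.0][1]  # fixation distance is strongly tuned

    def test_familywise_error_of_holm_screen(self, design):
        """Null neurons are declared tuned at any distance <= 7%."""
        truth = synth.GroundTruthNeuron(
            preferred_tilt=[0.0] * 4, preferred_slant=[30.0] * 4,
            gain_per_distance=[0.0] * 4, baseline=15.0)
        hits = 0
        n_sims = 400
        for s in range(n_sims):
            data = synth.simulate_neuron(truth, design, 3, seed=90_000 + s,
                                         spike_times="none")
            sig = tuning.orientation_significance(data)
            hits += any(v[1] for v in sig.values())
        assert hits / n_sims <= 0.07


class TestVonMisesTuning:
    DIRS = np.arange(0.0, 360.0, 45.0)

    def test_noiseless_recovery_of_narrow_tuning(self):
        truth = tuning.VonMisesFit(mu=90.0, kappa=6.3, gain=40.0, offset=5.0,
                                   goodness_r=1.0)
        fit = tuning.fit_vonmises_tuning(self.DIRS, truth.predict(self.DIRS))
        assert fit.kappa == pytest.approx(6.3, rel=0.02)
        assert fit.mu == pytest.approx(90.0, abs=1.0)
        assert fit.goodness_r == pytest.approx(1.0, abs=1e-9)

    def test_flat_tuning_flagged(self):
        fit = tuning.fit_vonmises_tuning(self.DIRS, np.full(8, 12.0))
        assert fit.flat
        assert fit.kappa < 0.1 or fit.gain < 1e-3
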