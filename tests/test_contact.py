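"""Hertz contact formulas and surface detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indentmap.contact import (
    InsufficientLoadingDataError,
    contact_area,
    contact_radius,
    detect_surface,
    hertz_force,
    indentation_strain,
    started_in_contact,
)
from indentmap.records import IndentationRecord, ProbeSpec, ProtocolSpec
from indentmap.simulate import simulate_record


class TestHertzForce:
    def test_closed_form_value(self):
        # hand evaluation: (4/3)*(1500/0.75)*sqrt(60e-6)*(10e-6)^1.5
        F = hertz_force(E=1500.0, nu=0.5, R=60e-6, h=10e-6)
        assert F == pytest.approx(6.53e-7, rel=1e-3)

    def test_zero_depth_gives_zero_force(self):
        assert hertz_force(E=2000.0, nu=0.5, R=80e-6, h=0.0) == 0.0

    def test_linear_in_modulus_and_three_halves_in_depth(self):
        F1 = hertz_force(1000.0, 0.5, 60e-6, 5e-6)
        assert hertz_force(2000.0, 0.5, 60e-6, 5e-6) == pytest.approx(2 * F1)
        assert hertz_force(1000.0, 0.5, 60e-6, 20e-6) == pytest.approx(8 * F1)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            hertz_force(1000.0, 0.5, 60e-6, -1e-6)


class TestContactGeometry:
    def test_contact_radius_hand_value(self):
        assert contact_radius(10e-6, 62.5e-6) == pytest.approx(25e-6)
        assert contact_radius(0.0, 100e-6) == 0.0

    def test_radius_bracket_for_deep_indentation(self):
        # over the working depth and probe-radius ranges the contact patch
        # stays within the 20-40 um bracket expected for tissue-scale probing
        a_min = contact_radius(8e-6, 60e-6)
        a_max = contact_radius(11e-6, 105e-6)
        assert 20e-6 < a_min < a_max < 40e-6

    def test_strain_hand_values(self):
        assert indentation_strain(8e-6, 60e-6) == pytest.approx(0.0730, abs=5e-5)
        assert indentation_strain(0.0, 60e-6) == 0.0
        # inversion: eps = 0.09 at h = R * (0.09/0.2)^2 = R * 0.2025
        assert indentation_strain(60e-6 * 0.2025, 60e-6) == pytest.approx(0.09)

    @given(h=st.floats(1e-9, 50e-6), R=st.floats(10e-6, 200e-6))
    @settings(derandomize=True, max_examples=50)
    def test_area_identity_and_small_strain_region(self, h, R):
        assert contact_area(h, R) == pytest.approx(math.pi * h * R, rel=1e-12)
        # eps < 0.08 exactly when h/R < 0.16
        assert (indentation_strain(h, R) < 0.08) == (h / R < 0.16)

    def test_strain_monotonicity(self):
        assert indentation_strain(9e-6, 60e-6) > indentation_strain(8e-6, 60e-6)
        assert indentation_strain(8e-6, 80e-6) < indentation_strain(8e-6, 60e-6)


def _hertz_record(offset=0.0, E=1500.0, n=200, sigma=0.0, seed=0, sample_rate=None):
    """Handmade loading curve: linear approach through a Hertz contact."""
    probe = ProbeSpec()
    protocol = ProtocolSpec(sample_rate=sample_rate)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / protocol.effective_sample_rate
    depth = protocol.approach_speed * t
    h = np.clip(depth - offset, 0.0, None)
    load = hertz_force(E, probe.poisson_ratio, probe.tip_radius, h)
    if sigma:
        load = load + rng.normal(0, sigma, n)
    return IndentationRecord(time=t, depth=depth, load=load, probe=probe, protocol=protocol)


class TestDetectSurface:
    def test_noise_free_offset_recovery(self, elastic_phantom, probe):
        phantom = elastic_phantom
        rec = simulate_record(phantom, probe, ProtocolSpec(), seed=3, noise_sigma=0.0)
        fit = detect_surface(rec)
        assert fit.surface_offset == pytest.approx(rec.truth["surface_offset"], abs=1e-9)
        assert fit.hertz_modulus == pytest.approx(1500.0, rel=0.01)
        assert fit.fit_r2 > 0.999

    def test_shallow_surface_offset_recovery(self, probe):
        from indentmap.rheology import RheologyModel
        from indentmap.simulate import TissuePhantom

        phantom = TissuePhantom(background=RheologyModel("elastic", 1500.0), surface_offset=2e-6)
        rec = simulate_record(phantom, probe, ProtocolSpec(), seed=4, noise_sigma=0.0)
        fit = detect_surface(rec)
        assert fit.surface_offset == pytest.approx(2e-6, rel=0.05)

    def test_zero_offset_keeps_raw_depth(self):
        # finer sampling so the short loading segment still has many samples
        rec = _hertz_record(offset=0.0, sample_rate=2000.0)
        fit = detect_surface(rec)
        assert abs(fit.surface_offset) < 1e-9
        assert np.allclose(fit.corrected_depth, rec.depth, atol=1e-9)

    def test_noisy_offset_recovery_median(self):
        errs = []
        for seed in range(10):
            rec = _hertz_record(offset=10e-6, n=400, sigma=0.5e-9, seed=seed)
            fit = detect_surface(rec)
            errs.append(abs(fit.surface_offset - 10e-6))
        assert np.median(errs) < 0.2e-6

    def test_insufficient_data_raises(self):
        rec = _hertz_record(offset=0.0, n=50)
        # threshold below the very first contact loads -> almost no samples
        with pytest.raises(InsufficientLoadingDataError):
            detect_surface(rec, threshold_load=1e-15)


class TestStartedInContact:
    def test_free_approach_not_flagged(self, clean_or_record):
        assert not started_in_contact(clean_or_record).in_contact

    def test_contact_at_start_flagged(self):
        # surface at the very first sample: load rises immediately
        rec = _hertz_record(offset=0.0, n=300)
        assert started_in_contact(rec).in_contact

    def test_degenerate_approach_conservatively_flagged(self):
        rec = _hertz_record(offset=0.5e-6, n=40)
        check = started_in_contact(rec)
        assert check.in_contact
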