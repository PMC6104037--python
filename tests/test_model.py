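"""Round-trip parameter recovery and QC behaviour of the record analysis."""

import math

import numpy as np
import pytest

from indentmap.model import DynamicIndentationModel, analyze_record
from indentmap.records import ProtocolSpec
from indentmap.rheology import RheologyModel
from indentmap.simulate import TissuePhantom, simulate_record


class TestElasticRoundTrip:
    def test_or_storage_recovered_to_a_tenth_percent(self, clean_or_results):
        pts = [p for p in clean_or_results.points if p.qc_pass]
        assert len(pts) >= 5
        for p in pts:
            assert p.E_storage == pytest.approx(1500.0, rel=1e-3)
            assert abs(p.E_loss) < 0.01 * p.E_storage
            assert abs(p.phase_lag) < 1e-4

    def test_fs_storage_recovered_at_all_frequencies(self, clean_fs_results):
        pts = [p for p in clean_fs_results.points if p.qc_pass]
        assert [p.frequency for p in pts] == [1.0, 1.78, 3.2, 5.62, 10.0]
        for p in pts:
            assert p.E_storage == pytest.approx(1500.0, rel=1e-3)
            assert abs(p.E_loss) < 0.01 * p.E_storage

    def test_loss_tangent_identity_on_emitted_points(self, clean_or_results, clean_fs_results):
        for p in clean_or_results.points + clean_fs_results.points:
            assert p.E_loss / p.E_storage == pytest.approx(math.tan(p.phase_lag), abs=1e-9)


class TestViscoelasticRoundTrip:
    def test_kelvin_voigt_loss_proportional_to_frequency(self, kv_phantom, probe, fs_protocol):
        rec = simulate_record(kv_phantom, probe, fs_protocol, seed=11, noise_sigma=0.0)
        pts = [p for p in analyze_record(rec) if p.qc_pass]
        etas = [p.E_loss / (2 * math.pi * p.frequency) for p in pts]
        assert len(etas) == 5
        for eta in etas:
            assert eta == pytest.approx(20.0, rel=0.01)
        # storage stays flat across frequency
        for p in pts:
            assert p.E_storage == pytest.approx(1500.0, rel=1e-3)

    def test_strain_stiffening_monotone_over_ramp(self, probe):
        phantom = TissuePhantom(
            background=RheologyModel("elastic", 1000.0, stiffening=3.0)
        )
        rec = simulate_record(phantom, probe, ProtocolSpec(), seed=12, noise_sigma=0.0)
        pts = [p for p in analyze_record(rec) if p.qc_pass]
        e = [p.E_storage for p in pts]
        assert all(b > a for a, b in zip(e, e[1:]))
        # and the recovered strains increase along the ramp
        s = [p.strain for p in pts]
        assert all(b > a for a, b in zip(s, s[1:]))


class TestQC:
    def test_windows_conservation(self, elastic_phantom, probe, or_protocol):
        rec = simulate_record(elastic_phantom, probe, or_protocol, seed=21, noise_sigma=2e-9)
        res = DynamicIndentationModel(rec).fit()
        assert res.n_passed + res.n_rejected == res.n_windows

    def test_square_wave_artifact_rejected(self, clean_or_record):
        rec = clean_or_record
        t0 = rec.truth["protocol_start"]
        f = rec.protocol.or_frequency
        # corrupt the second 5-cycle window with a square-wave artifact
        load = rec.load.copy()
        sel = (rec.time >= t0 + 5 / f) & (rec.time < t0 + 10 / f)
        load[sel] += 30e-9 * np.sign(np.sin(2 * math.pi * 40.0 * rec.time[sel]))
        res = DynamicIndentationModel(rec.with_arrays(load=load)).fit()
        bad = [p for p in res.points if p.window_index == 1]
        good = [p for p in res.points if p.window_index != 1]
        assert bad and not bad[0].qc_pass
        assert bad[0].r2_load <= 0.7
        assert all(p.qc_pass for p in good)

    def test_started_in_contact_fails_every_window(self, probe, or_protocol):
        phantom = TissuePhantom(
            background=RheologyModel("elastic", 1500.0), surface_offset=0.05e-6
        )
        rec = simulate_record(phantom, probe, or_protocol, seed=22, noise_sigma=0.0)
        res = DynamicIndentationModel(rec).fit()
        assert res.baseline.in_contact
        assert res.points and all(not p.qc_pass for p in res.points)
        assert all(p.qc_reason == "started_in_contact" for p in res.points)

    def test_strict_r2_threshold_reduces_passes(self, elastic_phantom, probe, or_protocol):
        rec = simulate_record(elastic_phantom, probe, or_protocol, seed=23, noise_sigma=3e-9)
        loose = DynamicIndentationModel(rec, r2_min=0.7).fit()
        strict = DynamicIndentationModel(rec, r2_min=0.999).fit()
        assert strict.n_passed < loose.n_passed


def test_summary_reports_counts(clean_or_results):
    text = clean_or_results.summary()
    assert "windows" in text
    assert str(clean_or_results.n_windows) in text


def test_from_dataframe_round_trip(clean_or_record):
    import pandas as pd

    rec = clean_or_record
    df = pd.DataFrame(
        {"time_s": rec.time, "depth_um": rec.depth * 1e6, "load_nN": rec.load * 1e9}
    )
    model = DynamicIndentationModel.from_dataframe(df, rec.probe, rec.protocol)
    pts = [p for p in model.fit().points if p.qc_pass]
    assert pts and pts[0].E_storage == pytest.approx(1500.0, rel=1e-3)
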