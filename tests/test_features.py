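import numpy as np
import pytest

from eamap import (
    annotate_points,
    classify_abnormal,
    count_deflections,
    detect_lat,
    egm_duration,
    peak_to_peak,
    synthesize_egm,
)
from eamap.egm import EgmTrace
from eamap.features import NoActivationError, extract_features


def sine_cycle(center: float, amplitude: float = 2.0, period: float = 20.0) -> EgmTrace:
    """Symmetric biphasic wavelet: one sine cycle, steepest slope at centre."""
    t = np.arange(0.0, 500.0, 1.0)
    v = np.where(
        np.abs(t - center) <= period / 2,
        -np.sin(2 * np.pi * (t - center) / period) * amplitude / 2,
        0.0,
    )
    return EgmTrace(t, v)


class TestDetectLat:
    def test_symmetric_biphasic_wavelet_annotated_at_centre(self):
        tr = sine_cycle(120.0)
        assert detect_lat(tr) == pytest.approx(120.0, abs=1.0)

    def test_time_shift_equivariance(self):
        a = detect_lat(sine_cycle(120.0))
        b = detect_lat(sine_cycle(170.0))
        assert b - a == pytest.approx(50.0, abs=1e-9)

    def test_flat_trace_raises(self):
        with pytest.raises(NoActivationError):
            detect_lat(EgmTrace(np.arange(100.0), np.full(100, 0.01)))

    def test_mean_error_below_2ms_on_simulator_traces(self):
        """Across 200 seeded traces spanning both morphology regimes the
        annotation error stays below 2 ms on average."""
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(200):
            if rng.random() < 0.5:
                amp, n, dur = rng.uniform(1.0, 3.0), int(rng.integers(1, 3)), rng.uniform(20, 45)
            else:
                amp, n, dur = rng.uniform(0.05, 0.45), int(rng.integers(4, 7)), rng.uniform(75, 95)
            lat = rng.uniform(80, 400)
            tr = synthesize_egm(lat, amp, n, dur, seed=int(rng.integers(2**31)))
            errs.append(abs(extract_features(tr).lat - lat))
        assert np.mean(errs) < 2.0


class TestPeakToPeak:
    def test_constant_trace_zero(self):
        assert peak_to_peak(EgmTrace(np.arange(10.0), np.full(10, 0.3))) == 0.0

    def test_matches_exhaustive_pairwise_difference(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, 300)
        tr = EgmTrace(np.arange(300.0), v)
        brute = max(abs(a - b) for a in v[::7] for b in v[::7])  # subsampled brute force
        assert peak_to_peak(tr) >= brute
        assert peak_to_peak(tr) == pytest.approx(v.max() - v.min())


class TestDuration:
    def test_all_zero_trace_is_zero(self):
        assert egm_duration(EgmTrace(np.arange(50.0), np.zeros(50))) == 0.0

    def test_rectangular_pulse_width_recovered(self):
        t = np.arange(0.0, 200.0, 1.0)
        v = np.where((t >= 60) & (t <= 140), 1.0, 0.0)
        assert egm_duration(EgmTrace(t, v)) == pytest.approx(80.0, abs=1.0)

    def test_synthesized_duration_close_to_target(self):
        tr = synthesize_egm(200.0, 2.0, 5, 90.0, noise_sd=0.0)
        assert egm_duration(tr) == pytest.approx(90.0, abs=10.0)

    def test_positive_floor_required(self):
        with pytest.raises(ValueError):
            egm_duration(EgmTrace(np.arange(5.0), np.zeros(5)), noise_floor=0.0)


class TestDeflections:
    def test_flat_trace_counts_zero(self):
        assert count_deflections(EgmTrace(np.arange(50.0), np.zeros(50))) == 0

    def test_baseline_offset_invariance(self):
        tr = synthesize_egm(150.0, 1.0, 4, 80.0, noise_sd=0.0)
        shifted = EgmTrace(tr.t, tr.v + 0.3)
        assert count_deflections(shifted) == count_deflections(tr)


class TestAbnormality:
    @pytest.mark.parametrize("p2p,dur,n,abnormal", [
        (0.14, 40.0, 2, True),    # very low voltage alone
        (0.49, 40.0, 2, True),    # just under the voltage cutoff
        (2.0, 50.0, 2, False),    # healthy sharp signal
        (0.6, 80.0, 4, True),     # long AND fractionated arm
        (0.5, 40.0, 2, False),    # exactly at cutoffs: strict inequalities
        (2.0, 70.0, 4, False),
        (2.0, 80.0, 3, False),
        (2.0, 71.0, 4, True),
    ])
    def test_rule_table(self, p2p, dur, n, abnormal):
        got_abn, got_frac = classify_abnormal(p2p, dur, n)
        assert got_abn is abnormal
        assert got_frac is (n > 3)

    def test_fractionated_implies_more_than_three_deflections(self):
        for n in range(0, 7):
            _, frac = classify_abnormal(1.0, 80.0, n)
            assert frac == (n > 3)


class TestScenarioClassification:
    def test_lva_points_mostly_abnormal_and_remote_points_normal(self, default_scenario):
        """On the default scenario >= 90% of points inside the planted LVA
        classify abnormal and >= 90% well outside the diseased zone normal."""
        mesh, substrate, truth, points = default_scenario
        feats = annotate_points(points)
        t = points.table
        d = np.linalg.norm(
            t[["x_mm", "y_mm", "z_mm"]].to_numpy()
            - mesh.vertices[substrate.center_vertex], axis=1,
        )
        r_lva = substrate.params["lva_radius"]
        r_out = r_lva + substrate.params["annulus_width"]
        inside = d < r_lva - 0.5
        outside = d > r_out + 0.5
        assert feats.loc[inside, "abnormal"].mean() >= 0.90
        assert (~feats.loc[outside, "abnormal"]).mean() >= 0.90
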