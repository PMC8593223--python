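"""Generator tests: determinism, the ΔΔG geometry, closed-form expected
scores, large-sample convergence, and the spectral signature of the
simulated helical modulation."""

import numpy as np
import pytest

from scanmap import (GroundTruth, InterfaceSegment, NoiseModel, detrend,
                     expected_mfi_ratio, fill_missing, mutant_ddg,
                     score_panel, simulate_scan_panel, simulate_titration)
from scanmap.titration import fit_one_site


class TestMutantDdg:
    def test_zero_outside_interface_segments(self):
        truth = GroundTruth(interface_segments=(
            InterfaceSegment(45, 66, 0.3, 0.9, 3.6),), seed=0)
        assert mutant_ddg(truth, 31) == 0.0
        assert mutant_ddg(truth, 82) == 0.0

    def test_zero_amplitude_gives_uniform_base(self):
        truth = GroundTruth(interface_segments=(
            InterfaceSegment(45, 66, 0.4, 0.0, 3.6),), seed=0)
        assert all(mutant_ddg(truth, p) == pytest.approx(0.4)
                   for p in range(45, 67))

    def test_matches_independent_formula_evaluation(self):
        truth = GroundTruth(seed=0)
        seg = truth.interface_segments[1]
        for pos in range(seg.first, seg.last + 1):
            expected = max(0.0, seg.ddg_base + seg.ddg_amp *
                           np.sin(2 * np.pi * pos / seg.period + seg.phase))
            assert mutant_ddg(truth, pos) == pytest.approx(expected, abs=1e-12)

    def test_position_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside window"):
            mutant_ddg(GroundTruth(seed=0), 5)


class TestSimulateScanPanel:
    def test_identical_seed_gives_bit_identical_panels(self):
        truth = GroundTruth(n_cells=500, seed=42)
        p1, l1 = simulate_scan_panel(truth)
        p2, l2 = simulate_scan_panel(truth)
        assert p1 == p2
        assert l1 == l2

    def test_different_seed_changes_measurements(self):
        p1, _ = simulate_scan_panel(GroundTruth(n_cells=500, seed=1))
        p2, _ = simulate_scan_panel(GroundTruth(n_cells=500, seed=2))
        assert p1 != p2

    def test_zero_noise_noninterface_scores_exactly_one(self, zero_noise_truth):
        panel, labels = simulate_scan_panel(zero_noise_truth)
        table = score_panel(panel)
        for _, row in table.mutant_scores().iterrows():
            if labels[row["position"]]["ddg"] == 0.0:
                assert row["mfi_ratio_mean"] == pytest.approx(1.0, abs=1e-12)

    def test_large_penalty_matches_closed_form(self):
        seg = InterfaceSegment(45, 66, ddg_base=10.0, ddg_amp=0.0, period=3.6)
        truth = GroundTruth(interface_segments=(seg,),
                            noise=NoiseModel.zero(), n_cells=100, seed=0)
        panel, _ = simulate_scan_panel(truth)
        row = score_panel(panel).ratio_by_position("D").loc[50]
        L, kd = truth.probe_conc, truth.kd_of(10.0)
        expected = (L / (kd + L)) / 0.5   # probe at Kd_wt -> f_wt = 1/2
        assert row == pytest.approx(expected, rel=1e-9)

    def test_empirical_score_converges_to_bound_fraction_ratio(self):
        # autofluorescence off: the remaining noise terms are zero-mean, so
        # the empirical score converges to f_mut/f_wt
        noise = NoiseModel(autofluor_mean=0.0, autofluor_sd=0.0)
        truth = GroundTruth(n_cells=100_000, n_replicates=1, seed=9,
                            noise=noise)
        panel, labels = simulate_scan_panel(truth)
        table = score_panel(panel)
        for pos in (40, 50, 60, 75):
            row = table.ratio_by_position("D").get(pos)
            expected = expected_mfi_ratio(truth, labels[pos]["ddg"])
            assert row == pytest.approx(expected, rel=0.01)

    def test_autofluorescence_biases_weak_binders_upward(self):
        # additive background inflates the normalized score of defective
        # mutants (it contributes relatively more where binding is low)
        base = GroundTruth(n_cells=50_000, n_replicates=1, seed=9)
        clean = GroundTruth(n_cells=50_000, n_replicates=1, seed=9,
                            noise=NoiseModel(autofluor_mean=0.0,
                                             autofluor_sd=0.0))
        pos = 50   # strong-penalty position in the default geometry
        s_auto = score_panel(simulate_scan_panel(base)[0]).ratio_by_position("D")[pos]
        s_clean = score_panel(simulate_scan_panel(clean)[0]).ratio_by_position("D")[pos]
        assert s_auto > s_clean

    def test_truth_labels_respect_detection_floor(self):
        truth = GroundTruth(seed=0)
        _, labels = simulate_scan_panel(truth)
        for pos, lab in labels.items():
            assert lab["interface"] == (lab["ddg"] >= truth.ddg_call)


def test_helical_modulation_has_dominant_spectral_period_near_truth(helix_truth):
    """Dominant FFT period of the corrected series over the helical segment
    stays within 0.2 residues of the generating repeat (mean over 50 seeds)."""
    periods = []
    for seed in range(1, 51):
        truth = GroundTruth(interface_segments=helix_truth.interface_segments,
                            seed=seed)
        panel, _ = simulate_scan_panel(truth)
        s = score_panel(panel).ratio_by_position("D")
        series = fill_missing(s.index, s.values, truth.window)
        corrected = detrend(series, 5).slice(45, 66)
        y = np.asarray(corrected.values)
        spec = np.abs(np.fft.rfft(y - y.mean()))
        k = int(np.argmax(spec[1:]) + 1)
        periods.append(len(y) / k)
    assert abs(np.mean(periods) - 3.6) < 0.2


class TestSimulateTitration:
    def test_zero_noise_curve_recovers_kd_exactly(self):
        truth = GroundTruth(seed=0)
        curve = simulate_titration(truth, ddg=1.0, noise_cv=0.0)
        fit = fit_one_site(curve)
        assert fit.kd == pytest.approx(truth.kd_of(1.0), rel=1e-6)

    def test_zero_penalty_curve_identical_to_wt_curve(self):
        truth = GroundTruth(seed=5)
        c1 = simulate_titration(truth, ddg=0.0, seed=77)
        c2 = simulate_titration(truth, ddg=0.0, seed=77, variant_id="other")
        assert c1.binding_mfi == c2.binding_mfi
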