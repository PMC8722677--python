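"""Generator contracts: determinism, ground-truth bookkeeping, error paths."""

import numpy as np
import pytest

from cardiofield import synthio
from cardiofield.synthio import GroundTruth, InvalidParameterError, SimSpec


def _generate(modality, seed=11, params=None, n=1):
    spec = SimSpec(modality, seed, params or {}, n_replicates=n)
    return {
        "ap": synthio.gen_ap_traces,
        "afm": synthio.gen_force_curves,
        "qpm": synthio.gen_phase_stack,
        "counts": synthio.gen_counts,
        "genome": synthio.gen_genome_fixture,
        "ocr": synthio.gen_ocr_trace,
    }[modality](spec)


def _flatten(obj):
    if isinstance(obj, dict):
        return [v for k in sorted(obj) for v in _flatten(obj[k])]
    if isinstance(obj, (list, tuple)):
        return [v for item in obj for v in _flatten(item)]
    if isinstance(obj, np.ndarray):
        return [obj.tobytes()]
    if hasattr(obj, "table"):
        return [obj.table.to_csv()]
    if hasattr(obj, "to_csv"):
        return [obj.to_csv()]
    if hasattr(obj, "__dataclass_fields__"):
        return _flatten(vars(obj))
    return [repr(obj)]


@pytest.mark.parametrize("modality", list(synthio.MODALITIES))
def test_identical_spec_gives_identical_output(modality):
    noisy = {"ap": {"noise_sd": 0.05}, "afm": {"noise_sd": 0.05},
             "qpm": {"background_noise": 1.0}, "counts": {},
             "genome": {"n_genes": 100}, "ocr": {"noise_sd": 2.0}}
    a = _generate(modality, params=dict(noisy[modality]), n=2)
    b = _generate(modality, params=dict(noisy[modality]), n=2)
    assert _flatten(a) == _flatten(b)
    c = _generate(modality, seed=12, params=dict(noisy[modality]), n=2)
    assert _flatten(a) != _flatten(c)


class TestAPGenerator:
    def test_noise_free_template_crossings_match_truth(self):
        traces, gt = _generate("ap", params={"noise_sd": 0.0, "n_beats": 3})
        x = traces.samples["site000"]
        dt = traces.dt_ms
        # first beat: read 30%/80% crossing times directly off the samples
        amp = x.max()
        below30 = np.nonzero(x[10:300] < 0.7 * amp)[0][0] + 10
        below80 = np.nonzero(x[10:300] < 0.2 * amp)[0][0] + 10
        assert abs(below30 * dt - 200.0) <= dt
        assert abs(below80 * dt - 350.0) <= dt

    def test_sampling_arithmetic(self):
        traces, _ = _generate("ap", params={"frame_rate_hz": 500.0,
                                            "n_beats": 4,
                                            "cycle_length_ms": 800.0})
        x = traces.samples["site000"]
        assert traces.dt_ms == 2.0
        assert x.size == round(4 * 800.0 / 2.0)

    @pytest.mark.parametrize("params", [
        {"apd30_ms": 400.0, "apd80_ms": 300.0},
        {"cycle_length_ms": 300.0, "apd80_ms": 350.0},
        {"polarity": "sideways"},
    ])
    def test_invalid_parameters_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            _generate("ap", params=params)


class TestForceCurveGenerator:
    def test_samples_match_hertz_closed_form(self):
        from cardiofield.afm_hertz import hertz_force_coefficient
        curves, gt = _generate("afm", params={"E_pa": 8000.0, "R_um": 5.0,
                                              "nu": 0.5, "noise_sd": 0.0})
        c = curves[0]
        delta, force = gt["delta_um"], gt["force_nN"]
        C = hertz_force_coefficient(8000.0, 5.0, 0.5)
        assert np.allclose(force, C * delta ** 1.5, atol=1e-12)
        # geometry (post-contact): z = contact + d + delta, with F = k*d
        k_um = c.k * 1000.0
        post = c.z >= 2.0
        assert np.allclose(c.z[post],
                           2.0 + force[post] / k_um + delta[post], atol=1e-9)

    def test_zero_indentation_means_zero_force(self):
        _, gt = _generate("afm", params={"noise_sd": 0.0})
        delta, force = gt["delta_um"], gt["force_nN"]
        assert np.all(force[delta == 0] == 0.0)

    def test_max_force_respects_protocol_cap(self):
        _, gt = _generate("afm", params={"max_force_nN": 3.0,
                                         "noise_sd": 0.0})
        assert gt["force_nN"].max() <= 3.0 + 1e-9

    @pytest.mark.parametrize("params", [
        {"E_pa": -5.0}, {"R_um": 0.0}, {"nu": 0.7},
    ])
    def test_invalid_parameters_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            _generate("afm", params=params)


class TestPhaseStackGenerator:
    def test_static_cell_frames_identical(self):
        stack, _ = _generate("qpm", params={
            "n_frames": 4, "background_noise": 0.0,
            "cells": [{"center": (64, 64), "mass_pg": 300.0,
                       "motion": "static"}]})
        for f in stack.frames[1:]:
            assert np.array_equal(f, stack.frames[0])

    def test_drift_moves_centroid_exactly(self):
        stack, gt = _generate("qpm", params={
            "n_frames": 5,
            "cells": [{"center": (40, 40), "mass_pg": 300.0,
                       "motion": "drift", "drift_px": (3.0, 0.0)}]})
        cents = np.array(gt["true_centroids_um"][0])
        steps = np.diff(cents, axis=0)
        assert np.allclose(np.hypot(steps[:, 0], steps[:, 1]),
                           3.0 * stack.pixel_size_um, atol=1e-9)

    def test_pulsate_truth_is_pixel_sum_of_states(self):
        _, gt = _generate("qpm", params={
            "n_frames": 2,
            "cells": [{"center": (64, 64), "mass_pg": 200.0,
                       "motion": "pulsate", "pulsate_fraction": 0.1}]})
        fluct = gt["true_pct_mass_fluctuation"][0]
        assert 0 < fluct < 20.0  # overlap keeps it under the 2f bound

    def test_overlapping_cells_rejected(self):
        with pytest.raises(InvalidParameterError):
            _generate("qpm", params={"cells": [
                {"center": (60, 60), "mass_pg": 100.0, "motion": "static"},
                {"center": (70, 70), "mass_pg": 100.0, "motion": "static"},
            ]})


class TestCountsGenerator:
    def test_engineered_casualties_recorded(self):
        mat, gt = _generate("counts", params={
            "n_genes": 400, "n_cells_per_group": 30,
            "n_lowgene_cells": 2, "n_lowumi_cells": 1, "n_rare_genes": 3})
        dense = mat.dense()
        for cell in gt["qc_fail_cells"]:
            j = list(mat.cells).index(cell)
            col = dense[:, j]
            assert (col > 0).sum() < 200 or col.sum() < 3000
        for gene in gt["qc_fail_genes"]:
            i = list(mat.genes).index(gene)
            assert (dense[i] > 0).sum() < 3

    def test_detection_fraction_marker_listed(self):
        mat, gt = _generate("counts", params={
            "n_genes": 300, "n_cells_per_group": 40,
            "markers": [{"gene": 5, "group": 0, "log2fc": 0.0,
                         "pct": (0.9, 0.05)}]})
        assert "G00005" in gt["true_marker_genes"]["FHF"]

    def test_unit_fold_change_marker_rejected(self):
        with pytest.raises(InvalidParameterError):
            _generate("counts", params={
                "markers": [{"gene": 1, "group": 0, "log2fc": 0.0}]})


class TestGenomeFixture:
    def test_degenerate_placement(self):
        enriched = [f"G{i:05d}" for i in range(20)]
        peaks, tss, gt = _generate("genome", params={
            "n_genes": 100, "enriched_genes": enriched,
            "p_in": 1.0, "p_out": 0.0, "require_enrichment": True})
        bound = gt["true_bound"]
        for g in tss["gene"]:
            assert bound[g] == (g in enriched)
        assert len(peaks) == 20

    def test_enrichment_request_with_bad_probs_rejected(self):
        with pytest.raises(InvalidParameterError):
            _generate("genome", params={
                "enriched_genes": ["G00000"], "p_in": 0.2, "p_out": 0.2,
                "require_enrichment": True})

    def test_null_generation_allowed(self):
        peaks, tss, gt = _generate("genome", params={
            "n_genes": 50, "enriched_genes": ["G00000"],
            "p_in": 0.3, "p_out": 0.3})
        assert len(tss) == 50


class TestOCRGenerator:
    def test_ground_truth_arithmetic(self):
        _, gt = _generate("ocr", params={
            "basal_raw": 100.0, "post_oligo": 40.0, "post_fccp": 150.0,
            "post_antimycin": 10.0, "noise_sd": 0.0})
        assert gt["true_basal"] == 90.0
        assert gt["true_atp_linked_ocr"] == 60.0
        assert gt["true_proton_leak"] == 30.0
        assert gt["true_maximal"] == 140.0
        assert gt["true_spare_capacity"] == 50.0
        assert gt["true_non_mito"] == 10.0

    def test_flat_trace_derives_zeros(self):
        _, gt = _generate("ocr", params={
            "basal_raw": 50.0, "post_oligo": 50.0, "post_fccp": 50.0,
            "post_antimycin": 50.0, "noise_sd": 0.0})
        assert gt["true_basal"] == 0.0
        assert gt["true_spare_capacity"] == 0.0
        assert gt["true_non_mito"] == 50.0

    def test_odd_profile_warns_but_generates(self):
        with pytest.warns(UserWarning):
            traces, _ = _generate("ocr", params={
                "basal_raw": 50.0, "post_antimycin": 80.0})
        assert len(traces) == 1

    def test_noisy_estimator_unbiased(self):
        """Monte-Carlo: phase-level estimates have ~zero bias vs truth."""
        from cardiofield.respirometry import phase_levels, stress_params
        errs = []
        for seed in range(100):
            traces, gt = _generate("ocr", seed=seed, params={
                "noise_sd": 2.0, "measurements_per_phase": 5})
            p = stress_params(phase_levels(traces[0], reduce="mean"),
                              normalize=False)
            errs.append(p.atp_linked - gt["true_atp_linked_ocr"])
        assert abs(np.mean(errs)) < 3.0 * np.std(errs) / 10 + 0.5


def test_spec_validation():
    with pytest.raises(InvalidParameterError):
        SimSpec("xray", 1)
    with pytest.raises(InvalidParameterError):
        SimSpec("ap", 1, n_replicates=0)
    with pytest.raises(InvalidParameterError):
        SimSpec("ap", 1, {"noise_sd": float("nan")})


def test_ground_truth_mapping_interface():
    gt = GroundTruth("ap", {"x": 1})
    assert "x" in gt and gt["x"] == 1
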