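"""Workflow-level behaviour: baselines, fraction evaluation, accumulation,
flags, exceedance rates and the course runner's error contract."""

import numpy as np
import pytest

from doseaccum.accumulation import (
    accumulate,
    evaluate_baseline,
    evaluate_fraction,
    run_course,
    threshold_exceedance_rate,
)
from doseaccum.config import RunConfig
from doseaccum.core import FractionRecord, TreatmentCourse
from doseaccum.errors import DoseAccumError, LookupError_
from doseaccum.phantom import PhantomConfig, generate_fraction, generate_planning_set


ORGANS = ("bladder", "rectum", "prostate")


def in_memory_course(cfg: PhantomConfig) -> tuple[TreatmentCourse, list]:
    """Build a TreatmentCourse directly from the generator (no disk)."""
    _, _, plan_ss, dose, truth = generate_planning_set(cfg)
    fractions = []
    for i in range(1, cfg.n_fractions + 1):
        ss, reg, ft = generate_fraction(cfg, i)
        # in-memory: align frame ids the way load_course validates them
        ss.frame_of_reference_id = reg.moving_frame_id
        fractions.append(FractionRecord(index=i, structure_set=ss,
                                        registration=reg))
        truth.fractions.append(ft)
    course = TreatmentCourse(planning_structures=plan_ss, plan_dose=dose,
                             fractions=fractions,
                             n_fractions_planned=cfg.n_fractions)
    return course, truth.fractions


@pytest.fixture(scope="module")
def drift_course():
    """3 fractions with volume change and prostate motion."""
    cfg = PhantomConfig(seed=31, n_fractions=3)
    return in_memory_course(cfg)


@pytest.fixture(scope="module")
def organs_config():
    return RunConfig(structures=ORGANS)


class TestBaseline:
    def test_prostate_dmean_near_prescription(self, drift_course,
                                              organs_config):
        course, _ = drift_course
        base = evaluate_baseline(course, organs_config)
        assert base.metrics["prostate"].Dmean_Gy == pytest.approx(60.0,
                                                                  rel=0.01)

    def test_margin_target_exists_and_is_larger(self, drift_course,
                                                organs_config):
        course, _ = drift_course
        base = evaluate_baseline(course, organs_config)
        assert "prostate+1cm" in base.masks
        assert base.masks["prostate+1cm"].n_set > base.masks["prostate"].n_set

    def test_missing_structure_lists_available(self, drift_course):
        course, _ = drift_course
        with pytest.raises(LookupError_, match="prostate"):
            evaluate_baseline(course, RunConfig(structures=("femur",)))

    def test_deterministic_repeat(self, drift_course, organs_config):
        course, _ = drift_course
        b1 = evaluate_baseline(course, organs_config)
        b2 = evaluate_baseline(course, organs_config)
        for n in b1.metrics:
            assert b1.metrics[n] == b2.metrics[n]
            assert np.array_equal(b1.masks[n].voxels, b2.masks[n].voxels)


class TestEvaluateFraction:
    def test_geometry_tracks_ground_truth(self, drift_course, organs_config):
        course, truths = drift_course
        base = evaluate_baseline(course, organs_config)
        for frac, ft in zip(course.fractions, truths):
            fr = evaluate_fraction(course, frac, base, organs_config)
            for organ in ORGANS:
                est = fr.geometry[organ].volume_cm3
                # absolute volumes carry the 3 mm slice-quantization bias
                assert est == pytest.approx(ft.true_volume_cm3(organ),
                                            rel=0.035)
                # ... which cancels in the deviation the pipeline reports
                true_dev = (ft.scales[organ] - 1.0) * 100.0
                assert fr.geometry[organ].volume_dev_pct == pytest.approx(
                    true_dev, abs=2.0)
            assert fr.geometry["prostate"].cmd_mm == pytest.approx(
                ft.true_displacement_norm("prostate"), abs=0.5)

    def test_shifted_prostate_lowers_d98(self, organs_config):
        cfg = PhantomConfig(seed=41, n_fractions=1, bladder_volume_cv=0,
                            rectum_volume_cv=0, prostate_volume_cv=0,
                            body_volume_cv=0, setup_error_sd_mm=0,
                            prostate_shift_sd_mm=0)
        course, _ = in_memory_course(cfg)
        base = evaluate_baseline(course, organs_config)
        # shift the daily prostate 5 mm toward the falloff by hand
        from doseaccum.core import RegistrationMatrix

        frac = course.fractions[0]
        shifted = FractionRecord(
            index=1, structure_set=frac.structure_set,
            registration=RegistrationMatrix.from_translation(
                (5.0, 0.0, 0.0),
                moving_frame_id=frac.registration.moving_frame_id,
                fixed_frame_id=frac.registration.fixed_frame_id))
        fr = evaluate_fraction(course, shifted, base, organs_config)
        assert fr.metrics["prostate"].D98_Gy < base.metrics["prostate"].D98_Gy

    def test_inflated_bladder_gets_less_mean_dose(self, organs_config):
        cfg = PhantomConfig(seed=42, n_fractions=1, bladder_volume_cv=0,
                            rectum_volume_cv=0, prostate_volume_cv=0,
                            body_volume_cv=0, setup_error_sd_mm=0,
                            prostate_shift_sd_mm=0)
        course, _ = in_memory_course(cfg)
        base = evaluate_baseline(course, organs_config)
        ss = course.fractions[0].structure_set
        # inflate 2x with the base anchored, as the generator does
        k = 2.0 ** (1.0 / 3.0) - 1.0
        big = cfg.baseline_shapes()["bladder"].scaled(2.0).translated(
            (0.0, 0.0, k * cfg.bladder_radius_mm))
        ct_zs = cfg.ct_geometry().axis_coords(2)
        roi = big.contours(ct_zs, cfg.contour_vertices)
        roi.name = "bladder"
        ss.rois["bladder"] = roi
        fr = evaluate_fraction(course, course.fractions[0], base,
                               organs_config)
        assert fr.deviation_pct["bladder"]["Dmean_Gy"] < 0
        assert fr.geometry["bladder"].volume_dev_pct == pytest.approx(
            100.0, abs=5.0)


class TestAccumulate:
    def _results(self, course, config, n=3):
        base = evaluate_baseline(course, config)
        frs = [evaluate_fraction(course, f, base, config)
               for f in course.fractions[:n]]
        return base, frs

    def test_identical_fractions_average_to_themselves(self, organs_config):
        cfg = PhantomConfig(seed=43, n_fractions=3, bladder_volume_cv=0,
                            rectum_volume_cv=0, prostate_volume_cv=0,
                            body_volume_cv=0, setup_error_sd_mm=0,
                            prostate_shift_sd_mm=0)
        course, _ = in_memory_course(cfg)
        base, frs = self._results(course, organs_config)
        acc = accumulate(frs, base, 3, organs_config)
        for organ in ORGANS:
            assert np.allclose(acc.curves[organ].cum_volume_pct,
                               frs[0].curves[organ].cum_volume_pct)
            for m, dev in acc.deviation_pct[organ].items():
                assert dev is None or dev == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance(self, drift_course, organs_config):
        course, _ = drift_course
        base, frs = self._results(course, organs_config)
        a1 = accumulate(frs, base, 3, organs_config)
        a2 = accumulate(frs[::-1], base, 3, organs_config)
        for organ in ORGANS:
            assert a1.metrics[organ] == a2.metrics[organ]

    def test_two_uniform_fractions_v50(self):
        """Uniform organ doses of 40 and 60 Gy accumulate to V50 = 50 %."""
        from doseaccum.accumulation import _evaluate_masks, FractionResult
        from doseaccum.core import DoseGrid, ImageGeometry
        from doseaccum.geometry import BinaryMask

        config = RunConfig(structures=("organ",))
        geom = ImageGeometry(origin=(0, 0, 0), spacing=(1, 1, 1),
                             dims=(8, 8, 8))
        mask = BinaryMask(geom, np.ones((8, 8, 8), bool), label="organ")
        frs = []
        baseline = None
        for level in (40.0, 60.0):
            dose = DoseGrid(geometry=geom,
                            values=np.full((8, 8, 8), level))
            samples, metrics, curves, hists = _evaluate_masks(
                {"organ": mask}, dose, config)
            if baseline is None:
                from doseaccum.accumulation import Baseline

                baseline = Baseline(metrics=metrics, curves=curves,
                                    masks={"organ": mask}, samples=samples,
                                    eval_geometry=geom, hists=hists)
            frs.append(FractionResult(
                fraction_index=len(frs) + 1, geometry={},
                metrics=metrics, curves=curves,
                deviation_pct={"organ": {}}, hists=hists))
        acc = accumulate(frs, baseline, 2, config)
        assert acc.metrics["organ"].V50Gy_pct == pytest.approx(50.0)
        assert acc.metrics["organ"].Dmean_Gy == pytest.approx(50.0)

    def test_relevance_flag_arithmetic(self, drift_course, organs_config):
        course, _ = drift_course
        base, frs = self._results(course, organs_config, n=1)
        acc = accumulate(frs, base, 1, organs_config)
        for organ in ORGANS:
            for m, dev in acc.deviation_pct[organ].items():
                flag = acc.relevant_flags[organ][m]
                if dev is None:
                    assert not flag
                else:
                    assert flag == (abs(dev) > 2.0)


class TestExceedance:
    def _fake(self, devs):
        from doseaccum.accumulation import FractionResult

        return [FractionResult(fraction_index=i + 1, geometry={}, metrics={},
                               curves={},
                               deviation_pct={"bladder": {"Dmean_Gy": d}})
                for i, d in enumerate(devs)]

    def test_all_zero(self):
        assert threshold_exceedance_rate(self._fake([0, 0, 0]), "Dmean_Gy",
                                         "bladder", 2.0) == 0.0

    def test_direct_count(self):
        res = self._fake([1.0, 3.0, 5.0, 0.5])
        assert threshold_exceedance_rate(res, "Dmean_Gy", "bladder",
                                         2.0) == 50.0

    def test_zero_threshold_includes_all_nonzero(self):
        res = self._fake([0.0, 1e-9, -2.0])
        assert threshold_exceedance_rate(res, "Dmean_Gy", "bladder",
                                         0.0) == pytest.approx(200 / 3)

    def test_unknown_metric_rejected(self):
        with pytest.raises(LookupError_):
            threshold_exceedance_rate(self._fake([1.0]), "D42_Gy",
                                      "bladder", 2.0)


class TestRunCourse:
    def test_lenient_mode_records_failure(self, small_course):
        from doseaccum.io import load_course
        import shutil

        manifest, _, _ = small_course
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            broken = f"{td}/broken"
            shutil.copytree(manifest.parent, broken)
            # corrupt fraction 2's structures: truncate the file
            p = f"{broken}/fx002/structures.dcm"
            data = open(p, "rb").read()
            open(p, "wb").write(data[:200])
            # load_course validates existence, reading happens there too ->
            # corrupting must be visible at evaluation or load; emulate a
            # per-fraction failure by removing the organ instead
            import pydicom

            open(p, "wb").write(data)
            ds = pydicom.dcmread(p)
            ds.StructureSetROISequence[3].ROIName = "not_prostate"
            ds.save_as(p, enforce_file_format=True)
            course = load_course(f"{broken}/manifest.yaml")
            cfg = RunConfig(structures=ORGANS)
            report = run_course(course, cfg)
            assert len(report.fraction_results) == 2
            assert len(report.failures) == 1
            assert report.failures[0][0] == 2
            cfg_strict = RunConfig(structures=ORGANS, strict=True)
            with pytest.raises(DoseAccumError):
                run_course(course, cfg_strict)

    def test_report_serialization(self, small_course, tmp_path):
        from doseaccum.io import load_course

        manifest, _, _ = small_course
        course = load_course(manifest)
        report = run_course(course, RunConfig(structures=ORGANS))
        report.write(tmp_path / "rep")
        import json

        doc = json.loads((tmp_path / "rep" / "report.json").read_text())
        assert doc["n_fractions_evaluated"] == 3
        assert "accumulated" in doc
        assert (tmp_path / "rep" / "fractions_bladder.csv").exists()
        assert (tmp_path / "rep" / "dvh_prostate_plus_1cm.csv").exists()
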