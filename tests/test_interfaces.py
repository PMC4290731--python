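import json

import numpy as np
import pytest
from click.testing import CliRunner

from dsfiber import io
from dsfiber.cli import main as cli_main
from dsfiber.config import PipelineConfig, load_config
from dsfiber.fiber_model import Tractogram
from dsfiber.landmark_space import LandmarkSet
from dsfiber.pipeline import run_cohort, run_pipeline
from dsfiber.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture
def tractogram(rng):
    fibers = [np.cumsum(rng.normal(0, 2, size=(8, 3)), axis=0) for _ in range(5)]
    return Tractogram("subjA", fibers)


class TestTractogramIO:
    @pytest.mark.parametrize("ext", ["trk", "tck"])
    def test_round_trip_preserves_coordinates(self, tmp_path, tractogram, ext):
        path = tmp_path / f"t.{ext}"
        io.write_tractogram(tractogram, path)
        back = io.read_tractogram(path)
        assert len(back) == len(tractogram)
        for fa, fb in zip(tractogram.fibers, back.fibers):
            np.testing.assert_allclose(fa, fb, atol=1e-4)

    def test_trk_and_tck_load_to_equal_coordinates(self, tmp_path, tractogram):
        io.write_tractogram(tractogram, tmp_path / "t.trk")
        io.write_tractogram(tractogram, tmp_path / "t.tck")
        a = io.read_tractogram(tmp_path / "t.trk")
        b = io.read_tractogram(tmp_path / "t.tck")
        for fa, fb in zip(a.fibers, b.fibers):
            np.testing.assert_allclose(fa, fb, atol=1e-4)

    def test_empty_tractogram_round_trips_and_pipeline_refuses(self, tmp_path):
        path = tmp_path / "empty.tck"
        io.write_tractogram(Tractogram("e", []), path)
        back = io.read_tractogram(path)
        assert len(back) == 0
        with pytest.raises(ValueError, match="usable fibers"):
            run_cohort([back], None)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            io.read_tractogram(tmp_path / "x.vtk")


class TestLandmarkIO:
    def test_json_round_trip(self, tmp_path, rng):
        ls = LandmarkSet("s1", rng.normal(0, 10, size=(4, 3)), labels=[10, 20, 30, 40])
        path = tmp_path / "lm.json"
        io.write_landmarks(ls, path)
        back = io.read_landmarks(path)
        assert back.subject_id == "s1"
        assert back.labels == [10, 20, 30, 40]
        np.testing.assert_allclose(back.points, ls.points)

    def test_label_order_canonicalized_across_subjects(self, tmp_path, rng):
        pts = rng.normal(0, 10, size=(3, 3))
        a = LandmarkSet("a", pts, labels=[1, 2, 3])
        b = LandmarkSet("b", pts[::-1], labels=[3, 2, 1])
        io.write_landmarks(a, tmp_path / "a.json")
        io.write_landmarks(b, tmp_path / "b.json")
        la = io.read_landmarks(tmp_path / "a.json", label_ids=[1, 2, 3])
        lb = io.read_landmarks(tmp_path / "b.json", label_ids=[1, 2, 3])
        assert la.labels == lb.labels == [1, 2, 3]
        np.testing.assert_allclose(la.points, lb.points)

    def test_csv_with_missing_column_rejected(self, tmp_path):
        path = tmp_path / "lm.csv"
        path.write_text("label_id,x_mm,y_mm\n1,0,0\n")
        with pytest.raises(ValueError, match="z_mm"):
            io.read_landmarks(path)

    def test_nifti_labels_delegate_to_centroid_extraction(self, tmp_path):
        import nibabel as nib

        vol = np.zeros((5, 5, 5), dtype=np.int16)
        vol[1, 1, 1] = 1
        vol[3, 3, 3] = 2
        nib.save(nib.Nifti1Image(vol, np.eye(4)), tmp_path / "labels.nii.gz")
        ls = io.read_landmarks(tmp_path / "labels.nii.gz", label_ids=[1, 2])
        np.testing.assert_allclose(ls.points, [[1, 1, 1], [3, 3, 3]])


class TestConfig:
    def test_defaults_match_published_operating_point(self):
        cfg = PipelineConfig()
        assert cfg.k_samples == 12
        assert cfg.theta == 1e-5
        assert cfg.epsilon == 1e-7
        assert cfg.tail_fraction == 0.05
        assert cfg.alpha == 0.05
        assert cfg.min_fiber_length_mm == 3.0

    def test_unknown_key_is_an_error_not_a_default(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("k_samples: 12\nthets: 1e-4\n")
        with pytest.raises(ValueError, match="thets"):
            load_config(path)

    def test_yaml_round_trip_and_hash_stability(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("k_samples: 10\nalpha: 0.01\n")
        cfg = load_config(path)
        assert cfg.k_samples == 10
        assert cfg.content_hash() == load_config(path).content_hash()
        assert cfg.content_hash() != PipelineConfig().content_hash()

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(stage1_metric="frechet")
        with pytest.raises(ValueError):
            PipelineConfig(tail_fraction=1.5)


@pytest.fixture(scope="module")
def cohort_on_disk(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    cfg = SyntheticConfig(n_subjects=3, n_bundles=4, fibers_per_bundle=15, seed=21)
    cohort = generate_cohort(cfg)
    paths = {"tractograms": [], "landmarks": []}
    for tg in cohort.tractograms:
        tp = out / f"{tg.subject_id}.trk"
        io.write_tractogram(tg, tp)
        lp = out / f"{tg.subject_id}_landmarks.json"
        io.write_landmarks(cohort.landmarks[tg.subject_id], lp)
        paths["tractograms"].append(tp)
        paths["landmarks"].append(lp)
    return paths


class TestRunPipeline:
    def test_end_to_end_writes_complete_manifest(self, tmp_path, cohort_on_disk):
        out = tmp_path / "run"
        run_pipeline(
            cohort_on_disk["tractograms"], cohort_on_disk["landmarks"], out
        )
        manifest = json.loads((out / "cross_manifest.json").read_text())
        assert manifest["n_subjects"] == 3
        assert manifest["n_complete_clusters"] >= 1
        assert (out / "run_log.txt").exists()
        for tp in cohort_on_disk["tractograms"]:
            assert (out / f"{tp.stem}_assignments.tsv").exists()

    def test_rerun_is_byte_identical(self, tmp_path, cohort_on_disk):
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            run_pipeline(
                cohort_on_disk["tractograms"], cohort_on_disk["landmarks"], out
            )
            outs.append((out / "cross_manifest.json").read_bytes())
        assert outs[0] == outs[1]

    def test_single_subject_skips_cross_stage(self, tmp_path, cohort_on_disk):
        out = tmp_path / "single"
        result = run_pipeline(cohort_on_disk["tractograms"][:1], None, out)
        assert result.cross_clusters is None
        assert any("skipped" in line for line in result.log)


class TestCLI:
    def test_simulate_then_evaluate(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(
            cli_main,
            ["simulate", "--out-dir", str(sim_dir), "--n-subjects", "2",
             "--n-bundles", "3", "--fibers-per-bundle", "5", "--seed", "3"],
        )
        assert result.exit_code == 0, result.output
        labels = sim_dir / "subject00_labels.tsv"
        assert labels.exists()
        result = runner.invoke(
            cli_main,
            ["evaluate", str(labels), str(labels),
             "--truth-column", "bundle_id", "--pred-column", "bundle_id"],
        )
        assert result.exit_code == 0, result.output
        assert json.loads(result.output)["ari"] == 1.0

    def test_intra_command_writes_assignments(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(
            cli_main,
            ["simulate", "--out-dir", str(sim_dir), "--n-subjects", "2",
             "--n-bundles", "3", "--fibers-per-bundle", "8", "--seed", "5"],
        )
        out_tsv = tmp_path / "assign.tsv"
        result = runner.invoke(
            cli_main,
            ["intra", str(sim_dir / "subject00.trk"), "--out", str(out_tsv)],
        )
        assert result.exit_code == 0, result.output
        pred = io.read_labels_tsv(out_tsv)
        truth = io.read_labels_tsv(sim_dir / "subject00_labels.tsv", "bundle_id")
        from dsfiber.evaluation import adjusted_rand_index

        assert adjusted_rand_index(truth, pred) == 1.0

    def test_misspelled_config_key_exits_nonzero(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("thets: 0.1\n")
        dummy = tmp_path / "d.trk"
        io.write_tractogram(
            Tractogram("d", [np.array([[0.0, 0, 0], [5.0, 0, 0]])]), dummy
        )
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["intra", str(dummy), "--out", str(tmp_path / "o.tsv"),
             "--config", str(cfg)],
        )
        assert result.exit_code != 0
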