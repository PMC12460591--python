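import json

import numpy as np
import pandas as pd
import pytest

import dyadkin as dk
from dyadkin.openpose_io import (
    OpenPoseParseError,
    OpenPoseSchemaError,
    frame_index_from_filename,
    read_rmea,
)

from conftest import flat_person, write_body_frame


class TestParseFrameFile:
    def test_body_model_two_people(self, tmp_path):
        p = tmp_path / "d_000000000007_keypoints.json"
        write_body_frame(p, [flat_person(400), flat_person(1400)])
        rec = dk.parse_frame_file(p, {"body"})
        assert rec.frame_index == 7
        assert len(rec.detections) == 2
        assert all(d.region_payloads["body"].shape == (25, 3) for d in rec.detections)

    def test_face_model_yields_70_triplets(self, tmp_path):
        p = tmp_path / "d_000000000000_keypoints.json"
        face = [float(v) for k in range(70) for v in (100 + k, 200 + k, 0.8)]
        p.write_text(json.dumps({"version": 1.3, "people": [{"face_keypoints_2d": face}]}))
        rec = dk.parse_frame_file(p, {"face"})
        assert rec.detections[0].region_payloads["face"].shape == (70, 3)

    def test_empty_people_registers_frame(self, tmp_path):
        p = tmp_path / "d_000000000003_keypoints.json"
        p.write_text(json.dumps({"version": 1.3, "people": []}))
        rec = dk.parse_frame_file(p)
        assert rec.frame_index == 3
        assert rec.detections == []

    def test_malformed_json_names_file(self, tmp_path):
        p = tmp_path / "bad_000000000000_keypoints.json"
        p.write_text("{not json")
        with pytest.raises(OpenPoseParseError, match="bad_000000000000"):
            dk.parse_frame_file(p)

    def test_wrong_array_length_is_schema_error(self, tmp_path):
        p = tmp_path / "d_000000000000_keypoints.json"
        p.write_text(json.dumps({"people": [{"pose_keypoints_2d": [1.0] * 74}]}))
        with pytest.raises(OpenPoseSchemaError):
            dk.parse_frame_file(p)
        p.write_text(json.dumps({"people": [{"pose_keypoints_2d": [1.0] * 72}]}))
        with pytest.raises(OpenPoseSchemaError, match="24 keypoints"):
            dk.parse_frame_file(p)

    def test_frame_index_parsing(self):
        assert frame_index_from_filename("v_000000000123_keypoints.json") == 123
        assert frame_index_from_filename("no_counter.json") is None


class TestScanRecording:
    def test_contiguous_frames_no_gaps(self, two_person_dir):
        records, report = dk.scan_recording(two_person_dir)
        assert [r.frame_index for r in records] == [0, 1, 2, 3, 4]
        assert report.missing_frames == []

    def test_gap_reported(self, tmp_path):
        d = tmp_path / "gappy"
        d.mkdir()
        for t in (0, 1, 3):
            write_body_frame(d / f"g_{t:012d}_keypoints.json", [flat_person(400)])
        _, report = dk.scan_recording(d)
        assert report.missing_frames == [2]

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="no frames found"):
            dk.scan_recording(tmp_path)

    def test_order_independent_of_creation_order(self, tmp_path):
        d = tmp_path / "shuffled"
        d.mkdir()
        for t in (4, 0, 2, 1, 3):  # create out of order
            write_body_frame(d / f"s_{t:012d}_keypoints.json", [flat_person(400 + t)])
        records, _ = dk.scan_recording(d)
        assert [r.frame_index for r in records] == [0, 1, 2, 3, 4]


class TestBuildDyadTable:
    def test_midline_assignment(self, two_person_dir):
        records, _ = dk.scan_recording(two_person_dir)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        left = table.df[(table.df.person == "left") & (table.df.frame == 0)]
        right = table.df[(table.df.person == "right") & (table.df.frame == 0)]
        assert left.iloc[0]["x0"] == 400.0
        assert right.iloc[0]["x0"] == 1400.0

    def test_default_frame_width_warns_and_is_1920(self, two_person_dir):
        records, _ = dk.scan_recording(two_person_dir)
        with pytest.warns(UserWarning, match="1920"):
            table = dk.build_dyad_table(records, "midline", fps=30)
        assert table.frame_width == 1920

    def test_single_person_yields_missing_partner_row(self, tmp_path):
        d = tmp_path / "solo"
        d.mkdir()
        for t in range(3):
            write_body_frame(d / f"s_{t:012d}_keypoints.json", [flat_person(300)])
        records, _ = dk.scan_recording(d)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        right = table.df[table.df.person == "right"]
        assert len(right) == 3
        assert right[[f"x{k}" for k in range(25)]].isna().all().all()
        assert (right[[f"c{k}" for k in range(25)]] == 0.0).all().all()

    def test_sentinel_completion_fills_missing_frames(self, tmp_path):
        d = tmp_path / "gappy"
        d.mkdir()
        for t in (0, 1, 4):
            write_body_frame(d / f"g_{t:012d}_keypoints.json", [flat_person(400)])
        records, _ = dk.scan_recording(d)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        for _, sub in table.group_iter():
            assert list(sub["frame"]) == [0, 1, 2, 3, 4]

    def test_more_than_two_detections_keeps_most_confident(self, tmp_path):
        d = tmp_path / "crowd"
        d.mkdir()
        write_body_frame(
            d / f"c_{0:012d}_keypoints.json",
            [flat_person(400, c=0.9), flat_person(960, c=0.2), flat_person(1500, c=0.8)],
        )
        records, report = dk.scan_recording(d)
        table = dk.build_dyad_table(
            records, "midline", frame_width=1920, fps=30, report=report
        )
        assert report.extra_detection_events == [(0, 3)]
        xs = sorted(table.df["x0"].dropna())
        assert xs == [400.0, 1500.0]

    def test_zero_sentinel_becomes_missing(self, tmp_path):
        d = tmp_path / "drop"
        d.mkdir()
        person = flat_person(400)
        person[0:3] = [0.0, 0.0, 0.0]  # keypoint 0 undetected
        write_body_frame(d / f"d_{0:012d}_keypoints.json", [person])
        records, _ = dk.scan_recording(d)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        row = table.df[table.df.person == "left"].iloc[0]
        assert np.isnan(row["x0"]) and row["c0"] == 0.0
        assert row["x1"] == 402.0  # others untouched


class TestCsvRoundTrip:
    def test_dyad_export_shape(self, tmp_path):
        d = tmp_path / "rec"
        d.mkdir()
        for t in range(10):
            write_body_frame(
                d / f"r_{t:012d}_keypoints.json", [flat_person(400), flat_person(1400)]
            )
        records, _ = dk.scan_recording(d)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        out = tmp_path / "rec.csv"
        dk.write_dyad_csv(table, out, export_type="dyad")
        df = pd.read_csv(out)
        assert df.shape == (20, 4 + 75)  # left+right rows, metadata + 25*3

    def test_individual_export_suffixes(self, two_person_dir, tmp_path):
        records, _ = dk.scan_recording(two_person_dir)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        files = dk.write_dyad_csv(table, tmp_path / "dyad.csv", export_type="individual")
        assert sorted(f.name for f in files) == ["dyad_left.csv", "dyad_right.csv"]

    def test_lossless_numeric_round_trip(self, two_person_dir, tmp_path):
        records, _ = dk.scan_recording(two_person_dir)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        # perturb with awkward floats to exercise repr precision
        table.df.loc[0, "x0"] = 400.1234567890123
        out = tmp_path / "t.csv"
        dk.write_dyad_csv(table, out)
        back = dk.read_dyad_csv(out, fps=30, frame_width=1920)
        cols = table.triplet_columns()
        pd.testing.assert_frame_equal(
            table.df[cols], back.df[cols], check_exact=True
        )

    def test_labelled_export_header(self, two_person_dir, tmp_path):
        records, _ = dk.scan_recording(two_person_dir)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        out = tmp_path / "lab.csv"
        dk.write_dyad_csv(table, out, include_labels=True)
        header = out.read_text().splitlines()[0].split(",")
        assert "nose_x" in header and "x0" not in header


class TestKeypointLabels:
    def test_rename_and_idempotence_and_inverse(self, two_person_dir):
        records, _ = dk.scan_recording(two_person_dir)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        labelled = dk.apply_keypoint_labels(table)
        assert {"nose_x", "nose_y", "nose_c"} <= set(labelled.df.columns)
        twice = dk.apply_keypoint_labels(labelled)
        assert list(twice.df.columns) == list(labelled.df.columns)
        restored = dk.strip_keypoint_labels(labelled)
        assert list(restored.df.columns) == list(table.df.columns)

    def test_unknown_columns_rejected(self, two_person_dir):
        records, _ = dk.scan_recording(two_person_dir)
        table = dk.build_dyad_table(records, "midline", frame_width=1920, fps=30)
        table.df["x99"] = 1.0
        with pytest.raises(ValueError, match="x99"):
            dk.apply_keypoint_labels(table)


class TestBatchConvert:
    def _make_dyads(self, base, n=3, corrupt=None):
        for i in range(n):
            d = base / f"dyad{i:02d}"
            d.mkdir(parents=True)
            for t in range(4):
                write_body_frame(
                    d / f"d_{t:012d}_keypoints.json", [flat_person(400), flat_person(1400)]
                )
            if corrupt == i:
                (d / f"d_{1:012d}_keypoints.json").write_text("{broken")

    def test_all_succeed(self, tmp_path):
        self._make_dyads(tmp_path / "in", 3)
        manifest = dk.batch_convert(tmp_path / "in", tmp_path / "out",
                                    frame_width=1920, fps=30)
        assert manifest["n_ok"] == 3 and manifest["n_failed"] == 0
        assert sorted(p.name for p in (tmp_path / "out").glob("*.csv")) == [
            "dyad00.csv", "dyad01.csv", "dyad02.csv",
        ]
        assert json.loads((tmp_path / "out" / "manifest.json").read_text())["n_ok"] == 3

    def test_corrupt_dyad_isolated(self, tmp_path):
        self._make_dyads(tmp_path / "in", 3, corrupt=1)
        manifest = dk.batch_convert(tmp_path / "in", tmp_path / "out",
                                    frame_width=1920, fps=30)
        assert manifest["n_ok"] == 2 and manifest["n_failed"] == 1
        assert manifest["dyads"]["dyad01"]["status"] == "failed"

    def test_no_subfolders_errors(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError):
            dk.batch_convert(tmp_path / "empty", tmp_path / "out")


class TestRmeaExport:
    def test_shape_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        left, right = rng.random(100), rng.random(100)
        path = dk.export_rmea(left, right, tmp_path, "dyad16", "groupA", sampling_rate=30)
        assert path.name == "dyad16_groupA.txt"
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 100 and all(len(l.split(",")) == 2 for l in lines)
        back_l, back_r = read_rmea(path)
        np.testing.assert_array_equal(back_l, left)
        np.testing.assert_array_equal(back_r, right)
        sidecar = json.loads((tmp_path / "dyad16_groupA.manifest.json").read_text())
        assert sidecar["sampling_rate_hz"] == 30

    def test_static_dyad_writes_zeros(self, tmp_path):
        z = np.zeros(10)
        path = dk.export_rmea(z, z, tmp_path, "d0")
        l, r = read_rmea(path)
        assert (l == 0).all() and (r == 0).all()

    def test_unequal_lengths_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="equal-length"):
            dk.export_rmea(np.zeros(5), np.zeros(6), tmp_path, "d0")
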