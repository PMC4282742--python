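import numpy as np
import pytest

import footkin as fk
from footkin.errors import (
    EmptyTrialError,
    FormatError,
    ParameterError,
    SchemaError,
)


def _toy_series(n_frames=10, labels=("CA", "ST"), rate=100.0, seed=0, **kw):
    rng = np.random.default_rng(seed)
    data = rng.uniform(-100, 400, size=(n_frames, len(labels), 3))
    return fk.MarkerFrameSeries(labels=list(labels), data=data, rate=rate, **kw)


class TestTsvRoundTrip:
    def test_lossless_to_1e6_mm(self, tmp_path, static_series):
        path = tmp_path / "trial.tsv"
        fk.write_markers_tsv(static_series, path)
        back = fk.read_markers_tsv(path, "R", trial_kind="static")
        assert back.labels == static_series.labels
        assert back.rate == static_series.rate
        assert np.nanmax(np.abs(back.data - static_series.data)) < 1e-6

    def test_missing_sentinel_preserved(self, tmp_path):
        s = _toy_series()
        s.data[3, 1, :] = np.nan
        path = tmp_path / "gap.tsv"
        fk.write_markers_tsv(s, path)
        back = fk.read_markers_tsv(path, "R")
        assert back.missing_mask("ST")[3]
        assert back.missing_mask("ST").sum() == 1

    def test_left_side_mirror_round_trip(self, tmp_path):
        s = _toy_series(side="right")
        path = tmp_path / "l.tsv"
        fk.write_markers_tsv(s, path)
        left = fk.read_markers_tsv(path, "L")
        assert left.mirrored and left.side == "left"
        # ingest mirrors Z; writing restores the on-disk coordinates
        assert np.allclose(left["CA"][:, 2], -s["CA"][:, 2])
        path2 = tmp_path / "l2.tsv"
        fk.write_markers_tsv(left, path2)
        assert path.read_text().splitlines()[1:] == path2.read_text().splitlines()[1:]

    def test_empty_series_refused(self, tmp_path):
        s = _toy_series(n_frames=1)
        s.data = s.data[:0]
        with pytest.raises(EmptyTrialError):
            fk.write_markers_tsv(s, tmp_path / "e.tsv")


class TestTsvSchema:
    def test_single_frame_values(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("frame\tCA_x\tCA_y\tCA_z\n0\t0\t100\t0\n")
        s = fk.read_markers_tsv(p, "R")
        assert np.allclose(s["CA"][0], [0, 100, 0])

    def test_blank_cell_is_missing(self, tmp_path):
        p = tmp_path / "blank.tsv"
        rows = ["frame\tST_x\tST_y\tST_z"] + [f"{i}\t1\t2\t3" for i in range(5)]
        rows[4] = "3\t1\t\t3"  # frame 3, ST_y blank
        p.write_text("\n".join(rows) + "\n")
        s = fk.read_markers_tsv(p, "R")
        assert s.missing_mask("ST")[3] and s.missing_mask("ST").sum() == 1

    @pytest.mark.parametrize("body, err", [
        ("frame\tCA_x\tCA_y\n0\t1\t2\n", SchemaError),  # not a multiple of 3
        ("frame\tCA_x\tCA_y\tCA_z\tCA_x\tCA_y\tCA_z\n0\t1\t2\t3\t4\t5\t6\n", SchemaError),
        ("frame\tCA_x\tCA_y\tCA_z\n1\t1\t2\t3\n0\t1\t2\t3\n", SchemaError),  # non-monotone
        ("", EmptyTrialError),
    ])
    def test_schema_errors(self, tmp_path, body, err):
        p = tmp_path / "bad.tsv"
        p.write_text(body)
        with pytest.raises(err):
            fk.read_markers_tsv(p, "R")


class TestC3d:
    def test_round_trip_17_labels(self, tmp_path, static_series):
        path = tmp_path / "trial.c3d"
        fk.write_c3d(static_series, path)
        back = fk.read_c3d(path, "R", trial_kind="static")
        assert len(back.labels) == 17
        assert back.labels == static_series.labels
        assert back.n_frames == static_series.n_frames
        assert np.nanmax(np.abs(back.data - static_series.data)) < 1e-3  # float32 storage

    def test_rate_from_header(self, tmp_path):
        s = _toy_series(rate=100.0)
        path = tmp_path / "r.c3d"
        fk.write_c3d(s, path)
        assert fk.read_c3d(path, "R").rate == 100.0

    def test_missing_becomes_nan(self, tmp_path):
        s = _toy_series()
        s.data[2, 0, :] = np.nan
        path = tmp_path / "m.c3d"
        fk.write_c3d(s, path)
        back = fk.read_c3d(path, "R")
        assert back.missing_mask("CA")[2]

    def test_truncated_file_raises(self, tmp_path, static_series):
        path = tmp_path / "t.c3d"
        fk.write_c3d(static_series, path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(FormatError):
            fk.read_c3d(path, "R")

    def test_garbage_raises(self, tmp_path):
        path = tmp_path / "g.c3d"
        path.write_bytes(b"\x00" * 1024)
        with pytest.raises((FormatError, EmptyTrialError)):
            fk.read_c3d(path, "R")

    def test_side_prefix_stripped(self, tmp_path):
        s = _toy_series(labels=("RCA", "R_ST"))
        path = tmp_path / "p.c3d"
        fk.write_c3d(s, path)
        back = fk.read_c3d(path, "R")
        assert back.labels == ["CA", "ST"]


class TestValidation:
    def test_static_without_hl_fails_naming_hl(self, static_series):
        labels = [l for l in static_series.labels if l != "HL"]
        idx = [static_series.labels.index(l) for l in labels]
        s = fk.MarkerFrameSeries(labels=labels, data=static_series.data[:, idx],
                                 rate=100.0, trial_kind="static")
        rep = fk.validate_marker_set(s)
        assert not rep.passed
        assert "HL" in rep.missing_labels
        assert any("HL" in m for m in rep.messages)

    def test_complete_walking_passes(self, walking):
        series, _ = walking
        assert fk.validate_marker_set(series).passed

    def test_fully_missing_label_fails(self, static_series):
        s = static_series.copy()
        s.data[:, s.labels.index("TN"), :] = np.nan
        rep = fk.validate_marker_set(s)
        assert not rep.passed
        assert rep.missing_fraction["TN"] == 1.0

    def test_validation_is_pure(self, static_series):
        before = static_series.data.copy()
        fk.validate_marker_set(static_series)
        assert np.array_equal(before, static_series.data)


class TestFillGaps:
    def _cubic_series(self, n=60):
        t = np.arange(n, dtype=float)
        coords = np.stack([0.01 * t**3 - 0.5 * t**2 + 3 * t,
                           2 * t + 5, -0.002 * t**3 + t], axis=1)
        return fk.MarkerFrameSeries(labels=["CA"], data=coords[:, None, :], rate=100.0)

    def test_cubic_trajectory_restored_exactly(self):
        s = self._cubic_series()
        truth = s.data.copy()
        s.data[20:26, 0, :] = np.nan
        filled = fk.fill_gaps(s, max_gap_frames=10)
        assert np.nanmax(np.abs(filled.data - truth)) < 1e-6

    def test_long_gap_left_missing(self):
        s = self._cubic_series()
        s.data[20:32, 0, :] = np.nan
        filled = fk.fill_gaps(s, max_gap_frames=5)
        assert np.isnan(filled.data[25, 0]).all()

    def test_edge_gap_never_extrapolated(self):
        s = self._cubic_series()
        s.data[:4, 0, :] = np.nan
        s.data[-3:, 0, :] = np.nan
        filled = fk.fill_gaps(s, max_gap_frames=10)
        assert np.isnan(filled.data[0, 0]).all()
        assert np.isnan(filled.data[-1, 0]).all()

    def test_negative_max_gap_rejected(self):
        with pytest.raises(ParameterError):
            fk.fill_gaps(self._cubic_series(), max_gap_frames=-1)


class TestLowpass:
    def test_constant_unchanged(self):
        s = fk.MarkerFrameSeries(labels=["CA"], data=np.full((200, 1, 3), 37.0), rate=100.0)
        out = fk.lowpass_filter(s, 6.0)
        assert np.abs(out.data - 37.0).max() < 1e-9

    def test_40hz_sinusoid_strongly_attenuated(self):
        t = np.arange(500) / 100.0
        sine = 10.0 * np.sin(2 * np.pi * 40.0 * t)
        data = np.zeros((500, 1, 3))
        data[:, 0, 0] = sine
        s = fk.MarkerFrameSeries(labels=["CA"], data=data, rate=100.0)
        out = fk.lowpass_filter(s, 6.0)
        # 4th-order zero-phase response at 40/6 x cutoff: residual < 1%
        assert np.abs(out.data[100:400, 0, 0]).max() < 0.01 * 10.0

    def test_cutoff_at_nyquist_rejected(self):
        s = fk.MarkerFrameSeries(labels=["CA"], data=np.zeros((50, 1, 3)), rate=100.0)
        with pytest.raises(ParameterError):
            fk.lowpass_filter(s, 60.0)
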