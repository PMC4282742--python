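"""Reading, validating, cleaning and writing marker trajectory data.

Conventions fixed here and used by every downstream module:

* positions in millimetres, angles (elsewhere) in degrees;
* laboratory frame: X = walking direction, Y = vertical up, Z = to the
  subject's right; the ground plane is Y = 0;
* missing samples carry a NaN sentinel (C3D negative residual, blank TSV
  cell), never zeros;
* left feet are mirrored (Z -> -Z) on ingest so all downstream sign
  conventions (inversion +, adduction +) are side-independent; writing a
  mirrored series restores the original coordinates.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from . import c3d
from .errors import DataError, EmptyTrialError, ParameterError, SchemaError

logger = logging.getLogger(__name__)

#: Marker roster of the static trial (walking = same minus HL).
REQUIRED_STATIC = (
    "CA", "PT", "ST", "HL", "TN", "C", "FMB", "SMB", "VMB",
    "FMH", "SMH", "VMH", "PM", "HF", "TT", "LM", "MM",
)
REQUIRED_WALKING = tuple(m for m in REQUIRED_STATIC if m != "HL")


@dataclass
class MarkerFrameSeries:
    """Labelled 3D marker positions for one trial of one foot.

    ``data`` has shape ``(n_frames, n_labels, 3)`` in mm with NaN marking
    missing samples. ``mirrored`` records whether a left-side Z flip was
    applied on ingest (so writers can undo it).
    """

    labels: list[str]
    data: np.ndarray
    rate: float
    side: str = "right"
    trial_kind: str = "walking"
    mirrored: bool = False
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise SchemaError("data must have shape (n_frames, n_labels, 3)")
        if self.data.shape[1] != len(self.labels):
            raise SchemaError("label count does not match data")
        if not self.rate > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.trial_kind not in ("static", "walking"):
            raise ParameterError(f"trial_kind must be 'static' or 'walking', got {self.trial_kind!r}")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != len(self.labels):
            raise SchemaError("duplicate marker labels")

    # -- accessors -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __getitem__(self, label: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one marker."""
        try:
            return self.data[:, self._index[label], :]
        except KeyError:
            raise KeyError(f"marker {label!r} not in series") from None

    def missing_mask(self, label: str) -> np.ndarray:
        """Boolean (n_frames,) mask of missing samples for one marker."""
        return np.isnan(self[label]).any(axis=1)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def copy(self) -> "MarkerFrameSeries":
        return replace(self, data=self.data.copy(), labels=list(self.labels))


@dataclass(frozen=True)
class MarkerSetSpec:
    """Required marker roster per trial kind and the lab axis convention."""

    required_static: tuple = REQUIRED_STATIC
    required_walking: tuple = REQUIRED_WALKING
    lab_axes: str = "X forward (progression), Y vertical up, Z to the subject's right"

    def required(self, trial_kind: str) -> tuple:
        return self.required_static if trial_kind == "static" else self.required_walking


@dataclass
class ValidationReport:
    passed: bool
    missing_labels: list
    missing_fraction: dict
    messages: list

    def __bool__(self) -> bool:
        return self.passed


# ---------------------------------------------------------------------------
# label normalisation

_KNOWN = set(REQUIRED_STATIC)


def _normalize_label(raw: str, side: str) -> str:
    lab = raw.strip().upper()
    if ":" in lab:  # subject-prefixed Vicon labels
        lab = lab.rsplit(":", 1)[1]
    if lab in _KNOWN:
        return lab
    prefix = side[0].upper()
    for pat in (f"{prefix}_", prefix):
        if lab.startswith(pat) and lab[len(pat):] in _KNOWN:
            return lab[len(pat):]
    return lab


def _mirror_if_left(data: np.ndarray, side: str) -> np.ndarray:
    if side == "left":
        data = data.copy()
        data[:, :, 2] *= -1.0
    return data


# ---------------------------------------------------------------------------
# readers / writers

def read_c3d(path, side: str, trial_kind: str = "walking") -> MarkerFrameSeries:
    """Read 3D point data from a C3D file.

    Labels are matched case-insensitively against the model roster with an
    optional side prefix (``R_``/``L_``/subject prefix) stripped; the
    sampling rate comes from the file header.
    """
    side = _canon_side(side)
    labels, pts, rate = c3d.read_c3d(path)
    labels = [_normalize_label(lab, side) for lab in labels]
    if pts.shape[0] == 0:
        raise EmptyTrialError(f"{path}: no frames")
    data = _mirror_if_left(pts, side)
    return MarkerFrameSeries(labels=labels, data=data, rate=rate, side=side,
                             trial_kind=trial_kind, mirrored=(side == "left"))


def write_c3d(series: MarkerFrameSeries, path) -> None:
    """Write a series to C3D (unmirrors left-side data first)."""
    if series.n_frames == 0:
        raise EmptyTrialError("refusing to write an empty series")
    data = _mirror_if_left(series.data, series.side) if series.mirrored else series.data
    c3d.write_c3d(path, series.labels, data, series.rate)


def _canon_side(side: str) -> str:
    s = str(side).strip().lower()
    if s in ("l", "left"):
        return "left"
    if s in ("r", "right"):
        return "right"
    raise ParameterError(f"side must be L or R, got {side!r}")


def read_markers_tsv(path, side: str, rate: float = 100.0,
                     trial_kind: str = "walking") -> MarkerFrameSeries:
    """Read the plain TSV trajectory dialect.

    Header row is ``frame`` followed by ``<LABEL>_x  <LABEL>_y  <LABEL>_z``
    triplets; a blank cell marks a missing coordinate. An optional comment
    line ``# rate=<Hz>`` overrides ``rate``.
    """
    side = _canon_side(side)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    for ln in lines:
        m = re.match(r"#\s*rate\s*=\s*([0-9.]+)", ln)
        if m:
            rate = float(m.group(1))
        elif ln.strip() and not ln.startswith("#"):
            body.append(ln)
    if not body:
        raise EmptyTrialError(f"{path}: empty trajectory file")
    header = body[0].split("\t")
    if header[0].strip().lower() != "frame":
        raise SchemaError(f"{path}: first column must be 'frame'")
    coord_cols = header[1:]
    if len(coord_cols) % 3 != 0:
        raise SchemaError(f"{path}: coordinate columns not a multiple of 3")
    labels = []
    for i in range(0, len(coord_cols), 3):
        trip = coord_cols[i : i + 3]
        names = []
        for col, ax in zip(trip, "xyz"):
            m = re.fullmatch(r"(.+)_([xyz])", col.strip(), flags=re.IGNORECASE)
            if not m or m.group(2).lower() != ax:
                raise SchemaError(f"{path}: column {col!r} does not follow <LABEL>_{ax}")
            names.append(m.group(1))
        if len(set(names)) != 1:
            raise SchemaError(f"{path}: mixed labels in triplet {trip}")
        labels.append(_normalize_label(names[0], side))
    if len(set(labels)) != len(labels):
        raise SchemaError(f"{path}: duplicated label columns")

    rows = []
    idx_prev = None
    for ln in body[1:]:
        cells = ln.split("\t")
        if len(cells) != 1 + 3 * len(labels):
            raise SchemaError(f"{path}: row has {len(cells)} cells, expected {1 + 3 * len(labels)}")
        idx = int(cells[0])
        if idx_prev is not None and idx <= idx_prev:
            raise SchemaError(f"{path}: non-monotone frame index at {idx}")
        idx_prev = idx
        vals = [float(c) if c.strip() != "" else np.nan for c in cells[1:]]
        rows.append(vals)
    if not rows:
        raise EmptyTrialError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(labels), 3)
    data = _mirror_if_left(data, side)
    return MarkerFrameSeries(labels=labels, data=data, rate=rate, side=side,
                             trial_kind=trial_kind, mirrored=(side == "left"))


def write_markers_tsv(series: MarkerFrameSeries, path) -> None:
    """Write the TSV dialect; round-trips with :func:`read_markers_tsv`."""
    if series.n_frames == 0:
        raise EmptyTrialError("refusing to write an empty series")
    data = _mirror_if_left(series.data, series.side) if series.mirrored else series.data
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rate={series.rate:g}\n")
        cols = ["frame"] + [f"{lab}_{ax}" for lab in series.labels for ax in "xyz"]
        fh.write("\t".join(cols) + "\n")
        for f in range(series.n_frames):
            cells = [str(f)]
            for v in data[f].ravel():
                cells.append("" if np.isnan(v) else f"{v:.9f}")
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# validation and cleaning

def validate_marker_set(series: MarkerFrameSeries,
                        spec: MarkerSetSpec | None = None) -> ValidationReport:
    """Report missing required labels and per-label missing-sample fractions.

    Pure: never mutates the series. A label that is present but 100%
    missing fails the trial-kind rule just like an absent label.
    """
    spec = spec or MarkerSetSpec()
    required = spec.required(series.trial_kind)
    missing_labels = [lab for lab in required if lab not in series]
    fractions = {}
    messages = []
    for lab in series.labels:
        frac = float(np.mean(series.missing_mask(lab))) if series.n_frames else 1.0
        fractions[lab] = frac
    all_missing = [lab for lab in required if lab in series and fractions.get(lab, 0.0) >= 1.0]
    for lab in missing_labels:
        messages.append(f"required marker {lab} absent for {series.trial_kind} trial")
    for lab in all_missing:
        messages.append(f"required marker {lab} present but 100% missing")
    passed = not missing_labels and not all_missing
    return ValidationReport(passed=passed, missing_labels=missing_labels,
                            missing_fraction=fractions, messages=messages)


def fill_gaps(series: MarkerFrameSeries, max_gap_frames: int = 10) -> MarkerFrameSeries:
    """Fill interior gaps up to ``max_gap_frames`` by cubic interpolation.

    The not-a-knot cubic spline through the valid samples reproduces any
    cubic-polynomial trajectory exactly. Longer gaps and leading/trailing
    gaps are left missing (never extrapolated) and logged.
    """
    if max_gap_frames < 0:
        raise ParameterError("max_gap_frames must be >= 0")
    out = series.copy()
    n = series.n_frames
    for j, lab in enumerate(series.labels):
        valid = ~np.isnan(out.data[:, j, :]).any(axis=1)
        if valid.all() or valid.sum() < 2:
            continue
        idx = np.flatnonzero(valid)
        gaps = _interior_gaps(valid)
        for start, stop in gaps:  # gap covers frames [start, stop)
            length = stop - start
            if length > max_gap_frames:
                logger.warning("marker %s: %d-frame gap at %d left unfilled", lab, length, start)
                continue
            t = np.arange(start, stop)
            for k in range(3):
                y = out.data[idx, j, k]
                if len(idx) >= 4:
                    out.data[t, j, k] = CubicSpline(idx, y, bc_type="not-a-knot")(t)
                else:
                    out.data[t, j, k] = np.interp(t, idx, y)
    return out


def _interior_gaps(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of missing frames with valid data on both sides."""
    n = len(valid)
    first = int(np.argmax(valid))
    last = n - 1 - int(np.argmax(valid[::-1]))
    gaps = []
    in_gap = False
    for i in range(first, last + 1):
        if not valid[i] and not in_gap:
            in_gap, g0 = True, i
        elif valid[i] and in_gap:
            in_gap = False
            gaps.append((g0, i))
    return gaps


def lowpass_filter(series: MarkerFrameSeries, cutoff_hz: float = 6.0) -> MarkerFrameSeries:
    """Zero-phase 4th-order Butterworth low-pass per coordinate.

    Implemented as a 2nd-order filter applied forward and backward
    (``filtfilt``), the conventional zero-lag 4th-order smoother of gait
    laboratories. Contiguous valid spans are filtered independently; spans
    too short for stable filtering are passed through unchanged.
    """
    if not 0 < cutoff_hz < series.rate / 2:
        raise ParameterError(f"cutoff {cutoff_hz} Hz must lie in (0, rate/2={series.rate / 2})")
    b, a = butter(2, cutoff_hz / (series.rate / 2))
    padlen = 3 * (max(len(a), len(b)) - 1)
    out = series.copy()
    for j in range(len(series.labels)):
        valid = ~np.isnan(out.data[:, j, :]).any(axis=1)
        for start, stop in _valid_runs(valid):
            if stop - start <= padlen + 1:
                continue
            seg = out.data[start:stop, j, :]
            out.data[start:stop, j, :] = filtfilt(b, a, seg, axis=0)
    return out


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(valid)
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def preprocess(series: MarkerFrameSeries, max_gap_frames: int = 10,
               cutoff_hz: float | None = 6.0) -> MarkerFrameSeries:
    """Default cleaning pipeline: gap fill then optional low-pass."""
    out = fill_gaps(series, max_gap_frames)
    if cutoff_hz is not None:
        out = lowpass_filter(out, cutoff_hz)
    return out
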