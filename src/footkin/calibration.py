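"""Static-trial calibration: hindfoot frontal offset, CAp virtual point,
and static reference angles.

The up-right double-leg static trial yields three per-foot products:

* ``hindfoot_frontal_offset`` -- the angle between CA-HL projected into the
  shank frontal plane and the shank vertical axis (positive = top of the
  calcaneus tilted laterally = valgus/eversion). This value replaces the
  frame-derived static Sha-Cal frontal angle as the reported clinical
  alignment, because the marker-frame construction is biased toward
  inversion by the typically higher position of ST relative to PT.
* ``cap_local`` -- CAp (the vertical ground projection of CA) expressed in
  the calcaneus technical frame, so it can be tracked rigidly during gait.
* ``static_angles`` -- the time-averaged static value of all 15 joint
  components and 8 planar angles (23 keys).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import joint_kinematics as jk
from .errors import CalibrationError, DataError
from .marker_io import MarkerFrameSeries
from .segment_frames import build_shank_frame, technical_frame


@dataclass
class StaticCalibration:
    """Per-foot calibration products from the static trial."""

    side: str
    hindfoot_frontal_offset: float  # deg, + = valgus/eversion
    cap_local: np.ndarray  # mm, calcaneus technical frame
    static_angles: dict = field(default_factory=dict)  # name -> deg

    def __post_init__(self):
        self.cap_local = np.asarray(self.cap_local, dtype=float)


def _cal_technical_frame(ca, pt, st):
    return technical_frame(ca, 0.5 * (pt + st), st, segment="Cal-cluster")


def _valid_frames(series: MarkerFrameSeries, markers) -> np.ndarray:
    ok = np.ones(series.n_frames, dtype=bool)
    for m in markers:
        if m not in series:
            raise CalibrationError(f"static trial lacks required marker {m}")
        ok &= ~series.missing_mask(m)
    if not ok.any():
        raise CalibrationError(f"no frame with all of {markers} valid")
    return ok


def compute_hindfoot_frontal_offset(static: MarkerFrameSeries) -> float:
    """Frontal-plane hindfoot alignment from the HL marker (deg).

    Per frame, CA - HL is projected into the shank frontal plane (spanned
    by the shank Y and Z axes) and the signed angle to the shank vertical
    axis is taken; frames are time-averaged. Positive = the top of the
    calcaneus tilts laterally (valgus/eversion).
    """
    ok = _valid_frames(static, ("CA", "HL", "HF", "TT", "LM", "MM"))
    ca, hl = static["CA"], static["HL"]
    hf, tt, lm, mm = (static[m] for m in ("HF", "TT", "LM", "MM"))
    vals = []
    for f in np.flatnonzero(ok):
        shank = build_shank_frame(hf[f], tt[f], lm[f], mm[f])
        v = ca[f] - hl[f]
        vy, vz = np.dot(v, shank.y), np.dot(v, shank.z)
        if np.hypot(vy, vz) < 1e-6:
            raise DataError("CA-HL projection into the shank frontal plane is degenerate")
        vals.append(np.degrees(np.arctan2(vz, vy)))
    return float(np.mean(vals))


def define_cap_point(static: MarkerFrameSeries) -> tuple[np.ndarray, np.ndarray]:
    """CAp = vertical projection of CA on the ground (Y=0), time-averaged.

    Returns ``(cap_lab, cap_local)`` where ``cap_local`` expresses CAp in
    the calcaneus technical frame so it can be tracked during walking.
    """
    ok = _valid_frames(static, ("CA", "PT", "ST"))
    ca, pt, st = static["CA"], static["PT"], static["ST"]
    if (ca[ok, 1] < 0).any():
        raise DataError("CA below the ground plane (y < 0) in the static trial")
    locals_ = []
    labs = []
    for f in np.flatnonzero(ok):
        cap_f = np.array([ca[f, 0], 0.0, ca[f, 2]])
        tf = _cal_technical_frame(ca[f], pt[f], st[f])
        locals_.append(tf.to_local(cap_f))
        labs.append(cap_f)
    return np.mean(labs, axis=0), np.mean(locals_, axis=0)


def track_cap(walking: MarkerFrameSeries, calib: StaticCalibration) -> np.ndarray:
    """Per-frame lab positions of CAp tracked by the calcaneus cluster."""
    return jk.track_cap_local(walking, calib.cap_local)


def compute_static_reference(static: MarkerFrameSeries, side: str | None = None) -> StaticCalibration:
    """Full static calibration: offset, CAp local coordinates and the
    time-averaged static value of all 23 angles.

    The Sha-Cal frontal component of ``static_angles`` is the HL-based
    offset itself (the frame-derived value is superseded by design).
    """
    side = side or static.side
    offset = compute_hindfoot_frontal_offset(static)
    _, cap_local = define_cap_point(static)
    calib = StaticCalibration(side=side, hindfoot_frontal_offset=offset, cap_local=cap_local)

    poses = jk.segment_poses(static)
    joints = jk.compute_joint_series(static, poses=poses)
    planars = jk.compute_planar_angles(static, calib, poses=poses)
    angles: dict[str, float] = {}
    for js in joints:
        if js.joint not in jk.JOINTS_3D:
            continue
        for comp in jk.COMPONENTS:
            angles[f"{js.joint}_{comp}"] = float(np.nanmean(js.component(comp)))
    for ps in planars:
        angles[ps.name] = float(np.nanmean(ps.values))
    angles["Sha-Cal_eveinv"] = offset
    missing = set(jk.STATIC_ANGLE_KEYS) - set(angles)
    if missing:
        raise CalibrationError(f"static trial could not produce angles: {sorted(missing)}")
    calib.static_angles = angles
    return calib


def compute_hindfoot_frontal_offset_legacy(static: MarkerFrameSeries) -> float:
    """Frame-derived static frontal offset of the original protocol.

    Comparison hook only: the HL-based offset supersedes this measure and
    the legacy computation is intentionally not provided.
    """
    raise NotImplementedError(
        "the legacy frame-derived frontal offset is out of scope; "
        "use compute_hindfoot_frontal_offset (HL-based)")


# ---------------------------------------------------------------------------
# persistence (YAML or JSON by file suffix)

def save_calibration(calib: StaticCalibration, path) -> None:
    doc = asdict(calib)
    doc["cap_local"] = [float(v) for v in calib.cap_local]
    doc["static_angles"] = {k: float(v) for k, v in calib.static_angles.items()}
    text = (json.dumps(doc, indent=2) if str(path).endswith(".json")
            else yaml.safe_dump(doc, sort_keys=True))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def load_calibration(path) -> StaticCalibration:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    return StaticCalibration(
        side=doc["side"],
        hindfoot_frontal_offset=float(doc["hindfoot_frontal_offset"]),
        cap_local=np.asarray(doc["cap_local"], dtype=float),
        static_angles={k: float(v) for k, v in doc["static_angles"].items()},
    )
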