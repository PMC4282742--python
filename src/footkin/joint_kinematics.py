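"""Grood-Suntay 3D joint rotations and planar angles, including the MLA.

Joint coordinate system: for the relative rotation ``Rrel = Rp^T Rd`` the
body-fixed axis e1 is the proximal Z (dorsi-/plantar-flexion, dorsiflexion
positive), e3 is the distal X (eversion/inversion, inversion positive) and
e2 = e3 x e1 is the floating axis (abduction/adduction, adduction
positive). This is the knee convention adapted to segments whose long axis
is antero-posterior (X), and is equivalent to an intrinsic Z-Y'-X'' Euler
sequence on ``Rrel`` with the middle angle mapped to Abd/Add.

Planar angles: F2G/S2G/V2G are metatarsal pitches in the foot sagittal
plane (head-up positive); S2F/S2V are transverse-plane deviations of the
1st/5th ray from the 2nd (medial positive); F2Ps/F2Pt are the sagittal and
transverse Met-Hal components; MLA is the angle at ST between rays to CAp
and FMH projected into the foot sagittal plane, with values above 180 deg
when ST drops below the CAp-FMH line (flat arch).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import CalibrationError
from .marker_io import MarkerFrameSeries
from .segment_frames import (
    SegmentPose,
    build_calcaneus_frame,
    build_foot_frame,
    build_metatarsus_frame,
    build_midfoot_frame,
    build_phalanx_frame,
    build_shank_frame,
    technical_frame,
)

JOINTS = ("Sha-Foo", "Sha-Cal", "Cal-Mid", "Mid-Met", "Cal-Met", "Met-Hal")
#: the five joints plotted as 3D rotations (Met-Hal feeds F2Ps/F2Pt instead)
JOINTS_3D = JOINTS[:5]
COMPONENTS = ("dopl", "eveinv", "abdadd")
PLANAR_NAMES = ("F2G", "S2G", "S2F", "V2G", "S2V", "F2Ps", "F2Pt", "MLA")

_JOINT_SEGMENTS = {
    "Sha-Foo": ("Shank", "Foot"),
    "Sha-Cal": ("Shank", "Calcaneus"),
    "Cal-Mid": ("Calcaneus", "Midfoot"),
    "Mid-Met": ("Midfoot", "Metatarsus"),
    "Cal-Met": ("Calcaneus", "Metatarsus"),
    "Met-Hal": ("Metatarsus", "Phalanx"),
}

#: static-calibration angle keys: 5 joints x 3 components + 8 planar = 23
STATIC_ANGLE_KEYS = tuple(
    f"{j}_{c}" for j in JOINTS_3D for c in COMPONENTS
) + PLANAR_NAMES


@dataclass
class JointAngleSeries:
    """Per-frame Grood-Suntay components (deg) of one joint."""

    joint: str
    dopl: np.ndarray
    eveinv: np.ndarray
    abdadd: np.ndarray
    rate: float

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def __len__(self) -> int:
        return len(self.dopl)


@dataclass
class PlanarAngleSeries:
    """Per-frame planar angle (deg) for one named definition."""

    name: str
    values: np.ndarray
    rate: float

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# JCS kernel

def jcs_compose(dopl: float, eveinv: float, abdadd: float) -> np.ndarray:
    """Forward JCS constructor: rotation matrix with the given components (deg)."""
    return Rotation.from_euler("ZYX", [dopl, abdadd, eveinv], degrees=True).as_matrix()


def _decompose_matrix(rrel: np.ndarray) -> tuple[float, float, float]:
    with warnings.catch_warnings():
        # scipy emits its own gimbal-lock warning; ours below carries context
        warnings.simplefilter("ignore", UserWarning)
        dopl, abdadd, eveinv = Rotation.from_matrix(rrel).as_euler("ZYX", degrees=True)
    if abs(abs(abdadd) - 90.0) < 1e-6:
        warnings.warn("JCS decomposition at gimbal singularity (|Abd/Add| ~ 90 deg)",
                      RuntimeWarning, stacklevel=3)
    return float(dopl), float(eveinv), float(abdadd)


def jcs_decompose(r_proximal, r_distal) -> tuple[float, float, float]:
    """Decompose the rotation of the distal relative to the proximal frame.

    Accepts :class:`SegmentPose` or 3x3 axis matrices; returns
    ``(dopl, eveinv, abdadd)`` in degrees.
    """
    rp = r_proximal.axes if isinstance(r_proximal, SegmentPose) else np.asarray(r_proximal, float)
    rd = r_distal.axes if isinstance(r_distal, SegmentPose) else np.asarray(r_distal, float)
    return _decompose_matrix(rp.T @ rd)


# ---------------------------------------------------------------------------
# per-frame segment poses

_BUILDERS = {
    "Shank": (("HF", "TT", "LM", "MM"), build_shank_frame),
    "Calcaneus": (("CA", "PT", "ST"), build_calcaneus_frame),
    "Midfoot": (("TN", "C", "SMB"), build_midfoot_frame),
    "Metatarsus": (("FMH", "VMH", "SMB"), build_metatarsus_frame),
    "Foot": (("CA", "FMH", "VMH"), build_foot_frame),
    "Phalanx": (("PM", "FMH", "VMH"), build_phalanx_frame),
}


def segment_poses(series: MarkerFrameSeries,
                  segments: tuple = tuple(_BUILDERS)) -> dict[str, list]:
    """Build every segment's pose at every frame (None where degenerate/missing).

    Frame-to-frame continuity: each construction uses the previous valid
    pose as the plane-normal sign reference, falling back to lab-up at the
    first frame.
    """
    out: dict[str, list] = {}
    for seg in segments:
        markers, builder = _BUILDERS[seg]
        if any(m not in series for m in markers):
            out[seg] = [None] * series.n_frames
            continue
        trajs = [series[m] for m in markers]
        poses: list = []
        prev = None
        for f in range(series.n_frames):
            pts = [tr[f] for tr in trajs]
            if any(np.isnan(p).any() for p in pts):
                poses.append(None)
                continue
            try:
                pose = builder(*pts) if seg == "Shank" else builder(*pts, ref=prev)
            except Exception:
                poses.append(None)
                continue
            poses.append(pose)
            prev = pose
        out[seg] = poses
    return out


def compute_joint_series(walking: MarkerFrameSeries, calib=None,
                         poses: dict | None = None) -> list[JointAngleSeries]:
    """All six 3D joint rotation series from per-frame anatomical frames."""
    poses = poses if poses is not None else segment_poses(walking)
    n = walking.n_frames
    out = []
    for joint in JOINTS:
        prox, dist = _JOINT_SEGMENTS[joint]
        comp = np.full((n, 3), np.nan)
        for f in range(n):
            pp, pd = poses[prox][f], poses[dist][f]
            if pp is None or pd is None:
                continue
            comp[f] = jcs_decompose(pp, pd)
        out.append(JointAngleSeries(joint=joint, dopl=comp[:, 0], eveinv=comp[:, 1],
                                    abdadd=comp[:, 2], rate=walking.rate))
    return out


# ---------------------------------------------------------------------------
# CAp tracking (virtual heel-ground point carried by the calcaneus cluster)

def track_cap_local(series: MarkerFrameSeries, cap_local: np.ndarray) -> np.ndarray:
    """Map calcaneus-technical-frame CAp coordinates to the lab, per frame."""
    n = series.n_frames
    out = np.full((n, 3), np.nan)
    for m in ("CA", "PT", "ST"):
        if m not in series:
            raise CalibrationError(f"marker {m} required to track CAp")
    ca, pt, st = series["CA"], series["PT"], series["ST"]
    for f in range(n):
        if np.isnan(ca[f]).any() or np.isnan(pt[f]).any() or np.isnan(st[f]).any():
            continue
        tf = technical_frame(ca[f], 0.5 * (pt[f] + st[f]), st[f], segment="Cal-cluster")
        out[f] = tf.to_lab(cap_local)
    return out


# ---------------------------------------------------------------------------
# planar angles

def _sagittal_basis(foot_pose: SegmentPose) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the foot sagittal plane: (horizontal heading, up)."""
    x = foot_pose.x
    h = x - x[1] * np.array([0.0, 1.0, 0.0])
    nh = np.linalg.norm(h)
    if nh < 1e-9:
        raise ValueError("foot heading vertical; sagittal plane undefined")
    return h / nh, np.array([0.0, 1.0, 0.0])


def _pitch_angle(vec: np.ndarray, e_h: np.ndarray) -> float:
    """Signed elevation (deg) of a vector in the sagittal plane, head-up +."""
    return float(np.degrees(np.arctan2(vec[1], np.dot(vec, e_h))))


def _heading(vec: np.ndarray) -> float:
    """Azimuth (deg) in the ground plane, positive toward lab +Z (lateral)."""
    return float(np.degrees(np.arctan2(vec[2], vec[0])))


def _wrap(deg: float) -> float:
    return (deg + 180.0) % 360.0 - 180.0


def compute_mla(walking: MarkerFrameSeries, calib,
                poses: dict | None = None) -> PlanarAngleSeries:
    """Medial-longitudinal-arch angle at ST between rays to CAp and FMH.

    All three points are projected into the foot sagittal plane. The
    interior angle at ST is reported while ST lies dorsal to the CAp-FMH
    line; a dropped ST (flat arch) yields the reflex angle 360 - interior,
    so flatter arches give values >= 180 deg.
    """
    poses = poses if poses is not None else segment_poses(walking, ("Foot",))
    caps = track_cap_local(walking, np.asarray(calib.cap_local, dtype=float))
    st, fmh = walking["ST"], walking["FMH"]
    n = walking.n_frames
    vals = np.full(n, np.nan)
    for f in range(n):
        pose = poses["Foot"][f]
        if pose is None or np.isnan(caps[f]).any() or np.isnan(st[f]).any() or np.isnan(fmh[f]).any():
            continue
        e_h, e_v = _sagittal_basis(pose)
        p2 = lambda p: np.array([np.dot(p, e_h), np.dot(p, e_v)])
        c2, s2, f2 = p2(caps[f]), p2(st[f]), p2(fmh[f])
        u, v = c2 - s2, f2 - s2
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        interior = np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)))
        w = f2 - c2
        dorsal = w[0] * (s2[1] - c2[1]) - w[1] * (s2[0] - c2[0])
        vals[f] = interior if dorsal >= 0 else 360.0 - interior
    return PlanarAngleSeries(name="MLA", values=vals, rate=walking.rate)


def compute_planar_angles(walking: MarkerFrameSeries, calib=None,
                          poses: dict | None = None) -> list[PlanarAngleSeries]:
    """The eight planar angle series (MLA included when ``calib`` given)."""
    poses = poses if poses is not None else segment_poses(walking)
    n = walking.n_frames
    rate = walking.rate

    sag = np.full((n, 3), np.nan)  # F2G, S2G, V2G
    trans = np.full((n, 2), np.nan)  # S2F, S2V
    rays = {}
    for base, head in (("FMB", "FMH"), ("SMB", "SMH"), ("VMB", "VMH")):
        if base in walking and head in walking:
            rays[head[0]] = walking[head] - walking[base]
    for f in range(n):
        pose = poses["Foot"][f]
        if pose is None:
            continue
        try:
            e_h, _ = _sagittal_basis(pose)
        except ValueError:
            continue
        for i, key in enumerate("FSV"):
            if key in rays and not np.isnan(rays[key][f]).any():
                sag[f, i] = _pitch_angle(rays[key][f], e_h)
        if "S" in rays and not np.isnan(rays["S"][f]).any():
            b = _heading(rays["S"][f])
            for i, key in enumerate("FV"):
                if key in rays and not np.isnan(rays[key][f]).any():
                    # medial deviation from the 2nd ray is positive
                    trans[f, i] = -_wrap(_heading(rays[key][f]) - b)

    methal = None
    for js in compute_joint_series(walking, poses=poses):
        if js.joint == "Met-Hal":
            methal = js
    series = [
        PlanarAngleSeries("F2G", sag[:, 0], rate),
        PlanarAngleSeries("S2G", sag[:, 1], rate),
        PlanarAngleSeries("S2F", trans[:, 0], rate),
        PlanarAngleSeries("V2G", sag[:, 2], rate),
        PlanarAngleSeries("S2V", trans[:, 1], rate),
        PlanarAngleSeries("F2Ps", methal.dopl, rate),
        PlanarAngleSeries("F2Pt", methal.abdadd, rate),
    ]
    if calib is not None:
        series.append(compute_mla(walking, calib, poses=poses))
    return series


# ---------------------------------------------------------------------------
# tidy export

def angles_to_dataframe(joint_series: list[JointAngleSeries],
                        planar_series: list[PlanarAngleSeries],
                        trial: str = "trial"):
    """Long-format DataFrame: trial, name, component, frame, time_s, value_deg."""
    import pandas as pd

    rows = []
    for js in joint_series:
        t = np.arange(len(js)) / js.rate
        for comp in COMPONENTS:
            vals = js.component(comp)
            rows.append(pd.DataFrame({
                "trial": trial, "name": js.joint, "component": comp,
                "frame": np.arange(len(js)), "time_s": t, "value_deg": vals,
            }))
    for ps in planar_series:
        t = np.arange(len(ps)) / ps.rate
        rows.append(pd.DataFrame({
            "trial": trial, "name": ps.name, "component": "planar",
            "frame": np.arange(len(ps)), "time_s": t, "value_deg": ps.values,
        }))
    return pd.concat(rows, ignore_index=True)
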