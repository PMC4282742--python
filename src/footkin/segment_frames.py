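"""Right-handed orthonormal anatomical frames from marker triads.

Each segment frame has columns X (antero-posterior, forward), Y (vertical,
dorsal/up) and Z (medio-lateral, to the right for a right foot). Plane
normals are disambiguated "up-positive": flipped to a positive lab-Y
component at construction, which assumes a near-upright subject; during
walking, callers pass the previous pose as ``ref`` so the sign follows the
segment continuously instead of the lab vertical.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

LAB_UP = np.array([0.0, 1.0, 0.0])

#: triangle area below which a marker triad is rejected (mm^2)
AREA_TOL = 1e-6


@dataclass
class SegmentPose:
    """Origin (mm) and 3x3 axis matrix (columns X, Y, Z) of one segment."""

    segment: str
    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def is_orthonormal(self, tol: float = 1e-9) -> bool:
        err = np.abs(self.axes.T @ self.axes - np.eye(3)).max()
        return bool(err < tol and np.linalg.det(self.axes) > 0)

    def to_local(self, p: np.ndarray) -> np.ndarray:
        return self.axes.T @ (np.asarray(p, dtype=float) - self.origin)

    def to_lab(self, p_local: np.ndarray) -> np.ndarray:
        return self.origin + self.axes @ np.asarray(p_local, dtype=float)


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n < 1e-9:
        raise DegenerateGeometryError(f"{what} has near-zero length")
    return v / n


def _check_area(a: np.ndarray, b: np.ndarray, what: str) -> None:
    area = 0.5 * np.linalg.norm(np.cross(a, b))
    if not np.isfinite(area) or area < AREA_TOL:
        raise DegenerateGeometryError(f"{what}: triangle area {area:.3g} mm^2 below tolerance")


def _up_hint(ref: "SegmentPose | np.ndarray | None") -> np.ndarray:
    if ref is None:
        return LAB_UP
    if isinstance(ref, SegmentPose):
        return ref.y
    return np.asarray(ref, dtype=float)


def frame_from_three_points(p_origin, p_ahead, p_third, segment: str = "",
                            ref: "SegmentPose | np.ndarray | None" = None) -> SegmentPose:
    """Plane-based frame: X toward ``p_ahead``, Y normal to the triad plane.

    Y is the normal of the plane through the three points with its sign
    matched to ``ref`` (a previous pose or an up vector; lab up when None);
    Z completes the right-handed triad (Z = X x Y).
    """
    o = np.asarray(p_origin, dtype=float)
    a = np.asarray(p_ahead, dtype=float) - o
    t = np.asarray(p_third, dtype=float) - o
    _check_area(a, t, segment or "frame_from_three_points")
    x = _unit(a, "antero-posterior axis")
    n = _unit(np.cross(a, t), "plane normal")
    if np.dot(n, _up_hint(ref)) < 0:
        n = -n
    y = n
    z = np.cross(x, y)
    return SegmentPose(segment=segment, origin=o, axes=np.column_stack([x, y, z]))


def technical_frame(p1, p2, p3, segment: str = "technical") -> SegmentPose:
    """Marker-cluster frame with a fixed orientation rule (no up flip).

    Deterministic in the argument order alone, hence exactly rigid under
    arbitrary rigid motion of the cluster -- used to track virtual points.
    """
    o = np.asarray(p1, dtype=float)
    a = np.asarray(p2, dtype=float) - o
    t = np.asarray(p3, dtype=float) - o
    _check_area(a, t, segment)
    x = _unit(a, "axis 1")
    y = _unit(np.cross(a, t), "cluster normal")
    z = np.cross(x, y)
    return SegmentPose(segment=segment, origin=o, axes=np.column_stack([x, y, z]))


# ---------------------------------------------------------------------------
# anatomical constructions

def build_phalanx_frame(PM, FMH, VMH, ref=None) -> SegmentPose:
    """Proximal phalanx of the hallux: origin FMH, X along FMH->PM, Y
    normal to the PM/FMH/VMH plane (dorsal), Z = X x Y."""
    return frame_from_three_points(FMH, PM, VMH, segment="Phalanx", ref=ref)


def build_metatarsus_frame(FMH, VMH, SMB, ref=None) -> SegmentPose:
    """Metatarsus: origin SMB, X toward the FMH/VMH midpoint."""
    mid = 0.5 * (np.asarray(FMH, dtype=float) + np.asarray(VMH, dtype=float))
    return frame_from_three_points(SMB, mid, VMH, segment="Metatarsus", ref=ref)


def build_calcaneus_frame(CA, PT, ST, ref=None) -> SegmentPose:
    """Calcaneus: origin CA, X toward the PT/ST midpoint."""
    mid = 0.5 * (np.asarray(PT, dtype=float) + np.asarray(ST, dtype=float))
    return frame_from_three_points(CA, mid, ST, segment="Calcaneus", ref=ref)


def build_midfoot_frame(TN, C, SMB, ref=None) -> SegmentPose:
    """Midfoot: origin at the TN/C midpoint, X toward SMB."""
    mid = 0.5 * (np.asarray(TN, dtype=float) + np.asarray(C, dtype=float))
    return frame_from_three_points(mid, SMB, TN, segment="Midfoot", ref=ref)


def build_foot_frame(CA, FMH, VMH, ref=None) -> SegmentPose:
    """Whole foot: origin CA, X toward the FMH/VMH midpoint.

    The foot sagittal plane is spanned by this X axis and the lab vertical,
    through CA.
    """
    mid = 0.5 * (np.asarray(FMH, dtype=float) + np.asarray(VMH, dtype=float))
    return frame_from_three_points(CA, mid, VMH, segment="Foot", ref=ref)


def build_shank_frame(HF, TT, LM, MM, ref=None) -> SegmentPose:
    """Shank (tibia/fibula): origin at the malleoli midpoint, Y proximal
    toward the HF/TT midpoint, Z lateral from MM to LM re-orthogonalised
    against Y, X = Y x Z (forward)."""
    hf, tt = np.asarray(HF, dtype=float), np.asarray(TT, dtype=float)
    lm, mm = np.asarray(LM, dtype=float), np.asarray(MM, dtype=float)
    origin = 0.5 * (lm + mm)
    y = _unit(0.5 * (hf + tt) - origin, "shank long axis")
    z0 = lm - mm
    z = z0 - np.dot(z0, y) * y
    z = _unit(z, "shank medio-lateral axis")
    x = np.cross(y, z)
    return SegmentPose(segment="Shank", origin=origin, axes=np.column_stack([x, y, z]))
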