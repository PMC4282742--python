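"""Forward-kinematics generator of marker trajectories with known truth.

A template foot (17 markers on a shank-calcaneus-midfoot-metatarsus-hallux
chain) is posed by prescribed joint-angle curves and a choreographed global
gait motion, and emitted as lab-frame marker trajectories at 100 Hz with
optional isotropic Gaussian noise. The generator reports ground truth for
every inverse computation: per-frame joint angles, gait event frames and
the CAp trajectory.

Rigid-chain construction notes:

* the chain is rooted at the calcaneus, whose global motion (pitch +
  heel-path translation) encodes stance, heel rise, swing and the strike
  impact; relative joint rotations are therefore exactly the prescribed
  Grood-Suntay compositions, independent of the global motion;
* the Mid-Met (Lisfranc) joint centre sits exactly at the SMB marker,
  which both the midfoot and metatarsus frames use -- the pivot is shared
  by both bodies, keeping both measured frames exactly rigid;
* the hallux is a single marker (PM) on a sphere around FMH, placed so the
  measured Met-Hal DoPl and Abd/Add equal the prescribed values exactly;
  its axial (Eve/Inv) component is not prescribable by construction, and
  is reported as derived ground truth.

Within a cycle (phase u in [0, 1), u = 0 at foot strike) the stance phase
occupies 60%: foot flat until u = 0.4, heel rise to -26 deg pitch by toe
off at u = 0.6, swing with heel clearance and a linear-descent impact at
the next strike (a velocity kink, as in real gait).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import brentq

from .errors import ParameterError
from .joint_kinematics import jcs_compose, jcs_decompose
from .marker_io import MarkerFrameSeries, write_markers_tsv
from .segment_frames import (
    DegenerateGeometryError,
    build_calcaneus_frame,
    build_foot_frame,
    build_metatarsus_frame,
    build_midfoot_frame,
    build_phalanx_frame,
    build_shank_frame,
)

#: neutral marker coordinates (mm) of a reference right foot, lab axes
#: (X forward, Y up, Z lateral), heel ground point at the origin;
#: overall span ~230 mm heel to toe tip
_BASE_MARKERS = {
    "CA": (0.0, 45.0, 0.0),
    "PT": (38.0, 28.0, 22.0),
    # ST y is the arch-height parameter (set in make_template)
    "ST": (78.0, 18.0, -28.0),
    "TN": (95.0, 38.0, -20.0),
    "C": (92.0, 30.0, 18.0),
    "SMB": (120.0, 25.0, 0.0),
    "FMB": (112.0, 28.0, -28.0),
    "VMB": (105.0, 20.0, 32.0),
    "FMH": (168.0, 48.0, -32.0),
    "SMH": (172.0, 18.0, 2.0),
    "VMH": (158.0, 15.0, 38.0),
    "PM": (200.0, 40.0, -36.0),
    "LM": (18.0, 72.0, 36.0),
    "MM": (22.0, 78.0, -38.0),
    "TT": (48.0, 350.0, -8.0),
    "HF": (12.0, 360.0, 42.0),
}
_BASE_FOOT_LENGTH = 230.0

_SEGMENT_OF = {
    "HF": "Shank", "TT": "Shank", "LM": "Shank", "MM": "Shank",
    "CA": "Calcaneus", "PT": "Calcaneus", "ST": "Calcaneus", "HL": "Calcaneus",
    "TN": "Midfoot", "C": "Midfoot", "SMB": "Midfoot",
    "FMB": "Metatarsus", "VMB": "Metatarsus", "FMH": "Metatarsus",
    "SMH": "Metatarsus", "VMH": "Metatarsus",
}

_CHAIN_JOINTS = ("Sha-Cal", "Cal-Mid", "Mid-Met")

#: stance fraction of the gait cycle and heel-rise onset
_TOEOFF_PHASE = 0.6
_HEEL_RISE_PHASE = 0.4
_PUSHOFF_PITCH_DEG = -26.0
_STRIKE_PITCH_DEG = 6.0
_SWING_CLEARANCE_MM = 30.0
_STANCE_RIPPLE_MM = 8.0


@dataclass
class FootTemplate:
    """Rigid template geometry with closed-form static properties."""

    markers: dict  # label -> neutral lab position (3,), incl. HL
    joint_centers: dict  # joint -> neutral lab position (3,)
    segment_of: dict
    foot_length_mm: float
    arch_height_mm: float
    hindfoot_tilt_deg: float  # + = valgus (top of calcaneus tilted laterally)
    hl_placement_offset_mm: float
    scale: float

    def neutral_axes(self) -> dict:
        m = self.markers
        return {
            "Shank": build_shank_frame(m["HF"], m["TT"], m["LM"], m["MM"]).axes,
            "Calcaneus": build_calcaneus_frame(m["CA"], m["PT"], m["ST"]).axes,
            "Midfoot": build_midfoot_frame(m["TN"], m["C"], m["SMB"]).axes,
            "Metatarsus": build_metatarsus_frame(m["FMH"], m["VMH"], m["SMB"]).axes,
            "Foot": build_foot_frame(m["CA"], m["FMH"], m["VMH"]).axes,
            "Phalanx": build_phalanx_frame(m["PM"], m["FMH"], m["VMH"]).axes,
        }

    def static_mla(self) -> float:
        """Closed-form static MLA angle of the template geometry (deg)."""
        ca, st, fmh, vmh = (np.asarray(self.markers[k]) for k in ("CA", "ST", "FMH", "VMH"))
        cap = np.array([ca[0], 0.0, ca[2]])
        x = 0.5 * (fmh + vmh) - ca  # foot antero-posterior axis
        h = x - np.array([0.0, x[1], 0.0])
        e_h = h / np.linalg.norm(h)
        p2 = lambda p: np.array([np.dot(p, e_h), p[1]])
        c2, s2, f2 = p2(cap), p2(st), p2(fmh)
        u, v = c2 - s2, f2 - s2
        interior = math.degrees(math.acos(np.clip(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)))
        w = f2 - c2
        dorsal = w[0] * (s2[1] - c2[1]) - w[1] * (s2[0] - c2[0])
        return interior if dorsal >= 0 else 360.0 - interior


def make_template(foot_length_mm: float = 230.0, arch_height_mm: float = 18.0,
                  hindfoot_tilt_deg: float = 2.0, hl_drop_mm: float = 30.0,
                  hl_placement_offset_mm: float = 0.0) -> FootTemplate:
    """Build a template with prescribed hindfoot tilt and arch height.

    ``hindfoot_tilt_deg`` is realised exactly: HL is placed below CA such
    that CA-HL makes that angle with the shank vertical axis inside the
    shank frontal plane (positive toward lateral = valgus).
    ``hl_placement_offset_mm`` adds a medio-lateral placement error to HL,
    modelling the acknowledged uncertainty of the landmark.
    """
    if foot_length_mm <= 0:
        raise ParameterError("foot length must be positive")
    if arch_height_mm < 0:
        raise ParameterError("arch height must be >= 0")
    if hl_drop_mm <= 0:
        raise ParameterError("HL drop must be positive")
    s = foot_length_mm / _BASE_FOOT_LENGTH
    markers = {k: np.array(v, dtype=float) * s for k, v in _BASE_MARKERS.items()}
    markers["ST"][1] = arch_height_mm
    try:
        shank = build_shank_frame(markers["HF"], markers["TT"], markers["LM"], markers["MM"])
        t = math.radians(hindfoot_tilt_deg)
        u = math.cos(t) * shank.y + math.sin(t) * shank.z
        markers["HL"] = markers["CA"] - hl_drop_mm * u + hl_placement_offset_mm * shank.z
        jcs = {
            "Sha-Cal": np.array([20.0, 75.0, 0.0]) * s,
            "Cal-Mid": np.array([75.0, 32.0, 0.0]) * s,
            "Mid-Met": markers["SMB"].copy(),  # Lisfranc pivot AT the shared marker
            "Met-Hal": markers["FMH"].copy(),
        }
        tpl = FootTemplate(markers=markers, joint_centers=jcs, segment_of=dict(_SEGMENT_OF),
                           foot_length_mm=foot_length_mm, arch_height_mm=arch_height_mm,
                           hindfoot_tilt_deg=hindfoot_tilt_deg,
                           hl_placement_offset_mm=hl_placement_offset_mm, scale=s)
        tpl.neutral_axes()  # raises on degenerate triads
    except DegenerateGeometryError as exc:
        raise ParameterError(f"template geometry degenerate: {exc}") from exc
    return tpl


def arch_height_for_mla(target_mla_deg: float, lo: float = 1.0, hi: float = 60.0,
                        **template_kwargs) -> float:
    """Invert the (monotone decreasing) arch-height -> static-MLA map."""
    def f(a):
        return make_template(arch_height_mm=a, **template_kwargs).static_mla() - target_mla_deg

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ParameterError(
            f"target MLA {target_mla_deg:.1f} deg outside achievable range "
            f"[{f(hi) + target_mla_deg:.1f}, {f(lo) + target_mla_deg:.1f}]")
    return float(brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# prescribed joint curves

#: default per-joint deviation curves: component -> [(amp_deg, harmonic, phase_rad)]
DEFAULT_CURVES = {
    "Sha-Cal": {"dopl": [(6.0, 1, 0.0), (3.0, 2, 1.0)],
                "eveinv": [(3.0, 1, 0.5)], "abdadd": [(2.0, 1, 1.2)]},
    "Cal-Mid": {"dopl": [(4.0, 1, 0.3), (2.0, 2, 2.0)],
                "eveinv": [(2.0, 1, 1.0)], "abdadd": [(1.5, 1, 0.7)]},
    "Mid-Met": {"dopl": [(3.0, 1, 0.9)], "eveinv": [(1.5, 1, 0.2)],
                "abdadd": [(1.0, 2, 0.4)]},
    "Met-Hal": {"dopl": [(15.0, 1, 4.2), (8.0, 2, 1.0)], "abdadd": [(4.0, 1, 0.6)]},
}


def _curve_value(harmonics, phase: float) -> float:
    return sum(a * math.sin(2.0 * math.pi * n * phase + p) for a, n, p in harmonics)


@dataclass
class SimSpec:
    """Walking-trial simulation parameters."""

    cadence_hz: float = 1.0  # gait cycles per second
    n_cycles: int = 3
    rate_hz: float = 100.0
    stride_mm: float = 1100.0
    noise_mm: float = 0.0
    seed: int = 0
    curves: dict = field(default_factory=lambda: {
        j: {c: list(h) for c, h in comps.items()} for j, comps in DEFAULT_CURVES.items()})
    lead_in_phase: float = 0.3  # start mid-stance so the first strike is interior

    def validate(self) -> None:
        if self.cadence_hz <= 0 or self.rate_hz <= 0 or self.n_cycles < 1:
            raise ParameterError("cadence, rate and n_cycles must be positive")
        if self.noise_mm < 0:
            raise ParameterError("noise SD must be >= 0")
        for joint, comps in self.curves.items():
            for comp, harm in comps.items():
                if sum(abs(a) for a, _, _ in harm) >= 60.0:
                    raise ParameterError(f"{joint} {comp} curve exceeds the 60 deg bound")


@dataclass
class GroundTruth:
    """Per-frame truth emitted alongside a generated trial."""

    joint_angles: dict  # joint -> (n, 3) deg, columns (dopl, eveinv, abdadd)
    foot_strikes: list
    toe_offs: list
    cycles: list
    cap: np.ndarray  # (n, 3) mm
    phase: np.ndarray  # (n,) cycle phase, strikes at integers


# ---------------------------------------------------------------------------
# gait choreography (global calcaneus motion)

def _cos_ramp(v: float) -> float:
    return 0.5 * (1.0 - math.cos(math.pi * min(max(v, 0.0), 1.0)))


def _smoothstep(v: float) -> float:
    v = min(max(v, 0.0), 1.0)
    return v * v * (3.0 - 2.0 * v)


def _pitch_deg(u: float) -> float:
    if u < 0.10:
        return _STRIKE_PITCH_DEG * (1.0 - _cos_ramp(u / 0.10))
    if u < _HEEL_RISE_PHASE:
        return 0.0
    if u < _TOEOFF_PHASE:
        return _PUSHOFF_PITCH_DEG * _cos_ramp((u - _HEEL_RISE_PHASE) / 0.20)
    span = _STRIKE_PITCH_DEG - _PUSHOFF_PITCH_DEG
    return _PUSHOFF_PITCH_DEG + span * _cos_ramp((u - _TOEOFF_PHASE) / 0.40)


def _heel_path(u: float, lever_mm: float, stride_mm: float) -> tuple[float, float, float]:
    """(x, y, pitch_deg) of the heel ground point within one cycle.

    The heel stays put during stance (ripple aside), rises with the pitch
    so the toe stays grounded through push-off, clears the ground in swing
    and descends linearly into the next strike (impact kink).
    """
    psi = _pitch_deg(u)
    psi_neg = math.radians(min(psi, 0.0))
    y = -lever_mm * math.sin(psi_neg)
    x = lever_mm * (1.0 - math.cos(psi_neg))
    if u < _TOEOFF_PHASE:
        y += _STANCE_RIPPLE_MM * math.sin(math.pi * u / _TOEOFF_PHASE)
    else:
        w = (u - _TOEOFF_PHASE) / 0.40
        y += (_SWING_CLEARANCE_MM * math.sin(math.pi * w) ** 2 if w <= 0.5
              else 2.0 * _SWING_CLEARANCE_MM * (1.0 - w))
        x += stride_mm * _smoothstep(w)
    return x, y, psi


def _rz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# trial generation

def _static_chain_angles(tpl: FootTemplate) -> dict:
    r0 = tpl.neutral_axes()
    pairs = {"Sha-Cal": ("Shank", "Calcaneus"), "Cal-Mid": ("Calcaneus", "Midfoot"),
             "Mid-Met": ("Midfoot", "Metatarsus"), "Met-Hal": ("Metatarsus", "Phalanx")}
    return {j: np.array(jcs_decompose(r0[p], r0[d])) for j, (p, d) in pairs.items()}


def generate_static_trial(tpl: FootTemplate, side: str = "right", n_frames: int = 200,
                          rate_hz: float = 100.0, noise_mm: float = 0.0,
                          seed: int = 0) -> MarkerFrameSeries:
    """Up-right double-leg static trial (all 17 markers, HL included)."""
    labels = list(tpl.markers)
    data = np.tile(np.stack([tpl.markers[m] for m in labels]), (n_frames, 1, 1)).astype(float)
    if noise_mm > 0:
        data += np.random.default_rng(seed).normal(0.0, noise_mm, data.shape)
    return MarkerFrameSeries(labels=labels, data=data, rate=rate_hz, side=side,
                             trial_kind="static", mirrored=(side == "left"))


def generate_trial(tpl: FootTemplate, spec: SimSpec,
                   side: str = "right") -> tuple[MarkerFrameSeries, GroundTruth]:
    """Walking trial with ``spec.n_cycles`` complete gait cycles.

    The trial starts mid-stance and covers ``n_cycles + 1`` foot strikes;
    ground-truth event frames, per-frame joint angles and CAp positions
    are returned alongside the marker series.
    """
    spec.validate()
    r0 = tpl.neutral_axes()
    static = _static_chain_angles(tpl)
    jc = tpl.joint_centers
    lever = tpl.markers["SMH"][0] - tpl.markers["CA"][0]
    m0 = tpl.markers
    pm_rel0 = m0["PM"] - m0["FMH"]
    l_ph = np.linalg.norm(pm_rel0)

    phi0 = spec.lead_in_phase
    phi_end = spec.n_cycles + 1.0 + phi0 + 0.1
    n = int(round((phi_end - phi0) / spec.cadence_hz * spec.rate_hz)) + 1
    t = np.arange(n) / spec.rate_hz
    phase = phi0 + spec.cadence_hz * t

    labels = [m for m in m0 if m != "HL"]  # HL is a static-only marker
    data = np.empty((n, len(labels), 3))
    truth_chain = {j: np.empty((n, 3)) for j in _CHAIN_JOINTS}
    methal_presc = np.full((n, 3), np.nan)
    cap = np.empty((n, 3))
    prev_foot = prev_phal = None
    derived = {j: np.empty((n, 3)) for j in ("Sha-Foo", "Cal-Met", "Met-Hal")}

    for f in range(n):
        phi = phase[f]
        m_idx = math.floor(phi)
        u = phi - m_idx
        xh, yh, psi = _heel_path(u, lever, spec.stride_mm)
        a_cal = _rz(psi)
        b_cal = np.array([m_idx * spec.stride_mm + xh, yh, 0.0])

        def theta(joint):
            comps = spec.curves.get(joint, {})
            return static[joint] + np.array([
                _curve_value(comps.get("dopl", []), phi),
                _curve_value(comps.get("eveinv", []), phi),
                _curve_value(comps.get("abdadd", []), phi)])

        th_sc, th_cm, th_mm = theta("Sha-Cal"), theta("Cal-Mid"), theta("Mid-Met")
        c_sc, c_cm, c_mm = (jcs_compose(*th) for th in (th_sc, th_cm, th_mm))
        a_sh = a_cal @ r0["Calcaneus"] @ c_sc.T @ r0["Shank"].T
        b_sh = a_cal @ jc["Sha-Cal"] + b_cal - a_sh @ jc["Sha-Cal"]
        a_mid = a_cal @ r0["Calcaneus"] @ c_cm @ r0["Midfoot"].T
        b_mid = a_cal @ jc["Cal-Mid"] + b_cal - a_mid @ jc["Cal-Mid"]
        a_met = a_mid @ r0["Midfoot"] @ c_mm @ r0["Metatarsus"].T
        b_met = a_mid @ jc["Mid-Met"] + b_mid - a_met @ jc["Mid-Met"]
        xform = {"Shank": (a_sh, b_sh), "Calcaneus": (a_cal, b_cal),
                 "Midfoot": (a_mid, b_mid), "Metatarsus": (a_met, b_met)}

        pos = {}
        for lab in labels:
            if lab == "PM":
                continue
            a, b = xform[tpl.segment_of[lab]]
            pos[lab] = a @ m0[lab] + b
        # hallux: Met-Hal DoPl/AbdAdd prescribed exactly via the PM direction
        comps = spec.curves.get("Met-Hal", {})
        a_ang = math.radians(static["Met-Hal"][0] + _curve_value(comps.get("dopl", []), phi))
        b_ang = math.radians(static["Met-Hal"][2] + _curve_value(comps.get("abdadd", []), phi))
        dir_local = np.array([math.cos(a_ang) * math.cos(b_ang),
                              math.sin(a_ang) * math.cos(b_ang),
                              -math.sin(b_ang)])
        pos["PM"] = pos["FMH"] + l_ph * (a_met @ r0["Metatarsus"]) @ dir_local

        for i, lab in enumerate(labels):
            data[f, i] = pos[lab]
        for j, th in zip(_CHAIN_JOINTS, (th_sc, th_cm, th_mm)):
            truth_chain[j][f] = th
        methal_presc[f, 0] = math.degrees(a_ang)
        methal_presc[f, 2] = math.degrees(b_ang)
        cap[f] = b_cal  # the heel ground point is calcaneus-fixed at the origin

        # derived truth: mixed-segment foot frame + hallux axial component
        foot_pose = build_foot_frame(pos["CA"], pos["FMH"], pos["VMH"], ref=prev_foot)
        prev_foot = foot_pose
        derived["Sha-Foo"][f] = jcs_decompose(a_sh @ r0["Shank"], foot_pose.axes)
        derived["Cal-Met"][f] = jcs_decompose(a_cal @ r0["Calcaneus"], a_met @ r0["Metatarsus"])
        phal_pose = build_phalanx_frame(pos["PM"], pos["FMH"], pos["VMH"], ref=prev_phal)
        prev_phal = phal_pose
        derived["Met-Hal"][f] = jcs_decompose(a_met @ r0["Metatarsus"], phal_pose.axes)

    if spec.noise_mm > 0:
        data = data + np.random.default_rng(spec.seed).normal(0.0, spec.noise_mm, data.shape)

    strikes = [int(round((k - phi0) / spec.cadence_hz * spec.rate_hz))
               for k in range(1, spec.n_cycles + 2)]
    toeoffs = [int(round((k + _TOEOFF_PHASE - phi0) / spec.cadence_hz * spec.rate_hz))
               for k in range(0, spec.n_cycles + 1)]
    toeoffs = [f for f in toeoffs if 0 <= f < n]
    strikes = [f for f in strikes if 0 <= f < n]
    cycles = []
    for s0, s1 in zip(strikes, strikes[1:]):
        inside = [f for f in toeoffs if s0 < f < s1]
        if len(inside) == 1:
            cycles.append((s0, inside[0], s1))

    joint_angles = {
        "Sha-Foo": derived["Sha-Foo"],
        "Sha-Cal": truth_chain["Sha-Cal"],
        "Cal-Mid": truth_chain["Cal-Mid"],
        "Mid-Met": truth_chain["Mid-Met"],
        "Cal-Met": derived["Cal-Met"],
        "Met-Hal": derived["Met-Hal"],
    }
    series = MarkerFrameSeries(labels=labels, data=data, rate=spec.rate_hz, side=side,
                               trial_kind="walking", mirrored=(side == "left"))
    truth = GroundTruth(joint_angles=joint_angles, foot_strikes=strikes,
                        toe_offs=toeoffs, cycles=cycles, cap=cap, phase=phase)
    return series, truth


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortSpec:
    """Synthetic cohort: participants, alignment composition, arch statistics.

    ``composition`` fixes the number of neutral / varus / valgus feet across
    the 2 x n_participants feet. Static MLA targets follow a normal law
    truncated to ``mla_range``, sampled by permuted quantile midpoints
    ('stratified', the default) so any seed yields a cohort representative
    of the prescribed distribution, or i.i.d. ('normal').
    """

    n_participants: int = 10
    #: neutral/varus/valgus feet; None allocates 2*n_participants in the
    #: 7:5:8 proportion by largest remainder
    composition: tuple | None = (7, 5, 8)
    mla_mean_deg: float = 183.0
    mla_sd_deg: float = 16.0
    mla_range_deg: tuple = (153.0, 206.0)
    mla_sampling: str = "stratified"
    offset_neutral_range: tuple = (-1.8, 1.8)
    offset_varus_range: tuple = (-6.5, -2.5)  # inversion > 2 deg
    offset_valgus_range: tuple = (2.5, 6.5)  # eversion > 2 deg
    n_walking: int = 3
    n_cycles: int = 3
    static_frames: int = 100
    noise_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.composition is None:
            n_feet = 2 * self.n_participants
            props = np.array([7.0, 5.0, 8.0]) / 20.0
            base = np.floor(props * n_feet).astype(int)
            rem = props * n_feet - base
            for i in np.argsort(-rem)[: n_feet - base.sum()]:
                base[i] += 1
            self.composition = tuple(int(c) for c in base)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if sum(self.composition) != 2 * self.n_participants:
            raise ParameterError("composition must sum to 2 * n_participants feet")
        if self.mla_sd_deg < 0 or self.noise_mm < 0:
            raise ParameterError("spread parameters must be >= 0")
        if self.mla_sampling not in ("stratified", "normal"):
            raise ParameterError("mla_sampling must be 'stratified' or 'normal'")


def _truncnorm_quantile_midpoints(mean, sd, lo, hi, n) -> np.ndarray:
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    q = (np.arange(n) + 0.5) / n
    return truncnorm.ppf(q, a, b, loc=mean, scale=sd)


def generate_cohort(spec: CohortSpec, out_dir=None) -> dict:
    """Per participant and side: one static + ``n_walking`` walking trials.

    Returns a manifest with per-foot ground truth (offset, category, static
    MLA, arch height, file paths when ``out_dir`` is given); with a fixed
    seed the dataset tree is reproducible byte for byte.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_feet = 2 * spec.n_participants
    categories = (["neutral"] * spec.composition[0] + ["varus"] * spec.composition[1]
                  + ["valgus"] * spec.composition[2])
    rng.shuffle(categories)

    lo, hi = spec.mla_range_deg
    if spec.mla_sampling == "stratified":
        mla_targets = _truncnorm_quantile_midpoints(spec.mla_mean_deg, spec.mla_sd_deg,
                                                    lo, hi, n_feet)
        rng.shuffle(mla_targets)
    else:
        mla_targets = np.clip(rng.normal(spec.mla_mean_deg, spec.mla_sd_deg, n_feet), lo, hi)

    ranges = {"neutral": spec.offset_neutral_range, "varus": spec.offset_varus_range,
              "valgus": spec.offset_valgus_range}
    manifest = {"seed": spec.seed, "n_participants": spec.n_participants, "feet": []}
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)

    foot_idx = 0
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        cadence = float(rng.uniform(0.9, 1.1))
        for side in ("left", "right"):
            cat = categories[foot_idx]
            offset = float(rng.uniform(*ranges[cat]))
            target_mla = float(mla_targets[foot_idx])
            arch = arch_height_for_mla(target_mla, hindfoot_tilt_deg=offset)
            tpl = make_template(arch_height_mm=arch, hindfoot_tilt_deg=offset)
            foot_seed = int(rng.integers(0, 2**31 - 1))
            static = generate_static_trial(tpl, side=side, n_frames=spec.static_frames,
                                           noise_mm=spec.noise_mm, seed=foot_seed)
            entry = {
                "participant": pid, "side": side, "category": cat,
                "hindfoot_frontal_offset_deg": offset, "static_mla_deg": tpl.static_mla(),
                "arch_height_mm": arch, "cadence_hz": cadence, "seed": foot_seed,
                "walking": [],
            }
            walking = []
            for w in range(spec.n_walking):
                wspec = SimSpec(cadence_hz=cadence, n_cycles=spec.n_cycles,
                                noise_mm=spec.noise_mm, seed=foot_seed + w + 1)
                series, truth = generate_trial(tpl, wspec, side=side)
                walking.append((series, truth))
            if out_dir is not None:
                import os

                sdir = os.path.join(out_dir, pid)
                os.makedirs(sdir, exist_ok=True)
                spath = os.path.join(sdir, f"{pid}_{side}_static.tsv")
                write_markers_tsv(static, spath)
                entry["static_file"] = spath
                for w, (series, truth) in enumerate(walking):
                    wpath = os.path.join(sdir, f"{pid}_{side}_walk{w + 1}.tsv")
                    write_markers_tsv(series, wpath)
                    entry["walking"].append({
                        "file": wpath,
                        "foot_strikes": truth.foot_strikes,
                        "toe_offs": truth.toe_offs,
                    })
            else:
                entry["static_series"] = static
                entry["walking_trials"] = walking
            manifest["feet"].append(entry)
            foot_idx += 1

    if out_dir is not None:
        import os

        clean = {"seed": manifest["seed"], "n_participants": manifest["n_participants"],
                 "feet": [{k: v for k, v in e.items() if not k.endswith("_series")
                           and k != "walking_trials"} for e in manifest["feet"]]}
        with open(os.path.join(out_dir, "manifest.yaml"), "w", encoding="utf-8") as fh:
            yaml.safe_dump(clean, fh, sort_keys=False)
    return manifest
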