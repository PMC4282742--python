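"""Gait event detection, cycle segmentation, time normalization and
ensemble statistics.

Events are detected from marker coordinates alone (no force platform):

* foot strike -- the calcaneus (CA) forward velocity drops out of the
  positive band (swing -> stance) coincident, within a few frames, with a
  local minimum of CA height;
* toe off -- the forefoot (SMH) forward velocity leaves the stationary
  band upward (stance -> swing) coincident with a local minimum of SMH
  height.

Velocity signs use a dead band so that quasi-stationary stance reads as
zero; the reported event frame is the velocity-transition frame, which is
much sharper than the vertical argmin near foot-flat, and the vertical
minimum acts as the coincidence gate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import SchemaError
from .marker_io import MarkerFrameSeries

logger = logging.getLogger(__name__)


@dataclass
class EventDetectionConfig:
    """Tunable thresholds of the coordinate-based event detector."""

    strike_marker: str = "CA"
    toeoff_marker: str = "SMH"
    deadband_mm_s: float = 80.0  # floor of the 'stationary' |v| band
    adaptive_fraction: float = 0.075  # dead band as a fraction of the p95 forward speed
    coincidence_frames: int = 3  # max gap between velocity transition and height minimum
    min_prominence_mm: float = 2.0  # vertical local-minimum prominence
    min_separation_s: float = 0.5  # between successive events of one type


@dataclass
class GaitCycleEvents:
    foot_strikes: list = field(default_factory=list)
    toe_offs: list = field(default_factory=list)
    cycles: list = field(default_factory=list)  # (strike_i, toe_off, strike_{i+1})


def _vel_sign(v: np.ndarray, deadband: float) -> np.ndarray:
    s = np.zeros_like(v, dtype=int)
    s[v > deadband] = 1
    s[v < -deadband] = -1
    return s


def _transitions(sign: np.ndarray, kind: str) -> list[int]:
    """Frames where the velocity sign pattern matches an event.

    ``kind='strike'``: +1 -> <=0 (forward motion stops);
    ``kind='toeoff'``: <=0 -> +1 (forward motion starts).
    """
    out = []
    for f in range(1, len(sign)):
        a, b = sign[f - 1], sign[f]
        if kind == "strike" and a == 1 and b <= 0:
            out.append(f)
        elif kind == "toeoff" and a <= 0 and b == 1:
            out.append(f)
    return out


def _refine_event(v: np.ndarray, f: int, kind: str, deadband: float) -> int:
    """Sub-frame event refinement: extrapolate the swing velocity ramp to zero.

    The forward velocity leaves/enters stance along an approximately linear
    ramp; points well clear of the (possibly low-pass-smeared) corner are
    fitted and the zero crossing is the event. Falls back to the raw
    transition frame when no clean ramp is found.
    """
    lo, hi = 2.0 * deadband, 8.0 * deadband
    if kind == "strike":
        idx = np.arange(max(0, f - 12), f + 1)
    else:
        idx = np.arange(f, min(len(v), f + 13))
    sel = idx[(np.abs(v[idx]) >= lo) & (np.abs(v[idx]) <= hi)]
    if len(sel) < 2:
        return f
    slope, intercept = np.polyfit(sel, v[sel], 1)
    if abs(slope) < 1e-9:
        return f
    root = -intercept / slope
    if not (f - 12 <= root <= f + 12):
        return f
    return int(round(root))


def _detect(series: MarkerFrameSeries, marker: str, kind: str,
            cfg: EventDetectionConfig) -> list[int]:
    if marker not in series:
        return []
    traj = series[marker]
    if np.isnan(traj).any():
        # event detection needs gap-filled data; run on the valid span only
        valid = ~np.isnan(traj).any(axis=1)
        if not valid.any():
            return []
        a, b = np.flatnonzero(valid)[[0, -1]]
        if not valid[a : b + 1].all():
            logger.warning("interior gaps in %s; events may be missed", marker)
    y = np.nan_to_num(traj[:, 1], nan=np.inf)
    x = traj[:, 0]
    v = np.gradient(np.nan_to_num(x)) * series.rate
    # the dead band scales with the trial's swing speed so low-pass smearing
    # of the stance/swing transition does not bias the crossing frame
    deadband = max(cfg.deadband_mm_s,
                   cfg.adaptive_fraction * float(np.percentile(np.abs(v), 95)))
    sign = _vel_sign(v, deadband)
    cands = _transitions(sign, kind)
    # light smoothing so marker noise does not spawn spurious height minima
    if len(y) >= 5:
        kernel = np.ones(5) / 5.0
        y = np.convolve(np.nan_to_num(y, posinf=1e6), kernel, mode="same")
    minima, _ = find_peaks(-y, prominence=cfg.min_prominence_mm)
    scored: list[tuple[int, int]] = []  # (refined frame, coincidence gap)
    for f in cands:
        if len(minima) == 0:
            break
        gap = int(np.min(np.abs(minima - f)))
        if gap > cfg.coincidence_frames:
            continue
        scored.append((_refine_event(v, f, kind, deadband), gap))
    # merge candidates closer than the minimum separation, keeping the one
    # with the tightest velocity/height coincidence
    min_sep = int(round(cfg.min_separation_s * series.rate))
    events: list[tuple[int, int]] = []
    for f_ref, gap in sorted(scored):
        if events and f_ref - events[-1][0] < min_sep:
            if gap < events[-1][1]:
                events[-1] = (f_ref, gap)
            continue
        events.append((f_ref, gap))
    return [f for f, _ in events]


def detect_gait_events(walking: MarkerFrameSeries,
                       cfg: EventDetectionConfig | None = None) -> GaitCycleEvents:
    """Detect foot strikes and toe offs and pair them into gait cycles."""
    cfg = cfg or EventDetectionConfig()
    strikes = _detect(walking, cfg.strike_marker, "strike", cfg)
    toeoffs = _detect(walking, cfg.toeoff_marker, "toeoff", cfg)
    cycles = []
    for s0, s1 in zip(strikes, strikes[1:]):
        inside = [t for t in toeoffs if s0 < t < s1]
        if len(inside) == 1:
            cycles.append((s0, inside[0], s1))
    if not cycles:
        logger.warning("no complete gait cycle detected (%d strikes, %d toe-offs)",
                       len(strikes), len(toeoffs))
    return GaitCycleEvents(foot_strikes=strikes, toe_offs=toeoffs, cycles=cycles)


# ---------------------------------------------------------------------------
# time normalization and ensembles

@dataclass
class EnsembleCurve:
    """Pointwise mean and sample SD over 0-100% of the gait cycle."""

    name: str
    mean: np.ndarray  # (n_points,)
    sd: np.ndarray  # (n_points,)
    n_curves: int


def normalize_to_cycle(values: np.ndarray, cycle: tuple, n_points: int = 101,
                       max_missing_fraction: float = 0.2) -> np.ndarray | None:
    """Resample one cycle span onto 0-100% (linear time base).

    Endpoints are preserved exactly; returns None (with a warning) when
    more than ``max_missing_fraction`` of the samples in the span are
    missing.
    """
    start, end = cycle[0], cycle[-1]
    values = np.asarray(values, dtype=float)
    if not (0 <= start < end < len(values)):
        raise SchemaError(f"cycle ({start}, {end}) outside series of length {len(values)}")
    span = values[start : end + 1]
    valid = np.isfinite(span)
    if valid.sum() < 2:
        return None
    if np.mean(~valid) > max_missing_fraction:
        logger.warning("cycle [%d, %d] rejected: %.0f%% samples missing",
                       start, end, 100 * np.mean(~valid))
        return None
    t = np.linspace(0.0, float(len(span) - 1), n_points)
    src = np.flatnonzero(valid).astype(float)
    return np.interp(t, src, span[valid])


def ensemble_stats(curves: list[np.ndarray], name: str = "") -> EnsembleCurve:
    """Pointwise mean and sample SD (n-1 denominator; SD = 0 when n = 1)."""
    if not curves:
        raise SchemaError("ensemble requires at least one curve")
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise SchemaError(f"mismatched curve lengths: {sorted(lengths)}")
    arr = np.asarray(curves, dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return EnsembleCurve(name=name, mean=mean, sd=sd, n_curves=arr.shape[0])


def cycle_curves(values: np.ndarray, events: GaitCycleEvents,
                 n_points: int = 101) -> list[np.ndarray]:
    """Normalized curves of one signal over every detected cycle."""
    out = []
    for cyc in events.cycles:
        c = normalize_to_cycle(values, (cyc[0], cyc[2]), n_points)
        if c is not None:
            out.append(c)
    return out
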