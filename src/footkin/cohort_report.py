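"""Hindfoot alignment classification, cohort summaries and report rendering.

Classification rule (static, HL-based frontal offset, + = eversion/valgus):
neutral when the offset lies between -2 and 2 deg inclusive, valgus when
eversion exceeds 2 deg, varus when inversion exceeds 2 deg.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import gait_cycle as gc
from . import joint_kinematics as jk
from .calibration import StaticCalibration, compute_static_reference
from .errors import DataError
from .marker_io import MarkerFrameSeries, preprocess

CATEGORIES = ("neutral", "varus", "valgus")

#: inclusive neutral band of the hindfoot frontal offset (deg)
NEUTRAL_BAND_DEG = 2.0


def classify_hindfoot(offset_deg: float, band_deg: float = NEUTRAL_BAND_DEG) -> str:
    """Partition the frontal offset into neutral / varus / valgus.

    Boundary values (+/- band) are assigned to neutral.
    """
    if not np.isfinite(offset_deg):
        raise DataError(f"non-finite hindfoot offset: {offset_deg}")
    if abs(offset_deg) <= band_deg:
        return "neutral"
    return "valgus" if offset_deg > band_deg else "varus"


@dataclass
class FootResult:
    """Per-foot analysis products."""

    participant: str
    side: str
    hindfoot_frontal_offset: float  # deg
    static_mla: float  # deg, double-leg stance
    category: str
    ensembles: dict = field(default_factory=dict)  # name -> EnsembleCurve
    static_angles: dict = field(default_factory=dict)


@dataclass
class CohortSummary:
    n_feet: int
    counts: dict
    n_neutral_or_valgus: int
    mla_mean: float
    mla_sd: float
    mla_min: float
    mla_max: float


def summarize_cohort(results: list[FootResult]) -> CohortSummary:
    """Category counts and static-MLA statistics (sample SD, n-1)."""
    if not results:
        raise DataError("cannot summarize an empty cohort")
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.category] += 1
    mla = np.array([r.static_mla for r in results], dtype=float)
    sd = float(mla.std(ddof=1)) if len(mla) > 1 else 0.0
    return CohortSummary(
        n_feet=len(results), counts=counts,
        n_neutral_or_valgus=counts["neutral"] + counts["valgus"],
        mla_mean=float(mla.mean()), mla_sd=sd,
        mla_min=float(mla.min()), mla_max=float(mla.max()),
    )


# ---------------------------------------------------------------------------
# per-foot pipeline

def analyze_foot(static: MarkerFrameSeries, walking: list[MarkerFrameSeries],
                 participant: str = "P01", calib: StaticCalibration | None = None,
                 cutoff_hz: float | None = 6.0, max_gap_frames: int = 10,
                 n_points: int = 101,
                 event_cfg: gc.EventDetectionConfig | None = None) -> FootResult:
    """Calibrate from the static trial and build ensemble curves over all
    gait cycles of all walking trials of one foot."""
    static_p = preprocess(static, max_gap_frames, cutoff_hz)
    calib = calib or compute_static_reference(static_p)
    curves: dict[str, list] = {}
    for trial in walking:
        # events come from the unfiltered (gap-filled) trajectories: the
        # strike/toe-off velocity transients are exactly what low-pass
        # smoothing blurs; angles use the filtered series below
        trial_g = preprocess(trial, max_gap_frames, cutoff_hz=None)
        events = gc.detect_gait_events(trial_g, event_cfg)
        trial_p = preprocess(trial_g, 0, cutoff_hz)
        if not events.cycles:
            continue
        poses = jk.segment_poses(trial_p)
        joints = jk.compute_joint_series(trial_p, poses=poses)
        planars = jk.compute_planar_angles(trial_p, calib, poses=poses)
        for js in joints:
            if js.joint not in jk.JOINTS_3D:
                continue
            for comp in jk.COMPONENTS:
                key = f"{js.joint}_{comp}"
                curves.setdefault(key, []).extend(
                    gc.cycle_curves(js.component(comp), events, n_points))
        for ps in planars:
            curves.setdefault(ps.name, []).extend(
                gc.cycle_curves(ps.values, events, n_points))
    ensembles = {name: gc.ensemble_stats(cs, name) for name, cs in curves.items() if cs}
    return FootResult(
        participant=participant, side=static.side,
        hindfoot_frontal_offset=calib.hindfoot_frontal_offset,
        static_mla=calib.static_angles["MLA"],
        category=classify_hindfoot(calib.hindfoot_frontal_offset),
        ensembles=ensembles, static_angles=dict(calib.static_angles),
    )


# ---------------------------------------------------------------------------
# rendering

def render_report(summary: CohortSummary, results: list[FootResult], out_dir) -> list:
    """Write per-foot CSVs, ensemble CSVs, a cohort summary table and the
    15-panel angle figure (mean +/- SD band with the static value overlaid
    as a dashed segment). Returns the list of files written."""
    import pandas as pd

    if not results:
        raise DataError("cannot render a report for an empty cohort")
    os.makedirs(out_dir, exist_ok=True)
    written = []

    rows = [{
        "participant": r.participant, "side": r.side,
        "hindfoot_frontal_offset_deg": r.hindfoot_frontal_offset,
        "static_mla_deg": r.static_mla, "category": r.category,
    } for r in results]
    feet_csv = os.path.join(out_dir, "feet.csv")
    pd.DataFrame(rows).to_csv(feet_csv, index=False)
    written.append(feet_csv)

    srow = {
        "n_feet": summary.n_feet, **{f"n_{c}": summary.counts[c] for c in CATEGORIES},
        "n_neutral_or_valgus": summary.n_neutral_or_valgus,
        "mla_mean_deg": summary.mla_mean, "mla_sd_deg": summary.mla_sd,
        "mla_min_deg": summary.mla_min, "mla_max_deg": summary.mla_max,
    }
    summary_csv = os.path.join(out_dir, "cohort_summary.csv")
    pd.DataFrame([srow]).to_csv(summary_csv, index=False)
    written.append(summary_csv)

    ens_rows = []
    for r in results:
        for name, ec in r.ensembles.items():
            for pct in range(len(ec.mean)):
                ens_rows.append({
                    "participant": r.participant, "side": r.side, "name": name,
                    "percent": pct, "mean_deg": ec.mean[pct], "sd_deg": ec.sd[pct],
                    "n": ec.n_curves,
                })
    if ens_rows:
        ens_csv = os.path.join(out_dir, "ensembles.csv")
        pd.DataFrame(ens_rows).to_csv(ens_csv, index=False)
        written.append(ens_csv)

    written.extend(_render_figures(results, out_dir))
    return written


def _pooled_ensembles(results: list[FootResult]) -> dict:
    pooled: dict[str, list] = {}
    for r in results:
        for name, ec in r.ensembles.items():
            pooled.setdefault(name, []).append(ec)
    return pooled


def _render_figures(results: list[FootResult], out_dir) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    pooled = _pooled_ensembles(results)
    if not pooled:
        return written
    statics = {}
    for r in results:
        for k, v in r.static_angles.items():
            statics.setdefault(k, []).append(v)

    panels_3d = [(j, c) for j in jk.JOINTS_3D for c in jk.COMPONENTS]
    for fname, panels, ncol in (
        ("joints_3d.png", [f"{j}_{c}" for j, c in panels_3d], 3),
        ("planar_angles.png", list(jk.PLANAR_NAMES), 2),
    ):
        keys = [k for k in panels if k in pooled]
        if not keys:
            continue
        nrow = (len(panels) + ncol - 1) // ncol
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.2 * nrow),
                                 squeeze=False, sharex=True)
        for i, key in enumerate(panels):
            ax = axes[i // ncol][i % ncol]
            ax.set_title(key, fontsize=8)
            if key not in pooled:
                ax.axis("off")
                continue
            ecs = pooled[key]
            mean = np.mean([e.mean for e in ecs], axis=0)
            sd = np.mean([e.sd for e in ecs], axis=0)
            pct = np.arange(len(mean))
            ax.fill_between(pct, mean - sd, mean + sd, color="0.8")
            ax.plot(pct, mean, "k-", lw=1)
            if key in statics:
                ax.axhline(float(np.mean(statics[key])), ls="-.", lw=0.8, color="0.3")
            ax.tick_params(labelsize=7)
        fig.suptitle("deg vs % gait cycle", fontsize=9)
        fig.tight_layout()
        path = os.path.join(out_dir, fname)
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
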