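# footkin

Multi-segment foot kinematics from stereophotogrammetric skin markers.

`footkin` implements a four-segment foot model — shank (Sha), calcaneus
(Cal), midfoot (Mid), metatarsus (Met) — plus a three-marker description of
the hallux proximal phalanx, for the clinical assessment of foot function
and in particular of the flexible flat foot (pes planus). It is aimed at
gait-laboratory users who capture marker trajectories (C3D or plain TSV) of
a static double-leg standing trial and barefoot walking trials, typically
at 100 Hz, and want:

* **Static calibration** — including a hindfoot frontal-plane offset
  measured from an extra marker (HL) at the base of the calcaneus: the
  angle between the CA–HL segment projected into the shank frontal plane
  and the shank vertical axis. This replaces the marker-frame-derived
  static frontal angle, which is biased toward inversion because the
  sustentaculum tali marker usually sits higher than the peroneal tubercle
  marker.
* **3D joint rotations** by the Grood–Suntay joint coordinate system for
  Sha-Foo, Sha-Cal, Cal-Mid, Mid-Met and Cal-Met: dorsi-/plantar-flexion
  (Do/Pl) about the proximal medio-lateral axis *e₁ = Z_prox*,
  eversion/inversion (Eve/Inv) about the distal antero-posterior axis
  *e₃ = X_dist*, abduction/adduction (Abd/Add) about the floating axis
  *e₂ = e₃ × e₁*; equivalently an intrinsic Z–Y′–X″ Euler decomposition of
  R_rel = R_proxᵀ R_dist. Signs: dorsiflexion +, inversion +, adduction +.
* **Eight planar angles** — sagittal metatarsal pitches F2G/S2G/V2G,
  transverse deviations S2F/S2V, the Met-Hal sagittal/transverse
  components F2Ps/F2Pt, and the **medial longitudinal arch angle (MLA)**:
  the angle at the sustentaculum tali (ST) between rays to FMH and to CAp,
  the vertical ground projection of the heel marker, all projected into
  the foot sagittal plane. CAp is fixed during standing and then tracked
  through gait by a technical frame on the calcaneus marker cluster, so
  the MLA stays consistent with rearfoot orientation; dropped arches give
  values above 180°.
* **Gait-cycle machinery** — coordinate-based foot-strike/toe-off
  detection from the calcaneus and forefoot markers, 0–100% time
  normalization (101 points) and ensemble mean ± SD curves.
* **Hindfoot alignment classification** — neutral (|offset| ≤ 2°), varus
  (inversion > 2°), valgus (eversion > 2°) — and cohort summaries.
* A **forward-kinematics synthetic gait generator** with exact per-frame
  ground truth (joint angles, event frames, CAp trajectory), used as the
  oracle for every inverse computation and available for building test
  datasets (`footkin simulate`).

## Worked example

```python
import footkin as fk

# a synthetic foot with 4 deg valgus hindfoot and a low arch
tpl = fk.make_template(hindfoot_tilt_deg=4.0, arch_height_mm=12.0)
static = fk.generate_static_trial(tpl, n_frames=100)
calib = fk.compute_static_reference(static)
print(f"hindfoot frontal offset: {calib.hindfoot_frontal_offset:+.2f} deg "
      f"({fk.classify_hindfoot(calib.hindfoot_frontal_offset)})")
print(f"static MLA: {calib.static_angles['MLA']:.1f} deg")

trial, truth = fk.generate_trial(tpl, fk.SimSpec(n_cycles=3, noise_mm=0.5, seed=42))
events = fk.detect_gait_events(trial)
print(f"gait cycles detected: {len(events.cycles)} "
      f"(foot strikes at frames {events.foot_strikes})")

filt = fk.preprocess(trial)                       # 6 Hz zero-phase low-pass
joints = {j.joint: j for j in fk.compute_joint_series(filt)}
ec = fk.ensemble_stats(fk.cycle_curves(joints["Sha-Cal"].dopl, events),
                       "Sha-Cal dorsiflexion")
print(f"Sha-Cal Do/Pl over the cycle: range {ec.mean.min():+.1f} to "
      f"{ec.mean.max():+.1f} deg (mean SD {ec.sd.mean():.2f} deg, n={ec.n_curves})")

import numpy as np
rms = np.sqrt(np.nanmean((joints["Sha-Cal"].dopl
                          - truth.joint_angles["Sha-Cal"][:, 0]) ** 2))
print(f"Sha-Cal Do/Pl RMS error vs ground truth: {rms:.2f} deg")
```

printed output:

```
hindfoot frontal offset: +4.00 deg (valgus)
static MLA: 193.0 deg
gait cycles detected: 3 (foot strikes at frames [71, 171, 271, 371])
Sha-Cal Do/Pl over the cycle: range -30.3 to -15.6 deg (mean SD 0.15 deg, n=3)
Sha-Cal Do/Pl RMS error vs ground truth: 0.17 deg
```

The offset recovers the constructed 4° valgus tilt exactly; the static MLA
of 193° (> 180°) reflects the dropped arch; the ankle-complex
dorsi-/plantar-flexion curve carries its static offset (≈ −23°, the
calcaneus anatomical frame points down toward the PT/ST midpoint) and, at
0.5 mm marker noise, tracks the generator's ground truth to 0.17° RMS.

The same pipeline runs from the shell:

```sh
footkin simulate --seed 42 --n-participants 10 -o data/
footkin calibrate --static data/P01/P01_right_static.tsv --side R -o calib.yaml
footkin analyze  --calib calib.yaml --side R --trials data/P01/P01_right_walk*.tsv -o out/
footkin report   --in data/ -o report/
```

`report/` contains per-foot and cohort CSV tables plus the 15-panel joint
figure and the 8-panel planar-angle figure, each with the mean ± SD band
and the static value overlaid as a dashed segment.

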