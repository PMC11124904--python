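# circumkin

Circumnutation kinematics of climbing plants, from marker trajectories to
mixed-model inference.

Climbing plants such as the pea (*Pisum sativum*) explore their
surroundings by circumnutation: the growing apex and the tendril-bearing
leaves sweep out helical loops until a support is found and grasped.
`circumkin` turns time-lapse marker trajectories of those organs — 3D
positions in mm, one frame every 3 min (0.0056 Hz), Y vertical, X–Z the
horizontal plane — into per-loop kinematic measures and fits the
statistical models used to compare supported and unsupported plants across
growth. A trajectory-level simulator with full ground truth makes every
stage testable without any recordings.

## What it computes

**Loop segmentation.** In the X–Z plane the signed turning angles between
consecutive displacement vectors are accumulated; a circumnutation closes
at the first passage of the winding magnitude |Σθ| past 2π (minus a small
sampling slack). A direction reversal (cusp) always closes the current
loop. Per loop the package reports:

- duration (min) and the leaf's total movement time,
- the signed turning-angle sum Σθ and the rotation direction
  (counterclockwise iff |Σθ − 2π| ≤ 1.2 rad, clockwise iff
  |Σθ + 2π| ≤ 1.2 rad, otherwise none),
- the circumnutation center (coordinate-wise mean in X–Z) and its
  Euclidean distance from the plant origin (mm),
- the raster footprint area (mm²): occupied 1-mm pixels of the binarized
  trajectory,
- mean speed ‖Δp‖/Δt (mm/min, 3D) and mean acceleration (mm/min²),
- per leaf: loop count and clockwise/counterclockwise switch counts.

Growth splits into a PRE phase (first two leaves, before 5000 min) and a
POST phase (third leaf onward, tendrils present).

**Inference.** One model family per question, statsmodels-style
(`Model(...).fit()` → results object with `summary()`):

- `KinematicsLMM` — REML linear mixed models
  `index ~ condition × phase + (1 + condition | plant)` (and the
  condition × leaf × landmark variant), with Type-III Wald χ² tests under
  sum-to-zero coding and Tukey-adjusted pairwise contrasts of estimated
  marginal means;
- `CrossIndexGAM` — penalized cubic regression splines (basis 10, REML
  smoothing) between pairs of kinematic indices with a smoothed per-plant
  intercept, reporting the smooth's effective degrees of freedom (edf);
- `SwitchCountGLMM` — a Poisson GLMM (log link, Laplace approximation)
  for direction-switch counts;
- `bspline_curve` — descriptive cubic B-splines with 3 degrees of freedom.

**Simulation.** `simulate_plant` generates helical leaf trajectories
(`p(t) = c(t) + R[cos θ, sin θ]` in X–Z, linear vertical growth, per-loop
direction flips, last-leaf drift toward the support, Gaussian noise), and
`render_stereo`/`triangulate_track` close the loop through a synthetic
two-camera rig (DLT triangulation).

## Worked example

```python
import pandas as pd
from circumkin import PlantSimConfig, simulate_plant, leaf_kinematics, KinematicsLMM
from circumkin.kinematics import build_kinematic_table
from circumkin.simulate import simulate_cohort_recordings

plant = simulate_plant(PlantSimConfig(seed=1))
rec = plant.recording
window = rec.windows_for("apex")[4]          # the terminal leaf
lk = leaf_kinematics(rec.trajectories["apex"], window, rec.origin_xz, rec.condition)
print(f"leaf {lk.leaf_ordinal} ({lk.phase}): {lk.n_circumnutations} circumnutations "
      f"over {lk.movement_time_min:.0f} min")

plants = simulate_cohort_recordings(16, 8, seed=1)   # the study's 24-plant design
kin = pd.concat([build_kinematic_table(p.recording, landmarks=("apex",)) for p in plants],
                ignore_index=True)
print(KinematicsLMM(kin, "mean_speed_mm_min").fit().type3_table())
```

prints

```
leaf 5 (POST): 4 circumnutations over 360 min
           term  chi_square  df       p_value
      condition    1.405718   1  2.357686e-01
          phase  882.306472   1 6.890067e-194
condition:phase    1.385805   1  2.391148e-01
```

The terminal leaf's four loops are recovered exactly from the noisy
trajectory. In the cohort model the phase effect is overwhelming (POST
loops are larger and faster by construction), while condition and the
condition × phase interaction are null — this simulated cohort encodes no
support effect, and the Type-III tests correctly find none.

The same pipeline runs from the shell:

```
circumkin simulate --out sim/ --seed 1
circumkin analyze --input sim/ --out run/ --seed 1
circumkin report --input run/ --out run/
```

`analyze` writes the per-circumnutation table (`kinematics.csv`), the
fitted models for all four questions (`models.json`), a Type-III summary
(`type3_summary.tsv`) and a content-hash manifest.

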