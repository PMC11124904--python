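"""Synthetic plant recordings and cohorts with known ground truth.

Two levels of simulation are provided:

* :func:`simulate_plant` — a full trajectory-level simulator: each leaf
  circumnutates on a horizontal circle (radius and period per leaf, with
  small/slow early leaves and larger/faster later ones), the vertical
  coordinate grows linearly, rotation direction may switch between loops,
  the last leaf of a supported plant drifts toward the support, and i.i.d.
  Gaussian positional noise is added per axis.  Every quantity the
  kinematics stage estimates (loop count, directions, switches, centers,
  speeds, movement times) is emitted as ground truth.
* :func:`simulate_cohort` — a table-level simulator that draws the
  long-format kinematic table directly from its statistical structure
  (condition x phase cell means, per-plant random intercepts, observation
  noise, Poisson loop counts, direction-flip probabilities), for fast
  calibration studies of the inferential stage.

Default cohort composition follows the study design: 16 supported and 8
unsupported plants, about five leaves each, with the first two leaves
before the 5000-min phase boundary.  Real circumnutation amplitudes and
periods are not printed in the source material; the defaults (radius 5 to
30 mm, period 300 down to 90 min across leaves) are plausible placeholders
chosen to reproduce the qualitative PRE/POST contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LeafWindow, MarkerTrajectory, PlantRecording
from .stereo import StereoRig, project_points

__all__ = [
    "PlantSimConfig",
    "SimulatedPlant",
    "simulate_plant",
    "simulate_cohort",
    "simulate_cohort_recordings",
    "render_stereo",
    "COHORT_N_SUPPORT",
    "COHORT_N_NOSUPPORT",
]

#: Study cohort composition: plants per condition.
COHORT_N_SUPPORT = 16
COHORT_N_NOSUPPORT = 8

RANK_NAMES = {0: "Last", 1: "Second last", 2: "Third last"}


@dataclass(frozen=True)
class PlantSimConfig:
    """Full parameterization of one synthetic plant.

    Schedules are per leaf, ordered from the first leaf; the first two
    leaves are the PRE leaves (small radius, long period), later leaves are
    POST.  ``directions`` fixes the per-loop rotation sense (+1
    counterclockwise, -1 clockwise) per leaf; when ``None``, directions are
    drawn with per-loop flip probability ``flip_p``.
    """

    plant_id: str = "P01"
    condition: str = "Support"
    n_leaves: int = 5
    loops_per_leaf: tuple[int, ...] = (6, 6, 5, 5, 4)
    radius_mm: tuple[float, ...] = (5.0, 8.0, 18.0, 24.0, 30.0)
    period_min: tuple[float, ...] = (300.0, 300.0, 150.0, 120.0, 90.0)
    center_distance_mm: tuple[float, ...] = (8.0, 12.0, 20.0, 26.0, 32.0)
    directions: tuple[tuple[int, ...], ...] | None = None
    flip_p: float = 0.0
    vertical_growth_mm_per_min: float = 0.03
    #: positional noise s.d. per axis (mm); a scalar, or one value per leaf
    #: (applied to the samples inside that leaf's window)
    noise_sd_mm: float | tuple[float, ...] = 0.5
    support_xz_mm: tuple[float, float] = (120.0, 0.0)
    support_height_mm: float = 530.0
    last_leaf_drift: float = 0.6
    sampling_step_min: float = 3.0
    first_leaf_start_min: float = 800.0
    inter_leaf_gap_min: float = 30.0
    post_start_min: float = 5100.0
    tendril_radius_factor: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_leaves
        for name in ("loops_per_leaf", "radius_mm", "period_min", "center_distance_mm"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per leaf ({n})")
        if any(l < 0 for l in self.loops_per_leaf):
            raise ValueError("loop counts must be >= 0")
        if any(r <= 0 for r in self.radius_mm) or any(p <= 0 for p in self.period_min):
            raise ValueError("radius and period must be positive")
        noise = self.noise_sd_mm
        noise_vals = noise if isinstance(noise, tuple) else (noise,)
        if isinstance(noise, tuple) and len(noise) != n:
            raise ValueError("per-leaf noise_sd_mm needs one value per leaf")
        if any(v < 0 for v in noise_vals) or not (0.0 <= self.last_leaf_drift <= 1.0):
            raise ValueError("noise_sd >= 0 and drift in [0, 1] required")
        if not (0.0 <= self.flip_p <= 1.0):
            raise ValueError("flip_p must be a probability")
        if self.condition not in ("Support", "NoSupport"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class SimulatedPlant:
    """A simulated recording bundled with its generating ground truth."""

    recording: PlantRecording
    truth: dict
    config: PlantSimConfig


def _leaf_schedule(cfg: PlantSimConfig) -> list[tuple[float, float]]:
    """Leaf windows [(start, end)] from the config's loop/period schedule."""
    windows = []
    t = cfg.first_leaf_start_min
    for leaf in range(cfg.n_leaves):
        if leaf == 2:  # phase passage: third leaf begins the POST phase
            t = max(t, cfg.post_start_min)
        dur = cfg.loops_per_leaf[leaf] * cfg.period_min[leaf]
        windows.append((t, t + dur))
        t += dur + cfg.inter_leaf_gap_min
    return windows


def _leaf_directions(cfg: PlantSimConfig, rng: np.random.Generator) -> list[list[int]]:
    if cfg.directions is not None:
        if len(cfg.directions) != cfg.n_leaves:
            raise ValueError("directions must have one tuple per leaf")
        return [list(d) for d in cfg.directions]
    out = []
    current = 1
    for leaf in range(cfg.n_leaves):
        dirs = []
        for _ in range(cfg.loops_per_leaf[leaf]):
            if dirs or out:
                if rng.random() < cfg.flip_p:
                    current = -current
            dirs.append(current)
        out.append(dirs)
    return out


def simulate_plant(cfg: PlantSimConfig) -> SimulatedPlant:
    """Simulate one plant's apex/tendril trajectories with ground truth.

    Per leaf the apex follows ``c(t) + R [cos th(t), sin th(t)]`` in the
    X-Z plane with ``dth/dt = +/- 2*pi/period``; the last leaf of a
    supported plant closes ``last_leaf_drift`` of the gap between its
    center and the support over its window.  Identical configs (including
    seed) give bit-identical recordings.
    """
    rng = np.random.default_rng(cfg.seed)
    schedule = _leaf_schedule(cfg)
    directions = _leaf_directions(cfg, rng)
    step = cfg.sampling_step_min
    t_end = schedule[-1][1] + step
    times = np.arange(0.0, t_end + step / 2, step)

    support = np.asarray(cfg.support_xz_mm, dtype=float)

    def center_at(leaf: int, t: np.ndarray) -> np.ndarray:
        base = np.array([cfg.center_distance_mm[leaf], 0.0])
        t0, t1 = schedule[leaf]
        is_last = leaf == cfg.n_leaves - 1
        if is_last and cfg.condition == "Support" and cfg.last_leaf_drift > 0:
            frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0) * cfg.last_leaf_drift
            return base[None, :] + frac[:, None] * (support - base)[None, :]
        return np.broadcast_to(base, (t.size, 2)).copy()

    def xz_track(radius_factor: float, phase0: float) -> np.ndarray:
        """Noiseless horizontal track over the full time grid."""
        xz = np.zeros((times.size, 2))
        # before the first window: sit at the first leaf's start point
        for leaf, (t0, t1) in enumerate(schedule):
            R = cfg.radius_mm[leaf] * radius_factor
            omega = 2.0 * np.pi / cfg.period_min[leaf]
            dirs = directions[leaf]
            in_win = (times >= t0) & (times <= t1)
            tw = times[in_win]
            # integrate the signed angular speed across per-loop segments
            theta = np.full(tw.size, phase0)
            elapsed = tw - t0
            loop_dur = cfg.period_min[leaf]
            loop_idx = np.minimum((elapsed / loop_dur).astype(int), max(len(dirs) - 1, 0))
            if dirs:
                cum = np.concatenate([[0.0], np.cumsum([d * 2.0 * np.pi for d in dirs])])
                within = elapsed - loop_idx * loop_dur
                theta = phase0 + cum[loop_idx] + np.array(dirs)[loop_idx] * omega * within
            centers = center_at(leaf, tw)
            xz[in_win] = centers + R * np.c_[np.cos(theta), np.sin(theta)]
            # hold the final pose until the next window starts
            after = times > t1
            if after.any() and tw.size:
                xz[after] = xz[in_win][-1]
        first_t0 = schedule[0][0]
        before = times < first_t0
        if before.any():
            start_idx = int(np.searchsorted(times, first_t0))
            start_idx = min(start_idx, times.size - 1)
            xz[before] = xz[start_idx]
        return xz

    if isinstance(cfg.noise_sd_mm, tuple):
        # per-leaf noise level: each sample gets the sigma of the leaf whose
        # window covers it (last level carried forward between windows)
        sigma = np.full(times.size, cfg.noise_sd_mm[0])
        for leaf, (t0, _) in enumerate(schedule):
            sigma[times >= t0] = cfg.noise_sd_mm[leaf]
    else:
        sigma = np.full(times.size, float(cfg.noise_sd_mm))

    def add_noise(arr: np.ndarray, sig: np.ndarray) -> np.ndarray:
        if np.all(sig == 0):
            return arr
        return arr + rng.normal(0.0, 1.0, arr.shape) * sig[:, None]

    growth = cfg.vertical_growth_mm_per_min
    apex_xz = xz_track(1.0, 0.0)
    apex = np.column_stack([apex_xz[:, 0], growth * times, apex_xz[:, 1]])

    tendril_start = schedule[2][0] if cfg.n_leaves >= 3 else None
    trajectories: dict[str, MarkerTrajectory] = {}
    trajectories["apex"] = MarkerTrajectory(
        cfg.plant_id, "apex", times, add_noise(apex, sigma)
    )

    if tendril_start is not None:
        mask = times >= tendril_start
        tend_xz = xz_track(cfg.tendril_radius_factor, 0.5)[mask]
        tend = np.column_stack(
            [tend_xz[:, 0], growth * times[mask] - 15.0, tend_xz[:, 1]]
        )
        trajectories["tendrils"] = MarkerTrajectory(
            cfg.plant_id, "tendrils", times[mask], add_noise(tend, sigma[mask])
        )

    onoise = rng.normal(0.0, 1.0, (times.size, 3)) * sigma[:, None]
    trajectories["origin"] = MarkerTrajectory(
        cfg.plant_id, "origin", times, np.zeros((times.size, 3)) + onoise
    )

    windows = []
    for leaf, (t0, t1) in enumerate(schedule):
        terminal = leaf == cfg.n_leaves - 1
        coiled = terminal and cfg.condition == "Support"
        windows.append(
            LeafWindow(leaf + 1, "apex", t0, t1, terminal=terminal, coiled=coiled)
        )
        if leaf >= 2:
            windows.append(
                LeafWindow(leaf + 1, "tendrils", t0, t1, terminal=terminal, coiled=coiled)
            )

    support_position = (
        (float(support[0]), float(support[1]), cfg.support_height_mm)
        if cfg.condition == "Support"
        else None
    )
    recording = PlantRecording(
        plant_id=cfg.plant_id,
        condition=cfg.condition,
        trajectories=trajectories,
        leaf_windows=windows,
        support_position=support_position,
        origin_position=(0.0, 0.0),
    )

    truth = _plant_truth(cfg, schedule, directions, times, apex)
    return SimulatedPlant(recording=recording, truth=truth, config=cfg)


def _plant_truth(cfg, schedule, directions, times, apex_noiseless) -> dict:
    label = {1: "counterclockwise", -1: "clockwise"}
    leaves = []
    for leaf, (t0, t1) in enumerate(schedule):
        dirs = [label[d] for d in directions[leaf]]
        n_cw = n_ccw = 0
        for a, b in zip(dirs, dirs[1:]):
            if a != b:
                if b == "clockwise":
                    n_cw += 1
                else:
                    n_ccw += 1
        in_win = (times >= t0) & (times <= t1)
        pts = apex_noiseless[in_win]
        tw = times[in_win]
        speeds = np.linalg.norm(np.diff(pts, axis=0), axis=1) / np.diff(tw)
        leaves.append(
            {
                "leaf_ordinal": leaf + 1,
                "window": (float(t0), float(t1)),
                "movement_time_min": float(t1 - t0),
                "n_loops": cfg.loops_per_leaf[leaf],
                "directions": dirs,
                "n_switches_cw": n_cw,
                "n_switches_ccw": n_ccw,
                "radius_mm": cfg.radius_mm[leaf],
                "period_min": cfg.period_min[leaf],
                "center_xz_mm": (cfg.center_distance_mm[leaf], 0.0),
                "center_distance_mm": cfg.center_distance_mm[leaf],
                "mean_speed_mm_min": float(speeds.mean()) if speeds.size else np.nan,
            }
        )
    return {"plant_id": cfg.plant_id, "condition": cfg.condition, "leaves": leaves}


# ---------------------------------------------------------------------------
# table-level cohort simulator

#: Baseline cell means of the kinematic indices by phase (PRE, POST); mm,
#: mm/min, mm/min^2, mm^2 respectively.
BASE_MEANS = {
    "mean_speed_mm_min": {"PRE": 0.35, "POST": 0.9},
    "mean_accel_mm_min2": {"PRE": 0.01, "POST": 0.03},
    "center_distance_mm": {"PRE": 10.0, "POST": 25.0},
    "area_mm2": {"PRE": 60.0, "POST": 300.0},
}

#: Baseline Poisson rate of loops per leaf and movement-time (min) per leaf.
BASE_LOOP_RATE = 6.0
BASE_MOVEMENT_TIME = {"PRE": 1800.0, "POST": 700.0}


def simulate_cohort(
    n_support: int = COHORT_N_SUPPORT,
    n_nosupport: int = COHORT_N_NOSUPPORT,
    effects: Mapping | None = None,
    seed: int = 0,
    n_leaves: int = 5,
    sd_plant: float = 0.25,
    sd_obs: float = 0.4,
    flip_p: float = 0.25,
) -> tuple[pd.DataFrame, dict]:
    """Draw a per-circumnutation kinematic table from its statistical model.

    Each index value is ``cell_mean * multiplier + (plant_intercept +
    noise) * index_scale``: the additive plant intercept (s.d.
    ``sd_plant``) and observation noise (s.d. ``sd_obs``) are expressed on
    a fixed per-index scale, matching the constant-variance random
    intercept structure the mixed models assume.  Loops per leaf are
    Poisson, directions flip between consecutive loops with probability
    ``flip_p``.  ``effects`` may hold multiplier maps:

    * ``index``: ``{(index, condition, phase): factor}``
    * ``loops``: ``{(condition, leaf_rank): factor}`` on the loop rate
    * ``movement_time``: ``{(condition, leaf_rank): factor}``
    * ``flip``: ``{(condition, leaf_rank): factor}`` on ``flip_p``

    Returns the table and the ground-truth cell structure.
    """
    rng = np.random.default_rng(seed)
    effects = dict(effects or {})
    e_index = dict(effects.get("index", {}))
    e_loops = dict(effects.get("loops", {}))
    e_mt = dict(effects.get("movement_time", {}))
    e_flip = dict(effects.get("flip", {}))

    plants = [("Support", f"S{i:02d}") for i in range(1, n_support + 1)] + [
        ("NoSupport", f"N{i:02d}") for i in range(1, n_nosupport + 1)
    ]
    rows = []
    truth_cells: dict = {"index_means": {}, "loop_rates": {}, "movement_times": {}}
    for condition, plant_id in plants:
        u = rng.normal(0.0, sd_plant)  # shared plant intercept, in cell-mean units
        for leaf in range(1, n_leaves + 1):
            phase = "PRE" if leaf <= 2 else "POST"
            rank = RANK_NAMES.get(n_leaves - leaf, "")
            rate = BASE_LOOP_RATE * e_loops.get((condition, rank), 1.0)
            n_loops = int(rng.poisson(rate))
            truth_cells["loop_rates"][(condition, rank)] = rate
            mt = BASE_MOVEMENT_TIME[phase] * e_mt.get((condition, rank), 1.0)
            mt_scale = 0.25 * BASE_MOVEMENT_TIME["POST"]
            mt_val = mt + (u + rng.normal(0.0, sd_obs / 2)) * mt_scale
            truth_cells["movement_times"][(condition, rank)] = mt
            p_flip = min(1.0, flip_p * e_flip.get((condition, rank), 1.0))
            direction = 1
            dirs = []
            for k in range(n_loops):
                if k > 0 and rng.random() < p_flip:
                    direction = -direction
                dirs.append(direction)
            n_cw = sum(
                1 for a, b in zip(dirs, dirs[1:]) if a != b and b == -1
            )
            n_ccw = sum(1 for a, b in zip(dirs, dirs[1:]) if a != b and b == 1)
            # a zero-loop leaf still contributes one row (counts of zero are
            # data for the count models; its per-loop indices are missing)
            for k in range(max(n_loops, 1)):
                row = {
                    "plant_id": plant_id,
                    "condition": condition,
                    "landmark": "apex",
                    "leaf_ordinal": leaf,
                    "leaf_rank": rank,
                    "phase": phase,
                    "movement_time_min": mt_val,
                    "duration_min": mt / max(n_loops, 1),
                    "direction": (
                        ("counterclockwise" if dirs[k] == 1 else "clockwise")
                        if n_loops
                        else "none"
                    ),
                    "n_circumnutations": n_loops,
                    "n_switches_cw": n_cw,
                    "n_switches_ccw": n_ccw,
                }
                for index, means in BASE_MEANS.items():
                    mu = means[phase] * e_index.get((index, condition, phase), 1.0)
                    truth_cells["index_means"][(index, condition, phase)] = mu
                    scale = means["POST"]
                    row[index] = (
                        mu + (u + rng.normal(0.0, sd_obs)) * scale
                        if n_loops
                        else np.nan
                    )
                rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "cells": truth_cells,
        "sd_plant": sd_plant,
        "sd_obs": sd_obs,
        "flip_p": flip_p,
        "n_plants": len(plants),
    }
    return table, truth


def simulate_cohort_recordings(
    n_support: int = COHORT_N_SUPPORT,
    n_nosupport: int = COHORT_N_NOSUPPORT,
    base_cfg: PlantSimConfig | None = None,
    seed: int = 0,
) -> list[SimulatedPlant]:
    """Trajectory-level cohort: one :func:`simulate_plant` run per plant,
    with per-plant seeds derived from ``seed`` and mild radius jitter."""
    base = base_cfg or PlantSimConfig()
    rng = np.random.default_rng(seed)
    plants = []
    specs = [("Support", f"S{i:02d}") for i in range(1, n_support + 1)] + [
        ("NoSupport", f"N{i:02d}") for i in range(1, n_nosupport + 1)
    ]
    for condition, plant_id in specs:
        jitter = rng.uniform(0.85, 1.15)
        cfg = replace(
            base,
            plant_id=plant_id,
            condition=condition,
            radius_mm=tuple(r * jitter for r in base.radius_mm),
            flip_p=base.flip_p if base.directions is None else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        plants.append(simulate_plant(cfg))
    return plants


def render_stereo(
    plant: SimulatedPlant,
    rig: StereoRig,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
    landmark: str = "apex",
) -> tuple[np.ndarray, np.ndarray]:
    """Project a simulated landmark into both cameras, with pixel noise.

    Returns per-frame pixel tracks ``(track_a, track_b)``, each (n, 2);
    raises if the plant leaves either camera's field of view (behind
    camera)."""
    rng = np.random.default_rng(seed)
    pts = plant.recording.trajectories[landmark].positions
    track_a = project_points(pts, rig.camera_a)
    track_b = project_points(pts, rig.camera_b)
    if pixel_noise_sd > 0:
        track_a = track_a + rng.normal(0.0, pixel_noise_sd, track_a.shape)
        track_b = track_b + rng.normal(0.0, pixel_noise_sd, track_b.shape)
    return track_a, track_b
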