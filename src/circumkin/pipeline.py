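"""End-to-end orchestration: recordings -> kinematic table -> models -> report.

The four analysis questions map onto the fitted models as:

* Q1 — does a support change kinematics?  One LMM per kinematic index,
  ``index ~ condition * phase + (1 + condition | plant)``, apex only.
* Q2 — nonlinear cross-index structure: one REML additive model per
  ordered pair of distinct indices, apex only.
* Q3 — growth pattern across the last three leaves for apex and tendrils:
  ``index ~ condition * leaf_rank * landmark + (1 + condition | plant)``.
* Q4 — loop counts (Gaussian LMM), direction-switch counts (Poisson GLMM)
  and movement time (LMM) over the last three leaves.

All outputs are deterministic given the run seed; files carry a manifest
of content hashes, and an existing output with different content is
renamed (suffixed with its short hash) rather than silently overwritten.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .io import LeafWindow, PlantRecording
from .kinematics import (
    KINEMATIC_INDICES,
    PHASE_BOUNDARY_MIN,
    build_kinematic_table,
)
from .models import CrossIndexGAM, KinematicsLMM, SwitchCountGLMM, bspline_curve
from .simulate import PlantSimConfig, SimulatedPlant, simulate_cohort_recordings

__all__ = [
    "RunConfig",
    "RunArtifacts",
    "run_pipeline",
    "leaf_rank",
    "per_leaf_table",
    "switch_count_table",
    "load_recordings",
    "write_cohort",
]

log = logging.getLogger("circumkin")


class PipelineError(RuntimeError):
    """Raised for malformed inputs or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_dir`` (a directory of per-plant trajectory CSVs
    with matching ``.yaml`` metadata) or ``simulate`` (a cohort
    specification) must be given.
    """

    output_dir: str | Path
    input_dir: str | Path | None = None
    simulate: dict | None = None  # keys: n_support, n_nosupport, plant config
    pixel_size: float = 1.0
    phase_boundary: float = PHASE_BOUNDARY_MIN
    rank_depth: int = 3
    seed: int = 0
    log_level: str = "INFO"
    make_figures: bool = True

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise PipelineError("specify exactly one of input_dir or simulate")


@dataclass
class RunArtifacts:
    """Paths of the files a pipeline run produced."""

    output_dir: Path
    kinematics_csv: Path
    per_leaf_csv: Path
    models_json: Path
    summary_tsv: Path
    figures: list[Path]
    manifest_json: Path


def leaf_rank(windows: Sequence[LeafWindow], depth: int = 3) -> dict[int, str]:
    """Rank a plant's last ``depth`` leaves from the end.

    The last three windows by start time are labelled "Third last",
    "Second last" and "Last"; with fewer windows only the trailing labels
    are used.  Tied start times are ambiguous and raise an error.
    """
    starts = [w.start_time for w in windows]
    if len(set(starts)) != len(starts):
        raise PipelineError("tied leaf-window start times; ranks are ambiguous")
    ordered = sorted(windows, key=lambda w: w.start_time)[-depth:]
    names = ["Last", "Second last", "Third last"]
    return {
        w.leaf_ordinal: names[len(ordered) - 1 - i] for i, w in enumerate(ordered)
    }


# ---------------------------------------------------------------------------
# input handling


def load_recordings(input_dir: str | Path) -> list[PlantRecording]:
    """Load every ``<plant>.csv`` + ``<plant>.yaml`` pair in a directory."""
    input_dir = Path(input_dir)
    csvs = sorted(input_dir.glob("*.csv"))
    if not csvs:
        raise PipelineError(f"no trajectory CSV files in {input_dir}")
    recordings = []
    for csv in csvs:
        meta = csv.with_suffix(".yaml")
        try:
            recordings.append(tio.read_recording(csv, meta if meta.exists() else None))
        except (tio.FormatError, tio.ValidationError) as exc:
            raise PipelineError(f"{csv.name}: {exc}") from exc
    return recordings


def write_cohort(plants: Sequence[SimulatedPlant], out_dir: str | Path) -> list[Path]:
    """Write simulated plants as the CSV/YAML pairs ``load_recordings`` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    truths = {}
    for sp in plants:
        base = out_dir / sp.recording.plant_id
        tio.write_recording(sp.recording, base.with_suffix(".csv"))
        tio.write_metadata(sp.recording, base.with_suffix(".yaml"))
        truths[sp.recording.plant_id] = sp.truth
        written += [base.with_suffix(".csv"), base.with_suffix(".yaml")]
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truths, indent=2, default=float))
    written.append(truth_path)
    return written


# ---------------------------------------------------------------------------
# derived tables


def per_leaf_table(kin: pd.DataFrame) -> pd.DataFrame:
    """Collapse the per-circumnutation table to one row per leaf window."""
    keys = ["plant_id", "condition", "landmark", "leaf_ordinal"]
    firsts = kin.groupby(keys, as_index=False).first()
    cols = keys + [
        "leaf_rank",
        "phase",
        "movement_time_min",
        "n_circumnutations",
        "n_switches_cw",
        "n_switches_ccw",
    ]
    return firsts[cols]


def switch_count_table(leaf_tab: pd.DataFrame) -> pd.DataFrame:
    """Long switch-count table: one row per plant x leaf x direction."""
    rows = []
    for _, r in leaf_tab.iterrows():
        for direction, n in (
            ("Clockwise", r["n_switches_cw"]),
            ("Counterclockwise", r["n_switches_ccw"]),
        ):
            rows.append(
                {
                    "plant_id": r["plant_id"],
                    "condition": r["condition"],
                    "leaf_rank": r["leaf_rank"],
                    "switch_direction": direction,
                    "n_switches": int(n),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model stages


def _fit_q1(kin: pd.DataFrame) -> dict:
    apex = kin[kin["landmark"] == "apex"]
    out = {}
    for index in KINEMATIC_INDICES:
        res = KinematicsLMM(apex, index).fit()
        out[index] = res.to_dict()
        out[index]["contrasts"] = res.contrast_table(["condition", "phase"]).to_dict(
            orient="records"
        )
        out[index]["emmeans"] = res.emmeans(["condition", "phase"]).to_dict(
            orient="records"
        )
    return out


def _fit_q2(kin: pd.DataFrame) -> dict:
    apex = kin[kin["landmark"] == "apex"]
    out = {}
    for response in KINEMATIC_INDICES:
        for predictor in KINEMATIC_INDICES:
            if response == predictor:
                continue
            res = CrossIndexGAM(apex, response, predictor).fit()
            out[f"{response}~s({predictor})"] = res.to_dict()
    return out


def _fit_q3(kin: pd.DataFrame) -> dict:
    last3 = kin[(kin["leaf_rank"] != "") & kin["landmark"].isin(["apex", "tendrils"])]
    terms = (
        "condition",
        "leaf_rank",
        "landmark",
        "condition:leaf_rank",
        "condition:landmark",
        "leaf_rank:landmark",
        "condition:leaf_rank:landmark",
    )
    out = {}
    for index in KINEMATIC_INDICES:
        res = KinematicsLMM(last3, index, fixed=terms).fit()
        out[index] = res.to_dict()
        out[index]["emmeans"] = res.emmeans(
            ["condition", "leaf_rank", "landmark"]
        ).to_dict(orient="records")
    return out


def _fit_q4(leaf_tab: pd.DataFrame) -> dict:
    last3 = leaf_tab[leaf_tab["leaf_rank"] != ""]
    terms = ("condition", "leaf_rank", "condition:leaf_rank")
    out = {}

    loops = KinematicsLMM(
        last3, "n_circumnutations", fixed=terms, random_slope=None
    ).fit()
    out["circumnutations"] = loops.to_dict()
    out["circumnutations"]["emmeans"] = loops.emmeans(
        ["condition", "leaf_rank"]
    ).to_dict(orient="records")
    out["circumnutations"]["contrasts"] = loops.contrast_table(
        ["condition", "leaf_rank"]
    ).to_dict(orient="records")

    sw = switch_count_table(last3)
    glmm = SwitchCountGLMM(
        sw,
        "n_switches",
        fixed=(
            "condition",
            "leaf_rank",
            "switch_direction",
            "condition:leaf_rank",
            "condition:switch_direction",
            "leaf_rank:switch_direction",
        ),
    ).fit()
    out["switches"] = glmm.to_dict()
    out["switches"]["emmeans"] = glmm.emmeans(["condition", "leaf_rank"]).to_dict(
        orient="records"
    )

    mt = KinematicsLMM(
        last3, "movement_time_min", fixed=terms, random_slope=None
    ).fit()
    out["movement_time"] = mt.to_dict()
    out["movement_time"]["emmeans"] = mt.emmeans(["condition", "leaf_rank"]).to_dict(
        orient="records"
    )
    return out


# ---------------------------------------------------------------------------
# report


def _figures(kin: pd.DataFrame, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    apex = kin[kin["landmark"] == "apex"]
    paths = []
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, index in zip(axes.ravel(), KINEMATIC_INDICES):
        for condition, color in (("Support", "tab:red"), ("NoSupport", "tab:blue")):
            sub = apex[apex["condition"] == condition].sort_values("start_time_min")
            if len(sub) < 5:
                continue
            curve = bspline_curve(
                sub["start_time_min"].to_numpy(), sub[index].to_numpy(), df=3
            )
            xs = np.linspace(sub["start_time_min"].min(), sub["start_time_min"].max(), 200)
            ax.plot(sub["start_time_min"], sub[index], ".", ms=2, alpha=0.3, color=color)
            ax.plot(xs, curve(xs), color=color, label=condition)
        ax.set_title(index)
        ax.set_xlabel("time (min)")
    axes[0, 0].legend()
    fig.suptitle("Kinematic indices over experimental time (cubic B-spline, df=3)")
    fig.tight_layout()
    p = out_dir / "indices_over_time.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _versioned_write(path: Path, writer) -> Path:
    """Write via ``writer(tmp_path)``; if ``path`` exists with different
    content, the old file is kept under a hash-suffixed name."""
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    if path.exists():
        old, new = _sha256(path), _sha256(tmp)
        if old != new:
            backup = path.with_name(f"{path.stem}.{old[:8]}{path.suffix}")
            path.rename(backup)
            log.info("kept previous %s as %s", path.name, backup.name)
        else:
            path.unlink()
    tmp.rename(path)
    return path


def run_pipeline(cfg: RunConfig) -> RunArtifacts:
    """Run simulate|ingest -> kinematics -> statistics -> report."""
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", json.dumps(dataclasses.asdict(cfg), default=str))

    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        base_kwargs = {
            k: v
            for k, v in sim.items()
            if k not in ("n_support", "n_nosupport") and v is not None
        }
        plants = simulate_cohort_recordings(
            n_support=int(sim.get("n_support", 16)),
            n_nosupport=int(sim.get("n_nosupport", 8)),
            base_cfg=PlantSimConfig(**base_kwargs) if base_kwargs else None,
            seed=cfg.seed,
        )
        recordings = [p.recording for p in plants]
        log.info("simulated %d plants", len(recordings))
    else:
        recordings = load_recordings(cfg.input_dir)
        log.info("loaded %d recordings from %s", len(recordings), cfg.input_dir)

    tables = []
    for rec in recordings:
        if not rec.leaf_windows:
            raise PipelineError(f"recording {rec.plant_id!r} has no leaf windows")
        tab = build_kinematic_table(
            rec,
            pixel_size=cfg.pixel_size,
            phase_boundary=cfg.phase_boundary,
            rank_depth=cfg.rank_depth,
        )
        tables.append(tab)
    kin = pd.concat(tables, ignore_index=True)
    if kin.empty:
        raise PipelineError("no circumnutations detected in any recording")
    leaf_tab = per_leaf_table(kin)

    kin_path = _versioned_write(
        out_dir / "kinematics.csv", lambda p: kin.to_csv(p, index=False)
    )
    leaf_path = _versioned_write(
        out_dir / "per_leaf.csv", lambda p: leaf_tab.to_csv(p, index=False)
    )

    log.info("fitting Q1 (condition x phase LMMs)")
    q1 = _fit_q1(kin)
    log.info("fitting Q2 (cross-index GAMs)")
    q2 = _fit_q2(kin)
    log.info("fitting Q3 (condition x leaf x landmark LMMs)")
    q3 = _fit_q3(kin)
    log.info("fitting Q4 (counts, switches, movement time)")
    q4 = _fit_q4(leaf_tab)

    models = {"Q1": q1, "Q2": q2, "Q3": q3, "Q4": q4, "seed": cfg.seed}
    models_path = _versioned_write(
        out_dir / "models.json",
        lambda p: p.write_text(json.dumps(models, indent=2, default=float)),
    )

    rows = []
    for q, block in (("Q1", q1), ("Q3", q3)):
        for index, res in block.items():
            for t in res["type3"]:
                rows.append({"question": q, "model": index, **t})
    for name, res in q4.items():
        for t in res["type3"]:
            rows.append({"question": "Q4", "model": name, **t})
    summary = pd.DataFrame(rows)
    summary_path = _versioned_write(
        out_dir / "type3_summary.tsv",
        lambda p: summary.to_csv(p, sep="\t", index=False),
    )

    figures = _figures(kin, out_dir) if cfg.make_figures else []

    manifest = {
        "config": dataclasses.asdict(cfg),
        "files": {
            p.name: _sha256(p)
            for p in [kin_path, leaf_path, models_path, summary_path, *figures]
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    return RunArtifacts(
        output_dir=out_dir,
        kinematics_csv=kin_path,
        per_leaf_csv=leaf_path,
        models_json=models_path,
        summary_tsv=summary_path,
        figures=figures,
        manifest_json=manifest_path,
    )
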