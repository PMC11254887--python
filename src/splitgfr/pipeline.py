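"""End-to-end experiment orchestration.

``run_experiment`` ties the stages together: phantom simulation, input-stack
construction, four-fold rotation training, prediction, mask post-processing
with the fallback background ROI, Gates GFR with ground-truth and predicted
ROI sets, and pooled agreement statistics.  Numeric tables (CSV/JSON) are the
tested surface; plots are advisory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evalstats, roi_tools, segmentation
from .core import DynamicRenogram, RoiSet
from .evalstats import AgreementReport, compute_agreement, dice
from .gates import GatesConfig, GfrResult, gates_gfr
from .phantom import PhantomScene, sample_scene, simulate_renogram
from .roi_tools import BackgroundRoiConfig, auto_background_roi, clean_mask
from .segmentation import (
    TrainConfig,
    aggregate_folds,
    build_input_stack,
    make_fold_plan,
    predict_roiset,
    roiset_to_labels,
    train,
)

__all__ = [
    "PhantomSection",
    "TrainingSection",
    "EvaluationSection",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "simulate_cohort",
    "postprocess_prediction",
    "load_config",
]

log = logging.getLogger("splitgfr")

CSV_COLUMNS = [
    "scan_id",
    "gfr_gt_left",
    "gfr_gt_right",
    "gfr_gt_total",
    "gfr_dl_left",
    "gfr_dl_right",
    "gfr_dl_total",
    "dice_lk",
    "dice_rk",
    "dice_bg_left",
    "dice_bg_right",
    "fallback_bg_left",
    "fallback_bg_right",
    "dl_failed",
]


@dataclass(frozen=True)
class PhantomSection:
    n: int = 24
    gfr_range: tuple[float, float] = (20.0, 150.0)
    split_range: tuple[float, float] = (0.35, 0.65)
    background_range: tuple[float, float] = (5.0, 20.0)
    noise: bool = True
    liver: bool = False


@dataclass(frozen=True)
class TrainingSection:
    input_size: int = 64
    base_filters: int = 8
    levels: int = 3
    epochs: int = 25
    batch_size: int = 8
    learning_rate: float = 1e-2
    folds: int = 4
    augment: bool = False
    channel_mode: str = "frames"


@dataclass(frozen=True)
class EvaluationSection:
    abs_threshold: float = 5.0
    rel_thresholds: tuple[float, ...] = (10.0, 20.0)


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: PhantomSection = field(default_factory=PhantomSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    gates: GatesConfig = field(default_factory=GatesConfig)
    background: BackgroundRoiConfig = field(default_factory=BackgroundRoiConfig)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    seed: int = 0
    make_plots: bool = True

    def train_config(self) -> TrainConfig:
        t = self.training
        return TrainConfig(
            input_size=t.input_size,
            learning_rate=t.learning_rate,
            epochs=t.epochs,
            batch_size=t.batch_size,
            folds=t.folds,
            seed=self.seed,
            base_filters=t.base_filters,
            levels=t.levels,
            channel_mode=t.channel_mode,
            augment=t.augment,
            window_frames=self.gates.window_frames,
        )


def _section(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ExperimentConfig(
        phantom=_section(PhantomSection, raw.get("phantom", {})),
        training=_section(TrainingSection, raw.get("training", {})),
        gates=_section(GatesConfig, raw.get("gates", {})),
        background=_section(BackgroundRoiConfig, raw.get("background", {})),
        evaluation=_section(EvaluationSection, raw.get("evaluation", {})),
        seed=raw.get("seed", 0),
        make_plots=raw.get("make_plots", True),
    )


@dataclass
class ExperimentReport:
    table: pd.DataFrame
    agreement: dict[str, AgreementReport]
    dice_mean: dict[str, float]
    fallback_counts: dict[str, int]
    n_failed: int
    n_scans: int

    def summary_dict(self) -> dict:
        out = {
            "n_scans": self.n_scans,
            "n_dl_failed": self.n_failed,
            "fallback_background": self.fallback_counts,
            "dice_mean": self.dice_mean,
            "agreement": {},
        }
        for key, rep in self.agreement.items():
            out["agreement"][key] = {
                "n": rep.n,
                "ccc": rep.ccc,
                "ccc_ci": list(rep.ccc_ci),
                "slope": rep.slope,
                "slope_ci": list(rep.slope_ci),
                "bias": rep.bias,
                "loa": [rep.loa_low, rep.loa_high],
                "frac_abs_lt": rep.frac_abs_lt,
                "frac_rel_lt": {str(k): v for k, v in rep.frac_rel_lt.items()},
            }
        return out


def simulate_cohort(config: ExperimentConfig) -> tuple[list[PhantomScene], list[DynamicRenogram]]:
    """Sample and forward-simulate the phantom cohort, deterministically."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.phantom.n)
    scenes, scans = [], []
    for i, child in enumerate(children):
        scene_seed, noise_seed = (int(s.generate_state(1)[0]) for s in child.spawn(2))
        scene = sample_scene(
            scene_seed,
            gfr_range=config.phantom.gfr_range,
            split_range=config.phantom.split_range,
            background_range=config.phantom.background_range,
            liver=config.phantom.liver,
            gates_config=config.gates,
            bg_config=config.background,
            scan_id=f"scan{i:04d}",
        )
        scan = simulate_renogram(
            scene.patient,
            scene.truth,
            scene.meta,
            noise=config.phantom.noise,
            rng_seed=noise_seed,
            gates_config=config.gates,
        )
        scan.scan_id = scene.scan_id
        scenes.append(scene)
        scans.append(scan)
    return scenes, scans


def postprocess_prediction(
    raw_rois: RoiSet,
    bg_config: BackgroundRoiConfig = BackgroundRoiConfig(),
) -> tuple[RoiSet, dict[str, bool], bool]:
    """Kill-islands/fill-holes on every predicted mask, enforce kidney/background
    disjointness and substitute the pie-sector background where the network
    produced none.

    Returns (cleaned ROI set, fallback flags per side, dl_failed flag); the
    failure flag is set when either kidney mask came out empty.
    """
    kl = clean_mask(raw_rois.kidney_left)
    kr = clean_mask(raw_rois.kidney_right)
    overlap = kl & kr
    if overlap.any():
        # contested pixels belong to neither side; re-clean to stay connected
        kl = clean_mask(kl & ~overlap)
        kr = clean_mask(kr & ~overlap)
    failed = not kl.any() or not kr.any()
    kidneys = kl | kr
    bg = {
        "left": clean_mask(raw_rois.bg_left) & ~kidneys,
        "right": clean_mask(raw_rois.bg_right) & ~kidneys,
    }
    fallback = {side: not bg[side].any() for side in ("left", "right")}
    if not failed:
        for side, kid in (("left", kl), ("right", kr)):
            if not fallback[side]:
                continue
            # widen the sector progressively if the kidney sits at the edge
            for half_angle in (bg_config.half_angle_deg, 60.0, 90.0):
                try:
                    cfg = dataclasses.replace(bg_config, half_angle_deg=half_angle)
                    bg[side] = auto_background_roi(kid, side, cfg) & ~kidneys
                except roi_tools.EmptyBackgroundError:
                    continue
                if bg[side].any():
                    break
            else:
                failed = True
    cleaned = RoiSet(kl, kr, bg["left"], bg["right"], provenance="deep-learning")
    return cleaned, fallback, failed


def _norm_gfr(result: GfrResult) -> tuple[float, float, float]:
    left = result.left.gfr_normalized if result.left.gfr_normalized is not None else np.nan
    right = result.right.gfr_normalized if result.right.gfr_normalized is not None else np.nan
    return left, right, result.total_gfr_normalized


def run_experiment(config: ExperimentConfig, outdir=None) -> ExperimentReport:
    """Run the full simulate -> train -> predict -> GFR -> evaluate experiment.

    When ``outdir`` is given, writes ``results.csv``, ``report.json`` and
    (optionally) scatter / Bland-Altman plots there.  Fully deterministic for
    a fixed config.
    """
    t0 = time.time()
    scenes, scans = simulate_cohort(config)
    n = len(scans)
    log.info("simulated %d phantoms in %.1fs", n, time.time() - t0)

    gt_results = [
        gates_gfr(scan, scene.truth.rois, config.gates, depths=scene.truth.depths())
        for scan, scene in zip(scans, scenes)
    ]

    tc = config.train_config()
    stacks = [build_input_stack(scan, tc) for scan in scans]
    labels = [roiset_to_labels(scene.truth.rois, tc.input_size) for scene in scenes]
    plan = make_fold_plan(n, tc.folds, config.seed)

    t0 = time.time()
    models = train(list(zip(stacks, labels)), plan, tc)
    log.info("trained %d rotations in %.1fs", len(models), time.time() - t0)

    per_rotation = []
    for model, (_, test_idx) in zip(models, plan.rotations):
        per_rotation.append({int(i): predict_roiset(model, stacks[i]) for i in test_idx})
    pooled = aggregate_folds(per_rotation, range(n))

    rows = []
    fallback_counts = {"left": 0, "right": 0}
    n_failed = 0
    for i, (scan, scene) in enumerate(zip(scans, scenes)):
        raw_rois, _ = pooled[i]
        dl_rois, fallback, failed = postprocess_prediction(raw_rois, config.background)
        truth_rois = scene.truth.rois
        row = {
            "scan_id": scan.scan_id,
            "dice_lk": dice(truth_rois.kidney_left, dl_rois.kidney_left),
            "dice_rk": dice(truth_rois.kidney_right, dl_rois.kidney_right),
            "dice_bg_left": dice(truth_rois.bg_left, dl_rois.bg_left),
            "dice_bg_right": dice(truth_rois.bg_right, dl_rois.bg_right),
            "fallback_bg_left": fallback["left"],
            "fallback_bg_right": fallback["right"],
            "dl_failed": failed,
        }
        for side in ("left", "right"):
            fallback_counts[side] += int(fallback[side])
        gl, gr, gt_tot = _norm_gfr(gt_results[i])
        row.update(gfr_gt_left=gl, gfr_gt_right=gr, gfr_gt_total=gt_tot)
        if failed:
            n_failed += 1
            row.update(gfr_dl_left=np.nan, gfr_dl_right=np.nan, gfr_dl_total=np.nan)
        else:
            dl_res = gates_gfr(scan, dl_rois, config.gates, depths=scene.truth.depths())
            dl, dr, dl_tot = _norm_gfr(dl_res)
            row.update(gfr_dl_left=dl, gfr_dl_right=dr, gfr_dl_total=dl_tot)
        rows.append(row)

    table = pd.DataFrame(rows, columns=CSV_COLUMNS)
    report = evaluate_table(table, config.evaluation)
    report.fallback_counts = fallback_counts
    report.n_failed = n_failed

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "results.csv", index=False, float_format="%.6f")
        (outdir / "report.json").write_text(json.dumps(report.summary_dict(), indent=2))
        if config.make_plots:
            _write_plots(table, report, outdir)
    return report


def evaluate_table(table: pd.DataFrame, evaluation: EvaluationSection = EvaluationSection()) -> ExperimentReport:
    """Pooled agreement statistics from a per-scan GFR table."""
    ok = table[~table["dl_failed"].astype(bool)]
    agreement = {}
    for key, gt_col, dl_col in (
        ("left", "gfr_gt_left", "gfr_dl_left"),
        ("right", "gfr_gt_right", "gfr_dl_right"),
        ("total", "gfr_gt_total", "gfr_dl_total"),
    ):
        if len(ok) >= 3:
            agreement[key] = compute_agreement(
                ok[gt_col].to_numpy(),
                ok[dl_col].to_numpy(),
                abs_threshold=evaluation.abs_threshold,
                rel_thresholds=evaluation.rel_thresholds,
            )
        else:
            nan = float("nan")
            agreement[key] = AgreementReport(
                n=len(ok), ccc=nan, ccc_ci=(nan, nan), slope=nan, slope_ci=(nan, nan),
                bias=nan, loa_low=nan, loa_high=nan, frac_abs_lt=nan,
                frac_rel_lt={float(t): nan for t in evaluation.rel_thresholds},
                abs_threshold=evaluation.abs_threshold,
                rel_thresholds=tuple(evaluation.rel_thresholds),
            )
    dice_mean = {
        "kidney_left": float(table["dice_lk"].mean()),
        "kidney_right": float(table["dice_rk"].mean()),
        "background": float(table[["dice_bg_left", "dice_bg_right"]].to_numpy().mean()),
    }
    return ExperimentReport(
        table=table,
        agreement=agreement,
        dice_mean=dice_mean,
        fallback_counts={
            "left": int(table["fallback_bg_left"].sum()),
            "right": int(table["fallback_bg_right"].sum()),
        },
        n_failed=int(table["dl_failed"].sum()),
        n_scans=len(table),
    )


def _write_plots(table: pd.DataFrame, report: ExperimentReport, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = table[~table["dl_failed"].astype(bool)]
    keys = [("left", "gfr_gt_left", "gfr_dl_left"), ("right", "gfr_gt_right", "gfr_dl_right"), ("total", "gfr_gt_total", "gfr_dl_total")]

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, (key, gcol, dcol) in zip(axes, keys):
        ax.scatter(ok[gcol], ok[dcol], s=8, alpha=0.6)
        lims = [0, max(ok[gcol].max(), ok[dcol].max()) * 1.05]
        ax.plot(lims, lims, "k--", lw=1)
        rep = report.agreement[key]
        ax.set_title(f"{key}: CCC {rep.ccc:.3f}, slope {rep.slope:.3f}")
        ax.set_xlabel("GT-ROI GFR (mL/min/1.73 m$^2$)")
        ax.set_ylabel("DL-ROI GFR (mL/min/1.73 m$^2$)")
    fig.tight_layout()
    fig.savefig(outdir / "scatter.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, (key, gcol, dcol) in zip(axes, keys):
        mean = (ok[gcol] + ok[dcol]) / 2.0
        diff = ok[gcol] - ok[dcol]
        rep = report.agreement[key]
        ax.scatter(mean, diff, s=8, alpha=0.6)
        for y, style in ((rep.bias, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
            ax.axhline(y, color="k", ls=style, lw=1)
        ax.set_title(f"{key}: bias {rep.bias:.2f} [{rep.loa_low:.2f}, {rep.loa_high:.2f}]")
        ax.set_xlabel("mean GFR")
        ax.set_ylabel("GT - DL")
    fig.tight_layout()
    fig.savefig(outdir / "bland_altman.png", dpi=120)
    plt.close(fig)
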