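"""Synthetic dynamic renogram phantoms with ground truth known by construction.

The forward model inverts the Gates computation: given a true total GFR and a
left/right split, per-kidney percent uptake follows from the linear Gates
relation, and kidney count amplitudes are calibrated so that the
depth-attenuated, background-subtracted rate in the 2-3 minute window divided
by the decay-corrected injected counts reproduces that uptake exactly in the
noiseless case.  Every downstream stage is therefore testable against exact
ground truth.

The module also builds synthetic scan registries for the exclusion-criteria
filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage import draw, measure

from .core import AcquisitionMeta, DynamicRenogram, PatientInfo, RoiSet
from .gates import GatesConfig, injected_counts, kidney_depth
from .roi_tools import BackgroundRoiConfig, auto_background_roi

__all__ = [
    "PatientRanges",
    "KineticParams",
    "PhantomTruth",
    "PhantomScene",
    "ScanRecord",
    "sample_patient",
    "make_kidney_masks",
    "forward_uptake",
    "simulate_renogram",
    "sample_scene",
    "apply_exclusion_criteria",
    "make_registry",
    "EXCLUSION_ORDER",
]


@dataclass(frozen=True)
class PatientRanges:
    age: tuple[int, int] = (16, 90)
    weight_kg: tuple[float, float] = (45.0, 110.0)
    height_cm: tuple[float, float] = (145.0, 195.0)
    p_male: float = 0.5

    def __post_init__(self) -> None:
        for name in ("age", "weight_kg", "height_cm"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class KineticParams:
    """Shape parameters for the simulated activity curves.

    The plasma/background curve is a biexponential a1*exp(-alpha1*t) +
    a2*exp(-alpha2*t) (t in minutes, normalised to 1 at t=0).  The kidney
    uptake curve is a gamma variate rising monotonically to a peak; with
    ``excretion`` off the curve holds its plateau after the peak.
    """

    a1: float = 0.7
    alpha1_per_min: float = math.log(2) / 3.0
    a2: float = 0.3
    alpha2_per_min: float = math.log(2) / 90.0
    uptake_shape_alpha: float = 3.0
    uptake_peak_min: float = 3.5
    excretion: bool = False

    def plasma(self, t_min: np.ndarray) -> np.ndarray:
        return self.a1 * np.exp(-self.alpha1_per_min * t_min) + self.a2 * np.exp(
            -self.alpha2_per_min * t_min
        )

    def uptake_shape(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        tp, a = self.uptake_peak_min, self.uptake_shape_alpha
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(t > 0, (t / tp) ** a * np.exp(a * (1.0 - t / tp)), 0.0)
        if not self.excretion:
            g = np.where(t >= tp, 1.0, g)
        return g


@dataclass
class PhantomTruth:
    true_total_gfr: float
    split_left: float
    depth_left_cm: float
    depth_right_cm: float
    rois: RoiSet  # ground-truth kidney and background masks
    kinetics: KineticParams = field(default_factory=KineticParams)
    background_level: float = 10.0  # counts/pixel/frame at t=0
    liver_present: bool = False

    def __post_init__(self) -> None:
        if self.true_total_gfr < 0:
            raise ValueError("true_total_gfr must be >= 0")
        if not (0.0 < self.split_left < 1.0):
            raise ValueError("split_left must be in (0, 1)")
        if self.depth_left_cm <= 0 or self.depth_right_cm <= 0:
            raise ValueError("depths must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")

    @property
    def split_right(self) -> float:
        return 1.0 - self.split_left

    def depths(self) -> dict[str, float]:
        return {"left": self.depth_left_cm, "right": self.depth_right_cm}


@dataclass
class PhantomScene:
    scan_id: str
    patient: PatientInfo
    truth: PhantomTruth
    meta: AcquisitionMeta


def sample_patient(rng_seed: int, config: PatientRanges = PatientRanges()) -> PatientInfo:
    rng = np.random.default_rng(rng_seed)
    age = int(rng.integers(config.age[0], config.age[1] + 1))
    sex = "male" if rng.random() < config.p_male else "female"
    weight = float(rng.uniform(*config.weight_kg))
    height = float(rng.uniform(*config.height_cm))
    return PatientInfo(age=age, sex=sex, weight_kg=weight, height_cm=height)


def _one_ellipse(center, axes, tilt_deg, grid) -> np.ndarray:
    mask = np.zeros((grid, grid), dtype=bool)
    rr, cc = draw.ellipse(
        center[0],
        center[1],
        axes[0] / 2.0,
        axes[1] / 2.0,
        shape=(grid, grid),
        rotation=math.radians(tilt_deg % 180.0),
    )
    mask[rr, cc] = True
    return mask


def make_kidney_masks(
    centers: Sequence[Sequence[float]],
    axes: Sequence[float] | Sequence[Sequence[float]],
    tilt: float | Sequence[float] = 0.0,
    grid: int = 64,
) -> RoiSet:
    """Rasterise two elliptical kidney masks on the raw grid.

    ``centers`` are (row, col) pairs; ``axes`` are full axis lengths
    (row-extent, col-extent), shared or per kidney; ``tilt`` in degrees.
    The kidney whose centroid lies in the higher-column half is labelled
    "right" (patient's right kidney on the image's right half).
    """
    if len(centers) != 2:
        raise ValueError("need exactly two kidney centres")
    axes = np.asarray(axes, dtype=float)
    if axes.ndim == 1:
        axes = np.stack([axes, axes])
    tilts = np.broadcast_to(np.asarray(tilt, dtype=float), (2,))

    masks = [_one_ellipse(centers[i], axes[i], tilts[i], grid) for i in range(2)]
    for m in masks:
        if not m.any():
            raise ValueError("ellipse rasterised to an empty mask")
        if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
            raise ValueError("kidney mask touches the image border")
        if measure.label(m, connectivity=2).max() != 1:
            raise ValueError("kidney mask not a single connected component")
    if np.any(masks[0] & masks[1]):
        raise ValueError("kidney ellipses overlap")

    # higher centroid column = image right half = patient's right kidney
    cols = [np.mean(np.nonzero(m)[1]) for m in masks]
    right = masks[int(np.argmax(cols))]
    left = masks[int(np.argmin(cols))]
    empty = np.zeros((grid, grid), dtype=bool)
    return RoiSet(left, right, empty.copy(), empty.copy(), provenance="phantom-truth")


def forward_uptake(
    true_total_gfr: float,
    split_left: float,
    gates_coeffs: GatesConfig = GatesConfig(),
) -> tuple[float, float, float]:
    """Invert the linear Gates relation: GFR -> (total, left, right) % uptake.

    The intercept is negative, so even GFR = 0 maps to a positive uptake.
    """
    if true_total_gfr < 0:
        raise ValueError("GFR must be >= 0")
    u_total = (true_total_gfr - gates_coeffs.gates_intercept) / gates_coeffs.gates_slope
    return u_total, u_total * split_left, u_total * (1.0 - split_left)


def _liver_mask(rois: RoiSet, grid: int) -> np.ndarray:
    """A liver blob superior-lateral to the right kidney, kept clear of all ROIs."""
    rr, cc = np.nonzero(rois.kidney_right)
    if len(rr) == 0:
        return np.zeros((grid, grid), dtype=bool)
    top = rr.min()
    c0 = min(int(cc.mean()) + 4, grid - 10)
    r0 = max(top - 8, 8)
    liver = np.zeros((grid, grid), dtype=bool)
    lr, lc = draw.ellipse(r0, c0, 7, 9, shape=(grid, grid))
    liver[lr, lc] = True
    for m in rois.masks().values():
        liver &= ~m
    return liver


def simulate_renogram(
    patient: PatientInfo,
    truth: PhantomTruth,
    meta: AcquisitionMeta,
    noise: bool = False,
    rng_seed: int = 0,
    gates_config: GatesConfig = GatesConfig(),
) -> DynamicRenogram:
    """Forward-simulate a dynamic renogram for a phantom truth.

    Expected per-frame counts are a background plane (biexponential plasma
    time course), per-kidney activity following the uptake curve, and an
    optional liver blob.  Kidney amplitudes are calibrated so the Gates
    pipeline run with the truth ROIs and depths recovers ``true_total_gfr``
    exactly in the noiseless case.  ``noise=True`` draws Poisson counts.
    """
    grid = meta.matrix_size
    for name, m in truth.rois.masks().items():
        if m.shape != (grid, grid):
            raise ValueError(f"mask {name} shape {m.shape} not on {grid}x{grid} grid")
    if truth.background_level < 0:
        raise ValueError("negative background level")

    t_min = meta.frame_mid_times() / 60.0
    plasma = truth.kinetics.plasma(t_min)  # background time course
    shape = truth.kinetics.uptake_shape(t_min)

    lo, hi = gates_config.window_frames
    window_shape_sum = shape[lo - 1 : hi].sum()
    window_minutes = (hi - lo + 1) * meta.frame_duration_s / 60.0
    q_inj = injected_counts(meta, gates_config.half_life_h)
    _, u_left, u_right = forward_uptake(truth.true_total_gfr, truth.split_left, gates_config)

    expected = truth.background_level * plasma[:, None, None] * np.ones((1, grid, grid))

    for side, uptake, depth in (
        ("left", u_left, truth.depth_left_cm),
        ("right", u_right, truth.depth_right_cm),
    ):
        mask = truth.rois.kidney(side)
        n_pix = int(mask.sum())
        if n_pix == 0:
            continue
        # total mask counts per unit uptake-shape so that the window net rate,
        # depth-corrected and divided by injected counts, equals the uptake
        amplitude = (
            (uptake / 100.0)
            * q_inj
            * math.exp(-gates_config.mu * depth)
            * window_minutes
            / window_shape_sum
        )
        expected += (amplitude / n_pix) * shape[:, None, None] * mask[None, :, :]

    if truth.liver_present:
        liver = _liver_mask(truth.rois, grid)
        expected += 2.0 * truth.background_level * plasma[:, None, None] * liver[None, :, :]

    if noise:
        rng = np.random.default_rng(rng_seed)
        counts = rng.poisson(expected).astype(np.int64)
    else:
        counts = expected
    return DynamicRenogram(counts=counts, meta=meta, patient=patient)


def sample_scene(
    rng_seed: int,
    gfr_range: tuple[float, float] = (20.0, 150.0),
    split_range: tuple[float, float] = (0.35, 0.65),
    background_range: tuple[float, float] = (5.0, 20.0),
    liver: bool = False,
    patient_ranges: PatientRanges = PatientRanges(),
    gates_config: GatesConfig = GatesConfig(),
    bg_config: BackgroundRoiConfig = BackgroundRoiConfig(),
    grid: int = 64,
    scan_id: str | None = None,
) -> PhantomScene:
    """Draw a random but geometrically valid phantom scene.

    Kidney geometry is jittered within safe bounds; ground-truth background
    ROIs use the pie-sector construction so they are consistent with the
    laterality convention.  Retries (bounded) on the rare geometry clash.
    """
    rng = np.random.default_rng(rng_seed)
    patient = sample_patient(int(rng.integers(0, 2**31 - 1)), patient_ranges)

    for _ in range(20):
        try:
            centers = (
                (rng.uniform(28, 36), rng.uniform(17, 23)),
                (rng.uniform(28, 36), rng.uniform(41, 47)),
            )
            axes = (
                (rng.uniform(14, 21), rng.uniform(9, 14)),
                (rng.uniform(14, 21), rng.uniform(9, 14)),
            )
            tilt = (rng.uniform(-25, 25), rng.uniform(-25, 25))
            rois = make_kidney_masks(centers, axes, tilt, grid)
            rois.bg_left = auto_background_roi(rois.kidney_left, "left", bg_config, grid)
            rois.bg_right = auto_background_roi(rois.kidney_right, "right", bg_config, grid)
            rois.validate_disjoint()
            if np.any(rois.bg_left & rois.bg_right):
                raise ValueError("background sectors overlap")
            break
        except ValueError:
            continue
    else:
        raise RuntimeError("could not sample a valid kidney geometry")

    pre = float(rng.uniform(1.8e6, 2.6e6))
    meta = AcquisitionMeta(
        syringe_pre_counts=pre,
        syringe_post_counts=0.08 * pre,
        t_pre=0.0,
        t_inj=120.0,
        t_post=180.0,
    )
    truth = PhantomTruth(
        true_total_gfr=float(rng.uniform(*gfr_range)),
        split_left=float(rng.uniform(*split_range)),
        depth_left_cm=kidney_depth(patient, "left", gates_config.depth_formula),
        depth_right_cm=kidney_depth(patient, "right", gates_config.depth_formula),
        rois=rois,
        background_level=float(rng.uniform(*background_range)),
        liver_present=liver,
    )
    return PhantomScene(
        scan_id=scan_id or f"phantom-{rng_seed:08d}",
        patient=patient,
        truth=truth,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# exclusion-criteria registry filter


@dataclass(frozen=True)
class ScanRecord:
    single_kidney: bool
    split_function_pct: float  # the smaller side's split function
    n_frames: int
    age: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.split_function_pct <= 100.0):
            raise ValueError("split_function_pct must be in [0, 100]")


EXCLUSION_ORDER = ("single_kidney", "low_split_function", "frame_count", "age")


def apply_exclusion_criteria(
    records: Sequence[ScanRecord],
    expected_frames: int = 80,
) -> tuple[list[ScanRecord], dict[str, int]]:
    """Sequential exclusion filter: single kidney, split function < 20%,
    frame count != 80, age <= 15.  The first matching criterion tallies the
    record, mirroring a flow-diagram accounting.
    """
    tally = {k: 0 for k in EXCLUSION_ORDER}
    kept: list[ScanRecord] = []
    for rec in records:
        if rec.single_kidney:
            tally["single_kidney"] += 1
        elif rec.split_function_pct < 20.0:
            tally["low_split_function"] += 1
        elif rec.n_frames != expected_frames:
            tally["frame_count"] += 1
        elif rec.age <= 15:
            tally["age"] += 1
        else:
            kept.append(rec)
    return kept, tally


def make_registry(
    rng_seed: int,
    total: int = 29550,
    n_single_kidney: int = 3334,
    n_low_split: int = 1653,
    n_bad_frames: int = 178,
    n_young: int = 21,
) -> list[ScanRecord]:
    """A synthetic scan registry with mutually exclusive exclusion flags,
    shuffled into a random order."""
    n_flagged = n_single_kidney + n_low_split + n_bad_frames + n_young
    if n_flagged > total:
        raise ValueError("flag counts exceed registry size")
    rng = np.random.default_rng(rng_seed)

    def normal_record() -> ScanRecord:
        return ScanRecord(
            single_kidney=False,
            split_function_pct=float(rng.uniform(25.0, 50.0)),
            n_frames=80,
            age=int(rng.integers(16, 91)),
        )

    records: list[ScanRecord] = []
    for _ in range(n_single_kidney):
        rec = normal_record()
        records.append(replace(rec, single_kidney=True))
    for _ in range(n_low_split):
        rec = normal_record()
        records.append(replace(rec, split_function_pct=float(rng.uniform(0.0, 19.9))))
    for _ in range(n_bad_frames):
        rec = normal_record()
        records.append(replace(rec, n_frames=int(rng.choice([40, 79, 81, 160]))))
    for _ in range(n_young):
        rec = normal_record()
        records.append(replace(rec, age=int(rng.integers(1, 16))))
    for _ in range(total - n_flagged):
        records.append(normal_record())

    order = rng.permutation(len(records))
    return [records[i] for i in order]
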