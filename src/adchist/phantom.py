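"""Synthetic multi-b-value DWI phantom cohorts with known ground truth.

Each case is a rectangular voxel grid holding an ellipsoidal rectal
tumor surrounded, from the inside out, by a rectal-wall shell, a shell
of adjacent soft tissue (normal wall, muscle, pelvic organs), suppressed
mesorectal fat, and -- anterior to the tumor at a random distance -- a
high-ADC bladder.  A small low-signal lumen is carved through the tumor
centre.  Every voxel draws a ground-truth ADC from its tissue's
(clipped) normal distribution; the noiseless signal follows the
mono-exponential decay model ``S(b) = S0 exp(-b ADC)`` and magnitude
(Rician) noise is added per b-value.

Two delineation styles are simulated per case, two readers each:

* *precise* masks trace the tumor label, perturbed per reader by a
  smooth, seeded erosion field of the boundary (delineation
  variability without intensity change);
* *non-precise* masks are, on every slice containing tumor, the filled
  bounding ellipse of the tumor cross-section expanded by a margin,
  with per-reader and per-slice margin perturbations, deliberately
  admitting the surrounding tissues.

Binary prognostic labels are simulated per cohort; the nodal-stage and
mesorectal-fascia labels depend (logistically) on true tumor volume
only, all other labels are independent of the imaging, so tumor volume
is the only feature with genuine prognostic signal.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import ndimage
from scipy.special import expit, logit

from .adcfit import DWISeries, ADCMap
from .voimetrics import VOIMask
from . import io as _io

log = logging.getLogger(__name__)

AXIS_NAMES = ("x", "y", "z")

#: Tissue label codes used in the label map.
LABELS = {
    "background": 0,
    "fat": 1,
    "muscle": 2,
    "bladder": 3,
    "wall": 4,
    "tumor": 5,
    "lumen": 6,
}

ADC_FLOOR = 1e-5  # mm^2/s; per-voxel truth draws are clipped here

__all__ = [
    "LABELS",
    "TissueParams",
    "PhantomConfig",
    "PhantomCase",
    "PhantomConfigError",
    "build_phantom_case",
    "draw_precise_mask",
    "draw_nonprecise_mask",
    "generate_cohort",
    "draw_cohort_labels",
    "case_seed_for",
    "write_case",
    "write_cohort",
]


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration cannot be realised."""


class TissueParams(BaseModel):
    """Signal and diffusion parameters of one tissue compartment.

    ``s0``: proton-density signal (arbitrary units); ``adc_mean`` /
    ``adc_sd``: per-voxel truth ADC distribution in mm^2/s.
    """

    s0: float = Field(ge=0)
    adc_mean: float = Field(ge=0)
    adc_sd: float = Field(ge=0)


def _default_tissues() -> Dict[str, TissueParams]:
    # Bladder urine is fast-diffusing, lumen/air has essentially no
    # signal, fat is SPAIR-suppressed (very low S0, so its fitted ADC is
    # noise-dominated near zero).
    return {
        "background": TissueParams(s0=5.0, adc_mean=1e-4, adc_sd=5e-5),
        "fat": TissueParams(s0=60.0, adc_mean=3e-4, adc_sd=1e-4),
        "muscle": TissueParams(s0=800.0, adc_mean=1.6e-3, adc_sd=5e-4),
        "bladder": TissueParams(s0=1200.0, adc_mean=3.0e-3, adc_sd=3e-4),
        "wall": TissueParams(s0=900.0, adc_mean=1.7e-3, adc_sd=5.5e-4),
        "tumor": TissueParams(s0=1000.0, adc_mean=1.44e-3, adc_sd=4e-4),
        "lumen": TissueParams(s0=5.0, adc_mean=1e-4, adc_sd=5e-5),
    }


class PhantomConfig(BaseModel):
    """Study conditions of a simulated cohort.

    Defaults mirror a 1.5 T rectal staging protocol: six b-values
    (0-1000 s/mm^2), 1.82 x 2.26 mm in-plane voxels and 5.5 mm
    centre-to-centre slice spacing (5 mm thickness + 0.5 mm gap), tumor
    ADC 1.44e-3 +/- 0.40e-3 mm^2/s within a case, and a between-case
    spread of the tumor mean (``case_adc_shift_sd``) matching the
    between-patient variation of mean tumor ADC.
    """

    model_config = ConfigDict(validate_assignment=True)

    grid_shape: Tuple[int, int, int] = (64, 64, 20)
    voxel_spacing: Tuple[float, float, float] = (1.82, 2.26, 5.5)
    b_values: Tuple[float, ...] = (0.0, 25.0, 50.0, 100.0, 500.0, 1000.0)
    tissue_params: Dict[str, TissueParams] = Field(default_factory=_default_tissues)
    tumor_axes_mm: Tuple[Tuple[float, float], Tuple[float, float], Tuple[float, float]] = (
        (7.0, 13.0),
        (7.0, 13.0),
        (6.0, 12.0),
    )
    wall_thickness_mm: float = 4.0
    organ_shell_mm: float = 12.0
    bladder_axes_mm: Tuple[Tuple[float, float], Tuple[float, float], Tuple[float, float]] = (
        (10.0, 18.0),
        (8.0, 14.0),
        (8.0, 14.0),
    )
    bladder_gap_mm: Tuple[float, float] = (0.5, 3.0)
    lumen_radius_mm: Tuple[float, float] = (3.0, 4.5)
    margin_mm: float = 5.0
    noise_sigma: float = 15.0
    reader_jitter: float = 0.8
    case_adc_shift_sd: float = 0.22e-3
    seed: int = 0

    @field_validator("voxel_spacing")
    @classmethod
    def _spacing_positive(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("all voxel spacings must be > 0")
        return v

    @field_validator("b_values")
    @classmethod
    def _b_ordered(cls, v):
        if len(v) < 2 or v[0] != 0 or any(b2 <= b1 for b1, b2 in zip(v, v[1:])):
            raise ValueError("b_values must be strictly increasing and start at 0")
        return v

    @field_validator("noise_sigma", "margin_mm", "reader_jitter", "wall_thickness_mm")
    @classmethod
    def _non_negative(cls, v):
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    @model_validator(mode="after")
    def _tissues_complete(self):
        missing = set(LABELS) - set(self.tissue_params)
        if missing:
            raise ValueError(f"tissue_params missing: {sorted(missing)}")
        return self

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz


@dataclass
class PhantomCase:
    """One simulated patient: signals, truth, masks."""

    case_id: str
    dwi: DWISeries
    label_map: np.ndarray
    truth_adc: ADCMap
    precise_masks: Dict[str, VOIMask]
    nonprecise_masks: Dict[str, VOIMask]
    tumor_center_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))
    tumor_axes_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.label_map == LABELS["tumor"]

    @property
    def true_tumor_volume_cm3(self) -> float:
        sx, sy, sz = self.dwi.voxel_spacing
        return float(self.tumor_mask.sum()) * sx * sy * sz / 1000.0


def _mm_grids(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _ellipsoid(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    gx, gy, gz = _mm_grids(shape, spacing)
    q = (
        ((gx - center_mm[0]) / semi_mm[0]) ** 2
        + ((gy - center_mm[1]) / semi_mm[1]) ** 2
        + ((gz - center_mm[2]) / semi_mm[2]) ** 2
    )
    return q <= 1.0


def case_seed_for(master_seed: int, case_id: str) -> int:
    """Stable per-case seed: hash of (master_seed, case_id), < 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{case_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_phantom_case(config: PhantomConfig, case_seed: int, case_id: str = "case") -> PhantomCase:
    """Simulate one patient with ground truth and four reader masks.

    The tumor is an ellipsoid with per-case random semi-axes and
    position, kept away from the volume edge; the same seed reproduces
    the case bit-for-bit.
    """
    rng = np.random.default_rng(case_seed)
    shape, spacing = config.grid_shape, config.voxel_spacing
    extent = config.extent_mm

    axes = np.array([rng.uniform(lo, hi) for lo, hi in config.tumor_axes_mm])
    pad = config.margin_mm + 2.0
    center = np.empty(3)
    for i in range(3):
        lo = axes[i] + (pad if i < 2 else spacing[2])
        hi = extent[i] - axes[i] - (pad if i < 2 else spacing[2])
        if lo > hi:
            raise PhantomConfigError(
                f"tumor semi-axis {AXIS_NAMES[i]} = {axes[i]:.1f} mm does not "
                f"fit in the {extent[i]:.1f} mm grid extent"
            )
        center[i] = rng.uniform(lo, hi)

    lab = np.full(shape, LABELS["fat"], dtype=np.int8)
    lab[_ellipsoid(shape, spacing, center, axes + config.organ_shell_mm)] = LABELS["muscle"]

    # bladder anterior (-y) of the tumor at a random gap from the tumor
    # surface; the wall shell is painted afterwards so a close bladder
    # never breaches the rectal wall itself
    b_axes = np.array([rng.uniform(lo, hi) for lo, hi in config.bladder_axes_mm])
    gap = rng.uniform(*config.bladder_gap_mm)
    b_center = center.copy()
    b_center[1] = center[1] - (axes[1] + gap + b_axes[1])
    lab[_ellipsoid(shape, spacing, b_center, b_axes)] = LABELS["bladder"]

    lab[_ellipsoid(shape, spacing, center, axes + config.wall_thickness_mm)] = LABELS["wall"]
    tumor = _ellipsoid(shape, spacing, center, axes)
    lab[tumor] = LABELS["tumor"]

    l_r = rng.uniform(*config.lumen_radius_mm, size=2)
    l_center = center + np.array(
        [rng.uniform(-0.3, 0.3) * axes[0], rng.uniform(-0.3, 0.3) * axes[1], 0.0]
    )
    lab[
        _ellipsoid(shape, spacing, l_center, (l_r[0], l_r[1], 0.8 * axes[2]))
    ] = LABELS["lumen"]

    # per-voxel truth ADC and S0; tumor mean gets a per-case shift to
    # emulate between-patient variation
    case_shift = rng.normal(0.0, config.case_adc_shift_sd)
    truth = np.empty(shape, dtype=float)
    s0 = np.empty(shape, dtype=float)
    for name, code in LABELS.items():
        sel = lab == code
        if not sel.any():
            continue
        tp = config.tissue_params[name]
        mean = tp.adc_mean + (case_shift if name == "tumor" else 0.0)
        truth[sel] = np.maximum(
            rng.normal(mean, tp.adc_sd, size=int(sel.sum())), ADC_FLOOR
        )
        s0[sel] = tp.s0

    b = np.asarray(config.b_values)
    clean = s0[..., None] * np.exp(-truth[..., None] * b)
    if config.noise_sigma > 0:
        sig = config.noise_sigma
        noisy = np.sqrt(
            (clean + rng.normal(0.0, sig, clean.shape)) ** 2
            + rng.normal(0.0, sig, clean.shape) ** 2
        )
    else:
        noisy = clean
    dwi = DWISeries(signal=noisy, b_values=b, voxel_spacing=spacing)
    truth_map = ADCMap(
        adc=truth, voxel_spacing=spacing, fit_valid=np.ones(shape, dtype=bool)
    )

    case = PhantomCase(
        case_id=case_id,
        dwi=dwi,
        label_map=lab,
        truth_adc=truth_map,
        precise_masks={},
        nonprecise_masks={},
        tumor_center_mm=tuple(center),
        tumor_axes_mm=tuple(axes),
    )
    reader_seeds = rng.integers(0, 2**31, size=4)
    case.precise_masks = {
        rid: draw_precise_mask(case, config.reader_jitter, int(seed), reader_id=rid)
        for rid, seed in zip(("R1", "R2"), reader_seeds[:2])
    }
    case.nonprecise_masks = {
        rid: draw_nonprecise_mask(case, config.margin_mm, int(seed), reader_id=rid)
        for rid, seed in zip(("R3", "R4"), reader_seeds[2:])
    }
    return case


def draw_precise_mask(
    case: PhantomCase, reader_jitter: float, reader_seed: int, reader_id: str = "R"
) -> VOIMask:
    """A reader's close tracing of the tumor boundary.

    The tumor label set is eroded by a smooth non-negative random depth
    field of magnitude ``reader_jitter`` (in in-plane voxel units), so
    each reader under-segments the boundary slightly differently;
    ``reader_jitter = 0`` returns the tumor label set exactly and the
    mask always contains the tumor core eroded by ``2 * reader_jitter``.
    """
    tumor = case.tumor_mask
    if not tumor.any():
        raise ValueError("case has no tumor voxels")
    spacing = np.asarray(case.dwi.voxel_spacing)
    if reader_jitter == 0:
        mask = tumor.copy()
    else:
        rng = np.random.default_rng(reader_seed)
        # interior distance in units of the finest spacing, so thick
        # slices are not over-eroded in z
        dist = ndimage.distance_transform_edt(
            tumor, sampling=spacing / spacing.min()
        )
        g = ndimage.gaussian_filter(rng.standard_normal(tumor.shape), sigma=1.5)
        g /= g.std()
        # erosion depth in [0, 2*jitter]: per-reader base depth plus a
        # smooth spatial field, so boundary patches differ between readers
        depth = reader_jitter * np.clip(rng.uniform(0.0, 1.0) + g, 0.0, 2.0)
        mask = tumor & (dist > depth)
        if not mask.any():  # pathological jitter for a tiny tumor
            mask = tumor.copy()
    return VOIMask(
        mask=mask,
        method="precise",
        reader_id=reader_id,
        voxel_spacing=case.dwi.voxel_spacing,
    )


def draw_nonprecise_mask(
    case: PhantomCase, margin_mm: float, reader_seed: int, reader_id: str = "R"
) -> VOIMask:
    """A reader's quick circular/oval delineation with a margin.

    On each slice containing tumor the mask is the filled bounding
    ellipse of the tumor cross-section expanded by ``margin_mm``,
    perturbed by a per-reader margin factor and a small per-slice
    jitter.  The mask deliberately includes the surrounding tissues; it
    is clipped (with a warning) where it would leave the grid.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    tumor = case.tumor_mask
    if not tumor.any():
        raise ValueError("case has no tumor voxels")
    sx, sy, _ = case.dwi.voxel_spacing
    rng = np.random.default_rng(reader_seed)
    factor = rng.uniform(0.95, 1.05)
    mask = np.zeros_like(tumor)
    nx, ny = tumor.shape[:2]
    gx = np.arange(nx)[:, None] * sx
    gy = np.arange(ny)[None, :] * sy
    clipped = False
    for z in range(tumor.shape[2]):
        sl = tumor[:, :, z]
        if not sl.any():
            continue
        ii, jj = np.nonzero(sl)
        cx = (ii.min() + ii.max()) / 2.0 * sx
        cy = (jj.min() + jj.max()) / 2.0 * sy
        add = max(margin_mm * factor + rng.uniform(-0.5, 0.5) * (margin_mm > 0), 0.0)
        # half a voxel of slack keeps every tumor voxel centre inside
        ax = (ii.max() - ii.min()) / 2.0 * sx + 0.51 * sx + add
        ay = (jj.max() - jj.min()) / 2.0 * sy + 0.51 * sy + add
        if cx - ax < 0 or cx + ax > (nx - 1) * sx or cy - ay < 0 or cy + ay > (ny - 1) * sy:
            clipped = True
        # union with the cross-section itself guarantees the bounding
        # ellipse covers every tumor voxel despite grid discretisation
        mask[:, :, z] = (((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 <= 1.0) | sl
    if clipped:
        log.warning("case %s: non-precise VOI clipped at the volume edge", case.case_id)
    return VOIMask(
        mask=mask,
        method="nonprecise",
        reader_id=reader_id,
        voxel_spacing=case.dwi.voxel_spacing,
    )


# ---------------------------------------------------------------------------
# cohorts and labels

#: Baseline prevalence of each positive/poor outcome label.
LABEL_BASE_RATES = {
    "cN": 0.70,
    "cMRF": 0.38,
    "differentiation": 0.15,
    "response": 0.40,
    "metastasis": 0.22,
}

#: Labels whose probability depends on true tumor volume.
VOLUME_LINKED = ("cN", "cMRF")


def draw_cohort_labels(
    case_ids, tumor_volumes_cm3, outcome_effect: float, seed: int
) -> pd.DataFrame:
    """Simulate the binary prognostic labels of a cohort.

    For the volume-linked labels the positive probability is
    ``expit(logit(base) + outcome_effect * z)`` with ``z`` the
    within-cohort z-score of log tumor volume; ``outcome_effect = 0``
    makes every label independent of the imaging.
    """
    vols = np.asarray(tumor_volumes_cm3, dtype=float)
    if vols.size < 2:
        raise ValueError("need at least two cases for cohort labels")
    lv = np.log(vols)
    sd = lv.std(ddof=0)
    z = (lv - lv.mean()) / sd if sd > 0 else np.zeros_like(lv)
    rng = np.random.default_rng(seed)
    data = {"case_id": list(case_ids)}
    for name, base in LABEL_BASE_RATES.items():
        p = expit(logit(base) + outcome_effect * z) if name in VOLUME_LINKED else base
        data[name] = (rng.random(vols.size) < p).astype(int)
    return pd.DataFrame(data).set_index("case_id")


def generate_cohort(
    config: PhantomConfig, n_cases: int, outcome_effect: float = 2.0
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Simulate ``n_cases`` independent patients plus their labels.

    Per-case seeds are stable hashes of ``(config.seed, case_id)``, so a
    cohort extension leaves existing cases unchanged.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2 (group statistics undefined)")
    cases = []
    for i in range(n_cases):
        cid = f"{i + 1:03d}"
        cases.append(
            build_phantom_case(config, case_seed_for(config.seed, cid), case_id=cid)
        )
    labels = draw_cohort_labels(
        [c.case_id for c in cases],
        [c.true_tumor_volume_cm3 for c in cases],
        outcome_effect,
        seed=case_seed_for(config.seed, "labels"),
    )
    return cases, labels


# ---------------------------------------------------------------------------
# on-disk layout


def write_case(case: PhantomCase, outdir) -> None:
    """Write one case's NIfTI volumes and b-value sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cid = case.case_id
    sp = case.dwi.voxel_spacing
    _io.save_nifti(case.dwi.signal, sp, outdir / f"case_{cid}_dwi.nii.gz")
    _io.save_bvals(case.dwi.b_values, outdir / f"case_{cid}.bval")
    _io.save_nifti(case.label_map, sp, outdir / f"case_{cid}_labels.nii.gz", dtype=np.int8)
    _io.save_nifti(case.truth_adc.adc, sp, outdir / f"case_{cid}_truthadc.nii.gz")
    for masks in (case.precise_masks, case.nonprecise_masks):
        for rid, voi in masks.items():
            _io.save_nifti(
                voi.mask.astype(np.uint8),
                sp,
                outdir / f"case_{cid}_mask_{voi.method}_{rid}.nii.gz",
                dtype=np.uint8,
            )


def write_cohort(cases, labels: pd.DataFrame, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        write_case(case, outdir)
    labels.to_csv(outdir / "labels.csv")
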