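"""First-order ADC histogram metrics within a volume of interest.

A VOI (volume of interest) is a 3-D binary mask drawn either *precisely*
(tracing the tumor boundary) or *non-precisely* (a circular/oval region
with a margin that also covers surrounding tissue).  From the ADC values
of the masked voxels this module computes the standard first-order
feature set: minimum, maximum, mean, median, standard deviation,
skewness, kurtosis, every fifth percentile (5th-95th), and the VOI
volume in cm^3.

Conventions (all switchable where noted):

* ADC values are reported on the 1e-3 mm^2/s scale.
* Kurtosis uses the Pearson (non-excess) convention: a normal
  distribution has kurtosis 3.
* Skewness and kurtosis are the biased population moment coefficients
  (``m3/m2^1.5`` and ``m4/m2^2``); set ``bias=False`` for the
  small-sample-corrected variants.
* Percentiles interpolate linearly between order statistics.
* SD uses the n-1 denominator.
* Voxels with an invalid decay fit are excluded from the value sample
  (and from ``n_voxels``) but still count toward the volume, which
  reflects the delineation rather than fit quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

PERCENTILES: tuple[int, ...] = tuple(range(5, 100, 5))

__all__ = [
    "PERCENTILES",
    "VOIMask",
    "HistogramMetrics",
    "extract_voi_values",
    "compute_histogram_metrics",
    "compute_volume",
    "metrics_record",
    "average_readers",
]


@dataclass
class VOIMask:
    """A binary volume-of-interest mask tagged with its provenance.

    ``method`` is ``"precise"`` or ``"nonprecise"``; ``reader_id``
    identifies the (simulated) reader who drew it.
    """

    mask: np.ndarray
    method: str
    reader_id: str
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.method not in ("precise", "nonprecise"):
            raise ValueError("method must be 'precise' or 'nonprecise'")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz


@dataclass
class HistogramMetrics:
    """The full first-order feature vector of one VOI sample.

    All ADC-valued fields are on the 1e-3 mm^2/s scale.  ``skewness`` and
    ``kurtosis`` are NaN when the sample has fewer than three values.
    ``n_voxels`` is the number of sampled (valid-fit) voxels;
    ``volume_cm3`` counts every mask voxel.
    """

    volume_cm3: float
    minimum: float
    maximum: float
    mean: float
    median: float
    sd: float
    skewness: float
    kurtosis: float
    percentiles: dict[int, float]
    n_voxels: int
    n_excluded: int = 0

    def as_record(self) -> dict[str, float]:
        """Flatten to the CSV column layout used across the package."""
        rec = {
            "volume_cm3": self.volume_cm3,
            "min": self.minimum,
            "max": self.maximum,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "skew": self.skewness,
            "kurt": self.kurtosis,
        }
        for p in PERCENTILES:
            rec[f"p{p}"] = self.percentiles[p]
        rec["n_voxels"] = self.n_voxels
        rec["n_excluded"] = self.n_excluded
        return rec


def extract_voi_values(adc_map, voi: VOIMask) -> tuple[np.ndarray, int]:
    """Collect the ADC values (1e-3 mm^2/s) at mask voxels with a valid fit.

    Returns the value sample and the count of mask voxels excluded
    because their fit was invalid.  Raises if the grids differ or no
    masked voxel has a valid fit.
    """
    if voi.mask.shape != adc_map.adc.shape:
        raise ValueError(
            f"mask grid {voi.mask.shape} does not match ADC grid {adc_map.adc.shape}"
        )
    if voi.n_voxels == 0:
        raise ValueError("empty VOI mask")
    usable = voi.mask & adc_map.fit_valid
    n_excluded = int(voi.n_voxels - usable.sum())
    if not usable.any():
        raise ValueError("VOI does not intersect any voxel with a valid fit")
    return adc_map.adc[usable] * 1e3, n_excluded


def compute_histogram_metrics(
    sample,
    voxel_volume_mm3: float,
    n_mask_voxels: int | None = None,
    n_excluded: int = 0,
    bias: bool = True,
    percentile_method: str = "linear",
) -> HistogramMetrics:
    """Compute the first-order feature vector of a value sample.

    Parameters
    ----------
    sample
        ADC values (1e-3 mm^2/s), at least one.
    voxel_volume_mm3
        Volume of one voxel in mm^3.
    n_mask_voxels
        Total mask voxel count for the volume; defaults to the sample
        size (i.e. no excluded voxels).
    bias
        Population (biased) moment coefficients when True (default).
    percentile_method
        Interpolation rule passed to :func:`numpy.percentile`.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if n_mask_voxels is None:
        n_mask_voxels = x.size
    pct = {
        p: float(v)
        for p, v in zip(
            PERCENTILES, np.percentile(x, PERCENTILES, method=percentile_method)
        )
    }
    if x.size >= 3:
        skew = float(stats.skew(x, bias=bias))
        kurt = float(stats.kurtosis(x, fisher=False, bias=bias))
    else:
        skew = kurt = float("nan")
    return HistogramMetrics(
        volume_cm3=n_mask_voxels * voxel_volume_mm3 / 1000.0,
        minimum=float(x.min()),
        maximum=float(x.max()),
        mean=float(x.mean()),
        median=float(np.percentile(x, 50, method=percentile_method)),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        skewness=skew,
        kurtosis=kurt,
        percentiles=pct,
        n_voxels=int(x.size),
        n_excluded=int(n_excluded),
    )


def compute_volume(voi: VOIMask) -> float:
    """VOI volume in cm^3: true-voxel count x voxel volume / 1000."""
    return voi.n_voxels * voi.voxel_volume_mm3 / 1000.0


def metrics_record(adc_map, voi: VOIMask, **kwargs) -> dict[str, float]:
    """One flat metrics row (without identifiers) for a (map, VOI) pair."""
    values, n_excluded = extract_voi_values(adc_map, voi)
    hm = compute_histogram_metrics(
        values,
        voi.voxel_volume_mm3,
        n_mask_voxels=voi.n_voxels,
        n_excluded=n_excluded,
        **kwargs,
    )
    return hm.as_record()


def average_readers(metrics, value_columns=None):
    """Average a long metrics table over readers within (case, method).

    ``metrics`` is the per-(case, method, reader) DataFrame produced by
    the pipeline.  Returns a DataFrame indexed by (case_id, method).
    """
    drop = {"reader"}
    if value_columns is None:
        value_columns = [
            c
            for c in metrics.columns
            if c not in drop | {"case_id", "method"}
        ]
    return (
        metrics.groupby(["case_id", "method"], sort=True)[list(value_columns)]
        .mean()
    )
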