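"""Voxelwise apparent diffusion coefficient (ADC) estimation.

In diffusion-weighted MRI the signal of a voxel decays approximately
mono-exponentially with the diffusion weighting ``b`` (s/mm^2)::

    S(b) = S0 * exp(-b * ADC)

so that ``ln S(b)`` is linear in ``b`` with slope ``-ADC``.  The default
estimator is ordinary least squares on ``(b, ln S)`` using every b-value
with a positive signal; a nonlinear least-squares variant on the raw
signal is available for sensitivity checks.  ADC is physically
non-negative: a fit with a positive slope (signal increasing with b,
which happens in pure-noise voxels) is clipped to 0 and kept valid.

Units: b-values in s/mm^2, ADC in mm^2/s.  Reporting elsewhere in the
package uses the conventional 1e-3 mm^2/s scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DWISeries", "ADCMap", "fit_adc_voxel", "compute_adc_map"]


@dataclass
class DWISeries:
    """A 4-D multi-b-value diffusion-weighted series.

    Parameters
    ----------
    signal
        Non-negative array indexed ``(x, y, z, b)``.
    b_values
        Strictly increasing b-values (s/mm^2), one per 4th-axis plane.
    voxel_spacing
        Voxel spacing in mm, ``(sx, sy, sz)``; ``sz`` is the
        centre-to-centre slice spacing (thickness + gap).
    """

    signal: np.ndarray
    b_values: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, b)")
        if self.signal.shape[-1] != self.b_values.size:
            raise ValueError(
                f"signal has {self.signal.shape[-1]} b-planes but "
                f"{self.b_values.size} b-values were given"
            )
        if self.b_values.size < 2:
            raise ValueError("at least two b-values are required")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive lengths in mm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ADCMap:
    """A 3-D ADC map (mm^2/s) with per-voxel fit validity.

    ``adc`` is finite and non-negative wherever ``fit_valid`` is true and
    0 elsewhere.  ``s0`` optionally stores the fitted intercept plane.
    """

    adc: np.ndarray
    voxel_spacing: tuple[float, float, float]
    fit_valid: np.ndarray
    s0: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        self.fit_valid = np.asarray(self.fit_valid, dtype=bool)
        if self.adc.ndim != 3:
            raise ValueError("adc must be 3-D")
        if self.fit_valid.shape != self.adc.shape:
            raise ValueError("fit_valid must match the adc grid")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz


def _ols_loglinear(signal: np.ndarray, b: np.ndarray):
    """Vectorised log-linear OLS over the last axis.

    Per voxel, b-points with non-positive signal are dropped; the voxel is
    invalid if fewer than two positive points remain.  Returns
    ``(adc, s0, valid)`` with the leading shape of ``signal``.
    """
    pos = signal > 0
    n = pos.sum(axis=-1)
    # log only where positive; the placeholder 1.0 is masked out below
    y = np.where(pos, np.log(np.where(pos, signal, 1.0)), 0.0)
    w = pos.astype(float)
    sb = w @ b
    sbb = w @ (b * b)
    sy = y.sum(axis=-1)
    sby = y @ b
    denom = n * sbb - sb * sb
    valid = (n >= 2) & (denom > 0)
    safe = np.where(valid, denom, 1.0)
    slope = np.where(valid, (n * sby - sb * sy) / safe, 0.0)
    intercept = np.where(valid, (sy - slope * sb) / np.maximum(n, 1), 0.0)
    adc = np.where(valid, np.maximum(-slope, 0.0), 0.0)
    s0 = np.where(valid, np.exp(intercept), 0.0)
    return adc, s0, valid


def _nls_voxel(signal: np.ndarray, b: np.ndarray, adc0: float, s00: float):
    from scipy.optimize import curve_fit

    def model(bv, s0, d):
        return s0 * np.exp(-bv * d)

    try:
        popt, _ = curve_fit(
            model, b, signal, p0=[max(s00, 1e-6), max(adc0, 1e-12)], maxfev=5000
        )
    except RuntimeError:
        return adc0, s00
    return max(float(popt[1]), 0.0), float(popt[0])


def fit_adc_voxel(
    signals, b_values, method: str = "ols"
) -> tuple[float, float, bool]:
    """Fit one voxel's decay curve.

    Parameters
    ----------
    signals, b_values
        Equal-length sequences (>= 2 points).
    method
        ``"ols"`` (log-linear, default) or ``"nls"`` (nonlinear on the raw
        signal, initialised from the OLS solution).

    Returns
    -------
    (adc, s0, valid)
        ADC in mm^2/s (clipped to >= 0), the fitted intercept in signal
        units, and whether at least two positive signals supported the
        fit.  On an invalid fit ``adc`` and ``s0`` are 0.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape or s.ndim != 1:
        raise ValueError("signals and b_values must be equal-length 1-D sequences")
    if s.size < 2:
        raise ValueError("at least two measurements are required")
    adc, s0, valid = _ols_loglinear(s[None, :], b)
    adc_v, s0_v, ok = float(adc[0]), float(s0[0]), bool(valid[0])
    if method == "nls" and ok:
        adc_v, s0_v = _nls_voxel(s, b, adc_v, s0_v)
    elif method not in ("ols", "nls"):
        raise ValueError(f"unknown fit method {method!r}")
    return adc_v, s0_v, ok


def compute_adc_map(dwi: DWISeries, method: str = "ols", keep_s0: bool = True) -> ADCMap:
    """Apply :func:`fit_adc_voxel` to every voxel of a series.

    The spacing of the input series is propagated unchanged.  With
    ``method="nls"`` the nonlinear refinement runs per voxel and is only
    intended for small sensitivity experiments.
    """
    if method not in ("ols", "nls"):
        raise ValueError(f"unknown fit method {method!r}")
    b = dwi.b_values
    flat = dwi.signal.reshape(-1, b.size)
    adc, s0, valid = _ols_loglinear(flat, b)
    if method == "nls":
        for i in np.flatnonzero(valid):
            adc[i], s0[i] = _nls_voxel(flat[i], b, adc[i], s0[i])
    shape = dwi.shape
    return ADCMap(
        adc=adc.reshape(shape),
        voxel_spacing=dwi.voxel_spacing,
        fit_valid=valid.reshape(shape),
        s0=s0.reshape(shape) if keep_s0 else None,
    )
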