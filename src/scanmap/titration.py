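"""Dissociation-constant estimation from yeast-display titrations.

Binding MFI versus ligand (dimer) concentration is fit to the one-site
saturation hyperbola

    MFI([L]) = Bmax * [L] / (Kd + [L])

by nonlinear least squares with deterministic initialization (Bmax from the
top of the curve, Kd from the concentration nearest half-maximum). A linear
calibration of experimentally fitted Kd values against normalized binding
scores (MFI_ratio) then converts scores of the remaining mutants into
apparent Kd values.

Concentrations are in nM throughout; Kd is reported in the same unit as the
input concentrations, so unit conversion is an exact rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .scan_data import TitrationCurve

__all__ = ["BindingFit", "KdCalibration", "one_site", "fit_one_site",
           "calibrate_kd", "apparent_kd"]


@dataclass(frozen=True)
class BindingFit:
    """One-site fit result: plateau, dissociation constant and uncertainty.

    ``poorly_constrained`` flags curves whose top concentration is below
    Kd/10, where the plateau (and hence Kd) is barely identified.
    """

    variant_id: str
    bmax: float
    kd: float
    se_bmax: float
    se_kd: float
    residual_sse: float
    poorly_constrained: bool = False

    def __post_init__(self) -> None:
        if self.bmax <= 0 or self.kd <= 0:
            raise ValueError("Bmax and Kd must be positive")


@dataclass(frozen=True)
class KdCalibration:
    """Linear map from MFI_ratio score to apparent Kd (nM)."""

    slope: float
    intercept: float
    r: float
    n: int
    kd_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("calibration coefficients must be finite")


def one_site(conc, bmax: float, kd: float) -> np.ndarray:
    """Hyperbolic one-site binding model, strictly increasing in [L] and
    bounded above by Bmax; equals Bmax/2 at [L] = Kd."""
    conc = np.asarray(conc, dtype=float)
    return bmax * conc / (kd + conc)


def fit_one_site(curve: TitrationCurve) -> BindingFit:
    """Fit the one-site model to a titration by nonlinear least squares.

    Initialization is deterministic: Bmax0 = max observed MFI, Kd0 = the
    concentration whose MFI is nearest half-maximum. Standard errors are
    asymptotic (from the fit covariance). A flat (zero-spread) curve is a
    hard error; a curve that never approaches saturation is fitted but
    flagged ``poorly_constrained``.
    """
    conc = np.asarray(curve.concentrations, dtype=float)
    mfi = np.asarray(curve.binding_mfi, dtype=float)
    if np.ptp(mfi) <= 0:
        raise ValueError(f"{curve.variant_id}: degenerate flat titration curve")
    if conc.max() / conc.min() < 100:
        raise ValueError(f"{curve.variant_id}: concentrations must span at least "
                         "two orders of magnitude")
    bmax0 = float(mfi.max())
    kd0 = float(conc[np.argmin(np.abs(mfi - bmax0 / 2))])
    popt, pcov = optimize.curve_fit(
        one_site, conc, mfi, p0=[bmax0, kd0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000)
    bmax, kd = (float(v) for v in popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    resid = mfi - one_site(conc, bmax, kd)
    return BindingFit(
        variant_id=curve.variant_id, bmax=bmax, kd=kd,
        se_bmax=float(se[0]), se_kd=float(se[1]),
        residual_sse=float(resid @ resid),
        poorly_constrained=bool(conc.max() < kd / 10),
    )


def calibrate_kd(pairs) -> KdCalibration:
    """Ordinary least-squares line Kd = slope * MFI_ratio + intercept.

    ``pairs`` is a sequence of (mfi_ratio, kd_nM) reference points, at
    least three. The Pearson correlation of the pairs is reported as the
    fit quality. Tighter binders score higher, so the slope is expected to
    be negative.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (mfi_ratio, kd) tuples")
    if arr.shape[0] < 3:
        raise ValueError(f"need >= 3 reference pairs, got {arr.shape[0]}")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    return KdCalibration(slope=float(res.slope), intercept=float(res.intercept),
                         r=float(res.rvalue), n=arr.shape[0])


def apparent_kd(calibration: KdCalibration, mfi_ratio: float) -> tuple[float, bool]:
    """Apparent Kd (nM) for a score via the linear calibration.

    Values at or below zero are clamped to the calibration's ``kd_floor``
    and flagged (a dissociation constant cannot be non-positive).

    Returns
    -------
    (kd_nM, clamped)
    """
    kd = calibration.slope * float(mfi_ratio) + calibration.intercept
    if kd <= 0:
        return calibration.kd_floor, True
    return float(kd), False
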