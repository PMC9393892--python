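"""Normalized spectral overlap and joint IR+VCD frequency-scaling search.

The overlap estimate between two spectra a and b over a frequency region
is the normalized inner product

    S_ab = Int I_a I_b dnu / sqrt(Int I_a^2 dnu * Int I_b^2 dnu),

evaluated by the trapezoid rule on a common grid.  By Cauchy-Schwarz,
S_ab lies in [-1, 1]: 1 for identical band shapes, -1 for perfect
mirror-image spectra (opposite enantiomers in VCD).  S is invariant to
positive rescaling of either spectrum, so absolute intensity units
cancel.

``optimize_scaling`` searches a grid of frequency scaling factors f,
rebuilding the broadened ensemble spectra from f-scaled sticks at each
step, and maximizes the combined objective S_IR(f) + S_VCD(f).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, InputError, ZeroSpectrumError
from .spectra import (
    ContinuousSpectrum,
    DEFAULT_FWHM,
    StickSpectrum,
    ensemble_spectrum,
    make_grid,
    scale_frequencies,
)
from .thermo import WeightTable

#: Default scaling-factor search grid: covers the factors commonly needed
#: for harmonic DFT frequencies in the mid-IR (0.94-1.01, step 0.001).
DEFAULT_F_RANGE: tuple[float, float, float] = (0.94, 1.01, 0.001)


@dataclass
class ComparisonResult:
    """Outcome of a calculated-vs-reference spectral comparison."""

    s_ir: Optional[float]
    s_vcd: Optional[float]
    scaling_factor: float
    region: tuple[float, float]
    intensity_factor: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.region
        if not lo < hi:
            raise InputError("region lo must be < hi")
        if self.scaling_factor <= 0:
            raise InputError("scaling factor must be > 0")
        for s in (self.s_ir, self.s_vcd):
            if s is not None and not -1.0 - 1e-9 <= s <= 1.0 + 1e-9:
                raise InputError("overlap estimate outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "s_ir": self.s_ir,
            "s_vcd": self.s_vcd,
            "scaling_factor": self.scaling_factor,
            "region": list(self.region),
            "intensity_factor": self.intensity_factor,
        }


def _normalize_region(region: tuple[float, float]) -> tuple[float, float]:
    lo, hi = region
    return (min(lo, hi), max(lo, hi))


def restrict_region(
    spec: ContinuousSpectrum, region: tuple[float, float]
) -> ContinuousSpectrum:
    """Truncate a spectrum to a region (endpoints kept when on-grid).

    The region orientation is normalized, so (1800, 1500) and
    (1500, 1800) are equivalent.
    """
    lo, hi = _normalize_region(region)
    mask = (spec.grid >= lo - 1e-12) & (spec.grid <= hi + 1e-12)
    if not mask.any():
        raise EmptyRegionError(f"empty region: [{lo}, {hi}] outside grid")
    return ContinuousSpectrum(
        grid=spec.grid[mask],
        intensity=spec.intensity[mask],
        modality=spec.modality,
        metadata={**spec.metadata, "region": (lo, hi)},
    )


def overlap_estimate(
    a: ContinuousSpectrum, b: ContinuousSpectrum, region: tuple[float, float]
) -> float:
    """Normalized overlap integral S_ab over a frequency region.

    Both spectra are linearly resampled onto a common uniform grid (the
    finer of the two steps) restricted to the region; integrals use the
    trapezoid rule.  Raises :class:`ZeroSpectrumError` when either
    spectrum is identically zero in the region.
    """
    lo, hi = _normalize_region(region)
    lo = max(lo, float(a.grid[0]), float(b.grid[0]))
    hi = min(hi, float(a.grid[-1]), float(b.grid[-1]))
    if not lo < hi:
        raise EmptyRegionError("empty region: spectra do not overlap it")
    step = min(a.step or 1.0, b.step or 1.0)
    grid = make_grid(lo, hi, step)
    ia = a.resample(grid).intensity
    ib = b.resample(grid).intensity
    na2 = np.trapezoid(ia * ia, grid)
    nb2 = np.trapezoid(ib * ib, grid)
    if na2 == 0.0 or nb2 == 0.0:
        raise ZeroSpectrumError("undefined overlap (zero norm)")
    s = float(np.trapezoid(ia * ib, grid) / np.sqrt(na2 * nb2))
    # guard round-off just past the Cauchy-Schwarz bound
    return float(np.clip(s, -1.0, 1.0))


def optimize_scaling(
    calc_ir: Sequence[StickSpectrum],
    calc_vcd: Sequence[StickSpectrum],
    weights: WeightTable,
    exp_ir: ContinuousSpectrum,
    exp_vcd: ContinuousSpectrum,
    region: tuple[float, float],
    f_range: tuple[float, float, float] = DEFAULT_F_RANGE,
    fwhm: float = DEFAULT_FWHM,
    grid_step: float = 1.0,
    ir_weight: float = 1.0,
    vcd_weight: float = 1.0,
    return_scan: bool = False,
):
    """Grid search for the frequency scaling factor maximizing S_IR + S_VCD.

    For every candidate f the ensemble spectra are rebuilt from f-scaled
    sticks and compared with the experimental spectra over ``region``.
    Ties are broken toward the f closest to 1.  With ``return_scan`` the
    per-f table (f, S_IR, S_VCD, objective) is returned alongside the
    :class:`ComparisonResult`.
    """
    f_lo, f_hi, f_step = f_range
    if not (0.8 < f_lo < f_hi < 1.2 and f_step > 0):
        raise InputError("f_range must satisfy 0.8 < lo < hi < 1.2 with step > 0")
    lo, hi = _normalize_region(region)
    pad = 5.0 * fwhm
    grid_spec = (max(lo - pad, grid_step), hi + pad, grid_step)
    n = int(round((f_hi - f_lo) / f_step))
    factors = f_lo + f_step * np.arange(n + 1)
    rows = []
    for f in factors:
        ir = ensemble_spectrum(
            [scale_frequencies(s, f) for s in calc_ir], weights, fwhm=fwhm, grid_spec=grid_spec
        )
        vcd = ensemble_spectrum(
            [scale_frequencies(s, f) for s in calc_vcd], weights, fwhm=fwhm, grid_spec=grid_spec
        )
        s_ir = overlap_estimate(ir, exp_ir, (lo, hi))
        s_vcd = overlap_estimate(vcd, exp_vcd, (lo, hi))
        rows.append((float(f), s_ir, s_vcd, ir_weight * s_ir + vcd_weight * s_vcd))
    scan = pd.DataFrame(rows, columns=["f", "s_ir", "s_vcd", "objective"])
    best_obj = scan["objective"].max()
    ties = scan[scan["objective"] >= best_obj - 1e-12]
    best = ties.loc[(ties["f"] - 1.0).abs().idxmin()]
    result = ComparisonResult(
        s_ir=float(best["s_ir"]),
        s_vcd=float(best["s_vcd"]),
        scaling_factor=float(best["f"]),
        region=(lo, hi),
    )
    if return_scan:
        return result, scan
    return result
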