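"""Stick spectra, Lorentzian broadening, and ensemble averaging.

A vibrational calculation yields, per conformer, a *stick spectrum*: one
(frequency, strength) pair per normal mode, where the strength is the
dipole strength (IR, 10^-40 esu^2 cm^2, non-negative) or the rotational
strength (VCD, 10^-44 esu^2 cm^2, signed).  Sticks are turned into a
continuous spectrum by Lorentzian broadening,

    I(nu) = sum_i S_i * nu * L(nu - nu_i; Gamma) * C,

with the unit-area Lorentzian L(x; Gamma) = (Gamma / 2 pi) / (x^2 +
(Gamma/2)^2), Gamma the full width at half maximum (default 10 cm^-1),
and C the modality-specific molar-absorptivity prefactor.  Ensemble
spectra are Boltzmann-weighted sums of per-conformer broadened spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .constants import IR_EPSILON_PREFACTOR, VCD_EPSILON_PREFACTOR
from .errors import EmptyRegionError, InputError, ZeroSpectrumError
from .thermo import WeightTable

logger = logging.getLogger(__name__)

DEFAULT_FWHM = 10.0  # cm^-1
DEFAULT_GRID_STEP = 1.0  # cm^-1
DEFAULT_GRID_PAD = 100.0  # cm^-1 beyond the extreme sticks

MODALITY_PREFACTOR = {"IR": IR_EPSILON_PREFACTOR, "VCD": VCD_EPSILON_PREFACTOR}


@dataclass
class StickSpectrum:
    """Per-conformer (frequency, strength) sticks of one modality."""

    modality: str  # "IR" | "VCD"
    frequencies: np.ndarray  # cm^-1, strictly positive, non-decreasing
    strengths: np.ndarray  # signed for VCD, >= 0 for IR
    conformer_label: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITY_PREFACTOR:
            raise InputError(f"unknown modality {self.modality!r}")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if self.frequencies.shape != self.strengths.shape or self.frequencies.ndim != 1:
            raise InputError("frequencies and strengths must be equal-length 1-D arrays")
        if self.frequencies.size:
            if np.any(self.frequencies <= 0):
                raise InputError("frequencies must be strictly positive")
            if np.any(np.diff(self.frequencies) < 0):
                raise InputError("frequencies must be non-decreasing")
        if self.modality == "IR" and self.frequencies.size and np.any(self.strengths < 0):
            raise InputError("IR dipole strengths must be non-negative")

    def __len__(self) -> int:
        return self.frequencies.size


@dataclass
class ContinuousSpectrum:
    """Intensity sampled on a uniform ascending wavenumber grid."""

    grid: np.ndarray  # cm^-1
    intensity: np.ndarray
    modality: str = "IR"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape or self.grid.ndim != 1:
            raise InputError("grid and intensity must be equal-length 1-D arrays")
        if self.grid.size >= 2:
            steps = np.diff(self.grid)
            if np.any(steps <= 0):
                raise InputError("grid must be strictly ascending")
            if np.max(np.abs(steps - steps[0])) > 1e-9:
                raise InputError("grid must be uniform")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size >= 2 else 0.0

    def resample(self, grid: np.ndarray) -> "ContinuousSpectrum":
        """Linear interpolation onto a new grid (zero outside support)."""
        intensity = np.interp(grid, self.grid, self.intensity, left=0.0, right=0.0)
        return ContinuousSpectrum(
            grid=np.asarray(grid, float),
            intensity=intensity,
            modality=self.modality,
            metadata=dict(self.metadata),
        )


GridSpec = tuple[float, float, float]  # (lo, hi, step)


def make_grid(lo: float, hi: float, step: float) -> np.ndarray:
    if not (lo < hi and step > 0):
        raise InputError("grid spec needs lo < hi and step > 0")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def default_grid_spec(
    sticks: Sequence[StickSpectrum],
    step: float = DEFAULT_GRID_STEP,
    pad: float = DEFAULT_GRID_PAD,
) -> GridSpec:
    """Grid spanning all sticks padded on each side (default 100 cm^-1)."""
    freqs = np.concatenate([s.frequencies for s in sticks if len(s)]) if sticks else np.array([])
    if freqs.size == 0:
        raise InputError("no sticks to infer a grid from")
    return (max(freqs.min() - pad, step), freqs.max() + pad, step)


def scale_frequencies(sticks: StickSpectrum, f: float) -> StickSpectrum:
    """Multiply every stick frequency by f > 0; strengths untouched.

    Harmonic frequencies overestimate fundamentals systematically; a
    multiplicative factor (typically 0.95-1.00) compensates before
    comparison with experiment.
    """
    if f <= 0:
        raise InputError(f"invalid scaling factor: {f}")
    return replace(sticks, frequencies=sticks.frequencies * f)


def lorentzian_broaden(
    sticks: StickSpectrum,
    fwhm: float = DEFAULT_FWHM,
    grid_spec: Optional[GridSpec] = None,
) -> ContinuousSpectrum:
    """Broaden a stick spectrum with unit-area Lorentzians.

    Each band attains half its own peak height at nu_i +/- fwhm/2.  A
    warning (not an error) is logged when the grid does not cover every
    stick by at least 5*fwhm on each side.
    """
    if fwhm <= 0:
        raise InputError("fwhm must be > 0")
    if grid_spec is None:
        grid_spec = default_grid_spec([sticks])
    grid = make_grid(*grid_spec)
    if len(sticks) == 0:
        return ContinuousSpectrum(
            grid=grid,
            intensity=np.zeros_like(grid),
            modality=sticks.modality,
            metadata={"fwhm": fwhm, "conformer": sticks.conformer_label},
        )
    if sticks.frequencies.min() - 5 * fwhm < grid[0] or sticks.frequencies.max() + 5 * fwhm > grid[-1]:
        logger.warning(
            "grid [%g, %g] does not cover all sticks +/- 5*fwhm", grid[0], grid[-1]
        )
    gamma = fwhm / 2.0
    x = grid[:, None] - sticks.frequencies[None, :]
    profile = (fwhm / (2.0 * np.pi)) / (x * x + gamma * gamma)
    prefactor = MODALITY_PREFACTOR[sticks.modality]
    intensity = grid * (profile @ sticks.strengths) * prefactor
    return ContinuousSpectrum(
        grid=grid,
        intensity=intensity,
        modality=sticks.modality,
        metadata={"fwhm": fwhm, "conformer": sticks.conformer_label},
    )


def ensemble_spectrum(
    per_conformer: Sequence[StickSpectrum],
    weights: WeightTable,
    fwhm: float = DEFAULT_FWHM,
    grid_spec: Optional[GridSpec] = None,
) -> ContinuousSpectrum:
    """Boltzmann-weighted sum of per-conformer broadened spectra.

    Every weighted conformer must be represented by exactly one stick
    spectrum of the same modality, matched by label.
    """
    if not per_conformer:
        raise InputError("no stick spectra supplied")
    modality = per_conformer[0].modality
    by_label = {s.conformer_label: s for s in per_conformer}
    if len(by_label) != len(per_conformer):
        raise InputError("inconsistent ensemble: duplicate conformer labels in spectra")
    missing = [lab for lab in weights.labels if lab not in by_label]
    extra = [s.conformer_label for s in per_conformer if s.conformer_label not in weights.labels]
    if missing or extra:
        raise InputError(
            f"inconsistent ensemble: missing spectra {missing}, unweighted spectra {extra}"
        )
    if any(s.modality != modality for s in per_conformer):
        raise InputError("inconsistent ensemble: mixed modalities")
    if grid_spec is None:
        grid_spec = default_grid_spec(per_conformer)
    total = None
    for lab, w in zip(weights.labels, weights.weights):
        spec = lorentzian_broaden(by_label[lab], fwhm=fwhm, grid_spec=grid_spec)
        total = w * spec.intensity if total is None else total + w * spec.intensity
    grid = make_grid(*grid_spec)
    return ContinuousSpectrum(
        grid=grid,
        intensity=total,
        modality=modality,
        metadata={"fwhm": fwhm, "n_conformers": len(per_conformer)},
    )


def match_intensity(
    calc: ContinuousSpectrum, ref: ContinuousSpectrum
) -> tuple[ContinuousSpectrum, float]:
    """Scale ``calc`` so its strongest band matches the reference's.

    The factor is max|ref| / max|calc| over the overlap of the two grids
    (reference resampled onto the calculated grid); for VCD this uses the
    band of maximum absolute intensity.
    """
    ref_on_calc = ref.resample(calc.grid)
    overlap = (calc.grid >= ref.grid[0]) & (calc.grid <= ref.grid[-1])
    if not overlap.any():
        raise EmptyRegionError("empty region: grids do not overlap")
    calc_max = float(np.max(np.abs(calc.intensity[overlap])))
    if calc_max == 0.0:
        raise ZeroSpectrumError("cannot scale zero spectrum")
    factor = float(np.max(np.abs(ref_on_calc.intensity[overlap]))) / calc_max
    scaled = ContinuousSpectrum(
        grid=calc.grid,
        intensity=calc.intensity * factor,
        modality=calc.modality,
        metadata={**calc.metadata, "intensity_factor": factor},
    )
    return scaled, factor


def sign_pattern(
    spec: ContinuousSpectrum,
    region: tuple[float, float],
    min_prominence: float = 0.05,
) -> list[tuple[float, int]]:
    """Signed local extrema in a region, reported high-to-low frequency.

    Extrema whose absolute intensity is below ``min_prominence`` times
    the region's absolute maximum are discarded.  The result supports the
    band-assignment style of sign-pattern tables (e.g. "-/+/+/-" across
    the amide I region).
    """
    lo, hi = min(region), max(region)
    mask = (spec.grid >= lo) & (spec.grid <= hi)
    if not mask.any():
        raise EmptyRegionError("empty region")
    grid = spec.grid[mask]
    inten = spec.intensity[mask]
    scale = np.max(np.abs(inten))
    if scale == 0.0:
        return []
    peaks_pos, _ = find_peaks(inten)
    peaks_neg, _ = find_peaks(-inten)
    extrema = [(grid[k], +1, inten[k]) for k in peaks_pos if inten[k] > 0]
    extrema += [(grid[k], -1, inten[k]) for k in peaks_neg if inten[k] < 0]
    extrema = [(f, s, v) for f, s, v in extrema if abs(v) >= min_prominence * scale]
    extrema.sort(key=lambda t: -t[0])
    return [(float(f), s) for f, s, _ in extrema]


def format_sign_pattern(pattern: Sequence[tuple[float, int]]) -> str:
    """Render a sign pattern as the conventional string, e.g. "-/+/+/-"."""
    return "/".join("+" if s > 0 else "-" for _, s in pattern)
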