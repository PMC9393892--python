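"""Relative energies, energy-window selection, and Boltzmann populations.

Energies arrive in Hartree and all user-facing quantities are in
kcal/mol.  Conformer selection keeps structures at most ``window``
kcal/mol above the most stable one (inclusive; default 2.5).  Boltzmann
weights are computed from a chosen energy field — Gibbs free energies by
default — as w_i = exp(-dE_i / RT) / sum_j exp(-dE_j / RT), from shifted
relative energies for numerical stability.  A conformer is reported
"significant" when its weight is strictly above the cutoff (default 5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, HARTREE_TO_KCAL, R_KCAL_PER_MOL_K
from .ensemble import Ensemble, validate_ensemble
from .errors import InputError


@dataclass
class WeightTable:
    """Boltzmann weights and relative energies of one ensemble."""

    labels: list[str]
    delta_e: np.ndarray  # kcal/mol relative to the minimum
    weights: np.ndarray  # fractions summing to 1
    energy_field: str
    temperature: float  # K

    def __post_init__(self) -> None:
        self.delta_e = np.asarray(self.delta_e, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.delta_e.shape != (n,) or self.weights.shape != (n,):
            raise InputError("labels, delta_e, weights must have equal length")
        if n and abs(self.weights.sum() - 1.0) > 1e-9:
            raise InputError("weights must sum to 1")
        if n and (self.delta_e.min() < 0 or self.delta_e.min() > 1e-12):
            raise InputError("delta_e must be >= 0 with at least one zero")

    def weight_of(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "dE_kcal": self.delta_e, "weight": self.weights}
        )


def relative_energies(ensemble: Ensemble, energy_field: str = "electronic") -> np.ndarray:
    """Per-conformer E_i - min_j E_j in kcal/mol (minimum entry exactly 0)."""
    validate_ensemble(ensemble)
    from .errors import EnergyUnavailableError

    for c in ensemble:
        if c.energy is None or not c.energy.has(energy_field):
            raise EnergyUnavailableError(
                f"energy unavailable: {energy_field} missing for conformer {c.label!r}"
            )
    e = np.array([c.energy.get(energy_field) for c in ensemble])
    return (e - e.min()) * HARTREE_TO_KCAL


def energy_window_filter(
    ensemble: Ensemble, window: float = 2.5, energy_field: str = "electronic"
) -> Ensemble:
    """Keep conformers with dE <= window (kcal/mol, inclusive).

    Order is preserved and the minimum-energy conformer is always kept,
    so the result is never empty.
    """
    if window <= 0:
        raise InputError("window must be > 0")
    de = relative_energies(ensemble, energy_field)
    kept = [c for c, d in zip(ensemble, de) if d <= window]
    return Ensemble(conformers=kept)


def boltzmann_weights(
    ensemble: Ensemble,
    energy_field: str = "gibbs",
    temperature: float = DEFAULT_TEMPERATURE,
) -> WeightTable:
    """Boltzmann populations at the given temperature.

    Uses relative energies (shifted so the minimum is zero) to avoid
    overflow; R = 1.987204e-3 kcal/(mol K).
    """
    if temperature <= 0:
        raise InputError("temperature must be > 0")
    de = relative_energies(ensemble, energy_field)
    unnorm = np.exp(-de / (R_KCAL_PER_MOL_K * temperature))
    weights = unnorm / unnorm.sum()
    return WeightTable(
        labels=list(ensemble.labels),
        delta_e=de,
        weights=weights,
        energy_field=energy_field,
        temperature=temperature,
    )


def significant_conformers(weights: WeightTable, cutoff: float = 0.05) -> list[str]:
    """Labels with weight strictly above the cutoff, by descending weight."""
    order = np.argsort(-weights.weights, kind="stable")
    return [weights.labels[k] for k in order if weights.weights[k] > cutoff]
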