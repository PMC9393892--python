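"""Core data model: conformers, energy records, ensembles.

A :class:`Conformer` holds an element list and Cartesian coordinates (in
Angstrom) for one structure, optionally with an :class:`EnergyRecord`
(electronic energy, enthalpy, Gibbs free energy; all in Hartree).  An
:class:`Ensemble` is an ordered collection of conformers sharing one atom
identity (same elements in the same order).

The module also provides the elementary geometry helpers and the genetic
crossing operation used by conformer-sampling workflows: for a reference
structure R_ref and a conformer pair (R_i, R_j), crossing generates
``R_new = R_ref + (R_i - R_j)``, i.e. the structural difference of the
pair is added to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import (
    HeterogeneousEnsembleError,
    IncompatibleStructuresError,
    InputError,
    LabelCollisionError,
)

ENERGY_FIELDS = ("electronic", "enthalpy", "gibbs")


def _valid_symbol(symbol: str) -> bool:
    from rdkit import Chem

    try:
        return Chem.GetPeriodicTable().GetAtomicNumber(symbol) > 0
    except Exception:
        return False


@dataclass(frozen=True)
class EnergyRecord:
    """Per-conformer energies in Hartree; any subset of fields may be set."""

    electronic: Optional[float] = None
    enthalpy: Optional[float] = None
    gibbs: Optional[float] = None

    def __post_init__(self) -> None:
        values = [getattr(self, f) for f in ENERGY_FIELDS]
        if all(v is None for v in values):
            raise InputError("energy record must carry at least one field")
        for name, v in zip(ENERGY_FIELDS, values):
            if v is not None and not np.isfinite(v):
                raise InputError(f"non-finite {name} energy: {v!r}")

    def get(self, energy_field: str) -> float:
        """Return the requested field (Hartree) or raise if absent."""
        from .errors import EnergyUnavailableError

        if energy_field not in ENERGY_FIELDS:
            raise InputError(f"unknown energy field {energy_field!r}")
        value = getattr(self, energy_field)
        if value is None:
            raise EnergyUnavailableError(f"energy unavailable: {energy_field}")
        return float(value)

    def has(self, energy_field: str) -> bool:
        return energy_field in ENERGY_FIELDS and getattr(self, energy_field) is not None


@dataclass
class Conformer:
    """One structure: element symbols, N x 3 coordinates (A), energies."""

    atoms: list[str]
    coords: np.ndarray
    energy: Optional[EnergyRecord] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError("coords must be an N x 3 array")
        if len(self.atoms) != self.coords.shape[0]:
            raise InputError("one coordinate row required per atom")
        if len(self.atoms) < 2:
            raise InputError("a conformer needs at least two atoms")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        bad = [a for a in self.atoms if not _valid_symbol(a)]
        if bad:
            raise InputError(f"invalid element symbols: {sorted(set(bad))}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def atom_identity(self) -> tuple[str, ...]:
        return tuple(self.atoms)

    def with_coords(self, coords: np.ndarray) -> "Conformer":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Ensemble:
    """Ordered conformer collection with a shared atom identity."""

    conformers: list[Conformer] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self) -> Iterator[Conformer]:
        return iter(self.conformers)

    def __getitem__(self, idx):
        return self.conformers[idx]

    @property
    def atom_identity(self) -> tuple[str, ...]:
        if not self.conformers:
            raise InputError("empty ensemble")
        return self.conformers[0].atom_identity

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.conformers]


def validate_ensemble(ensemble: Ensemble) -> Ensemble:
    """Check ensemble invariants; return the ensemble unchanged.

    Raises
    ------
    InputError
        If the ensemble is empty.
    HeterogeneousEnsembleError
        If any conformer's atom identity differs from the first one's.
    LabelCollisionError
        If two conformers share a label.
    """
    if not ensemble.conformers:
        raise InputError("empty ensemble")
    identity = ensemble.conformers[0].atom_identity
    for k, conf in enumerate(ensemble.conformers):
        if conf.atom_identity != identity:
            raise HeterogeneousEnsembleError(
                f"heterogeneous ensemble: conformer {conf.label or k} "
                f"has {conf.n_atoms} atoms / different elements"
            )
    seen: dict[str, int] = {}
    for k, lab in enumerate(ensemble.labels):
        if lab in seen:
            raise LabelCollisionError(f"label collision: {lab!r} (positions {seen[lab]}, {k})")
        seen[lab] = k
    return ensemble


def center_of_geometry(conformer: Conformer) -> np.ndarray:
    """Arithmetic mean of the coordinate rows (A)."""
    return conformer.coords.mean(axis=0)


def _require_same_identity(*conformers: Conformer) -> None:
    identity = conformers[0].atom_identity
    if any(c.atom_identity != identity for c in conformers[1:]):
        raise IncompatibleStructuresError("incompatible structures: atom identity differs")


def genetic_cross(ref: Conformer, i: Conformer, j: Conformer) -> Conformer:
    """Genetic crossing: add the structural difference (R_i - R_j) to R_ref.

    Returns a new conformer with coordinates ``ref.coords + i.coords -
    j.coords``, the shared element list, and no energy record (the crossed
    structure has not been evaluated by any method).
    """
    _require_same_identity(ref, i, j)
    coords = ref.coords + (i.coords - j.coords)
    label = f"gc({ref.label},{i.label},{j.label})"
    return Conformer(atoms=list(ref.atoms), coords=coords, energy=None, label=label)


def make_labels(n: int, existing: Optional[Sequence[Optional[str]]] = None) -> list[str]:
    """Default labels: 1-based position, used when a source file has none."""
    if existing is None:
        return [str(k + 1) for k in range(n)]
    return [e if e else str(k + 1) for k, e in enumerate(existing)]
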