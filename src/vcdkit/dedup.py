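"""Duplicate-conformer detection and removal.

After geometry optimization, many conformers that were distinct at the
sampling stage collapse into the same minimum.  A pair of conformers is
considered a duplicate when all three of the following agree within
thresholds:

1. total energy (|dE| <= ``energy_thr``, kcal/mol),
2. optimal-superposition (Kabsch) RMSD of the Cartesian coordinates
   (<= ``rmsd_thr``, Angstrom),
3. relative difference of each rotational constant
   (max over A, B, C of |dB| / mean(B) <= ``rotconst_rel_thr``).

Default thresholds follow the CREST conformer-sorting defaults: 0.05
kcal/mol, 0.125 A, 1%.  Pruning is a greedy sweep in ascending energy
order, so the lowest-energy representative of every duplicate group is
the one kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import HARTREE_TO_KCAL, LINEAR_MOMENT_CUTOFF, ROTCONST_CM
from .ensemble import Conformer, Ensemble, _require_same_identity, validate_ensemble
from .errors import DegenerateGeometryError, InputError


def atomic_masses(symbols: list[str]) -> np.ndarray:
    """Most-abundant-isotope masses (amu) for a list of element symbols."""
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    return np.array([pt.GetMostCommonIsotopeMass(s) for s in symbols])


@dataclass(frozen=True)
class DedupThresholds:
    """The three duplicate criteria thresholds (all strictly positive)."""

    energy_thr: float = 0.05  # kcal/mol
    rmsd_thr: float = 0.125  # Angstrom
    rotconst_rel_thr: float = 0.01  # dimensionless fraction

    def __post_init__(self) -> None:
        if min(self.energy_thr, self.rmsd_thr, self.rotconst_rel_thr) <= 0:
            raise InputError("dedup thresholds must be strictly positive")


class DuplicateMetrics(NamedTuple):
    """The three metrics evaluated for one conformer pair."""

    delta_e: float  # kcal/mol
    rmsd: float  # Angstrom
    max_rel_rotconst: float  # dimensionless


@dataclass
class DuplicateReport:
    """Bookkeeping of a pruning pass: kept labels and removal records."""

    kept: list[str] = field(default_factory=list)
    removed: list[tuple[str, str, DuplicateMetrics]] = field(default_factory=list)

    @property
    def removed_labels(self) -> list[str]:
        return [r[0] for r in self.removed]


def kabsch_rmsd(a: Conformer, b: Conformer, use_mass_weighting: bool = False) -> float:
    """Minimum RMSD (A) between two conformers over all rigid motions.

    Both structures are centered (at the plain or mass-weighted centroid)
    and the optimal rotation is found with the Kabsch/Wahba solution.
    Plain Cartesian RMSD is the default; with ``use_mass_weighting`` the
    superposition and the RMSD are both mass-weighted.
    """
    _require_same_identity(a, b)
    if use_mass_weighting:
        w = atomic_masses(list(a.atoms))
    else:
        w = np.ones(a.n_atoms)
    pa = a.coords - np.average(a.coords, axis=0, weights=w)
    pb = b.coords - np.average(b.coords, axis=0, weights=w)
    _, rssd = Rotation.align_vectors(pa, pb, weights=w)
    return float(rssd / np.sqrt(w.sum()))


def inertia_moments(conformer: Conformer) -> np.ndarray:
    """Principal moments of inertia (amu A^2), ascending."""
    masses = atomic_masses(list(conformer.atoms))
    com = np.average(conformer.coords, axis=0, weights=masses)
    r = conformer.coords - com
    # inertia tensor I = sum_i m_i (|r_i|^2 E - r_i r_i^T)
    r2 = np.einsum("ij,ij->i", r, r)
    tensor = np.diag([float((masses * r2).sum())] * 3) - np.einsum("i,ij,ik->jk", masses, r, r)
    moments = np.linalg.eigvalsh(tensor)
    return np.clip(moments, 0.0, None)


def rotational_constants(conformer: Conformer) -> np.ndarray:
    """Rotational constants A >= B >= C in cm^-1.

    Constants follow B = h / (8 pi^2 c I) from the principal moments of
    the mass-weighted inertia tensor about the center of mass.  For a
    linear molecule the smallest moment is numerically zero; the
    corresponding constant is returned as ``inf`` and callers exclude it
    from relative comparisons.
    """
    moments = inertia_moments(conformer)
    if np.all(moments < LINEAR_MOMENT_CUTOFF):
        raise DegenerateGeometryError("degenerate geometry: all principal moments vanish")
    constants = np.where(moments < LINEAR_MOMENT_CUTOFF, np.inf, ROTCONST_CM / np.maximum(moments, 1e-300))
    return np.sort(constants)[::-1]


def _rel_rotconst_diff(ba: np.ndarray, bb: np.ndarray) -> float:
    """Max over constants of |dB| / mean(B); infinite constants excluded."""
    finite = np.isfinite(ba) & np.isfinite(bb)
    if not finite.any():
        return 0.0
    num = np.abs(ba[finite] - bb[finite])
    den = 0.5 * (ba[finite] + bb[finite])
    return float(np.max(num / den))


def is_duplicate(
    a: Conformer,
    b: Conformer,
    thr: DedupThresholds = DedupThresholds(),
    energy_field: str = "electronic",
) -> tuple[bool, DuplicateMetrics]:
    """Evaluate the three duplicate criteria for a pair of conformers.

    Returns the verdict (True iff *all three* criteria pass) together
    with the computed metrics.
    """
    if a.energy is None or b.energy is None:
        from .errors import EnergyUnavailableError

        raise EnergyUnavailableError("energy unavailable: conformer has no energy record")
    de = abs(a.energy.get(energy_field) - b.energy.get(energy_field)) * HARTREE_TO_KCAL
    rmsd = kabsch_rmsd(a, b)
    drot = _rel_rotconst_diff(rotational_constants(a), rotational_constants(b))
    metrics = DuplicateMetrics(de, rmsd, drot)
    verdict = de <= thr.energy_thr and rmsd <= thr.rmsd_thr and drot <= thr.rotconst_rel_thr
    return verdict, metrics


def prune_duplicates(
    ensemble: Ensemble,
    thr: DedupThresholds = DedupThresholds(),
    energy_field: str = "electronic",
) -> tuple[Ensemble, DuplicateReport]:
    """Remove duplicates by a greedy sweep in ascending energy order.

    Conformers are visited from most to least stable; each is kept unless
    it is a duplicate of an already-kept conformer (in which case the
    kept, lower-energy structure is its representative).  The returned
    ensemble is sorted ascending by the selected energy; the sweep is
    deterministic for a fixed input order (stable sort).
    """
    validate_ensemble(ensemble)
    order = sorted(
        range(len(ensemble)),
        key=lambda k: ensemble[k].energy.get(energy_field) if ensemble[k].energy else np.inf,
    )
    kept: list[Conformer] = []
    report = DuplicateReport()
    for k in order:
        cand = ensemble[k]
        match = None
        for rep in kept:
            dup, metrics = is_duplicate(cand, rep, thr, energy_field)
            if dup:
                match = (rep.label, metrics)
                break
        if match is None:
            kept.append(cand)
            report.kept.append(cand.label)
        else:
            report.removed.append((cand.label, match[0], match[1]))
    return Ensemble(conformers=kept), report
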