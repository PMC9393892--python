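"""Seeded synthetic fixtures for every pipeline stage.

The generators emulate the statistical structure the workflow assumes —
clusters of near-identical rotamers, kcal-scale energy gaps between
conformers, and signed VCD bands in the amide regions — without any
external software.  Geometries are ring-like toys (atoms on a perturbed
circle, standing in for a cyclic peptide backbone), not chemically valid
molecules: every in-scope computation depends only on coordinates,
energies, frequencies and strengths, never on chemical validity.

All randomness flows from the seed in :class:`FixtureSpec`; each
generator draws from its own seeded stream, so adding a generator never
perturbs existing fixtures.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import HARTREE_TO_KCAL
from .dedup import DedupThresholds
from .ensemble import Conformer, EnergyRecord, Ensemble
from .errors import InputError
from .io import FREQ_TSV_COLUMNS
from .spectra import ContinuousSpectrum, StickSpectrum, ensemble_spectrum
from .thermo import WeightTable

#: Amide I band centers/signs used as the default fixture band structure
#: (a -/+/+/- pattern across 1800-1500 cm^-1).
DEFAULT_BAND_CENTERS = (1673.0, 1668.0, 1650.0, 1643.0)
DEFAULT_BAND_SIGNS = (-1, +1, +1, -1)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture; the seed is mandatory."""

    seed: int
    n_atoms: int = 12
    n_conformers: int = 6
    n_duplicate_pairs: int = 2
    duplicate_noise: float = 0.02  # A, below the RMSD threshold
    conformer_noise: float = 0.7  # A, above the RMSD threshold
    energy_spread: float = 3.0  # kcal/mol
    band_centers: tuple[float, ...] = DEFAULT_BAND_CENTERS
    band_signs: tuple[int, ...] = DEFAULT_BAND_SIGNS
    planted_scale: float = 0.975
    noise_sd: float = 0.0  # fraction of max |intensity|
    thresholds: DedupThresholds = field(default_factory=DedupThresholds)

    def __post_init__(self) -> None:
        if self.duplicate_noise >= self.conformer_noise:
            raise InputError("duplicate_noise must be < conformer_noise")
        if self.duplicate_noise * np.sqrt(3.0) >= self.thresholds.rmsd_thr:
            raise InputError("duplicate_noise too large for the RMSD threshold")
        if len(self.band_centers) != len(self.band_signs):
            raise InputError("band_centers and band_signs lengths differ")
        if self.n_conformers < 1 or self.n_atoms < 3:
            raise InputError("need n_conformers >= 1 and n_atoms >= 3")


def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    # module-local independent streams keyed by (seed, stream name);
    # crc32 keeps the stream key stable across processes
    return np.random.default_rng([spec.seed, zlib.crc32(stream.encode()) % 2**31])


def _base_ring(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    radius = max(1.5 * spec.n_atoms / (2 * np.pi), 1.2)
    theta = 2 * np.pi * np.arange(spec.n_atoms) / spec.n_atoms
    coords = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), 0.3 * np.sin(3 * theta)], axis=1
    )
    return coords + rng.normal(scale=0.15, size=coords.shape)


def _shrink_to_subthreshold(
    parent: Conformer, jitter: np.ndarray, atoms: list[str], thr: DedupThresholds
) -> np.ndarray:
    """Shrink a coordinate jitter until parent vs parent+jitter passes the
    RMSD and rotational-constant duplicate criteria with a 2x margin."""
    from .dedup import _rel_rotconst_diff, kabsch_rmsd, rotational_constants

    ref_const = rotational_constants(parent)
    for _ in range(60):
        cand = Conformer(list(atoms), parent.coords + jitter, None, "probe")
        ok_rmsd = kabsch_rmsd(parent, cand) <= 0.5 * thr.rmsd_thr
        ok_rot = _rel_rotconst_diff(ref_const, rotational_constants(cand)) <= 0.5 * thr.rotconst_rel_thr
        if ok_rmsd and ok_rot:
            return jitter
        jitter = 0.7 * jitter
    return jitter


def make_ensemble(spec: FixtureSpec) -> tuple[Ensemble, list[list[str]]]:
    """Ring-toy ensemble with planted duplicate pairs.

    The first ``n_duplicate_pairs`` distinct conformers each get one
    duplicate: the same geometry plus sub-threshold coordinate noise, a
    random rigid motion, and an energy jitter of at most half the energy
    threshold.  Distinct conformers differ by supra-threshold
    perturbations and are spread over ``energy_spread`` kcal/mol.

    Returns the ensemble (shuffled order, labels ``c1..cN``) and the
    planted duplicate partition as lists of labels.
    """
    if spec.n_duplicate_pairs > spec.n_conformers:
        raise InputError("more duplicate pairs than conformers")
    rng = _rng(spec, "ensemble")
    atoms = (["C", "N", "O"] * spec.n_atoms)[: spec.n_atoms]
    base = _base_ring(spec, rng)
    e0 = -500.0  # Hartree, arbitrary stable baseline
    distinct: list[Conformer] = []
    for k in range(spec.n_conformers):
        coords = base + rng.normal(scale=spec.conformer_noise, size=base.shape) * (k > 0)
        de = (spec.energy_spread * k / max(spec.n_conformers - 1, 1)) / HARTREE_TO_KCAL
        rec = EnergyRecord(electronic=e0 + de, gibbs=e0 + de + rng.normal(scale=2e-4))
        distinct.append(Conformer(atoms=list(atoms), coords=coords, energy=rec, label=f"c{k + 1}"))
    groups: list[list[str]] = [[c.label] for c in distinct]
    members: list[Conformer] = list(distinct)
    for k in range(spec.n_duplicate_pairs):
        parent = distinct[k]
        jitter = rng.normal(scale=spec.duplicate_noise, size=base.shape)
        # the planted noise must be sub-threshold for every duplicate
        # criterion (RMSD and rotational constants), so shrink it until
        # the pair sits comfortably inside the thresholds
        jitter = _shrink_to_subthreshold(parent, jitter, atoms, spec.thresholds)
        rot = Rotation.random(rng=rng)
        coords = rot.apply(parent.coords + jitter) + rng.normal(scale=5.0, size=3)
        de = rng.uniform(-0.5, 0.5) * spec.thresholds.energy_thr / HARTREE_TO_KCAL
        rec = EnergyRecord(
            electronic=parent.energy.get("electronic") + de,
            gibbs=parent.energy.get("gibbs") + de,
        )
        dup = Conformer(atoms=list(atoms), coords=coords, energy=rec, label=f"c{k + 1}d")
        members.append(dup)
        groups[k].append(dup.label)
    order = rng.permutation(len(members))
    return Ensemble(conformers=[members[i] for i in order]), groups


def make_frequency_tables(
    spec: FixtureSpec, ensemble: Ensemble
) -> list[pd.DataFrame]:
    """One frequency table per conformer with the planted band structure.

    Modes sit at ``band_centers`` plus small per-conformer jitter; VCD
    rotational strengths carry ``band_signs`` with random magnitudes and
    IR dipole strengths are positive.  Duplicate conformers (labels
    ending in 'd') reuse their parent's modes so averaging is consistent.
    """
    tables: dict[str, pd.DataFrame] = {}
    rng = _rng(spec, "frequencies")
    centers = np.asarray(spec.band_centers, float)
    signs = np.asarray(spec.band_signs, float)
    for conf in ensemble:
        parent = conf.label[:-1] if conf.label.endswith("d") else conf.label
        if parent in tables:
            df = tables[parent].copy()
        else:
            freqs = centers + rng.normal(scale=1.5, size=centers.shape)
            dip = rng.uniform(30.0, 120.0, size=centers.shape)
            rot = signs * rng.uniform(20.0, 60.0, size=centers.shape)
            order = np.argsort(freqs)
            df = pd.DataFrame(
                {
                    "mode": np.arange(1, len(centers) + 1),
                    "frequency_cm": freqs[order],
                    "dipole_strength": dip[order],
                    "rotational_strength": rot[order],
                }
            )
            tables[parent] = df
        out = df.copy()
        out.attrs["conformer_label"] = conf.label
        tables[conf.label] = out
    return [tables[c.label] for c in ensemble]


def tables_to_sticks(tables: Sequence[pd.DataFrame], modality: str) -> list[StickSpectrum]:
    from .io import frequency_table_to_sticks

    return [frequency_table_to_sticks(t, modality) for t in tables]


def make_pseudo_experiment(
    tables: Sequence[pd.DataFrame],
    weights: WeightTable,
    spec: FixtureSpec,
    fwhm: float = 10.0,
    grid_spec: Optional[tuple[float, float, float]] = None,
) -> tuple[ContinuousSpectrum, ContinuousSpectrum]:
    """Pseudo-experimental IR and VCD spectra with a planted distortion.

    Builds the Boltzmann-averaged spectra, multiplies the frequency axis
    by ``planted_scale`` (resampling back onto a uniform grid), and adds
    seeded Gaussian intensity noise of sd ``noise_sd * max|I|`` — the
    round-trip target for scaling-factor recovery tests.
    """
    rng = _rng(spec, "experiment")
    out = []
    for modality in ("IR", "VCD"):
        sticks = tables_to_sticks(tables, modality)
        calc = ensemble_spectrum(sticks, weights, fwhm=fwhm, grid_spec=grid_spec)
        scaled_axis = calc.grid * spec.planted_scale
        grid = np.arange(scaled_axis[0], scaled_axis[-1], calc.step)
        inten = np.interp(grid, scaled_axis, calc.intensity)
        if spec.noise_sd > 0:
            inten = inten + rng.normal(scale=spec.noise_sd * np.max(np.abs(inten)), size=inten.shape)
        out.append(
            ContinuousSpectrum(
                grid=grid,
                intensity=inten,
                modality=modality,
                metadata={"planted_scale": spec.planted_scale, "noise_sd": spec.noise_sd},
            )
        )
    return out[0], out[1]


def write_fixture_dir(spec: FixtureSpec, outdir: Path) -> dict:
    """Write a complete fixture directory and return its ground truth.

    Emits: ``ensemble.xyz`` (multi-XYZ), ``energies.csv``, one
    ``freq_<label>.tsv`` per conformer, ``exp_ir.txt`` / ``exp_vcd.txt``
    pseudo-experimental spectra, and ``ground_truth.json``.
    """
    from .io import write_frequency_table, write_multixyz, write_spectrum
    from .thermo import boltzmann_weights

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ensemble, groups = make_ensemble(spec)
    tables = make_frequency_tables(spec, ensemble)
    # multi-XYZ labels are positional (block order), so relabel everything
    # that is written to disk accordingly and translate the ground truth
    pos = {conf.label: str(k + 1) for k, conf in enumerate(ensemble)}
    relabeled = Ensemble(
        conformers=[
            Conformer(c.atoms, c.coords, c.energy, pos[c.label]) for c in ensemble
        ]
    )
    write_multixyz(relabeled, outdir / "ensemble.xyz")
    rows = []
    for conf in relabeled:
        rows.append(
            {
                "label": conf.label,
                "electronic": conf.energy.get("electronic"),
                "gibbs": conf.energy.get("gibbs"),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "energies.csv", index=False)
    for conf, table in zip(relabeled, tables):
        table = table.copy()
        table.attrs["conformer_label"] = conf.label
        write_frequency_table(table, outdir / f"freq_{conf.label}.tsv")
    weights = boltzmann_weights(ensemble, energy_field="gibbs")
    exp_ir, exp_vcd = make_pseudo_experiment(tables, weights, spec)
    write_spectrum(exp_ir, outdir / "exp_ir.txt")
    write_spectrum(exp_vcd, outdir / "exp_vcd.txt")
    truth = {
        "seed": spec.seed,
        "labels": [pos[lab] for lab in ensemble.labels],
        "planted_labels": ensemble.labels,
        "duplicate_groups": [[pos[lab] for lab in g] for g in groups],
        "n_unique": len(groups),
        "planted_scale": spec.planted_scale,
        "band_centers": list(spec.band_centers),
        "band_signs": list(spec.band_signs),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
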