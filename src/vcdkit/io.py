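"""Readers and writers for the interchange formats.

Supported formats
-----------------
* multi-structure XYZ (concatenated XYZ blocks, the ensemble convention
  of conformer samplers); an energy token in the comment line is read as
  the electronic energy in Hartree,
* an energy CSV with columns ``label, electronic, enthalpy, gibbs``
  (Hartree; blank cells allowed),
* a frequency-table TSV dialect with columns ``mode, frequency_cm,
  dipole_strength, rotational_strength`` (an artifact-defined
  interchange format for per-conformer harmonic results),
* a "qm_log" dialect extracting ``Frequencies`` / ``Dip. str.`` /
  ``Rot. str.`` blocks from a frequency-job text log,
* two-column (wavenumber, intensity) experimental spectra.

Readers reject malformed records rather than coercing them; every
writer/reader pair round-trips to numerical identity (coordinates to
1e-8 A, energies to 1e-10 Hartree).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .ensemble import Conformer, EnergyRecord, Ensemble, validate_ensemble
from .errors import InputError
from .spectra import ContinuousSpectrum, StickSpectrum

PathLike = Union[str, Path]

_FLOAT_RE = re.compile(r"[-+]?\d+\.\d+(?:[eEdD][-+]?\d+)?")

FREQ_TSV_COLUMNS = ["mode", "frequency_cm", "dipole_strength", "rotational_strength"]


# ---------------------------------------------------------------- multi-XYZ


def read_multixyz(path: PathLike) -> Ensemble:
    """Parse concatenated XYZ blocks into an ensemble.

    Comment lines are scanned for a decimal token, interpreted as the
    electronic energy in Hartree.  Labels are the 1-based block order.
    """
    lines = Path(path).read_text().splitlines()
    conformers: list[Conformer] = []
    k = 0
    block = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        block += 1
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise InputError(f"parse error at block {block}: bad atom count line") from exc
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        atom_lines = lines[k + 2 : k + 2 + n]
        if len(atom_lines) != n:
            raise InputError(f"parse error at block {block}: truncated coordinates")
        atoms: list[str] = []
        coords = np.empty((n, 3))
        for row, line in enumerate(atom_lines):
            parts = line.split()
            if len(parts) < 4:
                raise InputError(f"parse error at block {block}: bad atom line {row + 1}")
            atoms.append(parts[0])
            try:
                coords[row] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise InputError(
                    f"parse error at block {block}: bad coordinate on atom line {row + 1}"
                ) from exc
        match = _FLOAT_RE.search(comment)
        energy = EnergyRecord(electronic=float(match.group(0))) if match else None
        conformers.append(Conformer(atoms=atoms, coords=coords, energy=energy, label=str(block)))
        k += 2 + n
    ensemble = Ensemble(conformers=conformers)
    return validate_ensemble(ensemble)


def write_multixyz(ensemble: Ensemble, path: PathLike) -> None:
    """Write an ensemble as concatenated XYZ blocks (energy in comment)."""
    out = []
    for conf in ensemble:
        out.append(str(conf.n_atoms))
        if conf.energy is not None and conf.energy.has("electronic"):
            out.append(f"{conf.energy.get('electronic'):.10f}")
        else:
            out.append(conf.label or "")
        for sym, (x, y, z) in zip(conf.atoms, conf.coords):
            out.append(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


# ------------------------------------------------------------- energy CSV


def read_energy_csv(path: PathLike) -> dict[str, EnergyRecord]:
    """Energy table: columns label, electronic, enthalpy, gibbs (Hartree)."""
    df = pd.read_csv(path, dtype={"label": str})
    required = {"label"}
    if not required <= set(df.columns):
        raise InputError("energy CSV needs a 'label' column")
    records: dict[str, EnergyRecord] = {}
    for _, row in df.iterrows():
        kwargs = {}
        for f in ("electronic", "enthalpy", "gibbs"):
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = float(row[f])
        if not kwargs:
            raise InputError(f"no energies for conformer {row['label']!r}")
        records[str(row["label"])] = EnergyRecord(**kwargs)
    return records


def attach_energies(
    ensemble: Ensemble, records: dict[str, EnergyRecord], warn=None
) -> Ensemble:
    """Attach CSV energy records by label; CSV wins over XYZ-comment values."""
    out = []
    for conf in ensemble:
        rec = records.get(conf.label)
        if rec is None:
            out.append(conf)
            continue
        if conf.energy is not None and warn is not None:
            warn(f"conformer {conf.label}: energy CSV overrides XYZ comment energy")
        out.append(Conformer(conf.atoms, conf.coords, rec, conf.label))
    return Ensemble(conformers=out)


# -------------------------------------------------------- frequency tables


def _check_frequency_table(df: pd.DataFrame, label: str, require_vcd: bool) -> None:
    if df["mode"].duplicated().any() or not df["mode"].is_monotonic_increasing:
        raise InputError(f"{label}: mode indices must be unique and ascending")
    if (df["frequency_cm"] <= 0).any():
        raise InputError(
            f"non-minimum structure: {label} has imaginary/non-positive frequencies"
        )
    if require_vcd and df["rotational_strength"].isna().any():
        raise InputError(f"VCD data absent for {label}")


def read_frequency_table(
    path: PathLike,
    dialect: str = "tsv",
    conformer_label: Optional[str] = None,
    require_vcd: bool = True,
) -> pd.DataFrame:
    """Read one conformer's harmonic modes with dipole/rotational strengths.

    Returns a DataFrame with columns ``mode, frequency_cm,
    dipole_strength, rotational_strength`` and ``attrs['conformer_label']``
    set.  The ``tsv`` dialect is the package's interchange format; the
    ``qm_log`` dialect scans a frequency-job text log for ``Frequencies``,
    ``Dip. str.`` and ``Rot. str.`` lines.

    Structures with imaginary (negative) frequencies are rejected: the
    protocol averages over true minima only.  Missing rotational
    strengths raise unless ``require_vcd=False`` (IR-only mode).
    """
    label = conformer_label or Path(path).stem
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in FREQ_TSV_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"frequency tsv missing columns: {missing}")
        df = df[FREQ_TSV_COLUMNS].copy()
    elif dialect == "qm_log":
        df = _parse_qm_log(Path(path).read_text())
    else:
        raise InputError(f"unknown frequency-table dialect {dialect!r}")
    _check_frequency_table(df, label, require_vcd)
    df = df.reset_index(drop=True)
    df.attrs["conformer_label"] = label
    df.attrs["source"] = str(path)
    return df


def _parse_qm_log(text: str) -> pd.DataFrame:
    """Extract Frequencies / Dip. str. / Rot. str. blocks from a log."""
    freqs: list[float] = []
    dips: list[float] = []
    rots: list[float] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("Frequencies"):
            freqs.extend(float(t) for t in stripped.split("--")[-1].split())
        elif stripped.startswith("Dip. str."):
            dips.extend(float(t) for t in stripped.split("--")[-1].split())
        elif stripped.startswith("Rot. str."):
            rots.extend(float(t) for t in stripped.split("--")[-1].split())
    if not freqs:
        raise InputError("qm_log: no 'Frequencies' lines found")
    if len(dips) != len(freqs):
        raise InputError("qm_log: dipole-strength count does not match frequencies")
    rot_col = rots if len(rots) == len(freqs) else [np.nan] * len(freqs)
    if rots and len(rots) != len(freqs):
        raise InputError("qm_log: rotational-strength count does not match frequencies")
    return pd.DataFrame(
        {
            "mode": np.arange(1, len(freqs) + 1),
            "frequency_cm": freqs,
            "dipole_strength": dips,
            "rotational_strength": rot_col,
        }
    )


def write_frequency_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=FREQ_TSV_COLUMNS)


def frequency_table_to_sticks(df: pd.DataFrame, modality: str) -> StickSpectrum:
    """Convert a frequency table to a stick spectrum of one modality."""
    order = np.argsort(df["frequency_cm"].to_numpy(), kind="stable")
    freqs = df["frequency_cm"].to_numpy()[order]
    col = "dipole_strength" if modality == "IR" else "rotational_strength"
    return StickSpectrum(
        modality=modality,
        frequencies=freqs,
        strengths=df[col].to_numpy()[order],
        conformer_label=df.attrs.get("conformer_label", ""),
    )


# ------------------------------------------------------ experimental spectra


def read_experimental(path: PathLike, modality: str = "IR") -> ContinuousSpectrum:
    """Two-column (wavenumber, intensity) text, either axis order.

    Comment lines starting with '#' are ignored.  Non-uniform grids are
    resampled onto a uniform grid at the median spacing.
    """
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise InputError(f"bad spectrum line: {raw!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 8:
        raise InputError("insufficient spectrum: fewer than 8 points")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    wn, inten = arr[order, 0], arr[order, 1]
    steps = np.diff(wn)
    if np.any(steps <= 0):
        raise InputError("duplicate wavenumbers in spectrum")
    if np.max(np.abs(steps - steps[0])) > 1e-9:
        step = float(np.median(steps))
        grid = wn[0] + step * np.arange(int(round((wn[-1] - wn[0]) / step)) + 1)
        inten = np.interp(grid, wn, inten)
        wn = grid
    return ContinuousSpectrum(grid=wn, intensity=inten, modality=modality, metadata={"source": str(path)})


def write_spectrum(spec: ContinuousSpectrum, path: PathLike) -> None:
    """Write a two-column (wavenumber, intensity) text file."""
    with open(path, "w") as fh:
        fh.write(f"# modality: {spec.modality}\n")
        for wn, inten in zip(spec.grid, spec.intensity):
            fh.write(f"{wn:.4f} {inten:.10e}\n")
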