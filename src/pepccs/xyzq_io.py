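"""Readers and writers for geometry and ensemble-manifest files.

The geometry format is standard XYZ extended with an optional fifth numeric
column holding the per-atom partial charge in elementary-charge units
("XYZQ").  No charge-carrying XYZ standard exists; a trailing column is the
common convention of quantum-chemistry exporters and is what this toolkit
reads and writes.  The comment line carries the geometry label.

The ensemble manifest is a delimited text table (comma or tab, autodetected)
with columns ``file``, ``energy``, ``unit`` (hartree or kcal/mol).  Energies
are converted to kcal/mol and stored relative to the ensemble minimum.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .structures import (
    HARTREE_TO_KCAL,
    Atom,
    CompositionError,
    Conformer,
    Ensemble,
    Geometry,
    IonSpec,
)

__all__ = ["read_xyzq", "write_xyzq", "read_ensemble_manifest", "XYZParseError"]


class XYZParseError(ValueError):
    """Malformed XYZ/XYZQ content; the message names the offending line."""


def read_xyzq(path: str | Path) -> Geometry:
    """Read an XYZ file with an optional partial-charge fifth column.

    Missing charge columns read as zero; atom order is preserved.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError as exc:
        raise XYZParseError(
            f"{path}: line 1 must be an atom count, got {lines[0]!r}"
        ) from exc
    if len(lines) < n_atoms + 2:
        raise XYZParseError(
            f"{path}: expected {n_atoms} atom lines, file has {max(0, len(lines) - 2)}"
        )
    label = lines[1].strip() if len(lines) > 1 else ""
    atoms: list[Atom] = []
    for i in range(n_atoms):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) not in (4, 5):
            raise XYZParseError(
                f"{path}: line {lineno}: expected 'symbol x y z [q]', got "
                f"{lines[i + 2]!r}"
            )
        symbol = parts[0]
        try:
            xyz = [float(v) for v in parts[1:4]]
            q = float(parts[4]) if len(parts) == 5 else 0.0
        except ValueError as exc:
            raise XYZParseError(
                f"{path}: line {lineno}: non-numeric coordinate/charge"
            ) from exc
        atoms.append(Atom(symbol, np.array(xyz), q))
    return Geometry(atoms, label=label)


def write_xyzq(geometry: Geometry, path: str | Path) -> None:
    """Write a geometry in the XYZQ dialect with 6-decimal fixed formatting."""
    path = Path(path)
    out = [str(len(geometry)), geometry.label]
    for a in geometry.atoms:
        x, y, z = a.position
        out.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f} {a.charge:10.6f}")
    path.write_text("\n".join(out) + "\n")


def _sniff_delimiter(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_ensemble_manifest(
    path: str | Path,
    peptide_id: str = "",
    charge_state: int = 1,
) -> Ensemble:
    """Load an ensemble from a manifest of per-conformer geometry files.

    Each row names a geometry file (relative paths resolve against the
    manifest's directory), an electronic energy and its unit.  Hartree
    energies convert by 627.5095; stored energies are relative to the
    ensemble minimum.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty manifest")
    header = [c.strip().lower() for c in rows[0]]
    if header[:3] == ["file", "energy", "unit"]:
        rows = rows[1:]
    entries: list[tuple[Path, float]] = []
    for i, row in enumerate(rows, start=1):
        if len(row) < 3:
            raise ValueError(f"{path}: row {i}: expected file,energy,unit")
        fname, energy_s, unit = row[0].strip(), row[1].strip(), row[2].strip().lower()
        fpath = Path(fname)
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        if not fpath.exists():
            raise FileNotFoundError(f"{path}: row {i}: missing geometry file {fpath}")
        energy = float(energy_s)
        if unit in ("hartree", "ha", "au"):
            energy *= HARTREE_TO_KCAL
        elif unit not in ("kcal/mol", "kcal_mol", "kcal"):
            raise ValueError(
                f"{path}: row {i}: unknown energy unit {unit!r} "
                "(declare hartree or kcal/mol; no autodetection)"
            )
        entries.append((fpath, energy))
    geoms = [read_xyzq(f) for f, _ in entries]
    n0 = len(geoms[0])
    for i, g in enumerate(geoms):
        if len(g) != n0:
            raise CompositionError(
                f"{path}: row {i + 1}: conformer has {len(g)} atoms, expected {n0}"
            )
    e = np.array([en for _, en in entries], dtype=float)
    e -= e.min()
    conformers = [
        Conformer(g, float(ei), energy_kind="relative", source_id=str(f))
        for g, (f, _), ei in zip(geoms, entries, e)
    ]
    ion = IonSpec(z=charge_state, mass=geoms[0].total_mass)
    return Ensemble(peptide_id or path.stem, ion, conformers)
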