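"""Domain types for gas-phase ions and conformer ensembles.

The objects here are deliberately thin: an :class:`Atom` is an element symbol,
a Cartesian position in angstrom and a partial charge in elementary-charge
units; a :class:`Geometry` is an ordered list of atoms — the single snapshot
of an ion that every collision-cross-section engine consumes.  Conformers add
an electronic energy (kcal/mol), and an :class:`Ensemble` groups conformers of
one peptide/protomer identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELEMENT_MASSES",
    "UnknownElementError",
    "CompositionError",
    "Atom",
    "Geometry",
    "IonSpec",
    "Conformer",
    "Ensemble",
    "HARTREE_TO_KCAL",
]

#: Atomic masses (Da) for the registered elements.  The registry is closed on
#: purpose: interaction parameters for the buffer-gas potential are keyed by
#: element, and a silently accepted unknown symbol would corrupt CCS values.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00794,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    # He appears only as a buffer/validation species but may occur in toy ions.
    "He": 4.002602,
}

#: Hartree -> kcal/mol.
HARTREE_TO_KCAL = 627.5095

#: Two atoms closer than this (angstrom) are treated as a degenerate overlap.
MIN_ATOM_SEPARATION = 0.1

#: Tolerance (e) on |sum of partial charges - formal charge state|.
CHARGE_SUM_TOLERANCE = 0.02


class UnknownElementError(ValueError):
    """Element symbol not present in the registered element table."""


class CompositionError(ValueError):
    """Geometries that were expected to share atoms/elements do not."""


@dataclass(frozen=True)
class Atom:
    element: str
    position: np.ndarray  # shape (3,), angstrom
    charge: float = 0.0  # elementary charges

    def __post_init__(self) -> None:
        if self.element not in ELEMENT_MASSES:
            raise UnknownElementError(
                f"unknown element symbol {self.element!r}; registered: "
                f"{sorted(ELEMENT_MASSES)}"
            )
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom position components must be finite")
        object.__setattr__(self, "position", pos)

    @property
    def mass(self) -> float:
        return ELEMENT_MASSES[self.element]


@dataclass
class Geometry:
    """An ordered collection of atoms with optional role annotations.

    ``roles`` maps semantic atom names (e.g. ``"n_terminal_n"``,
    ``"c_terminal_ca"``) to atom indices; generators fill it in so downstream
    compactness metrics need not guess termini.
    """

    atoms: list[Atom]
    label: str = ""
    roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("a geometry needs at least one atom")
        pos = self.positions
        if len(self.atoms) > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            dmin = float(d.min())
            if dmin < MIN_ATOM_SEPARATION:
                i, j = np.unravel_index(int(d.argmin()), d.shape)
                raise ValueError(
                    f"atoms {i} and {j} overlap ({dmin:.4f} A < "
                    f"{MIN_ATOM_SEPARATION} A)"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def with_positions(self, positions: np.ndarray, label: str | None = None) -> "Geometry":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("positions shape mismatch")
        atoms = [
            Atom(a.element, positions[i], a.charge) for i, a in enumerate(self.atoms)
        ]
        return Geometry(atoms, self.label if label is None else label, dict(self.roles))

    def with_charges(self, charges: np.ndarray) -> "Geometry":
        charges = np.asarray(charges, dtype=float)
        if charges.shape != (len(self.atoms),):
            raise ValueError("charges shape mismatch")
        atoms = [
            Atom(a.element, a.position, float(charges[i]))
            for i, a in enumerate(self.atoms)
        ]
        return Geometry(atoms, self.label, dict(self.roles))


@dataclass(frozen=True)
class IonSpec:
    """Charge state and mass of the ion; ``z`` is signed and nonzero for
    mobility conversions."""

    z: int
    mass: float  # Da

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("ion mass must be positive")

    @classmethod
    def from_geometry(cls, geometry: Geometry, z: int) -> "IonSpec":
        return cls(z=z, mass=geometry.total_mass)


@dataclass
class Conformer:
    """A geometry with an electronic energy.

    ``energy`` is stored in kcal/mol; ``energy_kind`` tags whether it is an
    absolute electronic energy or already relative to an ensemble minimum.
    """

    geometry: Geometry
    energy: float  # kcal/mol
    energy_kind: str = "relative"  # "relative" | "absolute"
    source_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError("conformer energy must be finite")
        if self.energy_kind not in ("relative", "absolute"):
            raise ValueError("energy_kind must be 'relative' or 'absolute'")

    def check_charge_sum(self, ion: IonSpec, tol: float = CHARGE_SUM_TOLERANCE) -> None:
        total = float(self.geometry.charges.sum())
        if abs(total - ion.z) > tol:
            raise ValueError(
                f"partial charges sum to {total:+.4f} e but charge state is "
                f"{ion.z:+d} (tolerance {tol} e)"
            )


@dataclass
class Ensemble:
    peptide_id: str
    ion: IonSpec
    conformers: list[Conformer]

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("an ensemble needs at least one conformer")
        ref = self.conformers[0].geometry.elements
        for k, c in enumerate(self.conformers[1:], start=1):
            if c.geometry.elements != ref:
                raise CompositionError(
                    f"conformer {k} element composition differs from conformer 0"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def relative_energies(self) -> np.ndarray:
        e = np.array([c.energy for c in self.conformers], dtype=float)
        return e - e.min()
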