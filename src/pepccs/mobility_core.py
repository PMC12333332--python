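"""Buffer-gas models, Mason-Schamp conversions and ion-gas pair potentials.

Unit system
-----------
Length in angstrom, energy in kcal/mol, charge in elementary charges, mass in
dalton.  The Coulomb constant in these units is ``332.0637`` kcal*A/(mol*e^2).
Instrument quantities (drift length, field, pressure, temperature, arrival
time) use the conventional IM-MS units: cm, V/cm, Torr, K, s; CCS is reported
in A^2.

The drift gas is modeled as a single isotropic polarizable pseudo-atom: for
N2 a site of mass 28.0134 Da and polarizability 1.710 A^3 carrying
element-specific 12-6 Lennard-Jones parameters (see
``data/lj_parameters.csv``).  The full diatomic treatment with a quadrupole
is out of scope; the single-site model preserves the qualitative physics —
a van der Waals envelope plus the charge-induced-dipole attraction — that
the trajectory method integrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import constants as sc

from .structures import ELEMENT_MASSES, Geometry, IonSpec

__all__ = [
    "COULOMB_KCAL",
    "KB_KCAL_MOL",
    "BufferGas",
    "MobilityConditions",
    "PairPotentialParams",
    "get_buffer_gas",
    "mobility_from_drift",
    "ccs_from_arrival_time",
    "arrival_time_from_ccs",
    "vdw_energy",
    "coulomb_energy",
    "ion_gas_potential",
    "IonGasPotential",
    "RepulsiveCorePotential",
]

#: Coulomb constant, kcal*A/(mol*e^2).
COULOMB_KCAL = 332.0637
#: Boltzmann constant, kcal/(mol*K);  kB*T = 0.59219 kcal/mol at 298.0 K.
KB_KCAL_MOL = sc.k * sc.Avogadro / (sc.calorie * 1000.0)
#: 1 kcal/mol expressed in Da*(A/ps)^2 (trajectory-integrator energy unit).
KCAL_TO_DA_A2_PS2 = sc.calorie * 1000.0 / sc.Avogadro / sc.atomic_mass / 1e-20 * 1e-24

_GAS_CONSTANTS = {
    # name: (mass Da, polarizability A^3, PA gas radius A)
    "N2": (28.0134, 1.710, 1.850),
    "He": (4.002602, 0.205, 1.150),
}


@dataclass(frozen=True)
class BufferGas:
    """Drift-gas physical model: mass, polarizability, per-element LJ table.

    ``pa_radius`` is the effective gas hard radius used by the projection
    approximation (added to each ion atom's half-``r_min``).
    """

    name: str
    mass: float  # Da
    polarizability: float  # A^3
    lj_params: dict[str, tuple[float, float]]  # element -> (epsilon, r_min)
    pa_radius: float  # A

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.polarizability <= 0:
            raise ValueError("gas mass and polarizability must be positive")
        for el, (eps, rmin) in self.lj_params.items():
            if eps <= 0 or rmin <= 0:
                raise ValueError(f"nonpositive LJ parameters for element {el}")

    def lj(self, element: str) -> tuple[float, float]:
        try:
            return self.lj_params[element]
        except KeyError:
            raise KeyError(
                f"no {self.name} interaction parameters for element {element!r}"
            ) from None

    def collision_radius(self, element: str) -> float:
        """Hard collision radius (A) for the projection approximation."""
        return self.lj(element)[1] / 2.0 + self.pa_radius


def _load_lj_table() -> pd.DataFrame:
    with resources.files("pepccs.data").joinpath("lj_parameters.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


_LJ_TABLE: pd.DataFrame | None = None


def get_buffer_gas(name: str) -> BufferGas:
    """Return the registered buffer-gas model (``N2`` or ``He``)."""
    global _LJ_TABLE
    if name not in _GAS_CONSTANTS:
        raise KeyError(f"unknown buffer gas {name!r}; registered: N2, He")
    if _LJ_TABLE is None:
        _LJ_TABLE = _load_lj_table()
    sub = _LJ_TABLE[_LJ_TABLE["gas"] == name]
    params = {
        str(r.element): (float(r.epsilon_kcal_mol), float(r.r_min_angstrom))
        for r in sub.itertuples()
    }
    missing = set(ELEMENT_MASSES) - set(params)
    if missing:
        raise RuntimeError(f"LJ table for {name} missing elements {sorted(missing)}")
    mass, alpha, pa_r = _GAS_CONSTANTS[name]
    return BufferGas(name, mass, alpha, params, pa_r)


@dataclass
class MobilityConditions:
    """Drift-tube operating conditions.

    The buffer-gas number density defaults to the ideal-gas value
    ``N = P/(kB*T)`` (P in Torr converted to Pa) so that pressure and number
    density stay mutually consistent; pass ``number_density`` to override.
    """

    temperature: float  # K
    pressure: float  # Torr
    field: float  # V/cm
    drift_length: float  # cm
    arrival_time: float | None = None  # s
    number_density: float | None = None  # cm^-3

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "field", "drift_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.number_density is None:
            p_pa = self.pressure * sc.atm / 760.0
            n_m3 = p_pa / (sc.k * self.temperature)
            self.number_density = n_m3 * 1e-6  # cm^-3


def mobility_from_drift(drift_velocity: float, field: float) -> float:
    """Ion mobility K = v_d / E  (cm^2 V^-1 s^-1)."""
    if field <= 0:
        raise ValueError("field must be positive")
    return drift_velocity / field


def _mason_schamp_prefactor(cond: MobilityConditions, ion: IonSpec, gas: BufferGas) -> float:
    """Everything in the Mason-Schamp CCS expression except the arrival time.

    Returns d(Omega)/d(t_A) in A^2 per second.
    """
    if ion.z == 0:
        raise ValueError("charge state must be nonzero for mobility conversions")
    T = cond.temperature
    mi_kg = ion.mass * sc.atomic_mass
    mb_kg = gas.mass * sc.atomic_mass
    reduced = np.sqrt(1.0 / mi_kg + 1.0 / mb_kg)
    e_field = cond.field * 100.0  # V/m
    length = cond.drift_length / 100.0  # m
    n_m3 = cond.number_density * 1e6  # m^-3
    # The textbook form carries 760/P and T/273.15 to standardize the
    # mobility; those factors exactly convert the experimental number density
    # to the STP value, so with N taken at the drift-tube conditions they
    # cancel:  (760/P)(T/273.15)(1/N_STP) = 1/N_exp.
    pref = (
        np.sqrt(18.0 * np.pi) / 16.0
        * abs(ion.z) * sc.e / np.sqrt(sc.k * T)
        * reduced
        * e_field / length
        * (1.0 / n_m3)
    )
    return pref * 1e20  # m^2 -> A^2


def ccs_from_arrival_time(cond: MobilityConditions, ion: IonSpec, gas: BufferGas) -> float:
    """Collision cross section (A^2) from the arrival time via Mason-Schamp.

    Low-field relation: Omega = sqrt(18 pi)/16 * z e / sqrt(kB T) *
    sqrt(1/m_i + 1/m_b) * (t_A E / L) * 760/P * T/273.15 * 1/N_STP, where
    the pressure/temperature standardization factors together with the STP
    number density reduce to 1/N at the drift-tube conditions — the form
    evaluated here with ``cond.number_density``.
    """
    if cond.arrival_time is None:
        raise ValueError("conditions carry no arrival time")
    if cond.arrival_time <= 0:
        raise ValueError("arrival time must be positive")
    return _mason_schamp_prefactor(cond, ion, gas) * cond.arrival_time


def arrival_time_from_ccs(
    ccs: float, cond: MobilityConditions, ion: IonSpec, gas: BufferGas
) -> float:
    """Arrival time (s) that Mason-Schamp assigns to a CCS of ``ccs`` A^2."""
    if ccs <= 0:
        raise ValueError("CCS must be positive")
    return ccs / _mason_schamp_prefactor(cond, ion, gas)


@dataclass(frozen=True)
class PairPotentialParams:
    """Parameters of one ion-atom/gas pair interaction."""

    epsilon: float  # kcal/mol
    r_min: float  # A
    gas_polarizability: float = 0.0  # A^3

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.r_min <= 0:
            raise ValueError("epsilon and r_min must be positive")


def vdw_energy(params: PairPotentialParams, r_ab: float) -> float:
    """12-6 van der Waals pair energy: eps*[(r_min/r)^12 - 2 (r_min/r)^6].

    The minimum sits at ``r_ab = r_min`` with depth ``-epsilon``.
    """
    if r_ab <= 0:
        raise ValueError("pair distance must be positive")
    s6 = (params.r_min / r_ab) ** 6
    return params.epsilon * (s6 * s6 - 2.0 * s6)


def coulomb_energy(q_a: float, q_b: float, r_ab: float) -> float:
    """Coulomb pair energy 332.0637 * q_a q_b / r_ab (kcal/mol)."""
    if r_ab <= 0:
        raise ValueError("pair distance must be positive")
    return COULOMB_KCAL * q_a * q_b / r_ab


class IonGasPotential:
    """Ion--buffer-gas interaction: 12-6 sum plus charge-induced dipole.

    For a probe (gas pseudo-atom) at x the energy is

        V(x) = sum_a eps_a [(r_a*/r)^12 - 2 (r_a*/r)^6]
               - (k_C * alpha / 2) |sum_a q_a rhat_a / r_a^2|^2

    where the second term is the polarization of the gas by the Coulomb field
    of the ion's partial charges (k_C = 332.0637, alpha in A^3).  Energies in
    kcal/mol; the gradient is analytic.  Batched evaluation over probe
    positions of shape (B, 3).
    """

    min_probe_distance = 0.05  # A

    def __init__(self, geometry: Geometry, gas: BufferGas):
        self.positions = geometry.positions  # (N, 3)
        self.charges = geometry.charges
        eps, rmin = zip(*(gas.lj(el) for el in geometry.elements))
        self.eps = np.asarray(eps)
        self.rmin = np.asarray(rmin)
        self.alpha = gas.polarizability
        self.has_charges = bool(np.any(self.charges != 0.0))

    def site_distances(self, x: np.ndarray) -> np.ndarray:
        """Distances (B, N) from probes to ion atoms."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = x[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def evaluate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (energy (B,), gradient (B, 3)) at probe positions x (B, 3)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        dvec = x[:, None, :] - self.positions[None, :, :]  # (B, N, 3)
        r = np.linalg.norm(dvec, axis=-1)  # (B, N)
        if np.any(r <= self.min_probe_distance):
            raise ValueError("probe coincides with an ion atom")
        inv_r = 1.0 / r
        s6 = (self.rmin[None, :] * inv_r) ** 6
        e_vdw = np.sum(self.eps[None, :] * (s6 * s6 - 2.0 * s6), axis=1)
        # dV/dr for one pair: eps * (-12 s12 + 12 s6) / r
        dVdr = self.eps[None, :] * 12.0 * (s6 - s6 * s6) * inv_r  # (B, N)
        grad = np.sum(dVdr[..., None] * dvec * inv_r[..., None], axis=1)  # (B, 3)
        if self.has_charges:
            # Coulomb field of the partial charges at the probe (e/A^2 units):
            #   F = sum_a q_a (x - x_a) / r_a^3
            q = self.charges[None, :, None]
            inv_r3 = inv_r**3
            field = np.sum(q * dvec * inv_r3[..., None], axis=1)  # (B, 3)
            c = COULOMB_KCAL * self.alpha / 2.0
            e_ind = -c * np.sum(field * field, axis=-1)
            # dF/dx: sum_a q_a [ I / r^3 - 3 (d x d) / r^5 ]  (symmetric 3x3)
            eye = np.eye(3)
            jac = np.sum(
                q[..., None]
                * (
                    eye[None, None, :, :] * inv_r3[..., None, None]
                    - 3.0
                    * dvec[..., :, None]
                    * dvec[..., None, :]
                    * (inv_r**5)[..., None, None]
                ),
                axis=1,
            )  # (B, 3, 3)
            grad_ind = -2.0 * c * np.einsum("bij,bj->bi", jac, field)
            e_vdw = e_vdw + e_ind
            grad = grad + grad_ind
        return e_vdw, grad


def ion_gas_potential(
    geometry: Geometry, gas: BufferGas, probe_position: np.ndarray
) -> tuple[float, np.ndarray]:
    """Energy (kcal/mol) and gradient (kcal/mol/A) at a single probe point."""
    pot = IonGasPotential(geometry, gas)
    e, g = pot.evaluate(np.asarray(probe_position, dtype=float)[None, :])
    return float(e[0]), g[0]


class RepulsiveCorePotential:
    """Steep repulsive power-law core ``V = eps_ref (R/r)^n`` about the origin.

    Serves as the near-hard-sphere reference potential for validating the
    trajectory engine: as n grows the scattering approaches that of a hard
    sphere whose radius is the classical turning point at the collision
    energy, ``R (eps_ref/E)^(1/n)``.
    """

    min_probe_distance = 1e-6

    def __init__(self, radius: float, n: int = 100, eps_ref: float = KB_KCAL_MOL * 298.0):
        self.radius = radius
        self.n = n
        self.eps_ref = eps_ref
        self.positions = np.zeros((1, 3))

    def site_distances(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.linalg.norm(x, axis=-1)[:, None]

    def evaluate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        r = np.linalg.norm(x, axis=-1)
        e = self.eps_ref * (self.radius / r) ** self.n
        dVdr = -self.n * e / r
        grad = dVdr[:, None] * x / r[:, None]
        return e, grad

    def turning_radius(self, energy: float) -> float:
        """Classical turning point of a head-on collision at ``energy``."""
        return self.radius * (self.eps_ref / energy) ** (1.0 / self.n)
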