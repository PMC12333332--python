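"""Deterministic generators for test inputs.

Everything the toolkit's tests and examples consume is built here from code:
idealized polyglycine chains from standard internal coordinates, toy ions
with analytically known CCS behavior, and conformer ensembles with planted
cluster structure.  All generators are seed-deterministic and emit valid
:class:`~pepccs.structures.Geometry`/:class:`~pepccs.structures.Ensemble`
objects.

The polyglycine charge assignment is a documented toy scheme — a unit
protonation charge smeared over the N-terminal ammonium group — and is
explicitly not a surrogate for population-analysis charges.
"""

from __future__ import annotations

import numpy as np

from .structures import Atom, Conformer, Ensemble, Geometry, IonSpec

__all__ = ["build_polyglycine", "make_toy_ion", "make_clustered_ensemble"]

# Ideal peptide internal coordinates (angstrom, degrees).
_B = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C=O": 1.231,
    "C-OT": 1.340,
    "N-H": 1.010,
    "CA-H": 1.090,
    "O-H": 0.970,
}
_A = {
    "N-CA-C": 111.0,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "C-N-H": 119.0,
    "N-CA-H": 109.5,
    "CA-C-OT": 111.4,
    "C-OT-H": 106.0,
}
_CONFORMATIONS = {
    # (phi, psi): backbone dihedrals applied to every residue
    "extended": (180.0, 180.0),
    "helical": (-57.0, -47.0),
}
_OMEGA = 180.0  # trans peptide bond


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float,
           dihedral: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of a new atom bonded to ``c``."""
    ang = np.deg2rad(angle)
    dih = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_polyglycine(
    n_residues: int, conformation: str = "extended", protonated: bool = True
) -> Geometry:
    """Idealized polyglycine chain from standard internal coordinates.

    ``conformation`` sets the backbone dihedrals: ``extended`` (all-trans,
    maximally stretched) or ``helical`` (alpha-helical phi/psi).  Protonation
    adds a third N-terminal hydrogen and smears a +1 charge equally over the
    ammonium N and its three hydrogens (0.25 e each).  Atom roles
    ``n_terminal_n`` and ``c_terminal_ca`` are annotated for the N-to-C
    compactness metric.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if conformation not in _CONFORMATIONS:
        raise ValueError(f"unknown conformation {conformation!r}")
    phi, psi = _CONFORMATIONS[conformation]

    # backbone N, CA, C per residue
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_A["N-CA-C"])
    c0 = ca0 + _B["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = bb[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B["C-N"], _A["CA-C-N"], psi)
        ca = _place(prev["CA"], prev["C"], n, _B["N-CA"], _A["C-N-CA"], _OMEGA)
        c = _place(prev["C"], n, ca, _B["CA-C"], _A["N-CA-C"], phi)
        bb.append({"N": n, "CA": ca, "C": c})

    atoms: list[tuple[str, np.ndarray]] = []
    roles: dict[str, int] = {}

    def add(el: str, pos: np.ndarray, role: str | None = None) -> None:
        if role is not None:
            roles[role] = len(atoms)
        atoms.append((el, pos))

    for i, res in enumerate(bb):
        n, ca, c = res["N"], res["CA"], res["C"]
        add("N", n, "n_terminal_n" if i == 0 else None)
        if i == 0:
            # N-terminal amine hydrogens (third one is the proton)
            h_dihedrals = [60.0, 300.0] + ([180.0] if protonated else [])
            for k, dih in enumerate(h_dihedrals):
                add("H", _place(c, ca, n, _B["N-H"], 109.5, dih),
                    "proton" if protonated and k == 2 else None)
        else:
            prev_c = bb[i - 1]["C"]
            prev_ca = bb[i - 1]["CA"]
            add("H", _place(prev_ca, prev_c, n, _B["N-H"], _A["C-N-H"], _OMEGA + 180.0))
        add("C", ca, "c_terminal_ca" if i == n_residues - 1 else None)
        for dih_off in (120.0, -120.0):
            add("H", _place(c, n, ca, _B["CA-H"], _A["N-CA-H"], dih_off))
        add("C", c)
        if i < n_residues - 1:
            nxt = bb[i + 1]["N"]
            add("O", _place(nxt, ca, c, _B["C=O"], _A["CA-C-O"], 180.0))
        else:
            # C-terminal carboxylic acid: carbonyl O anti, hydroxyl O syn + H
            o = _place(n, ca, c, _B["C=O"], _A["CA-C-O"], psi + 180.0)
            add("O", o)
            ot = _place(n, ca, c, _B["C-OT"], _A["CA-C-OT"], psi)
            add("O", ot)
            add("H", _place(ca, c, ot, _B["O-H"], _A["C-OT-H"], 180.0))

    charges = np.zeros(len(atoms))
    if protonated:
        nt = roles["n_terminal_n"]
        # ammonium N and its three H's follow the N in insertion order
        for idx in (nt, nt + 1, nt + 2, nt + 3):
            charges[idx] = 0.25
    geom = Geometry(
        [Atom(el, p, float(q)) for (el, p), q in zip(atoms, charges)],
        label=f"polyglycine-{n_residues}-{conformation}"
        + ("-protonated" if protonated else ""),
    )
    geom.roles = roles
    return geom


def make_toy_ion(kind: str, **params) -> Geometry:
    """Toy ions with exact, documented coordinates and charges.

    Kinds: ``single_atom`` (element, charge), ``rigid_dimer`` (elements,
    separation — atoms at +-d/2 on x), ``charged_dipole_probe`` (separation,
    delta, net — two atoms carrying net/2 +- delta).
    """
    if kind == "single_atom":
        el = params.get("element", "He")
        q = params.get("charge", 0.0)
        return Geometry([Atom(el, np.zeros(3), q)], label=f"single-{el}")
    if kind == "rigid_dimer":
        els = params.get("elements", ("C", "C"))
        d = params.get("separation", 3.0)
        qs = params.get("charges", (0.0, 0.0))
        return Geometry(
            [
                Atom(els[0], np.array([-d / 2.0, 0.0, 0.0]), qs[0]),
                Atom(els[1], np.array([+d / 2.0, 0.0, 0.0]), qs[1]),
            ],
            label=f"dimer-{els[0]}{els[1]}-{d:g}A",
        )
    if kind == "charged_dipole_probe":
        d = params.get("separation", 8.0)
        delta = params.get("delta", 0.3)
        net = params.get("net", 0.0)
        return Geometry(
            [
                Atom("C", np.array([-d / 2.0, 0.0, 0.0]), net / 2.0 + delta),
                Atom("C", np.array([+d / 2.0, 0.0, 0.0]), net / 2.0 - delta),
            ],
            label=f"dipole-{delta:g}e-{d:g}A",
        )
    raise ValueError(f"unknown toy-ion kind {kind!r}")


_PEPTIDE_LIKE_ELEMENTS = ("C", "C", "C", "N", "O")


def _random_chain(rng: np.random.Generator, n_atoms: int) -> np.ndarray:
    """Compact self-avoiding random chain with ~1.5 A steps (peptide-like
    heavy-atom skeleton)."""
    pos = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= 1.5 / np.linalg.norm(step)
            # bias toward the origin to keep the cloud compact
            cand = pos[i - 1] + step - 0.04 * pos[i - 1]
            if np.min(np.linalg.norm(pos[:i] - cand, axis=1)) > 1.2:
                pos[i] = cand
                break
        else:
            raise RuntimeError("chain generation stalled")
    return pos - pos.mean(axis=0)


def _kabsch_rmsd_plain(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(a.T @ b)
    s[-1] *= np.sign(np.linalg.det(u @ vt))
    msd = (np.sum(a * a) + np.sum(b * b) - 2.0 * s.sum()) / len(a)
    return float(np.sqrt(max(msd, 0.0)))


def make_clustered_ensemble(
    n_conformers: int = 60,
    n_clusters: int = 3,
    within_spread: float = 0.4,
    between_separation: float = 2.0,
    energy_model: str = "basin",
    n_atoms: int = 40,
    seed: int = 0,
    peptide_id: str = "synthetic",
) -> tuple[Ensemble, np.ndarray]:
    """Conformer ensemble with planted cluster structure plus true labels.

    ``n_clusters`` template geometries are perturbations of one random
    compact chain, resampled until every template pair is at least
    ``between_separation`` (A, superposed RMSD) apart; members jitter around
    their template with RMSD ~ ``within_spread`` and are handed out in a
    random rigid pose.  The ``basin`` energy model gives each cluster a
    random offset in [0, 6] kcal/mol plus intra-cluster noise in [0, 0.5];
    ``uniform`` draws iid energies in [0, 6].
    """
    if n_clusters > n_conformers:
        raise ValueError("n_clusters cannot exceed n_conformers")
    if between_separation <= 0:
        raise ValueError("between_separation must be positive")
    if energy_model not in ("uniform", "basin"):
        raise ValueError("energy_model must be 'uniform' or 'basin'")
    rng = np.random.default_rng(seed)
    base = _random_chain(rng, n_atoms)
    sigma_t = 1.35 * between_separation / np.sqrt(6.0)
    templates = None
    for _ in range(60):
        cand = [base + rng.normal(scale=sigma_t, size=base.shape) for _ in range(n_clusters)]
        ok = all(
            _kabsch_rmsd_plain(cand[i], cand[j]) >= between_separation
            for i in range(n_clusters)
            for j in range(i + 1, n_clusters)
        )
        if ok:
            templates = cand
            break
    if templates is None:
        raise RuntimeError(
            "could not place templates at the requested separation; "
            "increase atom count or reduce n_clusters"
        )
    elements = [
        _PEPTIDE_LIKE_ELEMENTS[i % len(_PEPTIDE_LIKE_ELEMENTS)] for i in range(n_atoms)
    ]
    labels = np.sort(np.arange(n_conformers) % n_clusters)
    offsets = rng.uniform(0.0, 6.0, size=n_clusters)
    sigma_w = within_spread / np.sqrt(3.0)
    conformers = []
    for i, lab in enumerate(labels):
        for _ in range(100):
            pos = templates[lab] + rng.normal(scale=sigma_w, size=base.shape)
            # random rigid pose so clustering must superpose
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                    [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                    [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
                ]
            )
            pos = pos @ rot.T + rng.uniform(-5, 5, size=3)
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() > 0.15:
                break
        if energy_model == "basin":
            energy = float(offsets[lab] + rng.uniform(0.0, 0.5))
        else:
            energy = float(rng.uniform(0.0, 6.0))
        geom = Geometry(
            [Atom(el, p) for el, p in zip(elements, pos)],
            label=f"{peptide_id}-conf{i}",
        )
        conformers.append(
            Conformer(geom, energy, energy_kind="relative", source_id=f"planted:{lab}")
        )
    e = np.array([c.energy for c in conformers])
    for c, ei in zip(conformers, e - e.min()):
        c.energy = float(ei)
    ion = IonSpec(z=1, mass=conformers[0].geometry.total_mass)
    return Ensemble(peptide_id, ion, conformers), labels
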