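"""Conformer-ensemble reduction and Boltzmann-weighted ensemble CCS.

A conformer ensemble (hundreds to ~1000 geometries from a conformer
generator) is reduced to a handful of representative centers by clustering
on pairwise RMSD after optimal rigid superposition, then the ensemble CCS is
the Boltzmann-weighted average over conformers within an energy window of
the minimum (default 3 kcal/mol, boundary inclusive, 298 K).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .ccs_engines import CCSResult
from .mobility_core import KB_KCAL_MOL
from .structures import CompositionError, Ensemble, Geometry

__all__ = [
    "ClusterAssignment",
    "BoltzmannWeights",
    "pairwise_rmsd",
    "rmsd_matrix",
    "cluster_ensemble",
    "boltzmann_weights",
    "ensemble_ccs",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster labels plus one centroid conformer per cluster.

    The centroid of a cluster is the member minimizing the summed RMSD to
    all other members (the medoid).  ``rmsd_matrix_digest`` is a SHA-256
    checksum of the pairwise RMSD matrix for provenance.
    """

    labels: np.ndarray  # (n,) int cluster ids, 0..k-1
    centroid_ids: np.ndarray  # (k,) conformer indices
    rmsd_matrix_digest: str

    @property
    def n_clusters(self) -> int:
        return len(self.centroid_ids)


@dataclass(frozen=True)
class BoltzmannWeights:
    kept_ids: np.ndarray  # indices of conformers inside the window
    weights: np.ndarray  # fractions over the kept set, sum to 1
    window: float  # kcal/mol
    temperature: float  # K


def _heavy_mask(geometry: Geometry) -> np.ndarray:
    return np.array([el != "H" for el in geometry.elements], dtype=bool)


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD over proper rotations + translations (no reflection).

    The residual is evaluated from the explicitly rotated coordinates, which
    avoids the catastrophic cancellation of the inner-product shortcut for
    near-identical structures.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    rot = u @ vt
    return float(np.sqrt(np.mean(np.sum((a @ rot - b) ** 2, axis=1))))


def pairwise_rmsd(
    a: Geometry, b: Geometry, atom_mask: np.ndarray | None = None
) -> float:
    """Minimum RMSD (A) between two geometries under optimal superposition.

    ``atom_mask`` selects the atoms entering the fit (default: all); the two
    geometries must agree in atom count and element order under the mask.
    """
    if atom_mask is None:
        mask = np.ones(len(a), dtype=bool)
    else:
        mask = np.asarray(atom_mask, dtype=bool)
    if len(a) != len(b):
        raise CompositionError("geometries differ in atom count")
    ea = [el for el, m in zip(a.elements, mask) if m]
    eb = [el for el, m in zip(b.elements, mask) if m]
    if ea != eb:
        raise CompositionError("geometries differ in element order under the mask")
    return _kabsch_rmsd(a.positions[mask], b.positions[mask])


def rmsd_matrix(ensemble: Ensemble, heavy_only: bool = True) -> np.ndarray:
    """All-pairs RMSD matrix over an ensemble (heavy atoms by default).

    Kabsch superpositions are evaluated in vectorized blocks (stacked 3x3
    SVDs), which keeps thousand-conformer ensembles tractable.
    """
    geoms = [c.geometry for c in ensemble.conformers]
    mask = _heavy_mask(geoms[0]) if heavy_only else np.ones(len(geoms[0]), bool)
    coords = np.array([g.positions[mask] for g in geoms])  # (n, m, 3)
    coords = coords - coords.mean(axis=1, keepdims=True)
    n, m, _ = coords.shape
    sq = np.einsum("nmi,nmi->n", coords, coords)
    out = np.zeros((n, n))
    ii, jj = np.triu_indices(n, k=1)
    block = 20000
    for s in range(0, len(ii), block):
        bi, bj = ii[s : s + block], jj[s : s + block]
        h = np.einsum("pmi,pmj->pij", coords[bi], coords[bj])  # (p, 3, 3)
        u, sv, vt = np.linalg.svd(h)
        det = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", u, vt)))
        sv[:, -1] *= det
        msd = (sq[bi] + sq[bj] - 2.0 * sv.sum(axis=1)) / m
        out[bi, bj] = out[bj, bi] = np.sqrt(np.maximum(msd, 0.0))
    return out


def _medoid(ids: np.ndarray, dm: np.ndarray) -> int:
    sub = dm[np.ix_(ids, ids)]
    return int(ids[int(np.argmin(sub.sum(axis=1)))])


def cluster_ensemble(
    ensemble: Ensemble,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    heavy_only: bool = True,
    seed: int = 0,
) -> ClusterAssignment:
    """Partition an ensemble into conformational families and pick centroids.

    The all-pairs RMSD matrix feeds a k-nearest-neighbour affinity graph
    (``n_neighbors`` per conformer, union-symmetrized) with Gaussian edge
    weights ``w_ij = exp(-d_ij^2 / (2 sigma^2))``, kernel width sigma =
    median retained-edge RMSD; the graph is partitioned by seeded Louvain
    modularity community detection.  Sparsifying to nearest neighbours keeps
    the partition scale local, so many small conformational families are not
    merged by the resolution limit of modularity on a dense graph.  Each
    cluster's representative is its medoid.
    """
    n = len(ensemble)
    dm = rmsd_matrix(ensemble, heavy_only=heavy_only)
    digest = hashlib.sha256(np.round(dm, 8).tobytes()).hexdigest()
    if n == 1:
        return ClusterAssignment(np.zeros(1, int), np.zeros(1, int), digest)
    k_nn = min(n_neighbors, n - 1)
    order = np.argsort(dm, axis=1, kind="stable")
    keep = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_nn)
    cols = order[:, 1 : k_nn + 1].ravel()  # skip self (distance 0)
    keep[rows, cols] = True
    keep |= keep.T
    sigma = float(np.median(dm[keep]))
    if sigma <= 0.0:
        # all conformers identical: one cluster
        return ClusterAssignment(np.zeros(n, int), np.array([_medoid(np.arange(n), dm)]), digest)
    w = np.where(keep, np.exp(-(dm**2) / (2.0 * sigma**2)), 0.0)
    np.fill_diagonal(w, 0.0)
    g = nx.from_numpy_array(w)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    centroids = []
    for k, members in enumerate(communities):
        ids = np.asarray(members, dtype=int)
        labels[ids] = k
        centroids.append(_medoid(ids, dm))
    return ClusterAssignment(labels, np.asarray(centroids, dtype=int), digest)


def boltzmann_weights(
    relative_energies: np.ndarray,
    window: float = 3.0,
    temperature: float = 298.0,
) -> BoltzmannWeights:
    """Boltzmann weights over conformers within an energy window.

    Energies (kcal/mol) are shifted so the minimum is zero; conformers with
    relative energy <= ``window`` (boundary inclusive) are kept and weighted
    by ``exp(-dE / kB T)`` normalized over the kept set.  At 298.0 K,
    kB*T = 0.59219 kcal/mol.
    """
    e = np.asarray(relative_energies, dtype=float)
    if e.size == 0:
        raise ValueError("no conformer energies supplied")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    e = e - e.min()
    kept = np.flatnonzero(e <= window)
    kt = KB_KCAL_MOL * temperature
    w = np.exp(-e[kept] / kt)
    w /= w.sum()
    return BoltzmannWeights(kept, w, window, temperature)


def ensemble_ccs(conformer_ccs: list[CCSResult], weights: BoltzmannWeights) -> CCSResult:
    """Boltzmann-weighted average CCS over the kept conformers.

    ``conformer_ccs`` holds one result per kept conformer, in kept order;
    standard errors propagate as sqrt(sum w_i^2 se_i^2).
    """
    if len(conformer_ccs) != len(weights.kept_ids):
        raise ValueError(
            f"{len(weights.kept_ids)} kept conformers but "
            f"{len(conformer_ccs)} CCS results"
        )
    w = weights.weights
    vals = np.array([r.ccs for r in conformer_ccs])
    ses = np.array([r.std_error for r in conformer_ccs])
    engine = conformer_ccs[0].engine
    return CCSResult(
        ccs=float(np.sum(w * vals)),
        std_error=float(np.sqrt(np.sum(w**2 * ses**2))),
        engine=engine,
        config={
            "ensemble": True,
            "window_kcal_mol": weights.window,
            "temperature_K": weights.temperature,
            "n_members": int(len(w)),
        },
        seed=conformer_ccs[0].seed,
    )
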