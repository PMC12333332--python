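"""Reduce a conformer ensemble and form its Boltzmann-weighted CCS.

Mirrors the production workflow downstream of quantum-chemistry outputs: a
conformer pool is clustered on pairwise RMSD, cluster centroids within
3 kcal/mol of the minimum are weighted by exp(-dE/kT), and the ensemble CCS
is the weighted average.  A planted synthetic ensemble stands in for real
conformer-generator output so the script runs offline in seconds.
"""

import numpy as np

from pepccs import (
    boltzmann_weights,
    ccs_projection_approximation,
    cluster_ensemble,
    ensemble_ccs,
    get_buffer_gas,
    make_clustered_ensemble,
)

gas = get_buffer_gas("N2")
ens, planted = make_clustered_ensemble(
    n_conformers=120, n_clusters=4, within_spread=0.35, between_separation=2.0,
    energy_model="basin", seed=8,
)
print(f"ensemble: {len(ens)} conformers, {len(set(planted.tolist()))} planted families")

assignment = cluster_ensemble(ens)
print(f"clustering found {assignment.n_clusters} families; "
      f"centroids = conformers {assignment.centroid_ids.tolist()}")

centroid_energies = np.array([ens.conformers[i].energy for i in assignment.centroid_ids])
weights = boltzmann_weights(centroid_energies, window=3.0, temperature=298.0)
kept = [int(assignment.centroid_ids[i]) for i in weights.kept_ids]
print(f"{len(kept)} centroid(s) within 3 kcal/mol of the minimum; "
      f"weights = {np.round(weights.weights, 3).tolist()}")

member_ccs = [
    ccs_projection_approximation(ens.conformers[i].geometry, gas, 200, 1500, seed=3)
    for i in kept
]
total = ensemble_ccs(member_ccs, weights)
for i, res in zip(kept, member_ccs):
    print(f"  conformer {i:3d}: {res.ccs:7.1f} +- {res.std_error:.1f} A^2")
print(f"ensemble CCS: {total.ccs:.1f} +- {total.std_error:.1f} A^2")
# The ensemble value is a convex combination of its members: low-energy
# families dominate, and families above the window contribute nothing.
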