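# Per-element 12-6 Lennard-Jones parameters for the ion--buffer-gas pair
# potential, one row per (gas, ion element). epsilon in kcal/mol, r_min in
# angstrom (distance at the potential minimum; r_min = sigma * 2^(1/6)).
# N2 values follow the trajectory-method N2 parameterization lineage of
# Campuzano et al., Anal. Chem. 2012, 84, 1026 (MOBCAL-N2); He values follow
# Mesleh et al., J. Phys. Chem. 1996, 100, 16082 (MOBCAL-He). Sulfur entries
# are transferred literature estimates. v1
gas,element,epsilon_kcal_mol,r_min_angstrom
N2,H,0.018910,2.671460
N2,C,0.107232,4.018414
N2,N,0.101466,4.332704
N2,O,0.101466,3.659227
N2,S,0.129831,4.040863
N2,He,0.030901,3.415814
He,H,0.014989,2.671460
He,C,0.030901,3.415814
He,N,0.030901,3.415814
He,O,0.030901,3.415814
He,S,0.031132,3.928618
He,He,0.020000,2.964000
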