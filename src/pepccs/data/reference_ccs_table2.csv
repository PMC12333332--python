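# Computed Boltzmann-weighted CCS (A^2) for the same 23 peptides at
# B3LYP/6-31G(d,p) geometries (p-type polarization on hydrogens) with D3(0)
# and D3(BJ) dispersion. Experimental column repeated for convenience. v1
peptide,exp,"D3(0)-B3LYP/6-31G(d,p)","D3(BJ)-B3LYP/6-31G(d,p)"
ANELLINVK,322.50,335.91,332.21
AWEVTVK,278.20,286.04,294.42
AWSVAR,255.70,274.57,265.11
DYYFALAHTVR,374.80,389.49,392.12
ELR,200.30,207.93,199.88
EWTR,229.70,237.44,237.03
EYK,203.20,209.74,209.02
FAAYLER,293.10,292.77,287.53
FLNR,231.60,237.89,237.60
FPK,184.70,188.09,187.84
FSSDR,234.50,241.62,241.31
GLVK,205.30,208.71,211.01
LWSAK,237.70,236.19,250.71
NFNR,224.00,219.20,217.09
NIATGSK,255.30,260.08,253.95
poly-6-glycine,171.04,172.39,175.29
poly-8-glycine,206.52,197.76,197.50
poly-10-glycine,216.15,225.89,219.44
poly-14-glycine,254.51,264.76,263.74
TFAEALR,281.80,295.01,290.69
TIAQYAR,280.00,280.33,277.79
VASLR,232.00,228.70,228.30
WIR,213.20,205.63,210.41
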