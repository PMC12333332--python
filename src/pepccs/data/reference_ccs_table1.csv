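# Experimental and computed Boltzmann-weighted CCS (A^2) for 23 singly
# protonated tryptic peptides, N2 drift gas. Computed values: B3LYP/6-31G(d)
# geometries with and without Grimme D3 dispersion (zero-damping D3(0),
# Becke-Johnson D3(BJ)). Experimental values: drift-tube IM-MS (Unified CCS
# Compendium). v1
peptide,exp,B3LYP/6-31G(d),D3(0)-B3LYP/6-31G(d),D3(BJ)-B3LYP/6-31G(d)
ANELLINVK,322.50,347.62,322.93,342.93
AWEVTVK,278.20,333.91,295.78,296.11
AWSVAR,255.70,290.00,264.29,274.98
DYYFALAHTVR,374.80,410.42,412.60,422.64
ELR,200.30,197.81,203.43,201.62
EWTR,229.70,250.20,241.93,243.40
EYK,203.20,213.81,210.64,209.78
FAAYLER,293.10,335.07,302.10,307.17
FLNR,231.60,250.13,231.08,238.48
FPK,184.70,193.09,188.53,188.59
FSSDR,234.50,250.05,250.86,240.25
GLVK,205.30,210.80,210.69,210.63
LWSAK,237.70,267.85,243.40,243.63
NFNR,224.00,252.51,247.61,239.92
NIATGSK,255.30,298.74,257.95,248.67
poly-6-glycine,171.04,176.67,174.29,170.03
poly-8-glycine,206.52,203.34,201.43,197.56
poly-10-glycine,216.15,232.70,222.58,222.02
poly-14-glycine,254.51,277.82,266.42,266.33
TFAEALR,281.80,339.29,304.43,295.93
TIAQYAR,280.00,315.95,282.10,300.94
VASLR,232.00,230.65,223.39,232.05
WIR,213.20,210.41,217.68,208.50
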