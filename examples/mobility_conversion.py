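"""Convert a drift-tube arrival time to a collision cross section and back.

The low-field Mason-Schamp relation links the measured arrival time of an
ion (here a hypothetical [M+H]+ peptide of 322.5 Da) to its orientationally
averaged collision cross section, given the drift-tube conditions.
"""

from pepccs import (
    IonSpec,
    MobilityConditions,
    arrival_time_from_ccs,
    ccs_from_arrival_time,
    get_buffer_gas,
    mobility_from_drift,
)

gas = get_buffer_gas("N2")
ion = IonSpec(z=1, mass=322.5)
cond = MobilityConditions(
    temperature=298.0,  # K
    pressure=4.0,  # Torr
    field=18.0,  # V/cm
    drift_length=78.0,  # cm
    arrival_time=0.025,  # s
)

ccs = ccs_from_arrival_time(cond, ion, gas)
v_d = cond.drift_length / cond.arrival_time  # cm/s
k = mobility_from_drift(v_d, cond.field)
t_back = arrival_time_from_ccs(ccs, cond, ion, gas)

print(f"drift velocity   : {v_d:9.1f} cm/s")
print(f"mobility K       : {k:9.2f} cm^2/(V s)")
print(f"CCS              : {ccs:9.2f} A^2")
print(f"round-trip t_A   : {t_back * 1000:9.3f} ms (input was 25.000 ms)")
# A 25 ms arrival at these conditions corresponds to ~250 A^2 — the size of
# a typical small tryptic peptide ion; the inverse conversion recovers the
# arrival time to machine precision.
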