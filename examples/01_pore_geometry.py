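"""Conical pore geometry: conductance, tip sizing, half-angle.

The tip of a track-etched conical nanopore is too small to image, so it is
sized from the measured open-pore conductance G = kappa*pi*d_t*d_b/(4L),
with the base diameter obtained from the etch time (2.5 nm per minute of
etching in this protocol).
"""

import porepulse as pp

KAPPA = 10.0  # S/m, ~1 M KCl

d_b_nm = pp.base_diameter_from_etch_time(80.0)  # 80 min etch
print(f"base diameter from 80 min etch : {d_b_nm:.0f} nm")

G = pp.conductance(KAPPA, pp.PORE_1)
print(f"conductance of the 3 nm-tip pore: {G * 1e9:.4f} nS")

d_t = pp.tip_diameter_from_conductance(G, KAPPA, pp.PORE_1.d_b, pp.PORE_1.L)
print(f"tip diameter recovered from G   : {d_t * 1e9:.2f} nm")

for name, pore in (("pore 1", pp.PORE_1), ("pore 2", pp.PORE_2)):
    print(f"half-angle of {name}           : {pp.cone_half_angle(pore):.3f} deg")

print()
print("The sub-degree half-angles show how gently these pores taper over the")
print("13 um membrane; the conductance is dominated by the few-nm tip.")
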