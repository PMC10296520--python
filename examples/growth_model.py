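"""Tumor growth between surveillance scans under volume-doubling kinetics.

Volume doubles every doubling time Td; diameter grows with the cube root,
so the diameter doubles every 3*Td days. BRCA1-associated tumors (Td ~46 d)
therefore roughly double their diameter within about 138 days — one reason a
sub-centimeter focus missed on the prior scan can present as an overt tumor
a year later.
"""

from dcefoci import simulate_growth

d0 = 6.1  # mm, mean prior-scan lesion diameter
for gene, td in (("BRCA1", 46.0), ("BRCA2", 52.0)):
    for days in (138, 365):
        d = simulate_growth(d0, days, td)
        print(f"{gene} (Td={td:.0f} d): {d0} mm after {days:3d} d -> {d:5.1f} mm")

print()
print("After 3*Td = 138 days a BRCA1 tumor's diameter exactly doubles")
print(f"({d0} -> {simulate_growth(d0, 138, 46):.1f} mm): volume x8 = diameter x2.")
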