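"""Solution-vs-solid chemical-shift perturbation mapping.

Generates paired shift tables with perturbations planted at interface
residues, then flags residues whose summed |ΔCα| + |ΔCβ| exceeds 1.2 ppm —
the residues whose environment changes on filament formation.
"""

from helifil.nmr import signal_accounting, state_perturbation
from helifil.simulate import make_shift_tables, make_test_sequence

seq, first = make_test_sequence()
planted = {444: (1.2, 0.6), 470: (2.0, -0.4), 474: (1.8, 1.0)}
solution, solid = make_shift_tables(seq, first, planted, noise_sigma=0.05, seed=3)

table = state_perturbation(solution, solid, threshold_ppm=1.2)
flagged = table[table["flagged"]]
print("flagged residues (sum |dCA|+|dCB| >= 1.2 ppm):")
for row in flagged.itertuples():
    print(f"  residue {row.resnum} ({row.aa}): {row.sum_ppm:.2f} ppm")

# residue-type signal accounting with the disordered C-terminal tail hidden
assigned = set(range(first, 512))
acct = signal_accounting(assigned, seq, first, ["L", "T", "V", "P"])
print("\nobserved/expected per residue type (tail 512+ unassigned):")
for row in acct.itertuples():
    print(f"  {row.type}: {row.observed} of {row.expected}")
# The missing Leu/Val/Pro signals localize the disordered region.
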