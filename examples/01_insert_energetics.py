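"""Transition energies of the classic engineered Z-susceptible inserts.

Builds the three insert sequences used in the plasmid onset experiments and
prints their B-Z transition energies (nucleation excluded).  The perfect
(CG)16 insert costs 0.7 kcal/mol per dinucleotide unit; the phase-flipped
variant pays one extra GG Z-Z junction (+4.0); the 26-bp variant pays for a
GA and a TC unit (+3.4 each over nothing, 6.8 together on top of its CG
backbone).
"""

from sibz import assign_conformations, run_transition_energy
from sibz.fixtures import make_fixture

for name in ("seq1_insert", "seq2_insert", "seq3_insert"):
    fx = make_fixture(name)
    res = run_transition_energy(fx.sequence)
    print(f"{name}: {fx.sequence}")
    print(
        f"  length {len(fx.sequence)} bp, transition energy "
        f"{res.total:.1f} kcal/mol, {res.junction_count} Z-Z junction(s)"
    )

conf = assign_conformations(make_fixture("seq2_insert").sequence)
units = conf.units
print("\nseq2 unit conformations:", " ".join(units))
print("the AS->SA phase flip between units 8 and 9 is the GG junction")
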