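"""δ-notation arithmetic: from measured δ¹³C shifts to absolute excess ¹³C mass."""

from isotrace import (
    atom_fraction_to_delta,
    delta_to_atom_fraction,
    excess_mass,
    excess_mass_linear_approx,
)

# A 2.1 atom% labeled litter sits far above natural abundance on the δ scale.
label_delta = atom_fraction_to_delta(0.021)
print(f"2.1 atom% label      = {label_delta:+.1f} permil vs VPDB")
print(f"natural abundance    = {100 * delta_to_atom_fraction(-27.0):.4f} atom% (delta -27 permil)")

# A soil with 2% C (20 000 μg C/g) that shifts from −27‰ to −25‰ holds this
# much litter-derived ¹³C per gram:
exact = excess_mass(-25.0, -27.0, 20000.0)
approx = excess_mass_linear_approx(-25.0, -27.0, 20000.0)
print(f"excess mass (exact)  = {exact:.1f} ng 13C/g soil")
print(f"excess mass (linear) = {approx:.1f} ng 13C/g soil")
print(
    "The exact atom-fraction route and the small-delta linear shortcut agree here;\n"
    "near the +900 permil label itself the shortcut is biased by several percent,\n"
    "which is why all bookkeeping in this package goes through atom fractions."
)
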