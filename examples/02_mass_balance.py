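"""Thirty-day tracer mass balance from per-mesocosm pool masses.

Partitions a 531.3 μg ¹³C litter dose into respired CO₂, microbial biomass
and non-living SOM using the day-30 pool totals of a bacterially dominated
(low F:B) and a fungally dominated (high F:B) grassland soil.
"""

from isotrace import TracerDose, mass_balance

dose = TracerDose()  # 50 mg litter at 2.1 atom%, 531.3 μg 13C, 50 g dry soil

pools = {
    "low F:B soil": dict(respired=302.0, biomass=10.7, som=151.1),
    "high F:B soil": dict(respired=244.8, biomass=13.5, som=297.0),
}

for soil, p in pools.items():
    mb = mass_balance(
        dose,
        respired_ug13c=p["respired"],
        # per-mesocosm μg -> per-gram ng for a 50 g mesocosm
        biomass_excess_ng_g=p["biomass"] * 1000 / dose.soil_mass_g,
        som_excess_ng_g=p["som"] * 1000 / dose.soil_mass_g,
    )
    print(f"{soil}:")
    print(f"  respired     {100 * mb.fraction_respired:5.1f} % of dose")
    print(f"  biomass      {100 * mb.fraction_biomass:5.1f} %")
    print(f"  non-living SOM {100 * mb.fraction_som:3.1f} %")
    print(f"  unaccounted  {100 * mb.fraction_unaccounted:5.1f} %  (closure term)")

print(
    "\nThe fungal soil respires a smaller share of the litter carbon and routes\n"
    "more of it into non-living SOM - the pattern expected if fungal dominance\n"
    "favors short-term soil C storage."
)
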