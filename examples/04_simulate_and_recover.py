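"""Simulate a noisy mesocosm experiment and recover its tracer budget.

Generates a bacterially dominated scenario (known decay rate and carbon-use
efficiency), pushes the noisy measurement series through the mass-balance
pipeline, and compares the recovered dose fractions to the generator's
exact ledger.
"""

from isotrace import SimParams, mass_balance_from_series, simulate_decomposition

params = SimParams(
    k_litter=0.12,   # litter decay, d⁻¹
    cue=0.33,        # carbon-use efficiency
    m_turnover=0.2,  # biomass turnover, d⁻¹
    noise_delta_sd=0.5,   # ‰ measurement noise on δ¹³C
    noise_rate_cv=0.05,   # 5 % multiplicative noise on C contents/rates
    n_replicates=3,
    seed=42,
)
res = simulate_decomposition(params, soil_class="low_fb")
truth = res.ledger.iloc[-1]

mb = mass_balance_from_series(res.series, params.dose, 30.0, dose_interpretation="excess")
m, s = mb["low_fb"]["mean"], mb["low_fb"]["se"]

print("day-30 dose fractions (pipeline mean ± SE over 3 replicates vs generative truth):")
for name, truth_col in [
    ("respired", "fraction_respired"),
    ("biomass", "fraction_biomass"),
    ("non-living SOM", "fraction_som"),
]:
    print(
        f"  {name:<14} {m[truth_col]:.3f} ± {s[truth_col]:.3f}   truth {truth[truth_col]:.3f}"
    )
print(
    f"  unaccounted    {m['fraction_unaccounted']:.3f} ± {s['fraction_unaccounted']:.3f}"
    f"   truth (remaining litter) {truth['fraction_litter']:.3f}"
)
print(
    "\nBiomass and SOM come out essentially exact (the excess arithmetic inverts\n"
    "the generator); the respired fraction carries a small positive trapezoid\n"
    "bias from the weekly late-series sampling."
)
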