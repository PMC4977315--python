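# isotrace

Tracer bookkeeping for ¹³C-labeled litter-decomposition experiments in soil
mesocosms, plus the fungal:bacterial community indices used to interpret
them.

## The problem

A standard way to ask whether fungally dominated soils store more carbon is
to add a small dose of ¹³C-enriched plant litter to replicated soil
mesocosms and follow the label through the measurable pools: respired CO₂,
chloroform-labile microbial biomass, and bulk soil organic matter (SOM).
Closing this budget requires a chain of small but error-prone conversions —
δ¹³C notation to atom fractions, fumigation-extraction corrections,
two-pool isotope unmixing, time integration of the CO₂ efflux — and the
community side needs consistent fungal:bacterial (F:B) index arithmetic
across PLFA, RNA and protein platforms. `isotrace` implements that chain as
a tested library for soil ecologists and biogeochemists.

## The model

Isotope arithmetic is exact in atom fractions, never the linear δ
approximation (the litter label sits near +900‰, far outside the linear
regime):

- x = R/(1+R) with R = R_VPDB·(1 + δ/1000), R_VPDB = 0.0111802
- excess ¹³C of a pool: E = (x_post − x_pre)·C_pool, in ng ¹³C g⁻¹ soil
- microbial biomass C by CFE: C_mic = (C_fum − C_nf)/k_EC, k_EC = 0.45,
  with biomass δ from two-pool unmixing (δ_fum·C_fum − δ_nf·C_nf)/(C_fum − C_nf)
- non-living SOM excess = bulk SOM excess − biomass excess
- cumulative respired ¹³C: trapezoidal area under the excess-efflux curve
- mass balance at a horizon: fractions of the applied dose
  (respired, biomass, non-living SOM, unaccounted closure term)

Community indices: %F:B = 100 · fungal index / bacterial index (lipid
concentrations, sequence proportions or protein abundances); the
Actinobacteria:rest-of-bacteria ratio A:RB = A/(B_total − A); per-phylum
fold change of relative abundance; Hellinger transform; and PERMANOVA
(pseudo-F on a distance matrix, permutation p-values, exact exhaustive
enumeration for small designs, sequential multi-factor decomposition in the
adonis style).

A synthetic mesocosm generator closes the loop: litter-derived carbon
follows a linear three-pool system (litter → biomass → necromass, with a
respired fraction set by the carbon-use efficiency) solved in closed form,
so its ground-truth ledger conserves the dose to machine precision and
every pipeline stage can be tested against known truth.

## Worked example

```python
from isotrace import TracerDose, mass_balance, fb_percent

print(fb_percent(0.52, 18.46, ndigits=1), fb_percent(0.99, 23.55, ndigits=1))
# 2.8 4.2   <- %F:B of the two field soils from their PLFA index totals

dose = TracerDose()  # 50 mg litter, 2.1 atom%, 531.3 ug 13C, 50 g soil
mb = mass_balance(dose, respired_ug13c=302.0,
                  biomass_excess_ng_g=10.7 * 1000 / 50,
                  som_excess_ng_g=151.1 * 1000 / 50)
print(f"{100*mb.fraction_respired:.1f} {100*mb.fraction_biomass:.1f} "
      f"{100*mb.fraction_som:.1f} {100*mb.fraction_unaccounted:.1f}")
# 56.8 2.0 28.4 12.7   <- % of dose respired / in biomass / in SOM / unaccounted
```

The first line reproduces the percent proportion of fungi relative to
bacteria in a low- and a high-F:B soil (the high soil is 1.5× more fungal);
the second partitions a 531.3 μg ¹³C dose using day-30 pool masses — the
bacterial soil lost 56.8% of the label as CO₂ and retained 28.4% in
non-living SOM, with 12.7% unaccounted (undecomposed litter and
measurement closure).

The scripts in `examples/` walk through each capability: isotope
conversions, mass balance, community indices + PERMANOVA, noisy simulation
with parameter recovery, and the end-to-end pipeline. A thin CLI mirrors
the library (`isotrace simulate|validate|indices|massbalance|run`).

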