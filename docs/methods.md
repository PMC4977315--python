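# Methods

## Isotope arithmetic

All bookkeeping runs through atom fractions. For a δ¹³C value (‰ vs VPDB)
the isotope ratio is R = R_VPDB·(1 + δ/1000) and the atom fraction
x = R/(1+R); the package uses the IAEA consensus R_VPDB = 0.0111802
(configurable — the choice moves natural-abundance atom fractions in the
fourth decimal and cancels almost entirely in excess differences). Excess
¹³C of a pool is (x_post − x_pre)·C_pool. The familiar linear
approximation excess ≈ Δδ·(dx/dδ)|₀·C is exposed only as a diagnostic
(`excess_mass_linear_approx`): at natural abundance the two agree to
≈0.05%, but evaluated against a +900‰ label the linear form is biased by
several percent, which is material when the label is the numerator of a
mass balance.

Negative excesses arise from measurement noise whenever δ_post < δ_pre.
They are retained and flagged with a warning, never clipped: clipping
would bias replicate means upward and break the closure of the budget.

## Pool partitioning

**CFE biomass.** Microbial biomass C is (C_fum − C_nf)/k_EC with
k_EC = 0.45 by default. The biomass δ comes from two-pool unmixing,
δ_bio = (δ_fum·C_fum − δ_nf·C_nf)/(C_fum − C_nf), i.e. C-weighted δ
mixing inverted. The extraction-efficiency factor is applied to the carbon
mass only, not to δ: k_EC rescales how much of the biomass is captured,
while the isotopic composition of the chloroform-labile pool is already
mass-weighted. Pairs with C_fum < C_nf are flagged (not raised) and
excluded from isotopic unmixing; the pipeline then scores zero biomass
excess for that replicate with a log notice.

**Respiration integration.** Cumulative respired ¹³C is the trapezoidal
area under the excess-efflux curve times the mesocosm soil mass. A
zero-rate node is prepended at t = 0 by default — no label can have been
respired before it was added — and this convention is switchable to
left-extrapolation of the first measured rate. Near-coincident sampling
times (the dense first-day series meeting a harvest point) are averaged
within 0.5 h bins before integration so the integrator always sees
strictly increasing times. Each measured rate is treated as the
instantaneous rate at its nominal sampling time; the overnight-incubation
protocol behind such measurements makes this an approximation that users
can offset by adjusting the nominal times.

**Mass balance.** Per-gram excesses are scaled by the dry-soil mass
(default 50 g) and divided by the dose. Fractions sum to 1 exactly because
`fraction_unaccounted` is defined as the closure term. Replicates are
balanced independently and aggregated afterwards (mean ± SE with the n−1
sample SD), preserving the error semantics of an n = 3 design.

**Dose interpretation.** A litter label quoted as 2.1 atom% with a dose of
531.3 μg ¹³C is read as *absolute* atom% (531.3/0.021 ≈ 25.3 mg litter C,
i.e. ~50% C litter, which is physically sensible). Excess-based pipelines,
however, can only ever recover the *excess* dose,
litter C × (x_label − x_background) — about 47% of the absolute figure at
natural-abundance background. `TracerDose` exposes both; `mass_balance`
normalizes by the dose value as given by default (matching the
conventional 302/531.3 → 56.8% arithmetic) and by the excess dose on
request, which is the only normalization under which a noiseless synthetic
budget closes exactly. Mixing an excess numerator with an absolute
denominator — as conventional reporting does — understates all fractions
by the same factor; the package documents rather than silently corrects
this. Note also that published per-replicate pool masses can overshoot the
*mean* dose (per-mesocosm doses vary), which shows up as a negative
unaccounted fraction; the closure term makes that visible instead of
hiding it.

## Community indices

The default PLFA marker map carries 23 bacterial markers (14:0 … 18:1ω9)
and one fungal marker (18:2ω6,9). 18:1ω9 is classified bacterial by
default even though part of the literature treats it as fungal; the map is
an explicit argument, so either convention is one override away. Marker
names are canonicalized (whitespace stripped, ASCII `w` → `ω` before
digits); unknown markers are excluded with a warning rather than guessed.

%F:B = 100·fungal/bacterial is computed at full precision and rounded only
at the reporting layer (1 decimal for percents, 2 for ratios). Taxon
tables are stored taxa × samples with "Domain;Phylum" lineage labels;
relative abundance, Hellinger transform and the indices all operate per
sample (column), matching per-sample sequencing-depth normalization.
Archaea and non-fungal eukaryotes are excluded from both F:B indices by
construction.

**PERMANOVA.** The one-factor pseudo-F uses the among/within decomposition
of squared distances: SS_total = Σᵢ<ⱼ d²ᵢⱼ/N, SS_within summed per group,
F = (SS_A/(a−1))/(SS_W/(N−a)). When the number of distinct label
arrangements (the multinomial coefficient) is at most the requested
permutation count, every arrangement is enumerated and
p = #{F* ≥ F_obs}/#arrangements is exact, with the `exhaustive` flag set.
For balanced two-group designs the observed grouping and its complement
produce the same F, so the smallest attainable exact p is 2/#arrangements
(0.1 for 3+3) — worth knowing before powering a small design. Otherwise p
is the standard (count+1)/(n_perm+1) estimate from seeded random
relabelings. Ties are compared with a 10⁻¹² relative tolerance; a
zero-within-scatter design yields F = ∞, which orders correctly against
finite permuted statistics. Multi-factor designs use sequential (Type-I)
sums of squares on the Gower-centered squared-distance matrix with
pseudoinverse projectors (robust to redundant dummy columns); term order
is the caller's, as in the common adonis default, and the decomposition
was cross-checked term-by-term against vegan's `adonis2(..., by="terms")`.

## Synthetic mesocosm generator

The generator emulates a two-soil-class, 3-replicate, 7-time-point
(6 h – 30 d) litter-tracer experiment. Litter-derived carbon follows

L' = −kL; B' = cue·k·L − m·B; N' = m·B; CO₂' = (1−cue)·k·L

solved in closed form (including the m = k limit), so the ground-truth
ledger satisfies L + B + N + CO₂ = dose at machine precision — an exact
conservation oracle that isolates pipeline error from simulation error.
The label is uniform across litter C (ground, homogenized litter).

Scenario defaults were chosen once as field-plausible values: the
bacterially dominated scenario uses k = 0.12 d⁻¹, CUE = 0.33, m = 0.2 d⁻¹
(≈65% of the excess dose respired by day 30) and the fungally dominated
scenario k = 0.08 d⁻¹, CUE = 0.5, m = 0.2 d⁻¹ (≈45% respired, more routed
to necromass), reproducing the qualitative contrast that motivates such
experiments — higher CUE → lower respiratory loss and more label in
non-living SOM. Background constants: soil C 20 000 μg g⁻¹ (2% C),
background δ¹³C −27‰, unlabeled biomass 400 μg C g⁻¹, non-fumigated
extract 50 μg C g⁻¹, basal respiration 1 μg C g⁻¹ h⁻¹ so respired δ¹³C is
a realistic label/background mixture rather than pure label.

Measurement synthesis: pool δ values are produced by exact atom-fraction
mass balance against the background — with one deliberate exception. The
fumigated/non-fumigated extract pair is mixed with C-weighted *linear δ*
arithmetic so that the standard δ-space two-pool unmixing used by the
analysis side is its exact inverse; the deviation from exact
atom-fraction mixing is second-order in the atom fractions (≲10⁻⁴
relative here) and is the field's usual mixing convention anyway. The
simulated bulk-SOM measurement contains biomass + necromass but not the
undecomposed litter, which the ledger tracks separately; a noiseless mass
balance therefore leaves exactly the remaining-litter fraction
unaccounted, giving an end-to-end closure oracle. Respiration is the
instantaneous model rate at each sampling time, hourly over the first
24 h and at harvests thereafter. Noise: additive Gaussian on δ
(default studies use 0.5‰) and mean-preserving lognormal multiplicative
noise on C contents and rates (CV-parameterized).

The community generator draws multinomial counts at a configured
sequencing depth around "Domain;Phylum" proportions; litter effects are
per-lineage fold multipliers followed by renormalization. A builder
constructs baselines hitting exact generative %F:B and A:RB targets; the
two scenario defaults use pre-litter %F:B of 1.2 and 2.0, A:RB of 0.55
and 0.53, and fold effects that raise fungal phyla in both soils (more in
the fungal soil) and Actinobacteria mainly in the bacterial soil.

**What passing tests show — and don't.** The simulator provides exact
conservation, seeded determinism, and known effect sizes, so green tests
demonstrate that the analysis chain inverts a well-specified generative
process under realistic noise. Real mesocosm data add features the
generator omits by design: priming of native SOC, temporally varying CUE,
cross-feeding and biomass regrowth dynamics, incomplete/selective CFE
extraction, spatial heterogeneity, and platform-specific taxonomic
biases. Recovery performance here is therefore a lower bound on the
method's difficulty, not a validation against nature.

## Numerical choices and edge cases

- Trapezoid on the design's sparse late-series sampling over-integrates a
  convex decaying efflux by ~1–2 percentage points of the dose; the dense
  first-day sampling keeps the early pulse accurate. Hourly sampling of a
  30-day exponential is accurate to <0.05%.
- Round-trip δ → x → δ is identity to 10⁻¹² relative over δ ∈ [−100, 2000].
- δ ≤ −1000‰ and atom fractions outside [0,1) are domain errors; −1000 is
  the physical boundary where the isotope ratio vanishes.
- Problem sizes in tests and the acceptance script (100 recovery runs,
  1000 null PERMANOVA datasets at 999 permutations, depth-10⁶ community
  draws, 20-point conservation grid) were chosen as the smallest sizes at
  which the statistical assertions have comfortable margins.

## Known limitations

- No fractionation corrections (Suess, fumigation fractionation) and no ¹⁴C.
- No priming-effect decomposition and no fitting of decay constants to
  real data; decay parameters exist only on the generative side.
- The pipeline reports group means ± SE; hypothesis tests beyond PERMANOVA
  (ANOVA families, rank tests) are left to general statistics packages.
- F:B indices are only as good as the upstream taxonomic table; whether a
  sequence-based table counts rRNA-assigned reads or all annotated reads
  is an upstream choice the package takes as given.
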