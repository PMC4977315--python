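"""Synthetic mesocosm experiments with known ground truth.

The decomposition generator solves a three-pool first-order system for the
litter-derived carbon of one mesocosm (closed forms, so conservation of the
ledger is exact to machine precision):

    L' = −k·L                    remaining litter C
    B' = cue·k·L − m·B           living microbial biomass C
    N' = m·B                     necromass (non-living SOM) C
    CO₂' = (1−cue)·k·L           cumulative respired C

``k`` is the litter decay rate (d⁻¹), ``cue`` the carbon-use efficiency
(fraction of decomposed litter C assimilated rather than respired) and
``m`` the biomass turnover rate (d⁻¹). All litter C carries the uniform
label atom fraction of the dose; pool δ¹³C values follow from exact
atom-fraction mass balance against the unlabeled background — except the
fumigation-extract pair, which is mixed with C-weighted δ arithmetic so the
standard two-pool δ unmixing is its exact inverse.

Measurement noise: Gaussian on δ (sd ``noise_delta_sd`` ‰) and
mean-preserving lognormal multiplicative noise on C contents and rates
(coefficient of variation ``noise_rate_cv``).

The community generator draws multinomial counts at a configured sequencing
depth around phylum proportions with litter fold effects; the ledger
records the generative %F:B and A:RB.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import (
    BACTERIAL_PLFA_MARKERS,
    FUNGAL_PLFA_MARKERS,
    TaxonTable,
)
from .isotope import R_VPDB, atom_fraction_to_delta, delta_to_atom_fraction
from .pools import KEC_DEFAULT, TracerDose

__all__ = [
    "SimParams",
    "CommunitySimParams",
    "DecompositionResult",
    "CommunityResult",
    "simulate_decomposition",
    "simulate_community",
    "community_params_from_targets",
    "low_fb_scenario",
    "high_fb_scenario",
    "simulate_plfa",
    "generate_fixture_bundle",
]

#: Harvest schedule: 6 h then 1, 3, 7, 14, 21, 30 days after litter addition.
DEFAULT_TIMEPOINTS_D: tuple[float, ...] = (0.25, 1.0, 3.0, 7.0, 14.0, 21.0, 30.0)


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of one decomposition scenario.

    Defaults describe a 50 g mesocosm of a 2% C soil receiving 50 mg of
    2.1 atom% litter (531.3 μg ¹³C), harvested at 6 h – 30 d with three
    replicates, with a moderately bacterial community (low carbon-use
    efficiency, fast litter turnover).
    """

    k_litter: float = 0.12  # d⁻¹
    cue: float = 0.33
    m_turnover: float = 0.2  # d⁻¹
    dose: TracerDose = field(default_factory=TracerDose)
    background_delta: float = -27.0  # ‰ vs VPDB
    soil_c: float = 20000.0  # μg C g⁻¹ (2% C soil)
    biomass_c_background: float = 400.0  # μg C g⁻¹ unlabeled microbial biomass
    extract_c_background: float = 50.0  # μg C g⁻¹ in the non-fumigated extract
    basal_respiration: float = 1.0  # μg C g⁻¹ h⁻¹ of unlabeled soil C
    kec: float = KEC_DEFAULT
    noise_delta_sd: float = 0.0  # ‰
    noise_rate_cv: float = 0.0
    timepoints_d: tuple[float, ...] = DEFAULT_TIMEPOINTS_D
    dense_respiration_first24h: bool = True
    n_replicates: int = 3
    seed: int = 0
    r_std: float = R_VPDB

    def __post_init__(self) -> None:
        if self.k_litter < 0 or self.m_turnover < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.cue <= 1):
            raise ValueError("cue must lie in [0, 1]")
        tp = np.asarray(self.timepoints_d, dtype=float)
        if tp.size == 0 or np.any(np.diff(tp) <= 0) or tp[0] <= 0:
            raise ValueError("timepoints_d must be positive and strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _pool_masses(params: SimParams, t_d: np.ndarray):
    """Closed-form litter-derived C masses (μg per mesocosm) at times t (days)."""
    k, cue, m = params.k_litter, params.cue, params.m_turnover
    l0 = params.dose.litter_c_ug
    t = np.asarray(t_d, dtype=float)
    litter = l0 * np.exp(-k * t)
    decomposed = l0 - litter
    if k == 0:
        biomass = np.zeros_like(t)
    elif abs(m - k) < 1e-12:
        biomass = cue * k * l0 * t * np.exp(-k * t)
    else:
        biomass = cue * k * l0 * (np.exp(-k * t) - np.exp(-m * t)) / (m - k)
    necromass = cue * decomposed - biomass
    respired = (1.0 - cue) * decomposed
    return litter, biomass, necromass, respired


def _mix_delta_exact(c_bg, x_bg, c_lab, x_lab, r_std):
    """δ of a background + labeled-C mixture via exact atom-fraction balance."""
    total = np.asarray(c_bg, dtype=float) + np.asarray(c_lab, dtype=float)
    x = (np.asarray(c_bg) * x_bg + np.asarray(c_lab) * x_lab) / total
    return atom_fraction_to_delta(x, r_std), total


@dataclass(frozen=True)
class DecompositionResult:
    """Noisy measurement series plus the noiseless ground-truth ledger."""

    series: pd.DataFrame  # tidy: soil_class, replicate, time_h, pool_id, delta13c_permil, c_content
    ledger: pd.DataFrame  # per time point, per-mesocosm masses and fractions
    params: SimParams


def simulate_decomposition(params: SimParams, soil_class: str = "soil") -> DecompositionResult:
    """Simulate one scenario: replicate measurement series + ground-truth ledger.

    The bulk-SOM measurement contains biomass + necromass but not the
    undecomposed litter (tracked separately in the ledger), so a mass
    balance over respired/biomass/non-living-SOM leaves exactly the
    remaining-litter fraction unaccounted. The series includes a t = 0
    pre-label baseline row per pool and replicate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    d = params.dose
    x_lab = d.label_atom_percent / 100.0
    x_bg = delta_to_atom_fraction(params.background_delta, params.r_std)
    excess_per_ug = x_lab - x_bg  # μg ¹³C excess per μg litter-derived C

    t_d = np.asarray(params.timepoints_d, dtype=float)
    litter, biomass, necromass, respired = _pool_masses(params, t_d)
    dose_excess = d.litter_c_ug * excess_per_ug
    ledger = pd.DataFrame(
        {
            "time_d": t_d,
            "time_h": t_d * 24.0,
            "litter_c_ug": litter,
            "biomass_c_ug": biomass,
            "necromass_c_ug": necromass,
            "respired_c_ug": respired,
            "litter_excess_ug13c": litter * excess_per_ug,
            "biomass_excess_ug13c": biomass * excess_per_ug,
            "nonliving_som_excess_ug13c": necromass * excess_per_ug,
            "cumulative_respired_ug13c": respired * excess_per_ug,
        }
    )
    ledger["dose_excess_ug13c"] = dose_excess
    for frac, col in [
        ("fraction_respired", "cumulative_respired_ug13c"),
        ("fraction_biomass", "biomass_excess_ug13c"),
        ("fraction_som", "nonliving_som_excess_ug13c"),
        ("fraction_litter", "litter_excess_ug13c"),
    ]:
        ledger[frac] = ledger[col] / dose_excess

    # respiration sampling grid: harvest times, optionally plus hourly 1-24 h
    resp_t_h = t_d * 24.0
    if params.dense_respiration_first24h:
        resp_t_h = np.union1d(resp_t_h, np.arange(1.0, 25.0))

    rows: list[tuple] = []

    def emit(rep, time_h, pool, delta, c, noisy=True):
        if noisy:
            if params.noise_delta_sd > 0:
                delta = delta + rng.normal(0.0, params.noise_delta_sd)
            if params.noise_rate_cv > 0:
                cv = params.noise_rate_cv
                c = c * np.exp(rng.normal(0.0, cv) - cv**2 / 2.0)
        rows.append((soil_class, rep, float(time_h), pool, float(delta), float(c)))

    g = d.soil_mass_g
    delta_bg = params.background_delta
    for rep in range(1, params.n_replicates + 1):
        # t = 0 pre-label baseline
        emit(rep, 0.0, "bulk_som", delta_bg, params.soil_c)
        emit(rep, 0.0, "nonfumigated_extract", delta_bg, params.extract_c_background)
        emit(
            rep, 0.0, "fumigated_extract", delta_bg,
            params.extract_c_background + params.kec * params.biomass_c_background,
        )
        emit(rep, 0.0, "respired_co2", delta_bg, params.basal_respiration)

        for i, td in enumerate(t_d):
            th = td * 24.0
            # bulk SOM: background soil C + litter-derived biomass + necromass
            lab_c = (biomass[i] + necromass[i]) / g
            dlt, ctot = _mix_delta_exact(params.soil_c, x_bg, lab_c, x_lab, params.r_std)
            emit(rep, th, "bulk_som", dlt, ctot)

            # biomass pool (background biomass + litter-derived biomass)
            bio_c = params.biomass_c_background + biomass[i] / g
            d_bio, _ = _mix_delta_exact(
                params.biomass_c_background, x_bg, biomass[i] / g, x_lab, params.r_std
            )
            # extracts: non-fumigated at background; fumigated adds kec × biomass C.
            # The pair is mixed with C-weighted δ arithmetic so that δ-space
            # two-pool unmixing recovers d_bio exactly.
            c_nf = params.extract_c_background
            c_f = c_nf + params.kec * bio_c
            d_f = (c_nf * delta_bg + params.kec * bio_c * d_bio) / c_f
            emit(rep, th, "nonfumigated_extract", delta_bg, c_nf)
            emit(rep, th, "fumigated_extract", d_f, c_f)

            # remaining litter (per g soil)
            emit(rep, th, "litter", atom_fraction_to_delta(x_lab, params.r_std), litter[i] / g)

        # respiration: instantaneous model rate at each sampling time
        for th in resp_t_h:
            td = th / 24.0
            rate_lab = (
                (1.0 - params.cue) * params.k_litter * d.litter_c_ug * np.exp(-params.k_litter * td)
            ) / 24.0 / g  # μg C g⁻¹ h⁻¹ of litter-derived C
            d_resp, rate_tot = _mix_delta_exact(
                params.basal_respiration, x_bg, rate_lab, x_lab, params.r_std
            )
            emit(rep, th, "respired_co2", d_resp, rate_tot)

    series = pd.DataFrame(
        rows,
        columns=["soil_class", "replicate", "time_h", "pool_id", "delta13c_permil", "c_content"],
    ).sort_values(["replicate", "pool_id", "time_h"], kind="stable", ignore_index=True)
    return DecompositionResult(series=series, ledger=ledger, params=params)


# --------------------------------------------------------------------------
# Community tables


@dataclass(frozen=True)
class CommunitySimParams:
    """Multinomial community generator: baseline proportions × litter fold effects.

    ``proportions`` maps "Domain;Phylum" lineages to pre-litter expected
    relative abundances (must sum to 1 within 1e-9); ``fold_effects`` maps
    lineages to multiplicative litter responses (missing lineages default
    to 1); after-litter proportions are renormalized.
    """

    proportions: dict[str, float]
    fold_effects: dict[str, float] = field(default_factory=dict)
    depth: int = 100_000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")

    def after_proportions(self) -> dict[str, float]:
        raw = {k: p * self.fold_effects.get(k, 1.0) for k, p in self.proportions.items()}
        total = sum(raw.values())
        return {k: v / total for k, v in raw.items()}


def _expected_indices(props: dict[str, float]) -> dict[str, float]:
    fungal = sum(p for k, p in props.items() if k.split(";")[0].lower() == "fungi")
    bact = sum(p for k, p in props.items() if k.split(";")[0].lower() == "bacteria")
    actino = sum(
        p
        for k, p in props.items()
        if k.split(";")[0].lower() == "bacteria"
        and len(k.split(";")) > 1
        and k.split(";")[1].strip().lower() == "actinobacteria"
    )
    return {
        "percent_fb": 100.0 * fungal / bact,
        "arb_ratio": actino / (bact - actino),
    }


@dataclass(frozen=True)
class CommunityResult:
    """Simulated taxon count table (before + after litter) and generative ledger."""

    table: TaxonTable
    ledger: dict


def simulate_community(params: CommunitySimParams, soil_class: str = "soil") -> CommunityResult:
    """Draw before/after-litter count tables; ledger holds generative indices."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    lineages = list(params.proportions)
    before = np.array([params.proportions[k] for k in lineages])
    after_props = params.after_proportions()
    after = np.array([after_props[k] for k in lineages])

    cols, counts, meta_rows = [], [], []
    for treatment, probs in [("before_litter", before), ("after_litter", after)]:
        for rep in range(1, params.n_replicates + 1):
            name = f"{soil_class}_{treatment}_r{rep}"
            cols.append(name)
            counts.append(rng.multinomial(params.depth, probs))
            meta_rows.append({"sample_id": name, "soil_class": soil_class, "treatment": treatment})
    data = pd.DataFrame(np.column_stack(counts), index=lineages, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    ledger = {
        "before": _expected_indices(params.proportions),
        "after": _expected_indices(after_props),
        "depth": params.depth,
    }
    return CommunityResult(table=TaxonTable(data, meta), ledger=ledger)


#: fractions of the bacterial pool per phylum used by the target-based builder
_BACT_SPLIT = {
    "Proteobacteria": 0.28,
    "Firmicutes": 0.10,
    "Bacteroidetes": 0.08,
    "Acidobacteria": 0.09,
}
_FUNGI_SPLIT = {"Ascomycota": 0.7, "Basidiomycota": 0.2, "other_fungi": 0.1}


def community_params_from_targets(
    percent_fb: float,
    arb_ratio: float,
    depth: int = 100_000,
    n_replicates: int = 3,
    seed: int = 0,
    archaea: float = 0.02,
    fold_effects: dict[str, float] | None = None,
) -> CommunitySimParams:
    """Build baseline proportions realizing exact generative %F:B and A:RB targets."""
    other = 0.003  # non-fungal eukaryotes incl. plant RNA
    b = (1.0 - archaea - other) / (1.0 + percent_fb / 100.0)
    f = b * percent_fb / 100.0
    actino_frac = arb_ratio / (1.0 + arb_ratio)
    rest = 1.0 - actino_frac
    props = {"Bacteria;Actinobacteria": b * actino_frac}
    weights = {**_BACT_SPLIT, "other_bacteria": 0.10}
    wsum = sum(weights.values())
    for phylum, w in weights.items():
        props[f"Bacteria;{phylum}"] = b * rest * w / wsum
    for phylum, frac in _FUNGI_SPLIT.items():
        props[f"Fungi;{phylum}"] = f * frac
    props["Archaea;other_archaea"] = archaea
    props["Eukaryota;other_eukaryota"] = other
    # renormalize away float crumbs
    total = sum(props.values())
    props = {k: v / total for k, v in props.items()}
    return CommunitySimParams(
        proportions=props,
        fold_effects=fold_effects or {},
        depth=depth,
        n_replicates=n_replicates,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Two-soil default scenarios


def low_fb_scenario(seed: int = 0, **overrides) -> tuple[SimParams, CommunitySimParams, dict]:
    """Bacterially dominated soil: fast decay, low CUE → high respiratory loss.

    Returns (decomposition params, community params, PLFA targets).
    """
    sim = SimParams(
        k_litter=0.12, cue=0.33, m_turnover=0.2, seed=seed,
        **overrides,
    )
    comm = community_params_from_targets(
        percent_fb=1.2, arb_ratio=0.55, seed=seed + 1,
        fold_effects={
            "Fungi;Ascomycota": 1.5, "Fungi;Basidiomycota": 1.6, "Fungi;other_fungi": 1.2,
            "Bacteria;Actinobacteria": 1.5, "Bacteria;Proteobacteria": 0.98,
            "Bacteria;Firmicutes": 0.98, "Bacteria;Bacteroidetes": 0.98,
            "Bacteria;Acidobacteria": 0.98, "Bacteria;other_bacteria": 0.98,
            "Archaea;other_archaea": 0.8,
        },
    )
    plfa = {"bacterial_total": 18.46, "fungal_total": 0.52}
    return sim, comm, plfa


def high_fb_scenario(seed: int = 100, **overrides) -> tuple[SimParams, CommunitySimParams, dict]:
    """Fungally dominated soil: slower decay, higher CUE → more C retained in SOM."""
    sim = SimParams(
        k_litter=0.08, cue=0.5, m_turnover=0.2, seed=seed,
        **overrides,
    )
    comm = community_params_from_targets(
        percent_fb=2.0, arb_ratio=0.53, seed=seed + 1,
        fold_effects={
            "Fungi;Ascomycota": 1.1, "Fungi;Basidiomycota": 1.9, "Fungi;other_fungi": 1.1,
            "Bacteria;Actinobacteria": 1.07, "Bacteria;Acidobacteria": 0.5,
            "Archaea;other_archaea": 0.8,
        },
    )
    plfa = {"bacterial_total": 23.55, "fungal_total": 0.99}
    return sim, comm, plfa


def simulate_plfa(
    targets: dict, n_replicates: int = 3, noise_cv: float = 0.02, seed: int = 0, prefix: str = "soil"
) -> pd.DataFrame:
    """Tidy PLFA table (sample_id, marker, ug_per_g) around target index totals.

    The bacterial total is spread over the default 23 bacterial markers with
    a fixed declining weight profile; the fungal total goes to 18:2ω6,9.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    weights = np.linspace(2.0, 0.5, len(BACTERIAL_PLFA_MARKERS))
    weights /= weights.sum()
    rows = []
    for rep in range(1, n_replicates + 1):
        sample = f"{prefix}_r{rep}"
        for marker, w in zip(BACTERIAL_PLFA_MARKERS, weights):
            conc = targets["bacterial_total"] * w
            if noise_cv > 0:
                conc *= np.exp(rng.normal(0, noise_cv) - noise_cv**2 / 2)
            rows.append((sample, marker, conc))
        conc = targets["fungal_total"]
        if noise_cv > 0:
            conc *= np.exp(rng.normal(0, noise_cv) - noise_cv**2 / 2)
        rows.append((sample, FUNGAL_PLFA_MARKERS[0], conc))
    return pd.DataFrame(rows, columns=["sample_id", "marker", "ug_per_g"])


def generate_fixture_bundle(out_dir, seed: int = 0, noise_delta_sd: float = 0.5,
                            noise_rate_cv: float = 0.05, depth: int = 100_000) -> dict:
    """Write a complete two-scenario fixture bundle to ``out_dir``.

    Files: series.csv, plfa.csv, taxa.tsv, meta.csv, truth.json — the exact
    dialects the pipeline readers expect. Same seed → byte-identical files.
    Returns the truth dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": seed, "scenarios": {}}
    series_parts, plfa_parts, taxa_parts, meta_parts = [], [], [], []

    for name, builder, base_seed in [
        ("low_fb", low_fb_scenario, seed),
        ("high_fb", high_fb_scenario, seed + 1000),
    ]:
        sim, comm, plfa_targets = builder(seed=base_seed)
        sim = dataclasses.replace(sim, noise_delta_sd=noise_delta_sd, noise_rate_cv=noise_rate_cv)
        comm = dataclasses.replace(comm, depth=depth)
        dec = simulate_decomposition(sim, soil_class=name)
        com = simulate_community(comm, soil_class=name)
        series_parts.append(dec.series)
        plfa_parts.append(
            simulate_plfa(plfa_targets, n_replicates=sim.n_replicates, seed=base_seed + 2,
                          prefix=name)
        )
        taxa_parts.append(com.table.data)
        meta_parts.append(com.table.metadata.reset_index())
        horizon = dec.ledger.iloc[-1]
        truth["scenarios"][name] = {
            "k_litter": sim.k_litter,
            "cue": sim.cue,
            "m_turnover": sim.m_turnover,
            "dose_excess_ug13c": float(horizon["dose_excess_ug13c"]),
            "fraction_respired": float(horizon["fraction_respired"]),
            "fraction_biomass": float(horizon["fraction_biomass"]),
            "fraction_som": float(horizon["fraction_som"]),
            "fraction_litter": float(horizon["fraction_litter"]),
            "community": com.ledger,
            "plfa_targets": plfa_targets,
        }

    pd.concat(series_parts, ignore_index=True).to_csv(out / "series.csv", index=False)
    pd.concat(plfa_parts, ignore_index=True).to_csv(out / "plfa.csv", index=False)
    taxa = pd.concat(taxa_parts, axis=1).fillna(0).astype(int)
    taxa.index.name = "lineage"
    taxa.to_csv(out / "taxa.tsv", sep="\t")
    pd.concat(meta_parts, ignore_index=True).to_csv(out / "meta.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
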