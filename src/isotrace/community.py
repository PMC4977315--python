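"""Fungal:bacterial community indices and permutational multivariate ANOVA.

Covers the lipid- and sequence-based community summaries used around a
litter-decomposition experiment:

* PLFA biomarker classification into bacterial vs fungal index sums;
* %F:B = 100 · fungal index / bacterial index (any platform: PLFA, RNA,
  protein);
* relative abundance, per-phylum fold change, Actinobacteria:rest-of-bacteria
  (A:RB) ratio from taxon abundance tables;
* Hellinger transform of abundance tables (square root of per-sample
  relative abundances), the standard pre-treatment before Euclidean
  ordination;
* one-factor PERMANOVA on a distance matrix, with exact exhaustive
  enumeration for small designs, and sequential (Type-I) multi-factor
  decomposition in the style of adonis.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BACTERIAL_PLFA_MARKERS",
    "FUNGAL_PLFA_MARKERS",
    "default_marker_map",
    "canonicalize_marker",
    "PLFAProfile",
    "TaxonTable",
    "PermanovaResult",
    "classify_plfa",
    "fb_percent",
    "fb_from_taxa",
    "relative_abundance",
    "fold_change",
    "arb_ratio",
    "hellinger",
    "permanova",
    "permanova_sequential",
]

logger = logging.getLogger(__name__)

# 23 bacterial markers; 18:1ω9 is kept bacterial here (override via marker_map
# if you follow the convention that treats it as fungal).
BACTERIAL_PLFA_MARKERS: tuple[str, ...] = (
    "14:0", "15:0", "16:0", "17:0", "18:0",
    "14:0i", "15:0i", "15:0a", "16:0i", "17:0i", "17:0a",
    "16:0(10Me)", "17:0(10Me)", "18:0(10Me)",
    "17:0cy", "19:0cy",
    "15:1", "16:1ω7", "16:1ω5", "16:1", "17:1", "18:1ω7", "18:1ω9",
)
FUNGAL_PLFA_MARKERS: tuple[str, ...] = ("18:2ω6,9",)


def canonicalize_marker(name: str) -> str:
    """Normalize a PLFA marker name: strip spaces, ASCII 'w' → 'ω' before digits."""
    s = name.strip().replace(" ", "")
    s = re.sub(r"[wW](?=\d)", "ω", s)
    return s


def default_marker_map() -> dict[str, str]:
    """Marker → {'bacterial','fungal'} map for the default biomarker set."""
    m = {k: "bacterial" for k in BACTERIAL_PLFA_MARKERS}
    m.update({k: "fungal" for k in FUNGAL_PLFA_MARKERS})
    return m


@dataclass(frozen=True)
class PLFAProfile:
    """One sample's phospholipid-fatty-acid profile (marker → μg lipid g⁻¹ soil)."""

    sample_id: str
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if not self.concentrations:
            raise ValueError(f"empty PLFA profile for sample {self.sample_id!r}")
        canon = {}
        for marker, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"negative concentration for marker {marker!r}")
            canon[canonicalize_marker(marker)] = canon.get(canonicalize_marker(marker), 0.0) + conc
        object.__setattr__(self, "concentrations", canon)


@dataclass
class TaxonTable:
    """Taxa × samples abundance matrix with domain/phylum lineage labels.

    ``data`` is indexed by lineage strings ("Domain;Phylum[;...]"), columns
    are samples, cells are non-negative counts or proportions. ``metadata``
    optionally maps sample → soil_class / treatment.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("taxon table contains negative abundances")

    @property
    def domains(self) -> pd.Series:
        return self.data.index.to_series().str.split(";").str[0].str.strip()

    @property
    def phyla(self) -> pd.Series:
        parts = self.data.index.to_series().str.split(";")
        return parts.str[1].fillna("").str.strip()

    def domain_sum(self, domain: str) -> pd.Series:
        """Per-sample summed abundance of one domain (case-insensitive)."""
        mask = (self.domains.str.lower() == domain.lower()).to_numpy()
        return self.data.loc[mask].sum(axis=0)


def classify_plfa(
    profile: PLFAProfile, marker_map: dict[str, str] | None = None
) -> tuple[float, float]:
    """Sum marker concentrations into (fungal_index, bacterial_index).

    Markers absent from ``marker_map`` are excluded and logged — internal
    standards and unassigned lipids must not leak into either index.
    """
    if marker_map is None:
        marker_map = default_marker_map()
    marker_map = {canonicalize_marker(k): v for k, v in marker_map.items()}
    fungal = bacterial = 0.0
    for marker, conc in profile.concentrations.items():
        role = marker_map.get(marker)
        if role == "fungal":
            fungal += conc
        elif role == "bacterial":
            bacterial += conc
        elif role in (None, "ignored"):
            logger.warning(
                "sample %s: marker %r not in marker map, excluded", profile.sample_id, marker
            )
        else:
            raise ValueError(f"unknown marker role {role!r} for {marker!r}")
    return fungal, bacterial


def fb_percent(fungal_index: float, bacterial_index: float, ndigits: int | None = None) -> float:
    """Percent proportion of fungi relative to bacteria: 100·F/B.

    Full precision by default; pass ``ndigits`` (e.g. 1) at the reporting
    layer only.
    """
    if bacterial_index <= 0:
        raise ZeroDivisionError("bacterial index must be positive for a F:B percent")
    out = 100.0 * fungal_index / bacterial_index
    return round(out, ndigits) if ndigits is not None else out


def fb_from_taxa(table: TaxonTable) -> pd.DataFrame:
    """Per-sample fungal/bacterial index and %F:B from a taxon table.

    Indices are summed abundances of the Fungi and Bacteria domains; other
    domains (Archaea, plant RNA, ...) are excluded by construction. Works on
    counts or proportions — the percent is scale-invariant per sample.
    """
    fungal = table.domain_sum("Fungi")
    bacterial = table.domain_sum("Bacteria")
    if (bacterial <= 0).any():
        bad = bacterial.index[bacterial <= 0].tolist()
        raise ZeroDivisionError(f"zero bacterial abundance in sample(s) {bad}")
    return pd.DataFrame(
        {
            "fungal_index": fungal,
            "bacterial_index": bacterial,
            "percent_fb": 100.0 * fungal / bacterial,
        }
    )


def relative_abundance(table: TaxonTable) -> TaxonTable:
    """Normalize each sample (column) to sum to 1; idempotent."""
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {zero.index.tolist()}")
    return TaxonTable(table.data.div(sums, axis=1), table.metadata)


def fold_change(after, before):
    """Per-taxon fold change of relative abundance: after / before.

    Accepts scalars or aligned Series; a zero 'before' abundance yields NaN
    (reported as missing, not infinity).
    """
    if np.isscalar(after) and np.isscalar(before):
        return float(after) / float(before) if before > 0 else float("nan")
    after = pd.Series(after)
    before = pd.Series(before)
    out = after / before
    out[before <= 0] = np.nan
    return out


def arb_ratio(table: TaxonTable) -> pd.Series:
    """Actinobacteria : rest-of-bacteria ratio per sample, A / (B_total − A)."""
    is_bact = (table.domains.str.lower() == "bacteria").to_numpy()
    is_actino = is_bact & (table.phyla.str.lower() == "actinobacteria").to_numpy()
    a = table.data.loc[is_actino].sum(axis=0)
    b_total = table.data.loc[is_bact].sum(axis=0)
    rest = b_total - a
    out = pd.Series(0.0, index=table.data.columns, name="arb_ratio")
    nonzero = a > 0
    if (rest[nonzero] <= 0).any():
        bad = rest.index[nonzero & (rest <= 0)].tolist()
        raise ValueError(f"Actinobacteria abundance is not below total bacteria in {bad}")
    out[nonzero] = a[nonzero] / rest[nonzero]
    return out


def hellinger(table):
    """Hellinger transform: cell → sqrt(cell / sample total), per column.

    Each transformed column has unit sum of squares, so Euclidean distances
    on the result are Hellinger distances on the raw table. Accepts a
    :class:`TaxonTable` (returns one) or a 2-D array (columns = samples).
    """
    if isinstance(table, TaxonTable):
        return TaxonTable(hellinger_frame(table.data), table.metadata)
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundance in table")
    sums = arr.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("zero-sum column in table")
    return np.sqrt(arr / sums)


def hellinger_frame(df: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(hellinger(df.to_numpy()), index=df.index, columns=df.columns)


# --------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    """One-factor PERMANOVA outcome.

    ``p_value`` is exact (proportion of all distinct relabelings with
    F* ≥ F_obs) when ``exhaustive``; otherwise the standard permutation
    estimate (count + 1)/(n + 1).
    """

    pseudo_f: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    ss_among: float = field(default=float("nan"))
    ss_within: float = field(default=float("nan"))


def _check_distance_matrix(dist) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=0, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def _ss_decomposition(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(SS_among, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total - ss_within, ss_within


def _pseudo_f(ss_among, ss_within, n_groups, n) -> float:
    if ss_within == 0:
        return math.inf if ss_among > 0 else math.nan
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def _multiset_label_arrangements(counts: list[int]):
    """Yield every distinct assignment of group codes to positions."""
    n = sum(counts)
    positions = list(range(n))

    def rec(remaining, counts_left, assignment):
        live = [g for g, c in enumerate(counts_left) if c > 0]
        if not remaining:
            yield tuple(assignment)
            return
        # place the first remaining position into each still-open group
        pos = remaining[0]
        for g in live:
            counts_left[g] -= 1
            assignment[pos] = g
            yield from rec(remaining[1:], counts_left, assignment)
            counts_left[g] += 1

    yield from rec(positions, list(counts), [0] * n)


def permanova(dist, groups, n_permutations: int = 999, seed: int | None = None) -> PermanovaResult:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    The pseudo-F follows the among/within sum-of-squares decomposition of
    the squared distances. Significance is assessed by relabeling: when the
    number of distinct label arrangements is at most ``n_permutations``,
    every arrangement is enumerated and the p-value is exact
    (#{F* ≥ F_obs}/#arrangements, the observed arrangement included);
    otherwise ``n_permutations`` random relabelings drawn from ``seed`` give
    p = (#{F* ≥ F_obs} + 1)/(n_permutations + 1).
    """
    d = _check_distance_matrix(dist)
    labels = np.asarray(groups)
    if labels.shape[0] != d.shape[0]:
        raise ValueError("group labels must match the distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least two members (singleton group found)")
    n = d.shape[0]
    d2 = d**2
    ss_among, ss_within = _ss_decomposition(d2, codes, n_groups)
    f_obs = _pseudo_f(ss_among, ss_within, n_groups, n)

    n_arrangements = math.factorial(n) // math.prod(math.factorial(int(c)) for c in counts)
    tol = 1e-12 * max(1.0, abs(f_obs)) if math.isfinite(f_obs) else 0.0

    if n_arrangements <= n_permutations:
        count = total = 0
        for arrangement in _multiset_label_arrangements([int(c) for c in counts]):
            sa, sw = _ss_decomposition(d2, np.asarray(arrangement), n_groups)
            f_star = _pseudo_f(sa, sw, n_groups, n)
            total += 1
            if f_star >= f_obs - tol:
                count += 1
        return PermanovaResult(f_obs, count / total, total, True, ss_among, ss_within)

    rng = np.random.default_rng(seed)
    perms = np.array([codes[rng.permutation(n)] for _ in range(n_permutations)])
    ss_total = d2.sum() / (2.0 * n)
    ss_w = np.zeros(n_permutations)
    for g in range(n_groups):
        mask = (perms == g).astype(float)  # (n_perm, n) one-hot per group
        ss_w += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * counts[g])
    ss_a = ss_total - ss_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = (ss_a / (n_groups - 1)) / (ss_w / (n - n_groups))
    f_star = np.where(ss_w == 0, np.where(ss_a > 0, np.inf, np.nan), f_star)
    count = int(np.sum(f_star >= f_obs - tol))
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(f_obs, p, n_permutations, False, ss_among, ss_within)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _design_matrix(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy columns for a term; 'a:b' denotes an interaction of factors."""
    factors = term.split(":")
    combo = metadata[factors[0]].astype(str)
    for f in factors[1:]:
        combo = combo + "\x1f" + metadata[f].astype(str)
    return pd.get_dummies(combo, dtype=float).to_numpy()


def permanova_sequential(
    dist,
    metadata: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequential (Type-I) multi-factor PERMANOVA, adonis-style.

    Terms (factor names from ``metadata``, interactions as "a:b") are fitted
    in the given order on the Gower-centered squared-distance matrix; each
    term's SS is the increment in trace(H·G) over the previous model, its
    pseudo-F uses the full-model residual, and p-values come from random row
    relabelings of G. Returns a frame indexed by term with columns
    df, ss, pseudo_f, p_value (plus a Residual row).
    """
    d = _check_distance_matrix(dist)
    if len(metadata) != d.shape[0]:
        raise ValueError("metadata rows must match the distance matrix size")
    n = d.shape[0]
    g = _gower_center(d**2)

    hats, dfs = [], []
    x = np.ones((n, 1))
    rank_prev = 1
    for term in terms:
        x = np.hstack([x, _design_matrix(metadata, term)])
        h = x @ np.linalg.pinv(x)  # projector onto col(X), robust to redundant dummies
        rank = int(np.linalg.matrix_rank(x))
        hats.append(h)
        dfs.append(rank - rank_prev)
        rank_prev = rank

    ss_total = float(np.trace(g))
    tr = [float(np.trace(h @ g)) for h in hats]
    ss_terms = np.diff([0.0] + tr) + np.array([0.0] * len(terms))
    # the first model includes the intercept whose trace contribution is 0 for centered G
    ss_resid = ss_total - tr[-1]
    df_resid = n - rank_prev
    f_obs = np.array(
        [
            (ss_terms[i] / dfs[i]) / (ss_resid / df_resid) if dfs[i] > 0 else np.nan
            for i in range(len(terms))
        ]
    )

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(terms))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        tr_p = [float(np.trace(h @ gp)) for h in hats]
        ss_p = np.diff([0.0] + tr_p)
        ss_res_p = ss_total - tr_p[-1]
        f_p = np.array(
            [
                (ss_p[i] / dfs[i]) / (ss_res_p / df_resid) if dfs[i] > 0 else np.nan
                for i in range(len(terms))
            ]
        )
        counts += f_p >= f_obs - 1e-12
    pvals = (counts + 1) / (n_permutations + 1)

    rows = {
        term: {"df": dfs[i], "ss": ss_terms[i], "pseudo_f": f_obs[i], "p_value": pvals[i]}
        for i, term in enumerate(terms)
    }
    rows["Residual"] = {"df": df_resid, "ss": ss_resid, "pseudo_f": np.nan, "p_value": np.nan}
    return pd.DataFrame(rows).T
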