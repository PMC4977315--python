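"""Stable-carbon-isotope arithmetic: δ-notation, atom fractions and excess ¹³C.

All tracer bookkeeping in this package reduces to three conversions:

* δ¹³C (‰ vs VPDB)  ↔  isotope ratio  R = R_VPDB · (1 + δ/1000)
* isotope ratio     ↔  atom fraction  x = R / (1 + R)
* excess ¹³C mass of a pool = (x_post − x_pre) · C_pool

Excess masses are computed through atom fractions, not the linear
δ-difference shortcut: a ¹³C-enriched litter label sits near +900‰, far
outside the regime where δ differences are proportional to ¹³C mass. The
linear approximation is available as an explicit diagnostic only
(:func:`excess_mass_linear_approx`).

Units: δ in ‰ vs VPDB; carbon contents in μg C g⁻¹ dry soil (for respiration,
μg C g⁻¹ h⁻¹); excess masses in ng ¹³C g⁻¹ (ng g⁻¹ h⁻¹ for rates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "R_VPDB",
    "Pool",
    "IsotopeMeasurement",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "excess_mass",
    "excess_mass_linear_approx",
    "delta_excess",
    "NegativeExcessWarning",
]

logger = logging.getLogger(__name__)

#: IAEA consensus ¹³C/¹²C ratio of the Vienna Pee Dee Belemnite standard.
R_VPDB: float = 0.0111802


class NegativeExcessWarning(UserWarning):
    """A computed excess ¹³C mass is negative (measurement noise); retained, not clipped."""


class Pool(str, Enum):
    """Carbon pools measured in a mesocosm harvest."""

    BULK_SOM = "bulk_som"
    FUMIGATED_EXTRACT = "fumigated_extract"
    NONFUMIGATED_EXTRACT = "nonfumigated_extract"
    RESPIRED_CO2 = "respired_co2"
    LITTER = "litter"


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One pool at one time: δ¹³C plus carbon content.

    Parameters
    ----------
    pool
        Which pool was measured.
    time_h
        Hours since litter addition (≥ 0).
    delta13c
        δ¹³C in ‰ vs VPDB; must exceed −1000 (the ratio must stay positive).
    c_content
        μg C g⁻¹ dry soil, or μg C g⁻¹ h⁻¹ for the respiration rate pool.
    """

    pool: Pool
    time_h: float
    delta13c: float
    c_content: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        if self.delta13c <= -1000.0:
            raise ValueError(f"delta13c must be > -1000 permil, got {self.delta13c}")
        if self.c_content < 0:
            raise ValueError(f"c_content must be >= 0, got {self.c_content}")


def _check_delta(delta_permil, name: str = "delta") -> np.ndarray:
    d = np.asarray(delta_permil, dtype=float)
    if np.any(d <= -1000.0):
        raise ValueError(f"{name} must be > -1000 permil (isotope ratio must stay positive)")
    return d


def delta_to_atom_fraction(delta_permil, r_std: float = R_VPDB):
    """Convert δ¹³C (‰ vs a standard of ratio ``r_std``) to the ¹³C atom fraction.

    x = R/(1+R) with R = r_std·(1 + δ/1000). Strictly increasing in δ.
    Accepts scalars or arrays.
    """
    if r_std <= 0:
        raise ValueError(f"r_std must be positive, got {r_std}")
    d = _check_delta(delta_permil)
    r = r_std * (1.0 + d / 1000.0)
    x = r / (1.0 + r)
    return x if x.ndim else float(x)


def atom_fraction_to_delta(atom_fraction, r_std: float = R_VPDB):
    """Exact inverse of :func:`delta_to_atom_fraction`.

    δ = 1000·(R/r_std − 1) with R = x/(1−x), for atom fraction x ∈ [0, 1).
    """
    if r_std <= 0:
        raise ValueError(f"r_std must be positive, got {r_std}")
    x = np.asarray(atom_fraction, dtype=float)
    if np.any((x < 0) | (x >= 1)):
        raise ValueError("atom fraction must lie in [0, 1)")
    r = x / (1.0 - x)
    d = 1000.0 * (r / r_std - 1.0)
    return d if d.ndim else float(d)


def delta_excess(delta_post, delta_pre):
    """Δδ¹³C: the shift in δ¹³C of a pool after label addition (‰).

    A diagnostic companion to :func:`excess_mass`; may legitimately be
    negative under measurement noise.
    """
    d_post = _check_delta(delta_post, "delta_post")
    d_pre = _check_delta(delta_pre, "delta_pre")
    out = d_post - d_pre
    return out if np.ndim(out) else float(out)


def excess_mass(delta_post, delta_pre, c_pool, r_std: float = R_VPDB, *, warn_negative: bool = True):
    """Excess ¹³C mass of a pool, in ng ¹³C g⁻¹ dry soil.

    (x(δ_post) − x(δ_pre)) · C_pool with C_pool in μg C g⁻¹; the ×1000
    converts μg to ng. For the respiration pool pass the rate
    (μg C g⁻¹ h⁻¹) and read the result as ng ¹³C g⁻¹ h⁻¹.

    Negative values (δ_post < δ_pre) are retained — clipping would bias the
    downstream mass balance — and flagged with :class:`NegativeExcessWarning`.
    """
    c = np.asarray(c_pool, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_pool must be >= 0")
    x_post = delta_to_atom_fraction(delta_post, r_std)
    x_pre = delta_to_atom_fraction(delta_pre, r_std)
    out = (np.asarray(x_post) - np.asarray(x_pre)) * c * 1000.0
    if warn_negative and np.any(np.asarray(out) < 0):
        warnings.warn(
            "negative excess 13C mass encountered (retained, not clipped)",
            NegativeExcessWarning,
            stacklevel=2,
        )
    return out if np.ndim(out) else float(out)


def excess_mass_linear_approx(delta_post, delta_pre, c_pool, r_std: float = R_VPDB):
    """First-order (small-δ) approximation of :func:`excess_mass`, ng ¹³C g⁻¹.

    Uses dx/dδ evaluated at δ = 0: x ≈ x₀ + Δδ · r_std/(1000·(1+r_std)²).
    Provided only so users can quantify how badly the linear shortcut fails
    near a strongly enriched label; never used internally.
    """
    dd = delta_excess(delta_post, delta_pre)
    slope = r_std / (1000.0 * (1.0 + r_std) ** 2)
    out = np.asarray(dd) * slope * np.asarray(c_pool, dtype=float) * 1000.0
    return out if np.ndim(out) else float(out)
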