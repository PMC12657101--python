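"""Closed-form body-composition densitometry.

Implements the algebra linking whole-body (or tissue) density to the mass
fractions of its constituent compartments: mixture densities, the solve for
an unknown final compartment, Siri-type lipid-proportion equations against a
general or lean reference body, and the gas correction that converts tissue
density to whole-body density and mass.

All densities are in kg m-3, masses in kg, volumes in m3 and proportions are
mass fractions unless noted otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Constants",
    "CompartmentMix",
    "DensityEstimate",
    "MassResult",
    "mixture_density",
    "solve_final_compartment",
    "lipid_proportion_general",
    "delta_lipid",
    "lipid_proportion_lean",
    "gas_corrected_body",
    "lipid_mass",
    "read_density_csv",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Constants:
    """Physical constants of the four-constituent body model.

    Constituent densities are literature-calibrated defaults chosen so that
    the canonical lean composition (69.1% water / 27.4% protein / 3.4% ash)
    yields a lean tissue density of ~1093.5 kg m-3; ``rho_lipid`` ~= 860
    matches sperm whale oil at body temperature.  ``p_gas`` is the diving
    gas volume carried per unit tissue mass (ml kg-1).
    """

    rho_lipid: float = 860.0
    rho_protein: float = 1340.0
    rho_ash: float = 2300.0
    rho_water: float = 994.0
    rho_gas: float = 1.225  # air at one atmosphere
    p_gas: float = 30.0  # ml per kg of tissue

    def __post_init__(self) -> None:
        if not (self.rho_lipid < self.rho_water < self.rho_protein < self.rho_ash):
            raise ValueError(
                "expected rho_lipid < rho_water < rho_protein < rho_ash, got "
                f"{self.rho_lipid}, {self.rho_water}, {self.rho_protein}, {self.rho_ash}"
            )
        if self.rho_gas >= 2.0 or self.rho_gas <= 0:
            raise ValueError(f"rho_gas must be in (0, 2), got {self.rho_gas}")
        if self.p_gas < 0:
            raise ValueError(f"p_gas must be >= 0, got {self.p_gas}")

    @property
    def constituent_densities(self) -> dict[str, float]:
        return {
            "water": self.rho_water,
            "protein": self.rho_protein,
            "lipid": self.rho_lipid,
            "ash": self.rho_ash,
        }


@dataclass
class CompartmentMix:
    """Densities and fractions (mass or volume) of an n-compartment body."""

    densities: np.ndarray
    fractions: np.ndarray
    by: Literal["mass", "volume"] = "mass"

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.densities.shape != self.fractions.shape:
            raise ValueError("densities and fractions must have the same shape")
        if np.any(self.fractions < -_FRACTION_TOL):
            raise ValueError("fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"fractions must sum to 1, got {self.fractions.sum():.9f}"
            )


@dataclass(frozen=True)
class DensityEstimate:
    """Per-whale tissue density with its standard error, from biologging.

    Tissue density is estimated upstream by hydrodynamic modelling of
    non-stroking glide segments; this package consumes the estimate and its
    uncertainty, it does not compute them.
    """

    whale_id: str
    rho_t: float
    se: float
    n_subglides: int = 0

    def __post_init__(self) -> None:
        if not (1000.0 <= self.rho_t <= 1100.0):
            raise ValueError(f"rho_t={self.rho_t} outside plausible [1000, 1100]")
        if self.se <= 0:
            raise ValueError("se must be > 0")


@dataclass(frozen=True)
class MassResult:
    """Gas-corrected whole-body quantities for one animal/draw.

    ``v_gas`` and ``m_gas`` are on a per-1-m3-of-tissue basis, matching the
    closed-form gas correction; ``rho_b`` is whole-body density including gas
    spaces, ``m_b`` total body mass and ``m_l`` total lipid mass.
    """

    v_b: float
    v_gas: float
    m_gas: float
    rho_b: float
    m_b: float
    m_l: float = np.nan


def mixture_density(mix: CompartmentMix) -> float:
    """Density of a multi-compartment body.

    With volume fractions the body density is the volume-weighted arithmetic
    mean of compartment densities (rho = sum rho_c * Vc/V); with mass
    fractions it is the mass-weighted harmonic mean (1/rho = sum Pc/rho_c),
    which is the same physical statement re-expressed.
    """
    if mix.by == "volume":
        return float(np.sum(mix.densities * mix.fractions))
    return float(1.0 / np.sum(mix.fractions / mix.densities))


def solve_final_compartment(
    rho: float,
    known: Sequence[tuple[float, float]],
    rho_n: float,
) -> float:
    """Mass fraction of the last compartment given whole density and n-1 others.

    ``known`` is a sequence of (mass_fraction, density) pairs.  Solves
    Pn = rho_n * (1/rho - sum Pc/rho_c), the exact inverse of the harmonic
    mixture.  Values outside [0, 1] indicate inconsistent inputs and are
    returned with a warning rather than raised.
    """
    if rho <= 0 or rho_n <= 0:
        raise ValueError("densities must be positive")
    known_sum = 0.0
    frac_sum = 0.0
    for p_c, rho_c in known:
        if rho_c <= 0:
            raise ValueError("compartment densities must be positive")
        known_sum += p_c / rho_c
        frac_sum += p_c
    if frac_sum > 1.0 + _FRACTION_TOL:
        raise ValueError(f"known mass fractions sum to {frac_sum} > 1")
    p_n = rho_n * (1.0 / rho - known_sum)
    if not (0.0 - _FRACTION_TOL <= p_n <= 1.0 + _FRACTION_TOL):
        warnings.warn(
            f"solved mass fraction {p_n:.6f} outside [0, 1]: inconsistent inputs",
            stacklevel=2,
        )
    return float(p_n)


def lipid_proportion_general(
    rho_t: float | np.ndarray,
    rho_gamma: float,
    pl_gamma: float,
    rho_tau: float,
    pl_tau: float,
    rho_lipid: float,
) -> float | np.ndarray:
    """Total body lipid proportion against an arbitrary reference body.

    The reference body gamma (density ``rho_gamma``, lipid proportion
    ``pl_gamma``) is assumed to gain or lose a reserve tissue tau (density
    ``rho_tau``, lipid content ``pl_tau``).  Setting pl_gamma=0,
    rho_gamma=rho_lean, pl_tau=1, rho_tau=rho_lipid recovers the lean-
    reference special case (:func:`lipid_proportion_lean`).
    """
    if rho_gamma == rho_tau:
        raise ValueError("rho_gamma must differ from rho_tau")
    if rho_gamma == rho_lipid:
        raise ValueError("rho_gamma must differ from rho_lipid")
    rho_t = np.asarray(rho_t, dtype=float)
    term1 = (rho_tau * rho_gamma / rho_t) * (pl_tau - pl_gamma) / (rho_gamma - rho_tau)
    term2 = (rho_tau * pl_tau - rho_gamma * pl_gamma) / (rho_gamma - rho_lipid)
    out = term1 - term2
    return float(out) if out.ndim == 0 else out


def delta_lipid(
    rho_t: float | np.ndarray,
    rho_gamma: float | np.ndarray,
    rho_tau: float,
) -> float | np.ndarray:
    """Difference in lipid mass fraction between a body and the reference.

    delta_Pl = k/rho_t - c with k = rho_gamma*rho_tau/(rho_gamma - rho_tau)
    and c = rho_tau/(rho_gamma - rho_tau); linear in 1/rho_t and strictly
    decreasing in rho_t.  Zero when rho_t equals the reference density.
    Broadcasts over arrays of tissue and reference densities.
    """
    if np.any(np.asarray(rho_gamma) == rho_tau):
        raise ValueError("rho_gamma must differ from rho_tau")
    k, c = delta_lipid_coefficients(rho_gamma, rho_tau)
    rho_t = np.asarray(rho_t, dtype=float)
    out = k / rho_t - c
    return float(out) if out.ndim == 0 else out


def delta_lipid_coefficients(rho_gamma, rho_tau):
    """(k, c) such that delta_Pl = k/rho_t - c; also rho_t = k/(delta_Pl + c)."""
    denom = rho_gamma - rho_tau
    return rho_gamma * rho_tau / denom, rho_tau / denom


def lipid_proportion_lean(
    rho_t: float | np.ndarray,
    rho_lean: float,
    rho_lipid: float,
    warn_out_of_range: bool = True,
) -> float | np.ndarray:
    """Lipid mass fraction using a lipid-free (lean) reference body.

    Pl = (1/rho_t) * rho_lean*rho_lipid/(rho_lean - rho_lipid)
         - rho_lipid/(rho_lean - rho_lipid)

    Pl(rho_lean) = 0 and Pl(rho_lipid) = 1.  Tissue densities outside
    [rho_lipid, rho_lean] can arise from measurement noise; the value is
    extrapolated with a warning rather than rejected.
    """
    if rho_lipid >= rho_lean:
        raise ValueError("rho_lipid must be less than rho_lean")
    rho_arr = np.asarray(rho_t, dtype=float)
    if warn_out_of_range and (
        np.any(rho_arr < rho_lipid) or np.any(rho_arr > rho_lean)
    ):
        warnings.warn(
            "tissue density outside [rho_lipid, rho_lean]; lipid proportion "
            "extrapolated outside [0, 1]",
            stacklevel=2,
        )
    return delta_lipid(rho_t, rho_lean, rho_lipid)


def gas_corrected_body(
    rho_t: float,
    constants: Constants,
    v_b: float,
) -> MassResult:
    """Whole-body density and mass from tissue density plus diving gas.

    Per 1 m3 of tissue: the gas volume is Vg = Pg * 1e-6 * rho_t (ml kg-1
    times tissue mass, converted to m3), its mass Mg = Vg * rho_g, and the
    whole-body density rho_b = (rho_t + Mg) / (1 + Vg).  Total body mass is
    then Mb = Vb * rho_b.  With Pg = 0 this reduces to rho_b = rho_t.
    """
    if v_b <= 0:
        raise ValueError("v_b must be > 0")
    v_g = constants.p_gas * 1e-6 * rho_t
    m_g = v_g * constants.rho_gas
    rho_b = (rho_t + m_g) / (1.0 + v_g)
    return MassResult(v_b=v_b, v_gas=v_g, m_gas=m_g, rho_b=rho_b, m_b=v_b * rho_b)


def lipid_mass(pl: float, m_b: float) -> float:
    """Total body lipid mass Ml = Pl * Mb (kg)."""
    if not (0.0 <= pl <= 1.0):
        raise ValueError(f"lipid proportion {pl} outside [0, 1]")
    if m_b <= 0:
        raise ValueError("m_b must be > 0")
    return pl * m_b


def read_density_csv(path) -> list[DensityEstimate]:
    """Read per-whale tissue density estimates from a density.csv table."""
    df = pd.read_csv(path)
    required = {"whale_id", "rho_t", "rho_t_se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"density table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DensityEstimate(
                whale_id=str(row.whale_id),
                rho_t=float(row.rho_t),
                se=float(row.rho_t_se),
                n_subglides=int(getattr(row, "n_subglides", 0) or 0),
            )
        )
    return out
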