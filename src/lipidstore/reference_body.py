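"""Monte Carlo simulation of sperm-whale reference bodies.

A reference body is a hypothetical whale of known composition against which
an observed tissue density is compared.  Each simulated body is assembled
from eight tissue compartments (skeleton, muscle, organs, viscera, blubber,
sound production apparatus, other, blood); every compartment is itself a
mixture of four mutually insoluble constituents (water, lipid, protein,
mineral ash).  Summing constituent masses and volumes over compartments
yields total and lean (lipid-excluded) mass, volume and density:

    M_lean = sum_c M_c (Pp + Pa + Pw)          [lipid term added for total]
    V_lean = sum_c M_c (Pp/rho_p + Pa/rho_a + Pw/rho_w)
    rho_lean = M_lean / V_lean

Compartment masses scale with length through a total-mass allometry
M = a L^b multiplied by per-compartment mass fractions.  Mass fractions and
compositions are drawn as independent truncated Gaussians and renormalised
to sum to one, which propagates literature parameter uncertainty into the
lean- and standard-body density distributions used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .densitometry import Constants

__all__ = [
    "CompartmentParameterTable",
    "ReferenceBodyDraws",
    "ReferenceSummary",
    "default_compartment_table",
    "draw_reference_bodies",
    "summarize_reference",
    "external_validation",
    "spermaceti_share",
]

COMPARTMENT_NAMES = (
    "Skeleton",
    "Muscle",
    "Organs",
    "Viscera",
    "Blubber",
    "Sound production apparatus",
    "Other",
    "Blood",
)
CONSTITUENTS = ("water", "lipid", "protein", "ash")
SPA = "Sound production apparatus"


@dataclass
class CompartmentParameterTable:
    """Per-compartment mass-fraction and composition parameters.

    ``table`` must contain one row per compartment with columns
    mass_frac_mean/sd and p_{water,lipid,protein,ash}_{mean,sd}.  The total
    body mass allometry M = mass_a * L^mass_b (kg, m) distributes mass
    across compartments via the (renormalised) mass fractions.
    """

    table: pd.DataFrame
    mass_a: float = 18.5
    mass_b: float = 2.88

    def __post_init__(self) -> None:
        got = set(self.table["compartment"])
        if got != set(COMPARTMENT_NAMES):
            raise ValueError(
                f"expected exactly the 8 compartments {COMPARTMENT_NAMES}, got {sorted(got)}"
            )
        self.table = (
            self.table.set_index("compartment").loc[list(COMPARTMENT_NAMES)].reset_index()
        )
        mf = self.table["mass_frac_mean"].to_numpy()
        if abs(mf.sum() - 1.0) > 1e-3:
            raise ValueError(f"mean mass fractions sum to {mf.sum():.6f}, not 1")
        comp = self.composition_means
        if np.abs(comp.sum(axis=1) - 1.0).max() > 1e-3:
            raise ValueError("per-compartment composition means must sum to 1")
        if self.mass_a <= 0 or self.mass_b <= 0:
            raise ValueError("mass allometry coefficients must be positive")

    @property
    def mass_frac_means(self) -> np.ndarray:
        return self.table["mass_frac_mean"].to_numpy()

    @property
    def mass_frac_sds(self) -> np.ndarray:
        return self.table["mass_frac_sd"].to_numpy()

    @property
    def composition_means(self) -> np.ndarray:
        """(8, 4) array ordered as (water, lipid, protein, ash)."""
        return self.table[[f"p_{k}_mean" for k in CONSTITUENTS]].to_numpy()

    @property
    def composition_sds(self) -> np.ndarray:
        return self.table[[f"p_{k}_sd" for k in CONSTITUENTS]].to_numpy()


@dataclass
class ReferenceBodyDraws:
    """Columnar container for n simulated reference bodies.

    Arrays are aligned on the draw axis; ``compartment_masses`` is
    (n, 8) and ``constituent_fractions`` (n, 4) ordered as
    (water, lipid, protein, ash) by mass of the whole body.
    """

    length_m: np.ndarray
    m_total: np.ndarray
    compartment_masses: np.ndarray
    m_lean: np.ndarray
    v_total: np.ndarray
    v_lean: np.ndarray
    rho_total: np.ndarray
    rho_lean: np.ndarray
    constituent_fractions: np.ndarray
    v_lipid: np.ndarray
    spa_lipid_mass: np.ndarray

    def __len__(self) -> int:
        return self.length_m.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "length_m": self.length_m,
                "m_total_kg": self.m_total,
                "m_lean_kg": self.m_lean,
                "v_total_m3": self.v_total,
                "v_lean_m3": self.v_lean,
                "rho_total": self.rho_total,
                "rho_lean": self.rho_lean,
                "v_lipid_m3": self.v_lipid,
                "spa_lipid_kg": self.spa_lipid_mass,
            }
        )
        for j, k in enumerate(CONSTITUENTS):
            df[f"p_{k}"] = self.constituent_fractions[:, j]
        return df


def default_compartment_table() -> CompartmentParameterTable:
    """Packaged compartment parameter table.

    Synthetic reconstruction calibrated from literature whaling-era body
    composition values (see scripts/calibrate_compartments.py); replaceable
    by any table with the documented schema.
    """
    with resources.files("lipidstore.data").joinpath(
        "compartments_synthetic.csv"
    ).open() as fh:
        return CompartmentParameterTable(pd.read_csv(fh))


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, size: tuple
) -> np.ndarray:
    """Gaussian draws with negatives rejected and redrawn (vectorised)."""
    out = rng.normal(mean, sd, size=size)
    bad = out < 0
    tries = 0
    while bad.any():
        out[bad] = rng.normal(np.broadcast_to(mean, size)[bad], np.broadcast_to(sd, size)[bad])
        bad = out < 0
        tries += 1
        if tries > 100:  # pragma: no cover - pathological SDs only
            out[bad] = 0.0
            warnings.warn("negative fractions clipped to zero after 100 resamples")
            break
    return out


def draw_reference_bodies(
    params: CompartmentParameterTable,
    constants: Constants,
    n: int,
    length_range: tuple[float, float] = (8.0, 17.0),
    seed: int | np.random.Generator = 0,
) -> ReferenceBodyDraws:
    """Simulate n reference bodies over a uniform length range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    length = rng.uniform(lo, hi, size=n)
    m_total = params.mass_a * length**params.mass_b

    mf = _truncated_normal(rng, params.mass_frac_means, params.mass_frac_sds, (n, 8))
    mf = mf / mf.sum(axis=1, keepdims=True)
    comp = _truncated_normal(
        rng, params.composition_means, params.composition_sds, (n, 8, 4)
    )
    comp = comp / comp.sum(axis=2, keepdims=True)

    comp_masses = m_total[:, None] * mf  # (n, 8)
    constituent_masses = comp_masses[:, :, None] * comp  # (n, 8, 4): w,l,p,a
    rho_k = np.array(
        [constants.rho_water, constants.rho_lipid, constants.rho_protein, constants.rho_ash]
    )
    constituent_volumes = constituent_masses / rho_k  # (n, 8, 4)

    whole_const_mass = constituent_masses.sum(axis=1)  # (n, 4)
    m_lean = whole_const_mass[:, [0, 2, 3]].sum(axis=1)
    v_total = constituent_volumes.sum(axis=(1, 2))
    v_lean = constituent_volumes[:, :, [0, 2, 3]].sum(axis=(1, 2))
    v_lipid = constituent_volumes[:, :, 1].sum(axis=1)

    return ReferenceBodyDraws(
        length_m=length,
        m_total=m_total,
        compartment_masses=comp_masses,
        m_lean=m_lean,
        v_total=v_total,
        v_lean=v_lean,
        rho_total=m_total / v_total,
        rho_lean=m_lean / v_lean,
        constituent_fractions=whole_const_mass / m_total[:, None],
        v_lipid=v_lipid,
        spa_lipid_mass=constituent_masses[:, COMPARTMENT_NAMES.index(SPA), 1],
    )


@dataclass(frozen=True)
class ReferenceSummary:
    """Means, SDs and quantiles of the reference-body distributions."""

    stats: pd.DataFrame
    lipid_volume_by_length: pd.DataFrame

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "stats": self.stats.to_dict(orient="index"),
                    "lipid_volume_by_length": self.lipid_volume_by_length.to_dict(
                        orient="records"
                    ),
                },
                fh,
                indent=1,
            )


def summarize_reference(draws: ReferenceBodyDraws, n_length_bins: int = 9) -> ReferenceSummary:
    """Summary statistics of the simulated reference-body distributions."""
    if len(draws) < 1:
        raise ValueError("need at least one draw")
    cols = {
        "rho_lean": draws.rho_lean,
        "rho_total": draws.rho_total,
        "p_water": draws.constituent_fractions[:, 0],
        "p_lipid": draws.constituent_fractions[:, 1],
        "p_protein": draws.constituent_fractions[:, 2],
        "p_ash": draws.constituent_fractions[:, 3],
        "lean_p_water": draws.constituent_fractions[:, 0]
        / (1.0 - draws.constituent_fractions[:, 1]),
        "lean_p_protein": draws.constituent_fractions[:, 2]
        / (1.0 - draws.constituent_fractions[:, 1]),
        "lean_p_ash": draws.constituent_fractions[:, 3]
        / (1.0 - draws.constituent_fractions[:, 1]),
    }
    rows = {}
    for name, x in cols.items():
        q = np.percentile(x, [2.5, 25, 50, 75, 97.5])
        rows[name] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "q2.5": q[0],
            "q25": q[1],
            "median": q[2],
            "q75": q[3],
            "q97.5": q[4],
        }
    stats = pd.DataFrame.from_dict(rows, orient="index")

    edges = np.linspace(draws.length_m.min(), draws.length_m.max() + 1e-9, n_length_bins + 1)
    idx = np.clip(np.digitize(draws.length_m, edges) - 1, 0, n_length_bins - 1)
    recs = []
    for b in range(n_length_bins):
        sel = idx == b
        if not sel.any():
            continue
        vl = draws.v_lipid[sel]
        recs.append(
            {
                "length_lo": edges[b],
                "length_hi": edges[b + 1],
                "n": int(sel.sum()),
                "v_lipid_mean": float(vl.mean()),
                "v_lipid_q2.5": float(np.percentile(vl, 2.5)),
                "v_lipid_q97.5": float(np.percentile(vl, 97.5)),
            }
        )
    return ReferenceSummary(stats=stats, lipid_volume_by_length=pd.DataFrame(recs))


def external_validation(
    draws: ReferenceBodyDraws,
    observed_densities: np.ndarray | list | None = None,
    observed_yields: list[tuple[float, float]] | None = None,
    n_length_bins: int = 9,
) -> pd.DataFrame:
    """Coverage of independent observations by the simulation envelope.

    Observed tissue densities are compared against the central 95% interval
    of simulated whole-body tissue density; observed (length, lipid tonnes)
    yield pairs against the 95% lipid-mass envelope of the matching length
    bin.  Returns one row per comparison set with the fraction inside.
    """
    if len(draws) == 0:
        raise ValueError("draws must be non-empty")
    rows = []
    if observed_densities is not None and len(observed_densities) > 0:
        lo, hi = np.percentile(draws.rho_total, [2.5, 97.5])
        obs = np.asarray(observed_densities, dtype=float)
        inside = (obs >= lo) & (obs <= hi)
        rows.append(
            {
                "comparison": "tissue_density",
                "n_obs": obs.size,
                "fraction_inside_95": float(inside.mean()),
                "envelope_lo": lo,
                "envelope_hi": hi,
            }
        )
    if observed_yields:
        lipid_mass_t = (
            draws.constituent_fractions[:, 1] * draws.m_total / 1000.0
        )
        edges = np.linspace(
            draws.length_m.min(), draws.length_m.max() + 1e-9, n_length_bins + 1
        )
        idx = np.clip(np.digitize(draws.length_m, edges) - 1, 0, n_length_bins - 1)
        inside = []
        for L, yield_t in observed_yields:
            b = int(np.clip(np.digitize(L, edges) - 1, 0, n_length_bins - 1))
            sel = idx == b
            if not sel.any():
                continue
            lo, hi = np.percentile(lipid_mass_t[sel], [2.5, 97.5])
            inside.append(lo <= yield_t <= hi)
        if inside:
            rows.append(
                {
                    "comparison": "lipid_yield",
                    "n_obs": len(inside),
                    "fraction_inside_95": float(np.mean(inside)),
                    "envelope_lo": np.nan,
                    "envelope_hi": np.nan,
                }
            )
    if not rows:
        warnings.warn("no observations supplied; empty validation table")
        return pd.DataFrame(
            columns=["comparison", "n_obs", "fraction_inside_95", "envelope_lo", "envelope_hi"]
        )
    return pd.DataFrame(rows)


def spermaceti_share(draws: ReferenceBodyDraws) -> np.ndarray:
    """Fraction of total body lipid held in the sound production apparatus.

    Applied post hoc to per-whale lipid mass to report the approximate
    spermaceti tonnage alongside total lipid store.
    """
    total_lipid = draws.constituent_fractions[:, 1] * draws.m_total
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total_lipid > 0, draws.spa_lipid_mass / total_lipid, 0.0)
    return share
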