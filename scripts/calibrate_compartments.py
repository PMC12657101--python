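"""Calibrate the packaged compartment parameter table.

Starts from literature-plausible sperm-whale compartment mass fractions and
constituent compositions, then applies iterative proportional fitting so the
zero-variance aggregate reproduces the canonical whole-body composition
(52.8% water, 20.9% protein, 23.5% lipid, 2.6% ash by mass).  The lean
composition (69.1/27.4/3.4) and the lean/whole-body densities follow from
that aggregate and the constituent densities; they are not separately fitted.

Writes src/lipidstore/data/compartments_synthetic.csv.  Run from the repo
root:  python scripts/calibrate_compartments.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

COMPARTMENTS = [
    # name, mass_frac, sd, water, lipid, protein, ash  (initial guesses)
    ("Skeleton", 0.105, 0.010, 0.33, 0.28, 0.19, 0.20),
    ("Muscle", 0.335, 0.025, 0.70, 0.06, 0.23, 0.01),
    ("Organs", 0.045, 0.006, 0.75, 0.08, 0.16, 0.01),
    ("Viscera", 0.065, 0.008, 0.70, 0.15, 0.14, 0.01),
    ("Blubber", 0.245, 0.028, 0.40, 0.47, 0.125, 0.005),
    ("Sound production apparatus", 0.085, 0.010, 0.35, 0.55, 0.095, 0.005),
    ("Other", 0.070, 0.008, 0.60, 0.20, 0.19, 0.01),
    ("Blood", 0.050, 0.006, 0.80, 0.01, 0.18, 0.01),
]

# per-compartment constituent SDs (water, lipid, protein, ash)
COMPOSITION_SD = {
    "Skeleton": (0.035, 0.040, 0.025, 0.025),
    "Muscle": (0.030, 0.020, 0.025, 0.002),
    "Organs": (0.030, 0.025, 0.020, 0.002),
    "Viscera": (0.035, 0.035, 0.020, 0.002),
    "Blubber": (0.045, 0.070, 0.020, 0.001),
    "Sound production apparatus": (0.045, 0.070, 0.020, 0.001),
    "Other": (0.040, 0.040, 0.025, 0.002),
    "Blood": (0.020, 0.005, 0.020, 0.002),
}

TARGET = {"water": 0.528, "protein": 0.209, "lipid": 0.235, "ash": 0.026}


def main() -> None:
    names = [c[0] for c in COMPARTMENTS]
    mass = np.array([c[1] for c in COMPARTMENTS])
    mass_sd = np.array([c[2] for c in COMPARTMENTS])
    comp = np.array([[c[3], c[4], c[5], c[6]] for c in COMPARTMENTS])  # w,l,p,a
    target = np.array([TARGET["water"], TARGET["lipid"], TARGET["protein"], TARGET["ash"]])

    mass = mass / mass.sum()
    for _ in range(200):
        agg = mass @ comp
        comp = comp * (target / agg)[None, :]
        comp = comp / comp.sum(axis=1, keepdims=True)
        if np.abs(mass @ comp - target).max() < 1e-12:
            break
    agg = mass @ comp
    print("aggregate (w,l,p,a):", np.round(agg, 6))

    sd = np.array([COMPOSITION_SD[n] for n in names])
    df = pd.DataFrame(
        {
            "compartment": names,
            "mass_frac_mean": mass,
            "mass_frac_sd": mass_sd,
            "p_water_mean": comp[:, 0],
            "p_water_sd": sd[:, 0],
            "p_lipid_mean": comp[:, 1],
            "p_lipid_sd": sd[:, 1],
            "p_protein_mean": comp[:, 2],
            "p_protein_sd": sd[:, 2],
            "p_ash_mean": comp[:, 3],
            "p_ash_sd": sd[:, 3],
        }
    )
    out = Path(__file__).resolve().parents[1] / "src/lipidstore/data/compartments_synthetic.csv"
    df.round(6).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
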