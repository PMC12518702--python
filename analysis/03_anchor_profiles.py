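#!/usr/bin/env python
"""One-dimensional free-energy profiles of the Arg anchoring distances.

Projects synthetic ensembles onto the Arg430 CZ - Asp15 CG distance and the
Arg430 CZ - peptide-COM distance, comparing raw weighted histograms with
KDE-smoothed profiles.  The designed Asp15 anchor distance (8.5 Å) should
re-emerge as the free-energy minimum, with the COM profile broader - the
signature of a specific side-chain contact versus diffuse backbone
stabilization.  Writes results/anchor_profiles/profiles.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from halopose.free_energy import FEParams, profile_1d_free_energy
from halopose.synthetic import default_kinetics, simulate_series

OUT = Path(__file__).resolve().parents[1] / "results" / "anchor_profiles"


def main() -> None:
    series = simulate_series(default_kinetics(), 500.0, 0.1, seed=1)
    n = len(series)
    weights = np.full(n, 1.0 / n)
    edges = np.arange(4.0, 18.25, 0.25)
    rows = []
    for anchor in ("r430_d15", "r430_com"):
        profile = profile_1d_free_energy(
            series.anchor(anchor), weights, edges, FEParams()
        )
        print(
            f"{anchor}: raw minimum at {profile.argmin_raw:.2f} A, "
            f"KDE minimum at {profile.argmin_kde:.2f} A"
        )
        for c, p, f_raw, dens, f_kde in zip(
            profile.centers, profile.p_raw, profile.F_raw,
            profile.density, profile.F_kde,
        ):
            rows.append(
                {"anchor": anchor, "distance": c, "p_raw": p, "F_raw": f_raw,
                 "density": dens, "F_kde": f_kde}
            )
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "profiles.csv", index=False,
                              float_format="%.6g")
    print(f"profiles written to {OUT / 'profiles.csv'}")


if __name__ == "__main__":
    main()
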