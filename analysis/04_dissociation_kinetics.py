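#!/usr/bin/env python
"""Recover the designed dissociation kinetics from simulated trajectories.

The dissociating channel is parameterized with a 40 ns mean escape time
(k_off + Leu-contact displacement rate = 0.025/ns).  This script detects
threshold crossings (12 Å, 5 ns persistence) over 200 seeded realizations
with three iid dissociating channels each, subtracts the deterministic
basin-to-threshold transit time, and compares the recovered mean with the
design.  Writes results/dissociation/escape_times.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from halopose.geometry import dissociation_time
from halopose.synthetic import ChannelKinetics, simulate_series

OUT = Path(__file__).resolve().parents[1] / "results" / "dissociation"


def main() -> None:
    kin = ChannelKinetics(
        sd_d=1.2, sd_theta=14.0, k_off=0.005, leu_contact_rate=0.020
    )
    designed_ns = 1.0 / kin.total_escape_rate
    transit_ns = (12.0 - kin.basin_d) / kin.unbound_drift
    rows = []
    for seed in range(200):
        series = simulate_series({1: kin, 2: kin, 3: kin}, 300.0, 0.1, seed=seed)
        for identity in (1, 2, 3):
            t = dissociation_time(series, identity, 12.0, 5.0)
            rows.append({"seed": seed, "channel": identity,
                         "detected_ns": t, "corrected_ns":
                         None if t is None else t - transit_ns})
    df = pd.DataFrame(rows)
    detected = df["corrected_ns"].dropna()
    mean = detected.mean()
    print(f"designed mean escape time: {designed_ns:.1f} ns")
    print(f"recovered mean over {len(detected)} events: {mean:.2f} ns "
          f"({abs(mean - designed_ns) / designed_ns:.1%} off)")
    print(f"{len(df) - len(detected)} realizations never crossed "
          f"the threshold within 300 ns")
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "escape_times.csv", index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
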