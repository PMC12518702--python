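#!/usr/bin/env python
"""Generate the synthetic trajectory fixtures for every named scenario.

Writes, per scenario, a geometry CSV, a PDB frame subsample rebuilt by the
inverse-geometry constructor, and a JSON manifest of the generating
parameters, under results/fixtures/.  These bundles are the offline
stand-ins for enzyme-substrate trajectories: stable catalytic-pose channels
for Trp8/Trp12, a dissociating channel for Trp14, a Leu-displacement
variant, and an anchor-distance scenario.
"""

from pathlib import Path

from halopose.synthetic import SCENARIOS, write_fixture_bundle

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    for scenario in sorted(SCENARIOS):
        paths = write_fixture_bundle(OUT / scenario, scenario, seed=1)
        print(f"{scenario}:")
        for kind, path in paths.items():
            print(f"  {kind}: {path.relative_to(OUT.parents[1])}")


if __name__ == "__main__":
    main()
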