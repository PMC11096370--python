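#!/usr/bin/env python
"""Step 3: calibrate the LEKTI-elimination rate constant per scenario.

For each LEKTI-survival scenario (100 %, 50 %, 0.01 % of secreted LEKTI
remaining at the surface) finds the k_deg that hits the target on the
stepwise pH profile and verifies it with a full four-species simulation.
"""

import argparse
from pathlib import Path

import pandas as pd

import cornekin as ck

from common import INPUTS, RESULTS, load_curves


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=str, default=str(INPUTS))
    parser.add_argument("--outdir", type=str, default=str(RESULTS))
    args = parser.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    curves = load_curves(Path(args.indir))
    profile = ck.make_named_profile("stepwise_7.0_6.0_5.4_6.7")
    base = ck.ModelParams(k_auto=1e4, k_meso=3e5)

    rows = []
    for name, target in sorted(ck.SCENARIO_TARGETS.items()):
        scenario = ck.ScenarioSpec.named(name)
        k_deg = ck.calibrate_kdeg(scenario, base, profile, curves)
        traj = ck.simulate(base.replace(k_deg=k_deg), profile, curves)
        achieved = traj.C_Ltotal[-1] / traj.C_Ltotal[0]
        rows.append(
            dict(scenario=name, target_surviving_fraction=target,
                 k_deg=k_deg, achieved_surviving_fraction=achieved)
        )
        print(f"{name:20s} target {target:8.2e}  k_deg = {k_deg:12.6g} /M/s  achieved {achieved:.6e}")

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "kdeg_scenarios.csv", index=False)
    print(f"wrote {outdir / 'kdeg_scenarios.csv'}")


if __name__ == "__main__":
    main()
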