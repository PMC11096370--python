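#!/usr/bin/env python
"""Step 5: compare candidate pH depth-profiles on the identified parameters.

Simulates the representative accepted (k_auto, k_meso) pairs from the
continuous-decrease screen across the five named pH profiles and tabulates
the effective KLK activity shape (surface rise and E_KLK at key depths).
"""

import argparse
from pathlib import Path

import cornekin as ck
from cornekin.identification import GridSpec

from common import INPUTS, RESULTS, load_curves


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=str, default=str(INPUTS))
    parser.add_argument("--outdir", type=str, default=str(RESULTS))
    args = parser.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    curves = load_curves(Path(args.indir))
    stepwise = ck.make_named_profile("stepwise_7.0_6.0_5.4_6.7")
    base = ck.ModelParams(k_auto=1e4, k_meso=3e5)

    k_deg = ck.calibrate_kdeg(ck.ScenarioSpec.named("continuous_decrease"), base, stepwise, curves)
    screen = ck.screen_activation_rates(base, stepwise, curves, k_deg=k_deg,
                                        grid=GridSpec(n_per_axis=17))
    pairs = screen.representative_pairs()

    profiles = [ck.make_named_profile(n) for n in ck.NAMED_PROFILES]
    table = ck.compare_profiles(pairs, profiles, curves, k_deg=k_deg)
    path = outdir / "profile_comparison.csv"
    table.to_csv(path, index=False)

    summary = table.groupby("profile")[["surface_rise", "E_at_0_5", "E_at_1"]].mean()
    print(summary.round(4).to_string())
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
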