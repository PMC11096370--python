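#!/usr/bin/env python
"""Step 1: materialize the synthetic calibration inputs under results/inputs/.

Writes the enzyme pH-activity assays, the KLK5-LEKTI binding-rate table,
the ratiometric probe calibration series, and the in vivo-style ROI
intensity table, all from the seeded generators.
"""

import argparse

from cornekin import synthetic as syn

from common import INPUTS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=str, default=str(INPUTS))
    args = parser.parse_args()

    config = syn.GeneratorConfig(
        seed=args.seed,
        activity=syn.ActivityAssayConfig(noise_sd=0.0),
        calibration=syn.RatioCalibrationConfig(noise_sd=0.0),
    )
    paths = syn.generate_all(config, args.outdir)
    for name, path in sorted(paths.items()):
        print(f"{name:28s} -> {path}")


if __name__ == "__main__":
    main()
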