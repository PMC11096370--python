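#!/usr/bin/env python
"""Step 2: fit the pH-dependent rate functions and tabulate them.

Reads the assay tables from results/inputs/, fits the relative-activity
sigmoids and the binding-rate interpolants, and writes the fitted
parameters (JSON) plus a dense evaluation table (CSV) to results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from common import INPUTS, RESULTS, load_curves


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=str, default=str(INPUTS))
    parser.add_argument("--outdir", type=str, default=str(RESULTS))
    args = parser.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    curves = load_curves(Path(args.indir))

    params = {
        "a_klk": curves.a_klk.to_dict(),
        "a_meso": curves.a_meso.to_dict(),
        "binding": curves.binding.to_dict(),
    }
    with open(outdir / "rate_curves.json", "w") as fh:
        json.dump(params, fh, indent=2)
        fh.write("\n")

    ph = np.round(np.arange(3.5, 8.01, 0.05), 2)
    table = pd.DataFrame(
        {
            "pH": ph,
            "a_klk": curves.a_klk(ph),
            "a_meso": curves.a_meso(ph),
            "ka": curves.binding.ka(ph),
            "kd": curves.binding.kd(ph),
        }
    )
    table.to_csv(outdir / "rate_curves.csv", index=False)

    print(f"KLK5 activity midpoint  : {curves.a_klk.midpoint:.4f} (slope {curves.a_klk.slope:.3f})")
    print(f"mesotrypsin midpoint    : {curves.a_meso.midpoint:.4f} (slope {curves.a_meso.slope:.3f})")
    print(f"k_a range on table knots: {curves.binding.ka(4.5):.3e} .. {curves.binding.ka(7.5):.3e} /M/s")
    print(f"wrote {outdir / 'rate_curves.json'} and {outdir / 'rate_curves.csv'}")


if __name__ == "__main__":
    main()
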