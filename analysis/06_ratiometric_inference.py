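#!/usr/bin/env python
"""Step 6: ratiometric pH calibration and zone-wise pH inference.

Fits the probe calibration curve from the calibration series in
results/inputs/, inverts the background-subtracted ROI intensity ratios to
per-ROI pH values, and summarizes mean pH per SC zone.
"""

import argparse
from pathlib import Path

import pandas as pd

import cornekin as ck

from common import INPUTS, RESULTS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=str, default=str(INPUTS))
    parser.add_argument("--outdir", type=str, default=str(RESULTS))
    args = parser.parse_args()
    indir = Path(args.indir)
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    series = ck.CalibrationSeries.from_csv(indir / "ratio_calibration_VmC.csv")
    curve = ck.fit_calibration(series)
    print(f"fitted probe pKa = {curve.pKa:.4f}, slope = {curve.slope:.4f}")

    # the reference ratio at pH 8.0 under the same imaging condition as the ROIs
    ref = next(s for s in series if s.laser_condition == "power_1").reference_ratio

    rois_df = pd.read_csv(indir / "roi_intensities.csv")
    rois = [
        ck.ROIMeasurement(ch1=r.ch1, ch2=r.ch2, bg1=r.bg1, bg2=r.bg2, zone=r.zone)
        for r in rois_df.itertuples()
    ]
    estimates = [ck.infer_pH(curve, roi, ref) for roi in rois]
    summary = ck.summarize_zones(estimates)
    path = outdir / "zone_ph_summary.csv"
    summary.to_csv(path, index=False)
    print(summary.to_string(index=False))
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
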