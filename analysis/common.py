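"""Shared helpers for the numbered analysis scripts."""

from pathlib import Path

import cornekin as ck

RESULTS = Path(__file__).resolve().parent.parent / "results"
INPUTS = RESULTS / "inputs"


def load_curves(indir: Path = INPUTS) -> ck.RateFunctions:
    """Fit rate functions from the CSV tables written by 01_generate_inputs."""
    return ck.RateFunctions(
        a_klk=ck.fit_activity_curve(ck.ActivityPoints.from_csv(indir / "activity_klk5.csv")),
        a_meso=ck.fit_activity_curve(
            ck.ActivityPoints.from_csv(indir / "activity_mesotrypsin.csv")
        ),
        binding=ck.fit_binding_rates(ck.BindingRatePoints.from_csv(indir / "binding_rates.csv")),
    )
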