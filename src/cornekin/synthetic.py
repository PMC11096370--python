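"""Synthetic calibration-assay generators.

The model's calibration inputs are bench measurements (fluorogenic protease
assays, surface plasmon resonance binding kinetics, ratiometric probe
calibrations, in vivo ROI intensity tables) that are not deposited anywhere
machine-readable.  This module generates statistically faithful stand-ins
with explicit seeds so every downstream module is testable end to end:

* activity assays — logistic activity-vs-pH on the published buffer grids
  (acetate up to pH 5.6, phosphate 5.8–8.0), normalized to exactly 1 at the
  optimal pH 7.8 before additive Gaussian noise;
* binding tables — monotone log-linear k_a (increasing with pH) and k_d
  (decreasing), matching the physiology that acidic conditions weaken
  LEKTI's grip on KLK;
* ratiometric calibration series — a shared underlying sigmoid per probe
  (pKa 5.8 for Venus-mCherry, 7.0 for the H148G variant) scaled by a
  per-laser-condition factor, so normalized curves from different powers
  coincide;
* ROI tables — per-zone true pH draws (SG1 7.0, lower 6.0, middle 5.4,
  upper 6.7) pushed through the probe curve and split into two noisy
  channel intensities over a common random scale plus additive background.

Noise models: additive Gaussian on relative activity and on log rates,
multiplicative lognormal scale on fluorescence channels.  All generators are
pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .rate_curves import OPTIMAL_PH, ActivityPoints, BindingRatePoints
from .ratiometric import REFERENCE_PH, CalibrationSeries, ROIMeasurement

__all__ = [
    "ActivityAssayConfig",
    "BindingTableConfig",
    "RatioCalibrationConfig",
    "ZoneConfig",
    "ROITableConfig",
    "GeneratorConfig",
    "gen_activity_assay",
    "gen_binding_table",
    "gen_calibration_series",
    "gen_roi_table",
    "generate_all",
]


def _ph_grid(acetate_start: float) -> np.ndarray:
    """Assay buffer grid: acetate range up to 5.6, phosphate 5.8-8.0."""
    acetate = np.round(np.arange(acetate_start, 5.6 + 1e-9, 0.3), 10)
    phosphate = np.round(np.arange(5.8, 8.0 + 1e-9, 0.2), 10)
    return np.concatenate([acetate, phosphate])


@dataclass(frozen=True)
class ActivityAssayConfig:
    """Logistic activity-vs-pH truth per enzyme, plus assay noise."""

    optimum_ph: float = OPTIMAL_PH
    midpoint: dict = field(default_factory=lambda: {"klk5": 6.5, "mesotrypsin": 6.5})
    slope: dict = field(default_factory=lambda: {"klk5": 4.0, "mesotrypsin": 3.0})
    noise_sd: float = 0.02
    # acetate buffers start at 3.5 for the KLK5 assay and 4.1 for mesotrypsin
    acetate_start: dict = field(default_factory=lambda: {"klk5": 3.5, "mesotrypsin": 4.1})

    def truth(self, enzyme: str, ph):
        """Noise-free relative activity: logistic normalized at the optimum."""
        m, s = self.midpoint[enzyme], self.slope[enzyme]
        return expit(s * (np.asarray(ph, dtype=float) - m)) / expit(s * (self.optimum_ph - m))


@dataclass(frozen=True)
class BindingTableConfig:
    """Monotone log-linear binding-rate truth over a set of pH knots."""

    ph_knots: tuple[float, ...] = (4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5)
    log10_ka_range: tuple[float, float] = (4.0, 6.0)   # /M/s, increasing with pH
    log10_kd_range: tuple[float, float] = (-2.0, -4.0)  # /s, decreasing with pH
    noise_sd_log10: float = 0.0

    def truth(self):
        ph = np.asarray(self.ph_knots, dtype=float)
        frac = (ph - ph[0]) / (ph[-1] - ph[0])
        log_ka = self.log10_ka_range[0] + frac * (self.log10_ka_range[1] - self.log10_ka_range[0])
        log_kd = self.log10_kd_range[0] + frac * (self.log10_kd_range[1] - self.log10_kd_range[0])
        return ph, log_ka, log_kd


@dataclass(frozen=True)
class RatioCalibrationConfig:
    """Underlying ratiometric sigmoid per probe and laser-scale factors."""

    pka: dict = field(default_factory=lambda: {"VmC": 5.8, "VH148GmC": 7.0})
    slope: float = 2.3
    floor: float = 0.1
    ceiling: float = 1.0
    noise_sd: float = 0.02  # lognormal sigma on each ratio
    laser_scales: dict = field(default_factory=lambda: {"power_1": 1.0, "power_2": 1.6})
    ph_grid: tuple[float, ...] = (4.1, 4.6, 5.0, 5.4, 5.8, 6.2, 6.6, 7.0, 7.4, 8.0)

    def truth(self, probe: str, ph):
        """Noise-free, unscaled ratio (not yet normalized at pH 8.0)."""
        pka = self.pka[probe]
        return self.floor + (self.ceiling - self.floor) * expit(
            self.slope * (np.asarray(ph, dtype=float) - pka)
        )

    def reference_ratio(self, probe: str) -> float:
        """Unscaled true ratio at the reference pH 8.0."""
        return float(self.truth(probe, REFERENCE_PH))


@dataclass(frozen=True)
class ZoneConfig:
    """Per-zone true pH distribution and spot counts.

    Means are the measured zone pH values (SG1 layer 7.0, lower SC 6.0,
    middle SC 5.4, upper SC 6.7); counts mirror typical per-zone spot
    numbers in the imaging data.
    """

    means: dict = field(
        default_factory=lambda: {"sg1": 7.0, "lower": 6.0, "middle": 5.4, "upper": 6.7}
    )
    sds: dict = field(
        default_factory=lambda: {"sg1": 0.08, "lower": 0.08, "middle": 0.08, "upper": 0.08}
    )
    n_per_zone: dict = field(
        default_factory=lambda: {"sg1": 30, "lower": 67, "middle": 76, "upper": 37}
    )


@dataclass(frozen=True)
class ROITableConfig:
    """Channel-intensity model for synthetic ROI tables."""

    probe: str = "VmC"
    base_intensity: float = 1000.0   # mCherry-channel scale, arbitrary units
    scale_sigma: float = 0.2         # lognormal sigma of the common per-ROI scale
    background: tuple[float, float] = (50.0, 40.0)  # per-channel additive background
    intensity_noise_sd: float = 2.0  # additive Gaussian on each measured channel


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of all generator settings with a base seed."""

    seed: int = 0
    activity: ActivityAssayConfig = field(default_factory=ActivityAssayConfig)
    binding: BindingTableConfig = field(default_factory=BindingTableConfig)
    calibration: RatioCalibrationConfig = field(default_factory=RatioCalibrationConfig)
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    roi: ROITableConfig = field(default_factory=ROITableConfig)


def gen_activity_assay(config: GeneratorConfig, enzyme: str, *, seed: int | None = None) -> ActivityPoints:
    """Relative-activity points on the enzyme's buffer grid.

    Noise-free values lie exactly on the configured logistic and equal 1.0
    at the optimal pH 7.8.
    """
    ac = config.activity
    if enzyme not in ac.midpoint:
        raise ValueError(f"unknown enzyme {enzyme!r}; expected one of {sorted(ac.midpoint)}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ph = _ph_grid(ac.acetate_start[enzyme])
    activity = ac.truth(enzyme, ph)
    if ac.noise_sd > 0:
        activity = activity + rng.normal(0.0, ac.noise_sd, size=ph.shape)
    return ActivityPoints(ph=ph, activity=activity)


def gen_binding_table(config: GeneratorConfig, *, seed: int | None = None) -> BindingRatePoints:
    """KLK–LEKTI binding-rate table at the configured pH knots."""
    bc = config.binding
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ph, log_ka, log_kd = bc.truth()
    if bc.noise_sd_log10 > 0:
        log_ka = log_ka + rng.normal(0.0, bc.noise_sd_log10, size=ph.shape)
        log_kd = log_kd + rng.normal(0.0, bc.noise_sd_log10, size=ph.shape)
    return BindingRatePoints(ph=ph, ka=10.0**log_ka, kd=10.0**log_kd)


def gen_calibration_series(
    config: GeneratorConfig,
    probe: str,
    laser_condition: str,
    *,
    seed: int | None = None,
) -> CalibrationSeries:
    """Ratiometric calibration series under one laser condition.

    The underlying sigmoid is shared across conditions; only the
    multiplicative laser-scale factor (and the noise draw) differs, so the
    pH-8.0-normalized series coincide in the noise-free limit.
    """
    cc = config.calibration
    if probe not in cc.pka:
        raise ValueError(f"unknown probe {probe!r}; expected one of {sorted(cc.pka)}")
    if laser_condition not in cc.laser_scales:
        raise ValueError(
            f"unknown laser condition {laser_condition!r}; expected one of {sorted(cc.laser_scales)}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ph = np.asarray(cc.ph_grid, dtype=float)
    ratio = cc.truth(probe, ph) * cc.laser_scales[laser_condition]
    if cc.noise_sd > 0:
        ratio = ratio * np.exp(rng.normal(0.0, cc.noise_sd, size=ph.shape))
    return CalibrationSeries(ph=ph, ratio=ratio, laser_condition=laser_condition)


def gen_roi_table(config: GeneratorConfig, *, seed: int | None = None) -> list[ROIMeasurement]:
    """Zone-labeled two-channel ROI intensities.

    For each zone, true pH values are drawn Normal(zone mean, zone sd),
    mapped through the probe's ratio curve, and split into two channels
    sharing a random lognormal scale, with per-channel additive background
    and measurement noise.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    zc, rc, cc = config.zones, config.roi, config.calibration
    bg1, bg2 = rc.background
    rois: list[ROIMeasurement] = []
    for zone in sorted(zc.means):
        n = zc.n_per_zone[zone]
        true_ph = rng.normal(zc.means[zone], zc.sds[zone], size=n)
        true_ratio = cc.truth(rc.probe, true_ph)
        scale = rc.base_intensity * np.exp(rng.normal(0.0, rc.scale_sigma, size=n))
        ch2 = scale
        ch1 = true_ratio * scale
        if rc.intensity_noise_sd > 0:
            ch1 = ch1 + rng.normal(0.0, rc.intensity_noise_sd, size=n)
            ch2 = ch2 + rng.normal(0.0, rc.intensity_noise_sd, size=n)
        rois.extend(
            ROIMeasurement(ch1=float(a), ch2=float(b), bg1=bg1, bg2=bg2, zone=zone)
            for a, b in zip(ch1 + bg1, ch2 + bg2)
        )
    return rois


def generate_all(config: GeneratorConfig, outdir) -> dict:
    """Materialize a full fixture directory of CSV inputs; returns the paths."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    for i, enzyme in enumerate(("klk5", "mesotrypsin")):
        pts = gen_activity_assay(config, enzyme, seed=config.seed + i)
        p = outdir / f"activity_{enzyme}.csv"
        pts.to_csv(p)
        paths[f"activity_{enzyme}"] = p

    binding = gen_binding_table(config, seed=config.seed + 10)
    p = outdir / "binding_rates.csv"
    binding.to_csv(p)
    paths["binding_rates"] = p

    for probe in ("VmC", "VH148GmC"):
        frames = []
        for j, cond in enumerate(sorted(config.calibration.laser_scales)):
            s = gen_calibration_series(config, probe, cond, seed=config.seed + 20 + j)
            frames.append(
                pd.DataFrame({"pH": s.ph, "ratio": s.ratio, "laser_condition": s.laser_condition})
            )
        p = outdir / f"ratio_calibration_{probe}.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        paths[f"ratio_calibration_{probe}"] = p

    rois = gen_roi_table(config, seed=config.seed + 30)
    p = outdir / "roi_intensities.csv"
    pd.DataFrame(
        [dict(ch1=r.ch1, ch2=r.ch2, bg1=r.bg1, bg2=r.bg2, zone=r.zone) for r in rois]
    ).to_csv(p, index=False)
    paths["roi_intensities"] = p
    return paths
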