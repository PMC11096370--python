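"""Ratiometric fluorescence pH calibration and inference.

A pH-sensitive fluorophore (Venus, or the more alkaline-shifted Venus H148G
variant) is fused to the pH-insensitive mCherry; the Venus/mCherry intensity
ratio depends on pH but not on probe concentration or illumination.  SG1
cells equilibrated to buffers of known pH (4.1–8.0, with protonophores)
give a calibration series; the ratio normalized to its value at pH 8.0
("relative ratio") is fitted to a sigmoid whose midpoint is the probe pKa
(~5.8 for Venus-mCherry, ~7.0 for VenusH148G-mCherry).  In vivo pH is then
inferred by inverting the fitted curve at each region of interest (ROI)
after per-channel background subtraction.

Because the normalization pins the curve to 1 at pH 8.0, calibration series
acquired under different laser powers collapse onto the same relative curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.special import expit

from .rate_curves import FitError

__all__ = [
    "REFERENCE_PH",
    "CalibrationSeries",
    "CalibrationCurve",
    "ROIMeasurement",
    "PHEstimate",
    "fit_calibration",
    "infer_pH",
    "summarize_zones",
]

#: All ratios are normalized to their value at this buffer pH.
REFERENCE_PH = 8.0


@dataclass(frozen=True)
class CalibrationSeries:
    """Background-subtracted fluorescence ratios at known buffer pH values."""

    ph: np.ndarray
    ratio: np.ndarray
    laser_condition: str = "default"

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        ratio = np.asarray(self.ratio, dtype=float)
        if ph.shape != ratio.shape or ph.ndim != 1:
            raise ValueError("ph and ratio must be 1-D arrays of equal length")
        if np.unique(ph).size < 5:
            raise ValueError("need at least 5 pH values spanning the sigmoid transition")
        if np.any(ratio <= 0):
            raise ValueError("ratios must be positive")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "ratio", ratio)

    @property
    def reference_ratio(self) -> float:
        """Measured ratio at the reference pH 8.0 (required in the series)."""
        at_ref = np.isclose(self.ph, REFERENCE_PH, atol=1e-9)
        if not at_ref.any():
            raise ValueError("calibration series has no point at the reference pH 8.0")
        return float(np.mean(self.ratio[at_ref]))

    def normalized(self) -> "CalibrationSeries":
        return CalibrationSeries(
            ph=self.ph, ratio=self.ratio / self.reference_ratio,
            laser_condition=self.laser_condition,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"pH": self.ph, "ratio": self.ratio, "laser_condition": self.laser_condition}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "list[CalibrationSeries]":
        df = pd.read_csv(path)
        return [
            cls(ph=g["pH"].to_numpy(), ratio=g["ratio"].to_numpy(), laser_condition=str(name))
            for name, g in df.groupby("laser_condition")
        ]


def _sigmoid(ph, pka, slope, floor, ceiling):
    return floor + (ceiling - floor) * expit(slope * (ph - pka))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted relative-ratio-vs-pH sigmoid.

    The curve is a four-parameter logistic divided by its own value at
    pH 8.0, so the relative ratio at the reference pH is exactly 1.  Its
    midpoint is the probe pKa; it is strictly increasing between the
    (normalized) floor and ceiling, which bound the invertible range.
    """

    pKa: float
    slope: float
    floor: float
    ceiling: float
    reference_ph: float = REFERENCE_PH
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.ceiling <= self.floor:
            raise ValueError("calibration curve must be strictly increasing in pH")

    @property
    def _ref_value(self) -> float:
        return _sigmoid(self.reference_ph, self.pKa, self.slope, self.floor, self.ceiling)

    def __call__(self, ph):
        out = _sigmoid(np.asarray(ph, dtype=float), self.pKa, self.slope,
                       self.floor, self.ceiling) / self._ref_value
        return float(out) if np.isscalar(ph) else out

    @property
    def rel_floor(self) -> float:
        """Lower asymptote of the relative-ratio curve."""
        return self.floor / self._ref_value

    @property
    def rel_ceiling(self) -> float:
        """Upper asymptote of the relative-ratio curve."""
        return self.ceiling / self._ref_value

    def to_dict(self) -> dict:
        return {
            "pKa": self.pKa, "slope": self.slope, "floor": self.floor,
            "ceiling": self.ceiling, "reference_ph": self.reference_ph, "rss": self.rss,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(**d)


def fit_calibration(series: "CalibrationSeries | Sequence[CalibrationSeries]") -> CalibrationCurve:
    """Jointly fit the relative-ratio sigmoid over one or more laser conditions.

    Each series is first normalized by its own ratio at pH 8.0; the
    normalized points from all conditions are then fitted together with a
    single four-parameter logistic (itself normalized at pH 8.0).  If the
    conditions truly share one underlying curve — the laser-power-invariance
    property — the joint residual is as small as any single-condition fit.

    Raises ``FitError`` on non-convergence; warns when no data fall near the
    transition (the pKa is then poorly constrained).
    """
    if isinstance(series, CalibrationSeries):
        series = [series]
    normed = [s.normalized() for s in series]
    ph = np.concatenate([s.ph for s in normed])
    rel = np.concatenate([s.ratio for s in normed])

    def model(ph, pka, slope, floor, ceiling):
        return _sigmoid(ph, pka, slope, floor, ceiling) / _sigmoid(
            REFERENCE_PH, pka, slope, floor, ceiling
        )

    half = (rel.min() + rel.max()) / 2.0
    p0 = [float(ph[np.argmin(np.abs(rel - half))]), 2.0, float(max(rel.min(), 1e-3)), float(rel.max())]
    try:
        popt, _ = curve_fit(
            model, ph, rel, p0=p0,
            bounds=([3.0, 0.05, 0.0, 0.1], [9.0, 50.0, 1.0, 5.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"calibration fit did not converge: {exc}") from exc
    pka, slope, floor, ceiling = (float(p) for p in popt)
    if not np.any(np.abs(ph - pka) < 1.0 / slope * 2.0):
        import warnings

        warnings.warn(
            "no calibration points near the fitted transition; pKa is poorly constrained",
            UserWarning,
            stacklevel=2,
        )
    resid = rel - model(ph, *popt)
    return CalibrationCurve(pKa=pka, slope=slope, floor=floor, ceiling=ceiling,
                            rss=float(np.sum(resid**2)))


@dataclass(frozen=True)
class ROIMeasurement:
    """Mean two-channel intensities of one region of interest plus backgrounds."""

    ch1: float  # pH-sensitive channel (Venus-like)
    ch2: float  # pH-insensitive channel (mCherry-like)
    bg1: float = 0.0
    bg2: float = 0.0
    zone: str | None = None

    @property
    def ratio(self) -> float:
        """Background-subtracted channel ratio."""
        num, den = self.ch1 - self.bg1, self.ch2 - self.bg2
        if num <= 0 or den <= 0:
            raise ValueError("background-subtracted intensities must be positive")
        return num / den


@dataclass(frozen=True)
class PHEstimate:
    """Inferred pH of one ROI; ``censored`` flags out-of-range ratios."""

    ph: float
    censored: str | None = None  # None, "below range" or "above range"
    zone: str | None = None

    @property
    def usable(self) -> bool:
        return self.censored is None


def infer_pH(
    curve: CalibrationCurve,
    roi: ROIMeasurement,
    reference_ratio: float,
    *,
    tol: float = 1e-6,
) -> PHEstimate:
    """Invert the fitted calibration curve at one ROI's relative ratio.

    The relative ratio is the background-subtracted channel ratio divided by
    ``reference_ratio`` (the ratio at pH 8.0 under the same acquisition).
    Ratios at or beyond the curve's asymptotes cannot be inverted and return
    a censored estimate rather than a fabricated extreme pH.
    """
    if reference_ratio <= 0:
        raise ValueError("reference ratio must be positive")
    rel = roi.ratio / reference_ratio
    # margin: the curve is numerically flat within ~tol of its asymptotes
    if rel <= curve.rel_floor + tol:
        return PHEstimate(ph=math.nan, censored="below range", zone=roi.zone)
    if rel >= curve.rel_ceiling - tol:
        return PHEstimate(ph=math.nan, censored="above range", zone=roi.zone)

    # bracket generously around the transition; expit saturates ~40/slope away
    lo = curve.pKa - 60.0 / curve.slope
    hi = curve.pKa + 60.0 / curve.slope
    ph = brentq(lambda p: curve(p) - rel, lo, hi, xtol=tol)
    return PHEstimate(ph=float(ph), zone=roi.zone)


def summarize_zones(estimates: Iterable[PHEstimate]) -> pd.DataFrame:
    """Per-zone n, mean and SEM of usable estimates; censored counted separately.

    A zone with a single usable estimate reports SEM 0 by convention.
    """
    rows = [
        dict(zone=e.zone if e.zone is not None else "unlabeled", ph=e.ph, usable=e.usable)
        for e in estimates
    ]
    if not rows:
        raise ValueError("no estimates to summarize")
    df = pd.DataFrame(rows)
    out = []
    for zone, g in df.groupby("zone", sort=True):
        usable = g[g["usable"]]["ph"]
        n = int(usable.size)
        out.append(
            dict(
                zone=zone,
                n=n,
                mean_ph=float(usable.mean()) if n else math.nan,
                sem_ph=float(usable.std(ddof=1) / math.sqrt(n)) if n > 1 else (0.0 if n == 1 else math.nan),
                n_censored=int((~g["usable"]).sum()),
            )
        )
    return pd.DataFrame(out)
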