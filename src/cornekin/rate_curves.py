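"""pH-dependent rate functions of the desquamation model.

Four functions of pH enter the kinetic model:

* ``a_KLK(pH)`` — catalytic activity of kallikrein-related peptidases (KLK5
  as the representative subtype) relative to the activity at the optimal
  pH 7.8, fitted to fluorogenic-substrate assay points;
* ``a_meso(pH)`` — relative catalytic activity of mesotrypsin (PRSS3),
  fitted to casein-degradation assay points, same normalization;
* ``k_a(pH)`` / ``k_d(pH)`` — association / dissociation rate constants of
  the KLK–LEKTI complex, tabulated at a handful of pH values (surface
  plasmon resonance measurements) and interpolated.

Relative activities are dimensionless fractions in [0, 1]; they are fitted
as a logistic in pH normalized by its own value at pH 7.8, so that the fit
is exactly 1 at the assay optimum.  Binding rate constants are interpolated
monotonically on the log scale, exact at the measured knots, and held flat
beyond the measured pH range — no functional form is imposed on data that
never claimed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "OPTIMAL_PH",
    "ActivityPoints",
    "ActivityCurve",
    "BindingRatePoints",
    "BindingRateCurves",
    "FitError",
    "fit_activity_curve",
    "fit_binding_rates",
    "relative_activity",
]

#: pH of maximal catalytic activity for both murine KLK5 and mesotrypsin;
#: all relative activities are expressed against this point.
OPTIMAL_PH = 7.8


class FitError(RuntimeError):
    """Raised when a calibration fit cannot be performed or fails to converge."""


# ---------------------------------------------------------------------------
# point tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityPoints:
    """Relative enzyme activity measured at a set of assay pH values."""

    ph: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        if ph.shape != act.shape or ph.ndim != 1:
            raise ValueError("ph and activity must be 1-D arrays of equal length")
        if np.unique(ph).size < 4:
            raise ValueError("need at least 4 distinct pH values")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "activity", act)

    def to_csv(self, path) -> None:
        pd.DataFrame({"pH": self.ph, "value": self.activity}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivityPoints":
        df = pd.read_csv(path)
        return cls(ph=df["pH"].to_numpy(), activity=df["value"].to_numpy())


@dataclass(frozen=True)
class BindingRatePoints:
    """KLK–LEKTI association/dissociation rate constants vs pH.

    ``ka`` in /M/s, ``kd`` in /s; both strictly positive.
    """

    ph: np.ndarray
    ka: np.ndarray
    kd: np.ndarray

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        ka = np.asarray(self.ka, dtype=float)
        kd = np.asarray(self.kd, dtype=float)
        if not (ph.shape == ka.shape == kd.shape) or ph.ndim != 1:
            raise ValueError("ph, ka, kd must be 1-D arrays of equal length")
        if ph.size < 3:
            raise ValueError("need at least 3 pH values")
        if np.unique(ph).size != ph.size:
            raise ValueError("duplicate pH values in binding-rate table")
        if np.any(ka <= 0) or np.any(kd <= 0):
            raise ValueError("rate constants must be strictly positive")
        order = np.argsort(ph)
        object.__setattr__(self, "ph", ph[order])
        object.__setattr__(self, "ka", ka[order])
        object.__setattr__(self, "kd", kd[order])

    def to_csv(self, path) -> None:
        pd.DataFrame({"pH": self.ph, "ka": self.ka, "kd": self.kd}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BindingRatePoints":
        df = pd.read_csv(path)
        return cls(ph=df["pH"].to_numpy(), ka=df["ka"].to_numpy(), kd=df["kd"].to_numpy())


# ---------------------------------------------------------------------------
# fitted curves
# ---------------------------------------------------------------------------


def _logistic(ph, midpoint, slope, floor, ceiling):
    return floor + (ceiling - floor) * expit(slope * (ph - midpoint))


@dataclass(frozen=True)
class ActivityCurve:
    """Relative catalytic activity as a function of pH.

    The curve is a logistic in pH divided by its own value at
    ``reference_ph`` (the assay optimum, pH 7.8), so the relative activity
    at the optimum is exactly 1.  Evaluation clamps the result to [0, 1]:
    the model only ever needs a fraction of maximal activity, and the assay
    grid extends slightly past the optimum where the raw ratio could exceed
    1 marginally.

    A ``form`` of ``"flat"`` denotes the degenerate fit to constant data and
    evaluates to ``value`` everywhere.
    """

    midpoint: float = 6.5
    slope: float = 4.0
    floor: float = 0.0
    ceiling: float = 1.0
    reference_ph: float = OPTIMAL_PH
    form: str = "normalized_logistic"
    value: float = 1.0  # used by the flat form only
    rss: float = 0.0

    def __call__(self, ph):
        ph_arr = np.asarray(ph, dtype=float)
        if self.form == "flat":
            out = np.full_like(ph_arr, np.clip(self.value, 0.0, 1.0))
        else:
            ref = _logistic(self.reference_ph, self.midpoint, self.slope, self.floor, self.ceiling)
            out = np.clip(
                _logistic(ph_arr, self.midpoint, self.slope, self.floor, self.ceiling) / ref,
                0.0,
                1.0,
            )
        return float(out) if np.isscalar(ph) or ph_arr.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "midpoint": self.midpoint,
            "slope": self.slope,
            "floor": self.floor,
            "ceiling": self.ceiling,
            "reference_ph": self.reference_ph,
            "value": self.value,
            "rss": self.rss,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActivityCurve":
        return cls(**d)


def fit_activity_curve(points: ActivityPoints, *, four_parameter: bool = False) -> ActivityCurve:
    """Least-squares fit of the relative-activity sigmoid.

    By default the midpoint and slope are free while the logistic floor and
    ceiling stay at 0 and 1 (the normalization at pH 7.8 anchors the curve
    regardless).  With ``four_parameter=True`` the floor and ceiling are
    also fitted.

    Raises
    ------
    FitError
        If there are fewer points than free parameters, or the optimizer
        fails to converge.
    """
    ph, act = points.ph, points.activity
    n_free = 4 if four_parameter else 2
    if np.unique(ph).size < n_free:
        raise FitError(f"{np.unique(ph).size} distinct pH values cannot constrain {n_free} parameters")

    if np.ptp(act) < 1e-12:
        # Degenerate constant data: a flat curve is the exact least-squares fit.
        return ActivityCurve(form="flat", value=float(np.mean(act)), rss=0.0)

    def model2(ph, midpoint, slope):
        ref = _logistic(OPTIMAL_PH, midpoint, slope, 0.0, 1.0)
        return _logistic(ph, midpoint, slope, 0.0, 1.0) / ref

    def model4(ph, midpoint, slope, floor, ceiling):
        ref = _logistic(OPTIMAL_PH, midpoint, slope, floor, ceiling)
        return _logistic(ph, midpoint, slope, floor, ceiling) / ref

    # Midpoint guess: pH where activity crosses half its range.
    half = (act.min() + act.max()) / 2.0
    p0_mid = float(ph[np.argmin(np.abs(act - half))])
    try:
        if four_parameter:
            popt, _ = curve_fit(
                model4,
                ph,
                act,
                p0=[p0_mid, 2.0, float(max(act.min(), 0.0)), 1.0],
                bounds=([3.0, 0.01, 0.0, 0.1], [9.0, 50.0, 0.9, 2.0]),
                maxfev=20000,
            )
            mid, slope, floor, ceiling = popt
            resid = act - model4(ph, *popt)
        else:
            popt, _ = curve_fit(
                model2,
                ph,
                act,
                p0=[p0_mid, 2.0],
                bounds=([3.0, 0.01], [9.0, 50.0]),
                maxfev=20000,
            )
            mid, slope = popt
            floor, ceiling = 0.0, 1.0
            resid = act - model2(ph, *popt)
    except RuntimeError as exc:  # pragma: no cover - depends on optimizer
        raise FitError(f"activity-curve fit did not converge: {exc}") from exc

    return ActivityCurve(
        midpoint=float(mid),
        slope=float(slope),
        floor=float(floor),
        ceiling=float(ceiling),
        rss=float(np.sum(resid**2)),
    )


@dataclass(frozen=True)
class BindingRateCurves:
    """Monotone interpolants of log k_a and log k_d vs pH.

    Exact at the measured knots (PCHIP on the log scale preserves
    monotonicity between knots); flat beyond the measured pH range, so the
    rates stay bounded and positive everywhere.
    """

    points: BindingRatePoints
    _log_ka: PchipInterpolator = field(repr=False, default=None)
    _log_kd: PchipInterpolator = field(repr=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_log_ka", PchipInterpolator(self.points.ph, np.log(self.points.ka))
        )
        object.__setattr__(
            self, "_log_kd", PchipInterpolator(self.points.ph, np.log(self.points.kd))
        )

    def _clamp(self, ph):
        return np.clip(np.asarray(ph, dtype=float), self.points.ph[0], self.points.ph[-1])

    def ka(self, ph):
        out = np.exp(self._log_ka(self._clamp(ph)))
        return float(out) if np.isscalar(ph) else out

    def kd(self, ph):
        out = np.exp(self._log_kd(self._clamp(ph)))
        return float(out) if np.isscalar(ph) else out

    def to_dict(self) -> dict:
        return {
            "ph": self.points.ph.tolist(),
            "ka": self.points.ka.tolist(),
            "kd": self.points.kd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BindingRateCurves":
        return cls(points=BindingRatePoints(ph=d["ph"], ka=d["ka"], kd=d["kd"]))


def fit_binding_rates(points: BindingRatePoints) -> BindingRateCurves:
    """Build the monotone log-rate interpolants from a measured table."""
    return BindingRateCurves(points=points)


# ---------------------------------------------------------------------------
# assay normalization
# ---------------------------------------------------------------------------


def relative_activity(A: float, B: float, C: float) -> float:
    """Percent relative enzyme activity, (A - B) / (C - B) x 100.

    ``A`` is the fluorescence at the queried pH, ``B`` the no-enzyme
    background and ``C`` the maximum fluorescence in the assay (reached at
    the optimal pH).  The result is not clamped: noisy readings may fall
    below 0 or above 100.
    """
    if not C > B:
        raise ValueError("assay has no dynamic range: maximum fluorescence C must exceed background B")
    return (A - B) / (C - B) * 100.0
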