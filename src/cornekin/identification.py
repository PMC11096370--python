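"""Parameter identification for the desquamation model.

The degradation and activation rate constants are not measurable directly,
so they are pinned down by scenario calibration and feasibility screening:

* ``k_deg`` — total LEKTI (free + complexed) obeys a linear decay equation
  decoupled from KLK activation, so ``k_deg`` is calibrated by requiring the
  surviving LEKTI fraction at the surface to hit one of three scenario
  targets: 100 % (no degradation), 50 % (continuous decrease) or 0.01 %
  (complete depletion).
* ``(k_auto, k_meso)`` — screened over a log-spaced grid (1e2 to 1e6 /M/s on
  both axes).  A pair is accepted when total activated KLK rises comparably
  (within +-50 %) in the upper and lower halves of the SC and reaches more
  than 50 % of the secreted pro-KLK at the surface.
* profile comparison — representative accepted pairs (edges and center of
  the accepted region) are simulated across candidate pH profiles to compare
  effective-KLK-activity shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .klk_model import IntegrationError, ModelParams, RateFunctions, simulate, surface_rise
from .ph_profiles import PHProfile

__all__ = [
    "SCENARIO_TARGETS",
    "ScenarioSpec",
    "GridSpec",
    "ScreenResult",
    "CalibrationError",
    "surviving_fraction",
    "calibrate_kdeg",
    "screen_activation_rates",
    "compare_profiles",
]

#: Target surviving LEKTI fractions C_Ltotal(1)/C_Ltotal(0) per scenario.
SCENARIO_TARGETS = {
    "no_degradation": 1.0,
    "continuous_decrease": 0.5,
    "complete_depletion": 1e-4,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the three LEKTI-survival scenarios."""

    name: str
    target_surviving_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.target_surviving_fraction <= 1.0:
            raise ValueError("target surviving fraction must lie in (0, 1]")

    @classmethod
    def named(cls, name: str) -> "ScenarioSpec":
        if name not in SCENARIO_TARGETS:
            raise ValueError(f"unknown scenario {name!r}; valid: {sorted(SCENARIO_TARGETS)}")
        return cls(name=name, target_surviving_fraction=SCENARIO_TARGETS[name])


class CalibrationError(RuntimeError):
    """Scenario target unreachable within the k_deg search bracket."""


def surviving_fraction(
    k_deg: float,
    params: ModelParams,
    profile: PHProfile,
    curves: RateFunctions,
    *,
    rtol: float = 1e-10,
) -> float:
    """C_Ltotal(1)/C_Ltotal(0) for a given k_deg.

    Total LEKTI decays as dL/dx = -k_deg * a_meso(pH(x)) * C_meso * L / v,
    independent of KLK activation, so a scalar integration suffices.
    """
    if k_deg == 0.0:
        return 1.0

    def dlog_l(x, y):
        return [-k_deg * curves.a_meso(profile(x)) * params.C_meso / params.v]

    # Integrate d(log L)/dx: linear decay can span many decades (the
    # depletion scenario targets 1e-4) without underflow issues.
    sol = solve_ivp(dlog_l, (0.0, 1.0), [0.0], method="LSODA", rtol=rtol, atol=1e-12)
    if not sol.success:
        raise IntegrationError(f"LEKTI survival integration failed: {sol.message}",
                               float(sol.t[-1]), sol.y[:, -1])
    return float(np.exp(sol.y[0, -1]))


def calibrate_kdeg(
    scenario: ScenarioSpec,
    params: ModelParams,
    profile: PHProfile,
    curves: RateFunctions,
    *,
    bracket: tuple[float, float] = (1.0, 1e7),
    rel_tol: float = 1e-4,
) -> float:
    """Find the k_deg whose surviving LEKTI fraction equals the scenario target.

    The fraction is continuous and strictly decreasing in k_deg (the total-
    LEKTI equation is linear), so a bracketed root search on log10(k_deg) is
    exact up to tolerance.  The no-degradation scenario returns 0 directly.
    """
    target = scenario.target_surviving_fraction
    if target == 1.0:
        return 0.0

    lo, hi = bracket
    f_lo = surviving_fraction(lo, params, profile, curves)
    f_hi = surviving_fraction(hi, params, profile, curves)
    if not (f_hi <= target <= f_lo):
        raise CalibrationError(
            f"target {target} outside achievable surviving-fraction range "
            f"[{f_hi:.3e}, {f_lo:.3e}] for k_deg in [{lo:.3g}, {hi:.3g}]"
        )

    def objective(log_k):
        return np.log(surviving_fraction(10.0**log_k, params, profile, curves)) - np.log(target)

    log_k = brentq(objective, np.log10(lo), np.log10(hi), xtol=1e-10, rtol=1e-15)
    k_deg = float(10.0**log_k)
    achieved = surviving_fraction(k_deg, params, profile, curves)
    if abs(achieved - target) / target > rel_tol:
        raise CalibrationError(
            f"calibration converged to k_deg={k_deg:.6g} but surviving fraction "
            f"{achieved:.6g} misses target {target:.6g} beyond {rel_tol:g} relative"
        )
    return k_deg


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced (k_auto, k_meso) screening grid."""

    k_min: float = 1e2
    k_max: float = 1e6
    n_per_axis: int = 17

    def values(self) -> np.ndarray:
        return np.logspace(np.log10(self.k_min), np.log10(self.k_max), self.n_per_axis)


# screen acceptance band: upper/lower half increases comparable within +-50 %,
# surface total KLK above 50 % of the secreted pro-KLK
HALF_RATIO_BOUNDS = (0.5, 1.5)
SURFACE_FRACTION_MIN = 0.5


def _accept(half_ratio: float, surface_fraction: float) -> bool:
    return (
        HALF_RATIO_BOUNDS[0] < half_ratio < HALF_RATIO_BOUNDS[1]
        and surface_fraction > SURFACE_FRACTION_MIN
    )


@dataclass
class ScreenResult:
    """Outcome of the (k_auto, k_meso) grid screen.

    ``table`` has one row per grid pair with the two screen metrics:
    ``half_ratio`` = [C_Ktotal(1) - C_Ktotal(0.5)] / [C_Ktotal(0.5) - C_Ktotal(0)]
    and ``surface_fraction`` = C_Ktotal(1) / C_pKLK(0), plus the acceptance
    flag and a failure reason for pairs whose integration failed.
    """

    table: pd.DataFrame
    k_deg: float
    grid: GridSpec

    def accepted(self) -> pd.DataFrame:
        return self.table[self.table["accepted"]]

    def representative_pairs(self) -> list[tuple[float, float]]:
        """Edge and center picks from the accepted region.

        The four extreme accepted grid points along log k_auto and log
        k_meso, plus the accepted point nearest the accepted region's
        centroid in log-space.
        """
        acc = self.accepted()
        if acc.empty:
            return []
        la = np.log10(acc["k_auto"].to_numpy())
        lm = np.log10(acc["k_meso"].to_numpy())
        picks = {int(np.argmin(la)), int(np.argmax(la)), int(np.argmin(lm)), int(np.argmax(lm))}
        centroid = np.array([la.mean(), lm.mean()])
        picks.add(int(np.argmin((la - centroid[0]) ** 2 + (lm - centroid[1]) ** 2)))
        rows = acc.iloc[sorted(picks)]
        return list(dict.fromkeys(zip(rows["k_auto"], rows["k_meso"])))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def screen_activation_rates(
    params: ModelParams,
    profile: PHProfile,
    curves: RateFunctions,
    k_deg: float,
    grid: GridSpec | None = None,
    *,
    rtol: float = 1e-8,
) -> ScreenResult:
    """Simulate every (k_auto, k_meso) grid pair and flag accepted ones.

    Integration failures on extreme rate combinations are recorded per pair
    (rejected with a reason) rather than aborting the screen.  The result is
    deterministic for fixed curves and solver settings.
    """
    grid = grid or GridSpec()
    values = grid.values()
    x_grid = np.array([0.0, 0.5, 0.7, 1.0])
    rows = []
    for k_auto in values:
        for k_meso in values:
            p = params.replace(k_auto=float(k_auto), k_meso=float(k_meso), k_deg=float(k_deg))
            try:
                traj = simulate(p, profile, curves, x_grid, rtol=rtol)
            except IntegrationError as exc:
                rows.append(
                    dict(k_auto=k_auto, k_meso=k_meso, half_ratio=np.nan,
                         surface_fraction=np.nan, accepted=False, failure_reason=str(exc))
                )
                continue
            kt = traj.C_Ktotal
            lower = kt[1] - kt[0]
            upper = kt[3] - kt[1]
            half_ratio = upper / lower if lower > 0 else np.inf
            surface_fraction = kt[3] / p.C_pKLK_boundary
            rows.append(
                dict(
                    k_auto=k_auto,
                    k_meso=k_meso,
                    half_ratio=half_ratio,
                    surface_fraction=surface_fraction,
                    accepted=_accept(half_ratio, surface_fraction),
                    failure_reason="",
                )
            )
    return ScreenResult(table=pd.DataFrame(rows), k_deg=float(k_deg), grid=grid)


def compare_profiles(
    accepted_params: Sequence[tuple[float, float]],
    profiles: Iterable[PHProfile],
    curves: RateFunctions,
    k_deg: float,
    base_params: ModelParams | None = None,
    *,
    x_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate each accepted (k_auto, k_meso) pair on each candidate profile.

    Returns one row per (profile, pair) with the surface rise of effective
    KLK activity and E_KLK at x in {0, 0.5, 0.7, 1.0} (normalized by the
    pro-KLK boundary concentration), sorted by profile label.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    if not accepted_params:
        raise ValueError("need at least one accepted (k_auto, k_meso) pair")
    base = base_params or ModelParams()
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 201)
    rows = []
    for profile in profiles:
        for k_auto, k_meso in accepted_params:
            p = base.replace(k_auto=float(k_auto), k_meso=float(k_meso), k_deg=float(k_deg))
            traj = simulate(p, profile, curves, x_grid)
            e_rel = traj.E_KLK_relative
            rows.append(
                dict(
                    profile=profile.label,
                    k_auto=k_auto,
                    k_meso=k_meso,
                    k_deg=k_deg,
                    surface_rise=surface_rise(traj) / p.C_pKLK_boundary,
                    E_at_0=float(np.interp(0.0, traj.x, e_rel)),
                    E_at_0_5=float(np.interp(0.5, traj.x, e_rel)),
                    E_at_0_7=float(np.interp(0.7, traj.x, e_rel)),
                    E_at_1=float(np.interp(1.0, traj.x, e_rel)),
                )
            )
    return pd.DataFrame(rows).sort_values(
        ["profile", "k_auto", "k_meso"], kind="stable"
    ).reset_index(drop=True)
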