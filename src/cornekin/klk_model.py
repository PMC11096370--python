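"""Spatial kinetic model of KLK activation and inhibition in the SC.

Pro-kallikreins (pro-KLK) and the inhibitor LEKTI are secreted at the SG/SC
boundary (x = 0) and carried toward the skin surface (x = 1) by corneocyte
transit at a depth-independent rate ``v``.  Along the way, four pH-dependent
processes act on them:

1. activation of pro-KLK to active KLK, by KLK itself (autoactivation, rate
   constant ``k_auto``) and by mesotrypsin (``k_meso``);
2. reversible inhibition of KLK by LEKTI, forming the KLK–LEKTI complex
   (association ``k_a(pH)``, dissociation ``k_d(pH)``);
3. mesotrypsin-mediated degradation of LEKTI, both free and in the complex
   (``k_deg``), which releases active KLK from the complex;
4. corneodesmosome proteolysis by free KLK, summarized by the effective
   catalytic activity ``E_KLK(x) = a_KLK(pH(x)) * C_KLK(x)``.

Because the transit time to depth x is t = x / v, the time-domain mass
balances become a boundary-value-free initial value problem in x: every
reaction term is divided by v and integrated from x = 0 to 1 with initial
state (C_pKLK, 0, C_LEKTI, 0).  The state is the four concentrations
(pro-KLK, KLK, LEKTI, KLK–LEKTI complex), all in molar units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ph_profiles import PHProfile
from .rate_curves import ActivityCurve, BindingRateCurves

__all__ = [
    "SECONDS_PER_DAY",
    "ModelParams",
    "RateFunctions",
    "Trajectory",
    "IntegrationError",
    "rhs",
    "simulate",
    "effective_activity",
    "surface_rise",
    "transit_rate_from_days",
]

SECONDS_PER_DAY = 86400.0


def transit_rate_from_days(days: float) -> float:
    """Depth-independent transit rate v (per second) from a transit time in days.

    The murine SC transit time is about 5 days, giving v ~= 2.3e-6 /s.
    """
    if not days > 0:
        raise ValueError("transit time must be positive")
    return 1.0 / (days * SECONDS_PER_DAY)


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the model.

    Units: ``k_auto``, ``k_meso``, ``k_deg`` in /M/s; ``v`` in /s;
    concentrations in M.  Boundary concentrations of pro-KLK and LEKTI
    default to 1e-10 M (the order measured in epidermis); mesotrypsin is
    fixed at the same order since it only appears as k_meso*C_meso or
    k_deg*C_meso.
    """

    k_auto: float = 0.0
    k_meso: float = 0.0
    k_deg: float = 0.0
    v: float = field(default_factory=lambda: transit_rate_from_days(5.0))
    C_meso: float = 1.0e-10
    C_pKLK_boundary: float = 1.0e-10
    C_LEKTI_boundary: float = 1.0e-10

    def __post_init__(self) -> None:
        for name in ("k_auto", "k_meso", "k_deg", "C_meso", "C_pKLK_boundary", "C_LEKTI_boundary"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.v > 0:
            raise ValueError("transit rate v must be positive")

    def replace(self, **kwargs) -> "ModelParams":
        d = {k: getattr(self, k) for k in (
            "k_auto", "k_meso", "k_deg", "v", "C_meso", "C_pKLK_boundary", "C_LEKTI_boundary")}
        d.update(kwargs)
        return ModelParams(**d)

    def to_dict(self) -> dict:
        return {
            "k_auto": self.k_auto,
            "k_meso": self.k_meso,
            "k_deg": self.k_deg,
            "v": self.v,
            "C_meso": self.C_meso,
            "C_pKLK_boundary": self.C_pKLK_boundary,
            "C_LEKTI_boundary": self.C_LEKTI_boundary,
        }


@dataclass(frozen=True)
class RateFunctions:
    """Bundle of the four fitted pH-dependent model functions."""

    a_klk: ActivityCurve
    a_meso: ActivityCurve
    binding: BindingRateCurves


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last successful depth and state."""

    def __init__(self, message: str, x_last: float, state_last: np.ndarray):
        super().__init__(message)
        self.x_last = x_last
        self.state_last = state_last


# state layout
_PKLK, _KLK, _LEKTI, _KL = 0, 1, 2, 3


def rhs(
    x: float,
    state: np.ndarray,
    params: ModelParams,
    profile: PHProfile,
    curves: RateFunctions,
) -> np.ndarray:
    """Right-hand side d(state)/dx of the four-species system.

    All reaction terms carry the factor 1/v from the substitution t = x/v.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError(f"non-finite state at x={x}: {state}")
    ph = profile(x)
    a_klk = curves.a_klk(ph)
    a_meso = curves.a_meso(ph)
    ka = curves.binding.ka(ph)
    kd = curves.binding.kd(ph)

    c_pklk, c_klk, c_lekti, c_kl = state
    activation = c_pklk * (params.k_auto * a_klk * c_klk + params.k_meso * a_meso * params.C_meso)
    binding = ka * c_klk * c_lekti - kd * c_kl
    deg_free = params.k_deg * a_meso * params.C_meso * c_lekti
    deg_complex = params.k_deg * a_meso * params.C_meso * c_kl

    inv_v = 1.0 / params.v
    return np.array(
        [
            -activation * inv_v,
            (activation - binding + deg_complex) * inv_v,
            (-binding - deg_free) * inv_v,
            (binding - deg_complex) * inv_v,
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """Solved concentration profiles over depth and derived quantities.

    ``E_KLK`` is in molar units (activity-weighted free-KLK concentration);
    ``E_KLK_relative`` is the same normalized by the pro-KLK boundary
    concentration for cross-profile comparison.
    """

    x: np.ndarray
    C_pKLK: np.ndarray
    C_KLK: np.ndarray
    C_LEKTI: np.ndarray
    C_KL: np.ndarray
    params: ModelParams
    profile: PHProfile
    curves: RateFunctions = field(repr=False, default=None)

    @property
    def C_Ktotal(self) -> np.ndarray:
        """Total activated KLK (free plus complexed)."""
        return self.C_KLK + self.C_KL

    @property
    def C_Ltotal(self) -> np.ndarray:
        """Total LEKTI (free plus complexed)."""
        return self.C_LEKTI + self.C_KL

    @property
    def E_KLK(self) -> np.ndarray:
        return effective_activity(self)

    @property
    def E_KLK_relative(self) -> np.ndarray:
        return self.E_KLK / self.params.C_pKLK_boundary

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "C_pKLK": self.C_pKLK,
                "C_KLK": self.C_KLK,
                "C_LEKTI": self.C_LEKTI,
                "C_KL": self.C_KL,
                "C_Ktotal": self.C_Ktotal,
                "C_Ltotal": self.C_Ltotal,
                "E_KLK": self.E_KLK,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def manifest(self, solver_settings: dict | None = None) -> dict:
        return {
            "params": self.params.to_dict(),
            "profile": self.profile.to_dict(),
            "curves": {
                "a_klk": self.curves.a_klk.to_dict(),
                "a_meso": self.curves.a_meso.to_dict(),
                "binding": self.curves.binding.to_dict(),
            },
            "solver": solver_settings or {},
        }

    def write_manifest(self, path, solver_settings: dict | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(solver_settings), fh, indent=2)


def simulate(
    params: ModelParams,
    profile: PHProfile,
    curves: RateFunctions,
    x_grid: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-16,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from x = 0 to x = 1 and return the trajectory.

    Initial conditions: pro-KLK and LEKTI at their boundary concentrations,
    no free KLK, no complex.  Tight tolerances are required because the
    concentrations are ~1e-10 M while association terms can be orders of
    magnitude faster than transit, making the system stiff; LSODA switches
    to a stiff method automatically.

    Tiny negative undershoots within 10x the absolute tolerance are clipped
    to zero in the returned trajectory (reporting only); larger undershoots
    raise a warning.
    """
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 201)
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid[0] != 0.0 or x_grid[-1] != 1.0 or np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must increase strictly from 0 to 1")

    y0 = np.array([params.C_pKLK_boundary, 0.0, params.C_LEKTI_boundary, 0.0])

    # Integrate segment-by-segment between profile breakpoints so the solver
    # never steps across a pH discontinuity (stepwise) or kink
    # (piecewise_linear).  Within a stepwise segment the pH is frozen to the
    # segment value, which is the exact piecewise problem; the boundary pH at
    # the measure-zero point x = 0 does not influence the solution.
    edges = np.asarray(profile.breakpoints)
    y_chunks = [y0[:, None]]  # state at x = 0
    state = y0
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        if profile.kind == "stepwise":
            seg_profile = PHProfile(
                kind="uniform", breakpoints=(0.0, 1.0), values=(profile.values[i],)
            )
        else:
            seg_profile = profile
        inner = x_grid[(x_grid > lo) & (x_grid < hi)]
        t_eval = np.concatenate([inner, [hi]])
        sol = solve_ivp(
            rhs,
            (lo, hi),
            state,
            args=(params, seg_profile, curves),
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            x_last = float(sol.t[-1]) if sol.t.size else lo
            state_last = sol.y[:, -1] if sol.y.size else state
            raise IntegrationError(
                f"integration failed at x={x_last:.6g}: {sol.message}", x_last, state_last
            )
        state = sol.y[:, -1]
        keep = sol.y if hi in x_grid else sol.y[:, :-1]
        y_chunks.append(keep)
    y = np.concatenate(y_chunks, axis=1)
    assert y.shape[1] == x_grid.size
    undershoot = y.min()
    if undershoot < -10.0 * max(atol, rtol * params.C_pKLK_boundary):
        warnings.warn(
            f"solution undershoots zero by {undershoot:.3e} M (beyond solver tolerance)",
            RuntimeWarning,
            stacklevel=2,
        )
    y = np.where((y < 0) & (y > -10.0 * max(atol, rtol * params.C_pKLK_boundary)), 0.0, y)

    return Trajectory(
        x=x_grid,
        C_pKLK=y[_PKLK],
        C_KLK=y[_KLK],
        C_LEKTI=y[_LEKTI],
        C_KL=y[_KL],
        params=params,
        profile=profile,
        curves=curves,
    )


def effective_activity(traj: Trajectory) -> np.ndarray:
    """E_KLK(x) = a_KLK(pH(x)) * C_KLK(x), the desquamation proxy (molar)."""
    return traj.curves.a_klk(traj.profile(traj.x)) * traj.C_KLK


def surface_rise(traj: Trajectory) -> float:
    """Increase of effective KLK activity from x = 0.7 to the surface x = 1.

    Linear interpolation is used if 0.7 is not a grid point.
    """
    e = traj.E_KLK
    e_07 = float(np.interp(0.7, traj.x, e))
    e_10 = float(np.interp(1.0, traj.x, e))
    return e_10 - e_07
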