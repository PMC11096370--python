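"""pH profiles across the stratum corneum.

The model treats the stratum corneum (SC) as a one-dimensional column with
normalized depth ``x`` running from the stratum granulosum / stratum corneum
(SG/SC) boundary at ``x = 0`` to the skin surface at ``x = 1``.  The ambient
pH seen by the secreted proteases is a fixed function ``pH(x)`` of depth.
This module provides the profile container, the five named profiles used in
the simulation study, and (de)serialization to plain JSON/YAML blocks.

Murine SC shows a three-tiered pH zonation: a moderately acidic lower zone
(pH ~6.0), an acidic middle zone (pH ~5.4, the "acid mantle") and a
near-neutral upper zone (pH ~6.7), with the SG1 layer at the secretion
boundary near pH 7.0.  The stepwise profile encodes exactly that; the
gradient and uniform profiles are the hypothetical alternatives it is
compared against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PHProfile",
    "NAMED_PROFILES",
    "make_named_profile",
    "evaluate_pH",
]

_KINDS = ("stepwise", "piecewise_linear", "uniform")

#: Identifiers accepted by :func:`make_named_profile`.
NAMED_PROFILES = (
    "stepwise_7.0_6.0_5.4_6.7",
    "gradient_7.0_5.4",
    "gradient_7.0_5.4_6.7",
    "uniform_5.4",
    "uniform_7.0",
)


@dataclass(frozen=True)
class PHProfile:
    """A pH(x) profile over normalized SC depth x in [0, 1].

    Parameters
    ----------
    kind:
        ``"stepwise"`` (piecewise constant, right-continuous at interior
        breakpoints), ``"piecewise_linear"`` or ``"uniform"``.
    breakpoints:
        Strictly increasing depths, first 0 and last 1.  For stepwise
        profiles with n segments there are n+1 breakpoints; for
        piecewise-linear profiles one breakpoint per value; uniform profiles
        use (0, 1).
    values:
        Segment pH values (stepwise), node pH values (piecewise_linear) or a
        single pH (uniform).  All must lie in [0, 14].
    label:
        Free-text description.
    boundary_value:
        Optional pH applied at exactly ``x = 0``.  Used by the stepwise SC
        profile, where the SG/SC boundary (pH 7.0) is the secretion plane
        only and every ``x > 0`` already lies inside the lowest SC zone.
    """

    kind: str
    breakpoints: tuple[float, ...]
    values: tuple[float, ...]
    label: str = ""
    boundary_value: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.kind not in _KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}; expected one of {_KINDS}")
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size < 2 or bp[0] != 0.0 or bp[-1] != 1.0 or np.any(np.diff(bp) <= 0):
            raise ValueError(
                "breakpoints must be strictly increasing, starting at 0 and ending at 1"
            )
        vals = np.asarray(self.values, dtype=float)
        check = list(vals) + ([self.boundary_value] if self.boundary_value is not None else [])
        if np.any(np.asarray(check) < 0.0) or np.any(np.asarray(check) > 14.0):
            raise ValueError("all pH values must lie in [0, 14]")
        n_expected = {
            "stepwise": bp.size - 1,
            "piecewise_linear": bp.size,
            "uniform": 1,
        }[self.kind]
        if vals.size != n_expected:
            raise ValueError(
                f"{self.kind} profile with {bp.size} breakpoints needs "
                f"{n_expected} values, got {vals.size}"
            )
        if self.kind != "stepwise" and self.boundary_value is not None:
            raise ValueError("boundary_value is only meaningful for stepwise profiles")

    # -- evaluation ------------------------------------------------------

    def __call__(self, x):
        return evaluate_pH(self, x)

    @property
    def ph_min(self) -> float:
        extra = () if self.boundary_value is None else (self.boundary_value,)
        return min(self.values + extra)

    @property
    def ph_max(self) -> float:
        extra = () if self.boundary_value is None else (self.boundary_value,)
        return max(self.values + extra)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "breakpoints": list(self.breakpoints),
            "values": list(self.values),
            "label": self.label,
        }
        if self.boundary_value is not None:
            d["boundary_value"] = self.boundary_value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PHProfile":
        return cls(
            kind=d["kind"],
            breakpoints=tuple(d["breakpoints"]),
            values=tuple(d["values"]),
            label=d.get("label", ""),
            boundary_value=d.get("boundary_value"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "PHProfile":
        return cls.from_dict(json.loads(s))


def evaluate_pH(profile: PHProfile, x):
    """Evaluate ``pH(x)`` at scalar or array depths ``x`` in [0, 1].

    Stepwise profiles are right-continuous at interior breakpoints (the last
    segment is closed at x = 1); piecewise-linear profiles interpolate
    between nodes and hit node values exactly.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0.0) or np.any(x_arr > 1.0) or not np.all(np.isfinite(x_arr)):
        raise ValueError("depth x must lie in [0, 1]")
    bp = np.asarray(profile.breakpoints)
    vals = np.asarray(profile.values)
    if profile.kind == "uniform":
        out = np.full_like(x_arr, vals[0])
    elif profile.kind == "piecewise_linear":
        out = np.interp(x_arr, bp, vals)
    else:  # stepwise
        idx = np.clip(np.searchsorted(bp, x_arr, side="right") - 1, 0, vals.size - 1)
        out = vals[idx]
        if profile.boundary_value is not None:
            out = np.where(x_arr == 0.0, profile.boundary_value, out)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def make_named_profile(
    name: str,
    *,
    zone_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
    gradient_min_x: float = 2.0 / 3.0,
) -> PHProfile:
    """Construct one of the five named SC pH profiles.

    ``stepwise_7.0_6.0_5.4_6.7``
        SG/SC boundary pH 7.0 at x = 0 only, then three SC zones at pH 6.0
        (lower), 5.4 (middle) and 6.7 (upper).  Zone boundaries default to
        thirds of the SC depth and are configurable because the in vivo
        zone widths are not quantified.
    ``gradient_7.0_5.4``
        Linear ramp from pH 7.0 at x = 0 to pH 5.4 at x = 1 (the classical
        monotone neutral-to-acidic picture).
    ``gradient_7.0_5.4_6.7``
        Piecewise-linear 7.0 -> 5.4 -> 6.7 with the minimum at
        ``gradient_min_x``.
    ``uniform_5.4`` / ``uniform_7.0``
        Constant profiles.
    """
    b0, b1 = zone_boundaries
    if not (0.0 < b0 < b1 < 1.0):
        raise ValueError("zone_boundaries must satisfy 0 < b0 < b1 < 1")
    if name == "stepwise_7.0_6.0_5.4_6.7":
        return PHProfile(
            kind="stepwise",
            breakpoints=(0.0, b0, b1, 1.0),
            values=(6.0, 5.4, 6.7),
            boundary_value=7.0,
            label="pH7.0_6.0_5.4_6.7 stepwise",
        )
    if name == "gradient_7.0_5.4":
        return PHProfile(
            kind="piecewise_linear",
            breakpoints=(0.0, 1.0),
            values=(7.0, 5.4),
            label="pH7.0_5.4 gradient",
        )
    if name == "gradient_7.0_5.4_6.7":
        if not (0.0 < gradient_min_x < 1.0):
            raise ValueError("gradient_min_x must lie strictly inside (0, 1)")
        return PHProfile(
            kind="piecewise_linear",
            breakpoints=(0.0, gradient_min_x, 1.0),
            values=(7.0, 5.4, 6.7),
            label="pH7.0_5.4_6.7 gradient",
        )
    if name == "uniform_5.4":
        return PHProfile(kind="uniform", breakpoints=(0.0, 1.0), values=(5.4,), label="uniform pH 5.4")
    if name == "uniform_7.0":
        return PHProfile(kind="uniform", breakpoints=(0.0, 1.0), values=(7.0,), label="uniform pH 7.0")
    raise ValueError(f"unknown profile name {name!r}; valid names: {', '.join(NAMED_PROFILES)}")
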