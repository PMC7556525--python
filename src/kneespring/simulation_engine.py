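"""Quasi-static force-controlled gait trials for a surrogate knee.

A trial reproduces what the physical rig does: per time point of the gait
profile the applied AP force (and, depending on the control mode, the TR
torque) is balanced against the knee's passive restraint and any virtual
spring, and the displacement that zeroes the net load is recorded.  Two
control modes exist:

* ``AP_FORCE_ONLY`` — the AP axis is force-driven; the TR axis is either
  displacement-controlled (a recorded TR angle series is imposed) or left
  free (zero applied torque) when no series is supplied, as when recording
  an intact knee's unconstrained rotation;
* ``AP_TR_FORCE`` — both axes are force-driven.

The balance is memoryless: at 1 Hz gait the passive elastic restraint
dominates and no inertial or viscoelastic history is modelled.  Roots are
found by bisection on the dislocation-bounded interval; a point with no
root inside the limit marks the cycle unstable (dislocation risk).
Measurement-like Gaussian noise is added to the kinematic outputs per
cycle, so averaging across the usual ten cycles is meaningful.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import InstabilityError, UnstableTrialError, ValidationError
from .gait_profiles import GaitProfile
from .spring_model import SpringCondition
from .synthetic_knee import KneeRestraint

_SCHEMA_VERSION = 1


class Mode(str, Enum):
    AP_FORCE_ONLY = "AP_FORCE_ONLY"
    AP_TR_FORCE = "AP_TR_FORCE"


@dataclass(frozen=True)
class TrialConfig:
    """Control mode, cycle count and numerical settings for one trial."""

    mode: Mode
    n_cycles: int = 10
    frequency_hz: float = 1.0
    seed: int = 0
    tolerance: float = 1e-4

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be at least 1")
        if self.tolerance <= 0:
            raise ValidationError("solver tolerance must be positive")


@dataclass(frozen=True)
class KinematicTrace:
    """Per-cycle AP displacement and TR angle over one trial.

    Arrays are ``(n_cycles, n_points)``; cycles that hit a dislocation are
    flagged in ``stable`` (and contain NaN at the unstable points) rather
    than silently dropped.
    """

    ap_mm: np.ndarray
    tr_deg: np.ndarray
    stable: np.ndarray
    provenance: Mapping

    @property
    def n_cycles(self) -> int:
        return self.ap_mm.shape[0]

    @property
    def n_points(self) -> int:
        return self.ap_mm.shape[1]

    @property
    def n_stable(self) -> int:
        return int(np.sum(self.stable))

    def to_csv(self, path) -> None:
        n_c, n_p = self.ap_mm.shape
        t = np.tile(np.arange(n_p) / n_p, n_c)
        df = pd.DataFrame(
            {
                "cycle": np.repeat(np.arange(n_c), n_p),
                "time_s": t,
                "ap_mm": self.ap_mm.ravel(),
                "tr_deg": self.tr_deg.ravel(),
                "stable": np.repeat(self.stable.astype(int), n_p),
            }
        )
        df.to_csv(path, index=False)
        sidecar = str(path) + ".provenance.json"
        with open(sidecar, "w") as fh:
            json.dump({"schema_version": _SCHEMA_VERSION, **dict(self.provenance)}, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "KinematicTrace":
        df = pd.read_csv(path)
        cycles = np.sort(df["cycle"].unique())
        n_p = int((df["cycle"] == cycles[0]).sum())
        ap = df["ap_mm"].to_numpy(float).reshape(len(cycles), n_p)
        tr = df["tr_deg"].to_numpy(float).reshape(len(cycles), n_p)
        stable = df.groupby("cycle")["stable"].first().to_numpy() > 0
        try:
            with open(str(path) + ".provenance.json") as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            prov = {}
        return cls(ap_mm=ap, tr_deg=tr, stable=stable, provenance=prov)


@dataclass(frozen=True)
class MeanTrace:
    """Per-point average of a trace over its stable cycles."""

    ap_mm: np.ndarray
    tr_deg: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.ap_mm)

    def to_csv(self, path) -> None:
        n = self.n_points
        pd.DataFrame(
            {"time_s": np.arange(n) / n, "ap_mm": self.ap_mm, "tr_deg": self.tr_deg}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeanTrace":
        df = pd.read_csv(path)
        return cls(ap_mm=df["ap_mm"].to_numpy(float), tr_deg=df["tr_deg"].to_numpy(float))


# ---------------------------------------------------------------------------
# Root finding
# ---------------------------------------------------------------------------


def _bisect_array(
    applied: np.ndarray,
    restoring: Callable[[np.ndarray], np.ndarray],
    limit: float,
    tol: float,
) -> np.ndarray:
    """Vectorised bisection of ``applied + restoring(d) = 0`` on [-limit, limit].

    ``restoring`` must be monotone non-increasing in ``d`` (a restoring
    load).  Points with no bracketed root return NaN (dislocation).
    """
    applied = np.asarray(applied, dtype=float)
    lo = np.full_like(applied, -limit)
    hi = np.full_like(applied, limit)
    f_lo = applied + restoring(lo)
    f_hi = applied + restoring(hi)
    unstable = (f_hi > 0) | (f_lo < 0)
    n_iter = int(np.ceil(np.log2(2.0 * limit / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid = applied + restoring(mid)
        go_right = f_mid > 0
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    d = 0.5 * (lo + hi)
    return np.where(unstable, np.nan, d)


def solve_timepoint(
    applied_load: float,
    restraint: Callable[[float], float],
    spring: Callable[[float], float] | None,
    limit: float,
    tol: float = 1e-4,
) -> float:
    """Displacement balancing one applied load against restraint plus spring.

    Returns ``d`` with ``|applied + restraint(d) + spring(d)| <= tol`` and
    ``|d| < limit``.  The root is located by scanning outward from the
    neutral position for the first sign change (so the smallest-magnitude
    root is returned if the total restraint is non-monotone, with a
    warning) and refined by bisection.

    Raises
    ------
    InstabilityError
        If no root exists inside the dislocation limit.
    """

    def total(d: np.ndarray) -> np.ndarray:
        out = np.asarray(restraint(d), dtype=float)
        if spring is not None:
            out = out + spring(d)
        return out

    f0 = applied_load + float(total(np.asarray(0.0)))
    if abs(f0) <= tol:
        return 0.0
    # Scan outward on the side the net load pushes toward.
    sign = 1.0 if f0 > 0 else -1.0
    grid = sign * np.linspace(0.0, limit, 1024)
    f = applied_load + total(grid)
    changes = np.nonzero(np.diff(np.sign(f)) != 0)[0]
    if changes.size == 0:
        raise InstabilityError(
            f"no balance within the dislocation limit ({limit:g}) for load {applied_load:g}"
        )
    if changes.size > 1:
        warnings.warn(
            "multiple balance points found (non-monotone total restraint); "
            "returning the one closest to neutral",
            stacklevel=2,
        )
    lo, hi = grid[changes[0]], grid[changes[0] + 1]
    f_lo = applied_load + float(total(np.asarray(lo)))
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        f_mid = applied_load + float(total(np.asarray(mid)))
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


def run_trial(
    knee: KneeRestraint,
    profile: GaitProfile,
    config: TrialConfig,
    ap_spring: SpringCondition | None = None,
    tr_spring: SpringCondition | None = None,
    tr_displacement_input: np.ndarray | None = None,
) -> KinematicTrace:
    """Simulate one force-controlled trial and return the per-cycle trace.

    In ``AP_FORCE_ONLY`` mode the TR axis follows ``tr_displacement_input``
    if given (displacement control) and is otherwise free (zero torque);
    supplying the series in ``AP_TR_FORCE`` mode is a usage error.  The
    deterministic quasi-static solution is identical across cycles;
    measurement noise (specimen noise SDs, seeded by the trial config) is
    what distinguishes them.  A dislocation at any point flags every
    affected cycle unstable; the trace is returned flagged, never raised.
    """
    spec = knee.specimen
    n = profile.n_points
    if config.mode is Mode.AP_TR_FORCE and tr_displacement_input is not None:
        raise ValidationError("AP_TR_FORCE mode drives TR by torque; remove tr_displacement_input")
    if tr_displacement_input is not None and len(tr_displacement_input) != n:
        raise ValidationError("tr_displacement_input length must match the profile grid")

    def ap_total(d):
        out = knee.ap_load(d)
        if ap_spring is not None:
            out = out + ap_spring.load(d)
        return out

    ap_bal = _bisect_array(profile.ap_force_N, ap_total, spec.dislocation_limit_ap_mm, config.tolerance)

    tr_imposed = False
    if config.mode is Mode.AP_TR_FORCE:

        def tr_total(a):
            out = knee.tr_load(a)
            if tr_spring is not None:
                out = out + tr_spring.load(a)
            return out

        tr_bal = _bisect_array(
            profile.tr_torque_Nm, tr_total, spec.dislocation_limit_tr_deg, config.tolerance
        )
    elif tr_displacement_input is not None:
        tr_bal = np.asarray(tr_displacement_input, dtype=float)
        tr_imposed = True
    else:  # TR free: zero applied torque balances at the coupled neutral
        tr_bal = np.zeros(n)
    if not tr_imposed:
        tr_bal = tr_bal + knee.tr_coupling_offset(profile.fe_angle_deg)

    unstable_any = bool(np.isnan(ap_bal).any() or np.isnan(tr_bal).any())
    rng = np.random.default_rng(config.seed)
    noise_ap = rng.normal(0.0, spec.cycle_noise_sd_ap_mm, size=(config.n_cycles, n))
    noise_tr = rng.normal(0.0, spec.cycle_noise_sd_tr_deg, size=(config.n_cycles, n))
    ap = ap_bal[None, :] + noise_ap
    tr = tr_bal[None, :] + (0.0 if tr_imposed else noise_tr)
    if tr_imposed:
        tr = np.broadcast_to(tr_bal, (config.n_cycles, n)).copy()

    stable = np.full(config.n_cycles, not unstable_any)
    provenance = {
        "mode": config.mode.value,
        "donor_id": spec.donor_id,
        "intact": knee.intact,
        "n_cycles": config.n_cycles,
        "seed": config.seed,
        "ap_spring": None if ap_spring is None else ap_spring.to_dict(),
        "tr_spring": None if tr_spring is None else tr_spring.to_dict(),
        "tr_displacement_controlled": tr_imposed,
    }
    return KinematicTrace(ap_mm=ap, tr_deg=tr, stable=stable, provenance=provenance)


def average_cycles(trace: KinematicTrace) -> MeanTrace:
    """Per-point arithmetic mean over the stable cycles of a trace."""
    mask = np.asarray(trace.stable, dtype=bool)
    if not mask.any():
        raise UnstableTrialError("every cycle of the trial was unstable; nothing to average")
    return MeanTrace(
        ap_mm=trace.ap_mm[mask].mean(axis=0),
        tr_deg=trace.tr_deg[mask].mean(axis=0),
    )
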