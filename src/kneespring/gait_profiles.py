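"""Gait-cycle input waveforms for force-controlled knee simulation.

A knee simulator trial is driven by four demand channels over one walking
cycle: the flexion/extension (FE) angle, the compressive axial force, the
anterior-posterior (AP) shear force and the tibial-rotation (TR) torque.
The waveforms used here follow the force-control wear-testing convention of
ISO 14243-1, with one deliberate departure: the axial force carries *two*
stance peaks rather than the standard's three, reflecting the two-peak
axial loading that instrumented-implant measurements report for level
walking.

The cycle is the half-open interval [0, 1) s at 1 Hz, sampled on a uniform
grid (128 points by default); all waveforms are periodic.  Sign
conventions, used consistently throughout the package:

* AP force and displacement: anterior positive;
* TR torque and angle: internal positive;
* FE angle: flexion positive, full extension = 0.

The exact numeric waveform tables of the standard are licensed and are not
reproduced; the packaged default knot table is a documented piecewise-linear
approximation with the right shape features (two interior axial-force
maxima, an early posterior AP excursion followed by anterior peaks in
mid-stance and swing, external-then-internal TR torque).  Every channel is
fully overridable through :class:`WaveformSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

#: Channel names, in canonical column order.
CHANNELS = ("fe_angle_deg", "axial_force_N", "ap_force_N", "tr_torque_Nm")

#: Default knot tables (time fraction, value).  Piecewise-linear approximation
#: of an ISO-14243-1-style force-control gait input with a two-peak axial
#: force; values are representative, not a transcription of the standard.
DEFAULT_KNOTS: dict[str, tuple[tuple[float, float], ...]] = {
    # Stance flexion peak ~18 deg near 0.2 s, swing flexion peak ~55 deg.
    "fe_angle_deg": (
        (0.00, 0.0),
        (0.12, 11.0),
        (0.20, 18.0),
        (0.30, 12.0),
        (0.45, 4.0),
        (0.55, 6.0),
        (0.75, 55.0),
        (0.92, 3.0),
        (1.00, 0.0),
    ),
    # Two-peak axial force: early- and late-stance maxima, unloaded swing.
    "axial_force_N": (
        (0.00, 300.0),
        (0.13, 2600.0),
        (0.31, 1500.0),
        (0.47, 2400.0),
        (0.62, 300.0),
        (0.80, 180.0),
        (1.00, 300.0),
    ),
    # Posterior excursion at heel strike, anterior peaks in mid-stance and swing.
    "ap_force_N": (
        (0.00, 0.0),
        (0.03, -30.0),
        (0.06, -130.0),
        (0.11, -10.0),
        (0.15, 170.0),
        (0.25, 30.0),
        (0.35, -60.0),
        (0.50, 10.0),
        (0.60, 60.0),
        (0.67, 140.0),
        (0.75, 40.0),
        (0.85, -20.0),
        (1.00, 0.0),
    ),
    # External torque early in stance, internal torque peaking at mid-cycle.
    "tr_torque_Nm": (
        (0.00, 0.0),
        (0.10, -1.2),
        (0.20, 0.0),
        (0.35, 0.8),
        (0.50, 3.5),
        (0.70, -0.3),
        (0.90, 0.0),
        (1.00, 0.0),
    ),
}

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class WaveformSpec:
    """Piecewise-linear knot tables defining the four gait input channels.

    Parameters
    ----------
    channels
        Mapping from channel name to a sequence of ``(time_fraction, value)``
        knots.  Knot times must be strictly increasing within ``[0, 1]`` and
        the first and last knot values must agree (periodicity).
    smooth_halfwidth_s
        Optional half-width of a periodic moving-average filter applied after
        sampling, in seconds.  ``None`` (default) disables smoothing.
    """

    channels: Mapping[str, Sequence[tuple[float, float]]]
    smooth_halfwidth_s: float | None = None

    def validate(self) -> None:
        for name in CHANNELS:
            if name not in self.channels:
                raise ConfigurationError(f"waveform channel {name!r} is missing")
        for name, knots in self.channels.items():
            times = np.asarray([t for t, _ in knots], dtype=float)
            if len(times) < 2:
                raise ValidationError(f"channel {name!r} needs at least two knots")
            if times[0] < 0.0 or times[-1] > 1.0:
                raise ValidationError(f"channel {name!r} knot times must lie in [0, 1]")
            if np.any(np.diff(times) <= 0):
                raise ValidationError(f"channel {name!r} knot times must strictly increase")
            if not np.isclose(knots[0][1], knots[-1][1]):
                raise ValidationError(
                    f"channel {name!r} is not periodic: first/last knot values differ"
                )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "smooth_halfwidth_s": self.smooth_halfwidth_s,
            "channels": {
                name: [[float(t), float(v)] for t, v in knots]
                for name, knots in self.channels.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "WaveformSpec":
        channels = {
            name: tuple((float(t), float(v)) for t, v in knots)
            for name, knots in data["channels"].items()
        }
        return cls(channels=channels, smooth_halfwidth_s=data.get("smooth_halfwidth_s"))

    @classmethod
    def from_yaml(cls, path) -> "WaveformSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_waveform_spec() -> WaveformSpec:
    """The packaged ISO-style two-peak-axial-force waveform approximation."""
    return WaveformSpec(channels=DEFAULT_KNOTS)


@dataclass(frozen=True)
class GaitProfile:
    """One gait cycle of the four input waveforms on a uniform time grid."""

    time_s: np.ndarray
    fe_angle_deg: np.ndarray
    axial_force_N: np.ndarray
    ap_force_N: np.ndarray
    tr_torque_Nm: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.time_s)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def validate(self) -> None:
        n = self.n_points
        for name in CHANNELS:
            if len(self.channel(name)) != n:
                raise ValidationError(f"channel {name!r} length differs from time grid")
        if np.any(self.axial_force_N < 0):
            raise ValidationError("axial force must be non-negative")
        if np.any(self.fe_angle_deg < 0):
            raise ValidationError("flexion angle must be non-negative")
        n_max = count_circular_local_maxima(self.axial_force_N)
        if n_max != 2:
            raise ValidationError(
                f"axial force must have exactly two local maxima per cycle, found {n_max}"
            )

    # -- CSV round trip ------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, **{name: self.channel(name) for name in CHANNELS}}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GaitProfile":
        df = pd.read_csv(path)
        missing = [c for c in ("time_s", *CHANNELS) if c not in df.columns]
        if missing:
            raise ConfigurationError(f"gait CSV is missing columns: {missing}")
        return cls(
            time_s=df["time_s"].to_numpy(float),
            **{name: df[name].to_numpy(float) for name in CHANNELS},
        )


def count_circular_local_maxima(values: np.ndarray) -> int:
    """Count local maxima of a periodic sampled waveform.

    Plateaus (runs of equal samples) count as a single extremum.  A constant
    signal has no maxima.
    """
    y = np.asarray(values, dtype=float)
    # Compress consecutive duplicates (circularly) so plateaus become points.
    keep = np.r_[True, np.diff(y) != 0]
    z = y[keep]
    if len(z) > 1 and z[0] == z[-1]:
        z = z[:-1]
    if len(z) < 3:
        return 0
    prev = np.roll(z, 1)
    nxt = np.roll(z, -1)
    return int(np.sum((z > prev) & (z > nxt)))


def build_gait_profile(spec: WaveformSpec, n_points: int = 128) -> GaitProfile:
    """Sample a :class:`WaveformSpec` onto a uniform periodic time grid.

    Sampling is periodic linear interpolation of the knot tables, followed by
    an optional periodic moving-average smoothing.  The returned profile
    satisfies all :class:`GaitProfile` invariants (validated before return).
    """
    if n_points < 16:
        raise ValidationError("n_points must be at least 16")
    spec.validate()
    t = np.arange(n_points) / n_points
    sampled: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        knots = spec.channels[name]
        kt = np.asarray([k[0] for k in knots], dtype=float)
        kv = np.asarray([k[1] for k in knots], dtype=float)
        if np.isclose(kt[-1], 1.0):  # final knot duplicates t=0 under periodicity
            kt, kv = kt[:-1], kv[:-1]
        y = np.interp(t, kt, kv, period=1.0)
        if spec.smooth_halfwidth_s:
            y = _smooth_periodic(y, spec.smooth_halfwidth_s, n_points)
        sampled[name] = y
    profile = GaitProfile(time_s=t, **sampled)
    profile.validate()
    return profile


def _smooth_periodic(y: np.ndarray, halfwidth_s: float, n_points: int) -> np.ndarray:
    w = int(round(halfwidth_s * n_points))
    if w <= 0:
        return y
    kernel = np.full(2 * w + 1, 1.0 / (2 * w + 1))
    padded = np.r_[y[-w:], y, y[:w]]
    return np.convolve(padded, kernel, mode="valid")


def window_indices(n_points: int, center_s: float, halfwidth_s: float) -> np.ndarray:
    """Grid indices whose time lies within ``center ± halfwidth``, circularly.

    The window wraps across the t=0/1 seam; a half-width of 0.5 s therefore
    covers the whole cycle and returns every index exactly once.
    """
    if not 0.0 <= center_s < 1.0:
        raise ValidationError("window center must lie in [0, 1)")
    if halfwidth_s <= 0.0:
        raise ValidationError("window halfwidth must be positive")
    t = np.arange(n_points) / n_points
    circ_dist = np.abs((t - center_s + 0.5) % 1.0 - 0.5)
    idx = np.nonzero(circ_dist <= halfwidth_s + 1e-9)[0]
    if idx.size == 0:
        raise ValidationError(
            f"window {center_s}±{halfwidth_s}s contains no grid point "
            f"(grid spacing {1.0 / n_points:.4f}s)"
        )
    return idx


def window_index_set(profile: GaitProfile, center_s: float, halfwidth_s: float) -> np.ndarray:
    """Indices of ``profile`` samples inside the periodic window."""
    return window_indices(profile.n_points, center_s, halfwidth_s)
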