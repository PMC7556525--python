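"""Dead-zone linear virtual springs and candidate constraint grids.

A virtual spring is the simulator-controller constraint that stands in for
resected soft tissue on one axis.  Each axis carries two independent halves
(anterior/posterior for AP translation, internal/external for tibial
rotation); a half is characterised by a spring *rate* and a *free gap*
(free length in mm, or free angle in degrees) within which it exerts no
load — the software analogue of ligament laxity.

Candidate grids are filtered for joint stability: free gaps of 4 mm / 4°
or more make the force tuning of a physical rig unreliable and put the
femoro-tibial joint at risk of dislocation, so such conditions are excluded
(strictly: a gap must be *less than* the limit to survive).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError


class Axis(str, Enum):
    """Constraint axis; determines units and polarity labels."""

    AP = "AP"  # translation: rate N/mm, gap mm; + anterior, - posterior
    TR = "TR"  # rotation: rate Nm/deg, gap deg; + internal, - external

    @property
    def rate_unit(self) -> str:
        return "N/mm" if self is Axis.AP else "Nm/deg"

    @property
    def gap_unit(self) -> str:
        return "mm" if self is Axis.AP else "deg"

    @property
    def positive_label(self) -> str:
        return "Anterior" if self is Axis.AP else "Internal"

    @property
    def negative_label(self) -> str:
        return "Posterior" if self is Axis.AP else "External"


@dataclass(frozen=True)
class SpringHalf:
    """One polarity of a dead-zone spring: stiffness beyond a free gap."""

    rate: float
    free_gap: float

    def __post_init__(self):
        if self.rate < 0:
            raise ValidationError("spring rate must be non-negative")
        if self.free_gap < 0:
            raise ValidationError("free gap must be non-negative")


@dataclass(frozen=True)
class SpringCondition:
    """A bidirectional dead-zone spring for one axis.

    ``positive_half`` restrains anterior translation (AP) or internal
    rotation (TR); ``negative_half`` the opposite polarity.
    """

    axis: Axis
    positive_half: SpringHalf
    negative_half: SpringHalf

    def load(self, displacement) -> np.ndarray:
        """Signed restoring load at a signed displacement (vectorised)."""
        d = np.asarray(displacement, dtype=float)
        pos = -self.positive_half.rate * np.maximum(0.0, d - self.positive_half.free_gap)
        neg = self.negative_half.rate * np.maximum(0.0, -d - self.negative_half.free_gap)
        return pos + neg

    def describe(self) -> str:
        ax = self.axis
        return (
            f"{ax.value}: {ax.negative_label} {self.negative_half.rate:g} {ax.rate_unit} / "
            f"{self.negative_half.free_gap:g} {ax.gap_unit}, "
            f"{ax.positive_label} {self.positive_half.rate:g} {ax.rate_unit} / "
            f"{self.positive_half.free_gap:g} {ax.gap_unit}"
        )

    def to_dict(self) -> dict:
        return {
            "axis": self.axis.value,
            self.axis.positive_label.lower(): {
                "rate": self.positive_half.rate,
                "free_gap": self.positive_half.free_gap,
            },
            self.axis.negative_label.lower(): {
                "rate": self.negative_half.rate,
                "free_gap": self.negative_half.free_gap,
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SpringCondition":
        axis = Axis(data["axis"])
        pos = data[axis.positive_label.lower()]
        neg = data[axis.negative_label.lower()]
        return cls(
            axis=axis,
            positive_half=SpringHalf(float(pos["rate"]), float(pos["free_gap"])),
            negative_half=SpringHalf(float(neg["rate"]), float(neg["free_gap"])),
        )


def spring_load(cond: SpringCondition, displacement) -> np.ndarray:
    """Signed restoring load of a spring condition; zero inside the dead zone.

    For displacement ``d > 0`` the positive half applies
    ``-rate * max(0, d - free_gap)``; for ``d < 0`` the negative half applies
    ``+rate * max(0, |d| - free_gap)``.  The load always opposes the
    displacement and is continuous in ``d``.
    """
    return cond.load(displacement)


#: Free gaps at or above this many mm / deg destabilise force tuning.
DEFAULT_STABILITY_LIMIT = 4.0


@dataclass(frozen=True)
class GridSpec:
    """Candidate grid for one axis: per-polarity rate and gap values."""

    axis: Axis
    positive_rates: Sequence[float]
    positive_gaps: Sequence[float]
    negative_rates: Sequence[float]
    negative_gaps: Sequence[float]
    stability_limit: float = DEFAULT_STABILITY_LIMIT

    def __post_init__(self):
        for name in ("positive_rates", "positive_gaps", "negative_rates", "negative_gaps"):
            values = getattr(self, name)
            if len(values) == 0:
                raise ValidationError(f"grid {name} must be non-empty")
            if any(v < 0 for v in values):
                raise ValidationError(f"grid {name} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "axis": self.axis.value,
            "positive_rates": list(map(float, self.positive_rates)),
            "positive_gaps": list(map(float, self.positive_gaps)),
            "negative_rates": list(map(float, self.negative_rates)),
            "negative_gaps": list(map(float, self.negative_gaps)),
            "stability_limit": self.stability_limit,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GridSpec":
        return cls(
            axis=Axis(data["axis"]),
            positive_rates=tuple(data["positive_rates"]),
            positive_gaps=tuple(data["positive_gaps"]),
            negative_rates=tuple(data["negative_rates"]),
            negative_gaps=tuple(data["negative_gaps"]),
            stability_limit=float(data.get("stability_limit", DEFAULT_STABILITY_LIMIT)),
        )


def enumerate_candidates(grid: GridSpec) -> list[SpringCondition]:
    """All stability-admissible spring conditions of a grid.

    Cartesian product of per-polarity (rate, gap) values; any condition with
    a free gap at or beyond the stability limit on either half is removed.
    Ordering is deterministic: lexicographic by negative-half rate, then
    negative-half gap, then positive-half rate, then positive-half gap.
    """
    out: list[SpringCondition] = []
    for nr, ng, pr, pg in itertools.product(
        grid.negative_rates, grid.negative_gaps, grid.positive_rates, grid.positive_gaps
    ):
        if ng >= grid.stability_limit or pg >= grid.stability_limit:
            continue
        out.append(
            SpringCondition(
                axis=grid.axis,
                positive_half=SpringHalf(float(pr), float(pg)),
                negative_half=SpringHalf(float(nr), float(ng)),
            )
        )
    if not out:
        raise ValidationError(
            "stability filter removed every candidate "
            f"(all free gaps >= {grid.stability_limit} {grid.axis.gap_unit})"
        )
    return out


def default_ap_grid() -> GridSpec:
    """Packaged AP candidate grid: rates 20-70 N/mm step 5, gaps 0-3 mm step 1."""
    rates = tuple(np.arange(20.0, 75.0, 5.0))
    gaps = (0.0, 1.0, 2.0, 3.0)
    return GridSpec(Axis.AP, rates, gaps, rates, gaps)


def default_tr_grid() -> GridSpec:
    """Packaged TR candidate grid: rates 0.1-1.2 Nm/deg step 0.1, gaps 0-3 deg step 1."""
    rates = tuple(np.round(np.arange(0.1, 1.25, 0.1), 10))
    gaps = (0.0, 1.0, 2.0, 3.0)
    return GridSpec(Axis.TR, rates, gaps, rates, gaps)
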