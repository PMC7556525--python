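"""Staged selection of the most appropriate spring conditions per specimen.

The tuning procedure mirrors the workflow used on the physical rig.  The
intact knee is first recorded under the two control modes, giving four
reference outputs: AP displacement and TR angle under AP-force-only drive
(AP-1, TR-1) and under both-axes force drive (AP-2, TR-2).  The resected
knee is then constrained with virtual springs and tuned in three stages:

1. **AP selection** — AP force driven, TR displacement-controlled with the
   recorded TR-1 series; every admissible AP spring condition is run and
   the one whose AP output best matches AP-1 is kept.
2. **TR selection** — both axes force-driven with the stage-1 AP spring
   applied; TR candidates are ranked against TR-2.
3. **AP refinement** — both axes force-driven with the selected TR spring
   applied; the AP condition is re-selected against AP-2.

Determining the two unknown constraints sequentially rather than jointly
keeps each search one-axis and avoids the instability a simultaneous
search risks.  "Best match" is a windowed-peak criterion: within each
analysis window (three AP windows at 0.06, 0.13 and 0.67 s, two TR windows
at 0.10 and 0.50 s, each ±0.05 s — the windows where the extremes of
either polarity occur) the signed extremum of the dominant polarity is
compared between reference and candidate, and the deviation is the maximum
absolute peak difference across windows.  An RMS-across-windows metric is
available as an alternative.  The window holding each axis's global
extremum is specimen-specific and is recorded with the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import TuningFailureError, ValidationError
from .gait_profiles import GaitProfile, window_indices
from .simulation_engine import (
    KinematicTrace,
    MeanTrace,
    Mode,
    TrialConfig,
    average_cycles,
    run_trial,
)
from .spring_model import GridSpec, SpringCondition, enumerate_candidates
from .synthetic_knee import KneeRestraint

Polarity = Literal["positive", "negative", "auto"]


@dataclass(frozen=True)
class PeakWindow:
    """A periodic analysis window, ``center ± halfwidth`` seconds."""

    center_s: float
    halfwidth_s: float

    def __post_init__(self):
        if not 0.0 <= self.center_s < 1.0:
            raise ValidationError("window center must lie in [0, 1)")
        if self.halfwidth_s <= 0:
            raise ValidationError("window halfwidth must be positive")


@dataclass(frozen=True)
class PeakWindowSet:
    """The AP and TR analysis windows used for peak matching."""

    ap_windows: tuple[PeakWindow, ...]
    tr_windows: tuple[PeakWindow, ...]


def default_windows() -> PeakWindowSet:
    """Packaged analysis windows: AP {0.06, 0.13, 0.67}±0.05 s, TR {0.10, 0.50}±0.05 s."""
    return PeakWindowSet(
        ap_windows=(PeakWindow(0.06, 0.05), PeakWindow(0.13, 0.05), PeakWindow(0.67, 0.05)),
        tr_windows=(PeakWindow(0.10, 0.05), PeakWindow(0.50, 0.05)),
    )


@dataclass(frozen=True)
class ReferenceSet:
    """Intact-knee reference outputs: AP-1/TR-1 (AP force only), AP-2/TR-2 (both driven)."""

    ap1: np.ndarray
    tr1: np.ndarray
    ap2: np.ndarray
    tr2: np.ndarray

    def __post_init__(self):
        n = len(self.ap1)
        if any(len(x) != n for x in (self.tr1, self.ap2, self.tr2)):
            raise ValidationError("reference traces must share one length")


def extract_window_peak(series: np.ndarray, window: PeakWindow, polarity: Polarity) -> float:
    """Signed extremum of a series restricted to a periodic window.

    ``positive`` returns the window maximum, ``negative`` the minimum,
    ``auto`` the extremum of larger magnitude.
    """
    series = np.asarray(series, dtype=float)
    idx = window_indices(len(series), window.center_s, window.halfwidth_s)
    seg = series[idx]
    hi, lo = float(seg.max()), float(seg.min())
    if polarity == "positive":
        return hi
    if polarity == "negative":
        return lo
    return hi if abs(hi) >= abs(lo) else lo


@dataclass(frozen=True)
class WindowDeviation:
    """Per-window audit entry of a deviation computation."""

    window: PeakWindow
    polarity: str
    reference_peak: float
    candidate_peak: float
    abs_difference: float


def kinematic_deviation(
    reference: np.ndarray,
    candidate: np.ndarray,
    windows: Sequence[PeakWindow],
    polarities: Sequence[Polarity] | Polarity = "auto",
    metric: Literal["max", "rms"] = "max",
) -> tuple[float, list[WindowDeviation]]:
    """Windowed-peak deviation between a reference and a candidate trace.

    For each window the signed peak of the requested polarity is extracted
    from both series and the absolute difference taken; ``auto`` resolves
    the polarity from the reference (the direction of its larger-magnitude
    extremum in that window), which is then applied to the candidate too.
    The scalar deviation is the maximum (default) or RMS across windows; a
    per-window breakdown is always returned.
    """
    reference = np.asarray(reference, dtype=float)
    candidate = np.asarray(candidate, dtype=float)
    if reference.shape != candidate.shape:
        raise ValidationError("reference and candidate series must have equal length")
    if isinstance(polarities, str):
        polarities = [polarities] * len(windows)
    if len(polarities) != len(windows):
        raise ValidationError("one polarity per window is required")
    breakdown: list[WindowDeviation] = []
    for window, pol in zip(windows, polarities):
        if pol == "auto":
            ref_peak = extract_window_peak(reference, window, "auto")
            resolved: Polarity = "positive" if ref_peak >= 0 else "negative"
        else:
            resolved = pol
            ref_peak = extract_window_peak(reference, window, resolved)
        cand_peak = extract_window_peak(candidate, window, resolved)
        breakdown.append(
            WindowDeviation(window, resolved, ref_peak, cand_peak, abs(ref_peak - cand_peak))
        )
    diffs = np.array([b.abs_difference for b in breakdown])
    value = float(diffs.max()) if metric == "max" else float(np.sqrt(np.mean(diffs**2)))
    return value, breakdown


# ---------------------------------------------------------------------------
# Stage machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TuningConfig:
    """Cycle count, seeding and selection options shared by all stages."""

    n_cycles: int = 10
    seed: int = 0
    tolerance: float = 1e-4
    metric: Literal["max", "rms"] = "max"
    #: Stage-3 search radius in grid steps around the stage-1 condition;
    #: ``None`` searches the whole AP grid.
    stage3_neighborhood: int | None = None


@dataclass(frozen=True)
class CandidateRecord:
    condition: SpringCondition
    stable: bool
    deviation: float | None
    deviation_sum: float | None


@dataclass(frozen=True)
class StageLog:
    stage: str
    records: tuple[CandidateRecord, ...]

    @property
    def n_evaluated(self) -> int:
        return len(self.records)

    @property
    def n_unstable(self) -> int:
        return sum(1 for r in self.records if not r.stable)


@dataclass(frozen=True)
class TuningResult:
    """Outcome of the full three-stage tuning for one specimen."""

    donor_id: str
    ap_condition: SpringCondition  # final (stage-3) AP selection
    ap1_condition: SpringCondition  # initial (stage-1) AP selection
    tr_condition: SpringCondition
    ap_deviation_mm: float
    tr_deviation_deg: float
    ap_breakdown: tuple[WindowDeviation, ...]
    tr_breakdown: tuple[WindowDeviation, ...]
    selected_windows: dict
    references: ReferenceSet
    stage_logs: tuple[StageLog, ...]

    def to_dict(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "ap_condition": self.ap_condition.to_dict(),
            "ap1_condition": self.ap1_condition.to_dict(),
            "tr_condition": self.tr_condition.to_dict(),
            "ap_deviation_mm": self.ap_deviation_mm,
            "tr_deviation_deg": self.tr_deviation_deg,
            "ap_breakdown": [
                {
                    "center_s": b.window.center_s,
                    "halfwidth_s": b.window.halfwidth_s,
                    "polarity": b.polarity,
                    "reference_peak": b.reference_peak,
                    "candidate_peak": b.candidate_peak,
                    "abs_difference": b.abs_difference,
                }
                for b in self.ap_breakdown
            ],
            "tr_breakdown": [
                {
                    "center_s": b.window.center_s,
                    "halfwidth_s": b.window.halfwidth_s,
                    "polarity": b.polarity,
                    "reference_peak": b.reference_peak,
                    "candidate_peak": b.candidate_peak,
                    "abs_difference": b.abs_difference,
                }
                for b in self.tr_breakdown
            ],
            "selected_windows": self.selected_windows,
            "stages": [
                {"stage": log.stage, "n_evaluated": log.n_evaluated, "n_unstable": log.n_unstable}
                for log in self.stage_logs
            ],
        }


def _derive_seed(base_seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), *map(int, key)]).generate_state(1)[0] % (2**31))


def _condition_key(cond: SpringCondition) -> tuple:
    # Tie-break: stiffer total rate preferred, then smaller total gap.
    total_rate = cond.positive_half.rate + cond.negative_half.rate
    total_gap = cond.positive_half.free_gap + cond.negative_half.free_gap
    return (-total_rate, total_gap)

def _select(
    records: list[CandidateRecord], stage: str
) -> tuple[SpringCondition, float, StageLog]:
    stable = [r for r in records if r.stable]
    if not stable:
        raise TuningFailureError(f"{stage}: every spring candidate was unstable")
    best = min(
        stable,
        key=lambda r: (round(r.deviation, 9), round(r.deviation_sum, 9), *_condition_key(r.condition)),
    )
    return best.condition, best.deviation, StageLog(stage, tuple(records))


def _evaluate_candidates(
    resected: KneeRestraint,
    profile: GaitProfile,
    candidates: Sequence[SpringCondition],
    reference: np.ndarray,
    windows: Sequence[PeakWindow],
    config: TuningConfig,
    stage_index: int,
    *,
    mode: Mode,
    axis: Literal["ap", "tr"],
    fixed_ap: SpringCondition | None = None,
    fixed_tr: SpringCondition | None = None,
    tr_displacement_input: np.ndarray | None = None,
) -> list[CandidateRecord]:
    records: list[CandidateRecord] = []
    for idx, cond in enumerate(candidates):
        trial_cfg = TrialConfig(
            mode=mode,
            n_cycles=config.n_cycles,
            seed=_derive_seed(config.seed, stage_index, idx),
            tolerance=config.tolerance,
        )
        ap_spring = cond if axis == "ap" else fixed_ap
        tr_spring = cond if axis == "tr" else fixed_tr
        trace = run_trial(
            resected,
            profile,
            trial_cfg,
            ap_spring=ap_spring,
            tr_spring=tr_spring,
            tr_displacement_input=tr_displacement_input,
        )
        if trace.n_stable == 0:
            records.append(CandidateRecord(cond, False, None, None))
            continue
        mean = average_cycles(trace)
        series = mean.ap_mm if axis == "ap" else mean.tr_deg
        dev, breakdown = kinematic_deviation(reference, series, windows, metric=config.metric)
        records.append(
            CandidateRecord(cond, True, dev, float(sum(b.abs_difference for b in breakdown)))
        )
    return records


def stage1_select_ap(
    resected: KneeRestraint,
    reference: ReferenceSet,
    profile: GaitProfile,
    ap_grid: GridSpec,
    windows: PeakWindowSet,
    config: TuningConfig,
) -> tuple[SpringCondition, float, StageLog]:
    """Stage 1: AP spring selection under AP-force-only drive.

    The TR axis is displacement-controlled with the intact TR-1 series; the
    candidate minimising the windowed-peak deviation of the AP output from
    AP-1 wins.  Ties fall to the smaller all-window deviation sum, then to
    the stiffer rate and smaller gap (stability-favouring), then to grid
    order.  Unstable candidates are excluded.
    """
    candidates = enumerate_candidates(ap_grid)
    records = _evaluate_candidates(
        resected,
        profile,
        candidates,
        reference.ap1,
        windows.ap_windows,
        config,
        stage_index=1,
        mode=Mode.AP_FORCE_ONLY,
        axis="ap",
        tr_displacement_input=reference.tr1,
    )
    return _select(records, "stage1_ap")


def stage2_select_tr(
    resected: KneeRestraint,
    ap1_spring: SpringCondition,
    reference: ReferenceSet,
    profile: GaitProfile,
    tr_grid: GridSpec,
    windows: PeakWindowSet,
    config: TuningConfig,
) -> tuple[SpringCondition, float, StageLog]:
    """Stage 2: TR spring selection with both axes force-driven.

    The stage-1 AP spring is held fixed; candidates are ranked by the
    windowed-peak deviation of the TR output from TR-2.
    """
    candidates = enumerate_candidates(tr_grid)
    records = _evaluate_candidates(
        resected,
        profile,
        candidates,
        reference.tr2,
        windows.tr_windows,
        config,
        stage_index=2,
        mode=Mode.AP_TR_FORCE,
        axis="tr",
        fixed_ap=ap1_spring,
    )
    return _select(records, "stage2_tr")


def _neighborhood(
    grid: GridSpec, center: SpringCondition, radius: int
) -> list[SpringCondition]:
    """Grid candidates within ``radius`` index steps of ``center`` per dimension."""

    def near(values: Sequence[float], x: float) -> set[float]:
        ordered = sorted(set(float(v) for v in values))
        i = min(range(len(ordered)), key=lambda j: abs(ordered[j] - x))
        return set(ordered[max(0, i - radius) : i + radius + 1])

    pr = near(grid.positive_rates, center.positive_half.rate)
    pg = near(grid.positive_gaps, center.positive_half.free_gap)
    nr = near(grid.negative_rates, center.negative_half.rate)
    ng = near(grid.negative_gaps, center.negative_half.free_gap)
    return [
        c
        for c in enumerate_candidates(grid)
        if c.positive_half.rate in pr
        and c.positive_half.free_gap in pg
        and c.negative_half.rate in nr
        and c.negative_half.free_gap in ng
    ]


def stage3_refine_ap(
    resected: KneeRestraint,
    tr_spring: SpringCondition,
    ap1_spring: SpringCondition,
    reference: ReferenceSet,
    profile: GaitProfile,
    ap_grid: GridSpec,
    windows: PeakWindowSet,
    config: TuningConfig,
) -> tuple[SpringCondition, float, StageLog]:
    """Stage 3: AP refinement with the selected TR spring applied.

    Both axes are force-driven and the AP candidates are re-ranked against
    AP-2.  The search covers the whole grid by default, or a configurable
    neighbourhood of the stage-1 condition; the stage-1 condition itself is
    always in the candidate set, so the refined deviation can only improve.
    """
    if config.stage3_neighborhood is None:
        candidates = enumerate_candidates(ap_grid)
    else:
        candidates = _neighborhood(ap_grid, ap1_spring, config.stage3_neighborhood)
        if ap1_spring not in candidates:
            candidates = [ap1_spring, *candidates]
    records = _evaluate_candidates(
        resected,
        profile,
        candidates,
        reference.ap2,
        windows.ap_windows,
        config,
        stage_index=3,
        mode=Mode.AP_TR_FORCE,
        axis="ap",
        fixed_tr=tr_spring,
    )
    return _select(records, "stage3_ap")


def build_reference_set(
    intact: KneeRestraint, profile: GaitProfile, config: TuningConfig
) -> ReferenceSet:
    """Record the intact knee under both control modes and average the cycles."""
    cfg1 = TrialConfig(
        Mode.AP_FORCE_ONLY,
        n_cycles=config.n_cycles,
        seed=_derive_seed(config.seed, 0, 1),
        tolerance=config.tolerance,
    )
    mean1 = average_cycles(run_trial(intact, profile, cfg1))
    cfg2 = TrialConfig(
        Mode.AP_TR_FORCE,
        n_cycles=config.n_cycles,
        seed=_derive_seed(config.seed, 0, 2),
        tolerance=config.tolerance,
    )
    mean2 = average_cycles(run_trial(intact, profile, cfg2))
    return ReferenceSet(ap1=mean1.ap_mm, tr1=mean1.tr_deg, ap2=mean2.ap_mm, tr2=mean2.tr_deg)


def _global_extremum_window(
    series: np.ndarray, windows: Sequence[PeakWindow]
) -> dict:
    peaks = [extract_window_peak(series, w, "auto") for w in windows]
    i = int(np.argmax([abs(p) for p in peaks]))
    return {
        "center_s": windows[i].center_s,
        "halfwidth_s": windows[i].halfwidth_s,
        "polarity": "positive" if peaks[i] >= 0 else "negative",
        "peak": peaks[i],
    }


def run_full_tuning(
    intact: KneeRestraint,
    resected: KneeRestraint,
    profile: GaitProfile,
    ap_grid: GridSpec,
    tr_grid: GridSpec,
    windows: PeakWindowSet | None = None,
    config: TuningConfig | None = None,
) -> TuningResult:
    """Run the complete workflow for one specimen: references, then stages 1-3.

    Records the intact references (AP-1/TR-1, AP-2/TR-2), selects the AP
    spring under AP-force-only drive, the TR spring with both axes driven,
    and refines the AP spring under the final condition.  The returned
    result carries the final conditions, their per-window deviation audit,
    the specimen-specific windows of the global extrema and per-stage logs.
    """
    windows = windows or default_windows()
    config = config or TuningConfig()
    try:
        reference = build_reference_set(intact, profile, config)
    except Exception as exc:  # noqa: BLE001 - annotate stage context
        raise TuningFailureError(f"intact reference recording failed: {exc}") from exc

    ap1_cond, _, log1 = stage1_select_ap(resected, reference, profile, ap_grid, windows, config)
    tr_cond, tr_dev, log2 = stage2_select_tr(
        resected, ap1_cond, reference, profile, tr_grid, windows, config
    )
    ap_cond, ap_dev, log3 = stage3_refine_ap(
        resected, tr_cond, ap1_cond, reference, profile, ap_grid, windows, config
    )

    # Final audit run under the selected pair (deterministic re-evaluation).
    final_cfg = TrialConfig(
        Mode.AP_TR_FORCE,
        n_cycles=config.n_cycles,
        seed=_derive_seed(config.seed, 4, 0),
        tolerance=config.tolerance,
    )
    final_mean = average_cycles(
        run_trial(resected, profile, final_cfg, ap_spring=ap_cond, tr_spring=tr_cond)
    )
    ap_dev_final, ap_breakdown = kinematic_deviation(
        reference.ap2, final_mean.ap_mm, windows.ap_windows, metric=config.metric
    )
    tr_dev_final, tr_breakdown = kinematic_deviation(
        reference.tr2, final_mean.tr_deg, windows.tr_windows, metric=config.metric
    )

    return TuningResult(
        donor_id=resected.specimen.donor_id,
        ap_condition=ap_cond,
        ap1_condition=ap1_cond,
        tr_condition=tr_cond,
        ap_deviation_mm=ap_dev_final,
        tr_deviation_deg=tr_dev_final,
        ap_breakdown=tuple(ap_breakdown),
        tr_breakdown=tuple(tr_breakdown),
        selected_windows={
            "ap": _global_extremum_window(reference.ap2, windows.ap_windows),
            "tr": _global_extremum_window(reference.tr2, windows.tr_windows),
        },
        references=reference,
        stage_logs=(log1, log2, log3),
    )


def interior_peak(series: np.ndarray, indices: np.ndarray, prominence: float = 0.1) -> bool:
    """Whether a local maximum with the given prominence lies inside a window.

    Used to detect the flexion-coupled extra TR excursion: a monotone trace
    has no interior local maximum, a coupled trace shows a bump near peak
    stance flexion.  The prominence floor (default 0.1 deg) rejects local
    maxima produced by residual measurement noise in a cycle-averaged trace.
    """
    from scipy.signal import find_peaks

    seg = np.asarray(series, dtype=float)[np.asarray(indices)]
    peaks, _ = find_peaks(seg, prominence=prominence)
    return peaks.size > 0
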