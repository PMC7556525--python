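"""Shared fixtures: packaged profile, fixture donors, and self-match helpers."""

from __future__ import annotations

from dataclasses import replace

import pytest

import kneespring as ks
from kneespring.spring_model import SpringCondition, SpringHalf
from kneespring.synthetic_knee import KneeSpecimen, RestraintCurve


@pytest.fixture(scope="session")
def profile():
    return ks.build_gait_profile(ks.default_waveform_spec(), n_points=128)


@pytest.fixture(scope="session")
def fixture_donors():
    return ks.packaged_donor_set()


def dead_zone_curve(half: SpringHalf, residual: float) -> RestraintCurve:
    """Toe curve whose intact law equals residual + dead-zone spring law exactly."""
    return RestraintCurve(
        toe_length=half.free_gap,
        toe_stiffness=residual,
        linear_stiffness=residual + half.rate,
    )


def grid_law_specimen(
    ap_cond: SpringCondition,
    tr_cond: SpringCondition,
    residual_ap: float = 1.4,
    residual_tr: float = 0.05,
) -> KneeSpecimen:
    """Noise-free specimen whose intact soft tissue equals the given spring laws.

    Resecting it and applying exactly (ap_cond, tr_cond) reproduces the
    intact balance equations pointwise, so the tuning stages must recover
    these conditions with zero deviation.
    """
    return KneeSpecimen(
        donor_id="self-match",
        ap_positive=dead_zone_curve(ap_cond.positive_half, residual_ap),
        ap_negative=dead_zone_curve(ap_cond.negative_half, residual_ap),
        tr_positive=dead_zone_curve(tr_cond.positive_half, residual_tr),
        tr_negative=dead_zone_curve(tr_cond.negative_half, residual_tr),
        fe_tr_coupling=0.0,
        residual_stiffness_ap=residual_ap,
        residual_stiffness_tr=residual_tr,
        cycle_noise_sd_ap_mm=0.0,
        cycle_noise_sd_tr_deg=0.0,
    )


def noise_free(specimen: KneeSpecimen) -> KneeSpecimen:
    return replace(specimen, cycle_noise_sd_ap_mm=0.0, cycle_noise_sd_tr_deg=0.0)
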