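# kneespring

Specimen-specific virtual-spring soft-tissue constraints for force-controlled
knee gait simulation.

## The problem

Natural-knee simulators evaluate early-stage soft-tissue interventions
(cartilage repair, meniscal replacement) under walking loads.  To test such an
intervention the knee's own soft tissue must often be resected — and its
mechanical function replaced by *virtual springs*: controller-defined
constraints that apply a restoring load once the joint moves beyond a free gap,

```
F(d) = -k+ · max(0, d - g+)   for d > 0      (anterior / internal)
F(d) = +k- · max(0, |d| - g-) for d < 0      (posterior / external)
```

with spring rate `k` (N/mm for anterior-posterior translation, Nm/° for tibial
rotation) and free gap `g` (mm or °) emulating ligament laxity.  Human knees
vary too much for one average spring setting to serve every specimen: the
appropriate `(k, g)` pair per axis and polarity must be found *per specimen* by
matching the resected-plus-spring knee's kinematics to the same knee recorded
intact.

This package reproduces that methodology fully in silico.  Synthetic donor
knees with toe-region soft-tissue restraint curves stand in for cadaveric
specimens; a quasi-static force-balance engine plays the role of the rig; and a
staged grid search selects, for each donor, the spring conditions that best
reproduce the intact knee's anterior-posterior (AP) displacement and tibial
rotation (TR) angle over a 1 Hz, 128-point gait cycle driven by ISO-14243-1
style force-control waveforms (with a two-peak axial force).

## The tuning procedure

For each specimen:

1. Record the intact knee under **AP force driven only** (TR free), giving
   references AP-1/TR-1, then under **AP and TR force both driven**, giving
   AP-2/TR-2.
2. **Stage 1** — resected knee, AP force driven, TR displacement-controlled
   with TR-1: pick the AP spring condition minimising the windowed-peak
   deviation from AP-1.
3. **Stage 2** — both axes force-driven with the stage-1 AP spring: pick the TR
   condition against TR-2.
4. **Stage 3** — both axes force-driven with the selected TR spring: re-select
   the AP condition against AP-2.

The deviation metric is the maximum absolute difference of the dominant-
polarity extremum over the analysis windows (AP: 0.06, 0.13, 0.67 ± 0.05 s;
TR: 0.10, 0.50 ± 0.05 s).  Candidates whose free gap reaches 4 mm / 4° are
excluded for joint stability, and candidates that dislocate are excluded from
selection.

## Worked example

```python
import kneespring as ks

profile = ks.build_gait_profile(ks.default_waveform_spec())   # 128-point cycle
donor = ks.packaged_donor_set()[0]                            # "fixture-1"
intact, resected = ks.make_matched_pair(donor)

result = ks.run_full_tuning(
    intact, resected, profile,
    ks.default_ap_grid(), ks.default_tr_grid(),
    config=ks.TuningConfig(seed=1),
)
print(result.ap_condition.describe())
print(result.tr_condition.describe())
print(f"AP deviation {result.ap_deviation_mm:.3f} mm, "
      f"TR deviation {result.tr_deviation_deg:.3f} deg")
```

prints

```
AP: Posterior 30 N/mm / 0 mm, Anterior 20 N/mm / 3 mm
TR: External 0.2 Nm/deg / 2 deg, Internal 0.3 Nm/deg / 1 deg
AP deviation 0.298 mm, TR deviation 0.308 deg
```

i.e. for this (deliberately lax) donor the anterior side needs a soft spring
with a wide free length while a moderate no-gap posterior spring suffices, and
the tuned resected knee reproduces the intact windowed peaks to about a third
of a millimetre / degree.  The same workflow is available from the
shell via the `kneespring` CLI (`generate-donors`, `run-intact`, `tune`,
`summarize`, `report`).

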