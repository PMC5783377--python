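# bonediff

Time-lapse HR-pQCT bone remodelling analysis: detect and quantify local
bone **formation** and **resorption** between density-calibrated 3D scans
of the same site acquired months or years apart.

High-resolution peripheral quantitative CT (HR-pQCT) images the distal
radius and tibia in vivo at ~82 µm isotropic voxels with densities
calibrated in mg hydroxyapatite per cm³ (mg HA/cm³). Because bone
remodelling changes local density, subtracting two registered scans of
the same bone reveals where tissue was added or removed — if the noise,
calibration and interpolation artefacts that also show up in a voxel-wise
difference are filtered away. `bonediff` implements that analysis for
researchers studying age-, disease- or treatment-related bone change, and
ships a synthetic longitudinal bone phantom with voxel-level ground truth
so every stage of the pipeline can be validated end to end.

## Method

For a baseline scan *B* and a follow-up scan *F* with periosteal masks:

1. **Rigid registration.** *F* is aligned to *B* by maximising the Pearson
   correlation of voxel densities over a three-level coarse-to-fine
   resolution pyramid (decimation 4/2/1), with a deterministic
   derivative-free optimiser. Only the follow-up is interpolated
   (linearly); the baseline is never touched.
2. **Largest common volume (LCV).** The analysis region is the voxel-wise
   AND of the baseline mask and the transformed follow-up mask; everything
   outside is ignored.
3. **Subtraction.** Δ(v) = F′(v) − B(v) within the LCV, in mg HA/cm³,
   so density gain (formation) is positive.
4. **Two-step filter.** Voxels with Δ > +T become candidate formation
   sites and Δ < −T candidate resorption sites (default T = 225 mg HA/cm³);
   then connected components (26-connectivity, per class) smaller than a
   minimum cluster size (default 5 voxels) are discarded. The cluster step
   removes most residual noise. No Laplace–Hamming filtering is applied
   anywhere — it would destroy the density calibration the threshold
   relies on.
5. **Quantification.** The baseline is segmented by matching its bone
   volume fraction, BV/TV = mean trabecular density / 1200 mg HA/cm³
   (fully mineralised bone), via rank selection of the highest-density
   voxels. Formed and resorbed volumes are reported in mm³ and as a
   percentage of the baseline bone volume inside the LCV;
   net = formation − resorption.

Study-level workflows wrap this pipeline: a **threshold sweep** over
repeated (no-change) scan pairs to pick T, a **reproducibility summary**
(the least-detectable remodelling, mean ± SD, stratified by motion-artefact
quality grade 1–5, with grade ≥ 3 pairs excluded from the headline figure),
and a **longitudinal analysis** registering every follow-up of a series
independently to the same baseline.

## Worked example

A synthetic baseline with ten formation packets and fifteen larger
resorption events, degraded with repeated-scan noise (σ = 80 mg HA/cm³)
and a 2-voxel/2° misalignment, then analysed blind:

```python
from bonediff import (PhantomSpec, RemodellingEventSpec, RigidTransform3D,
                      FilterParams, generate_phantom, apply_events,
                      detect_remodelling, segment_bvtv, quantify)
from bonediff.phantom import degrade

phantom = generate_phantom(PhantomSpec(shape=(96, 96, 96), seed=42))
events = [RemodellingEventSpec("formation", 10, (15, 40), 500.0),
          RemodellingEventSpec("resorption", 15, (40, 120), 500.0)]
followup, truth = apply_events(phantom, events, seed=1)
centre = phantom.periosteal.centroid_physical()
misalignment = RigidTransform3D.from_euler([2.0, -1.0, 0.5],
                                           [0.164, -0.123, 0.082], centre)
followup = degrade(followup, noise_sd=80.0, transform=misalignment, seed=2)

detection = detect_remodelling(phantom.density, phantom.periosteal,
                               followup, phantom.periosteal, FilterParams())
bone, bvtv = segment_bvtv(phantom.density, phantom.trabecular)
result = quantify(detection.labels, bone, detection.lcv)
```

Printing the detection and result fields gives:

```
registration r after alignment : 0.9766
LCV retained                   : 95.2%
baseline BV/TV                 : 0.148
bone formation : 0.139 mm^3 (0.36% of baseline bone)
bone resorption: 0.818 mm^3 (2.10% of baseline bone)
net change     : -1.74%
ground truth   : 278 formation / 1153 resorption voxels
detected       : 253 formation / 1484 resorption voxels
```

The registration recovers the misalignment to a few hundredths of a
voxel (r ≈ 0.98 after alignment; the residual reflects interpolation
smoothing, not misregistration). Formation is slightly under-counted
(partial-volume voxels at packet rims fall below threshold) and
resorption slightly over-counted (the repeated-scan noise floor adds
a few hundred voxels) — both effects are characterised by the test
suite. The net loss of −1.74% is the kind of signal a 2-year follow-up
in postmenopausal women produces.

The same pipeline is available from the shell:

```sh
bonediff phantom --out-dir data/ --seed 42
bonediff analyze --baseline data/baseline.mha --followup data/followup.mha \
    --baseline-mask data/baseline_mask.mha --followup-mask data/followup_mask.mha \
    --threshold 225 --min-cluster 5 --connectivity 26 \
    --out-labels labels.mha --out-report report.json
bonediff quantify --labels labels.mha --baseline data/baseline.mha \
    --baseline-mask data/baseline_mask.mha --trab-mask data/baseline_trab_mask.mha \
    --out result.json
bonediff overlay --labels labels.mha --baseline data/baseline.mha \
    --baseline-mask data/baseline_mask.mha --out-dir slices/
```

`overlay` writes the familiar three-colour sections: unchanged bone grey,
formation green, resorption magenta.

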