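# Methods

This note documents the models, parameter choices and numerical
conventions behind `bonediff`, and what the synthetic validation does and
does not demonstrate about real data.

## The measurement model

Time-lapse HR-pQCT change detection treats two density-calibrated scans
of the same site as noisy samples of the same underlying mineral
distribution plus any true remodelling. A voxel-wise difference between
registered scans therefore contains three components: true local density
change (formation/resorption), repeated-scan noise, and systematic
artefacts (calibration drift, interpolation smoothing of the transformed
follow-up, motion artefacts). The two-step filter — a global threshold T
on |Δ density| followed by a minimum connected-cluster size — is designed
so that the joint probability of noise producing a *spatially coherent*
supra-threshold cluster is small, while genuine remodelling events, which
are connected by construction of the biology, survive.

All densities are floating-point mg HA/cm³ in memory regardless of the
on-disk type; every threshold is in density units. Grids are isotropic,
voxel-centred, 0-based; physical position = origin + index · voxel size.
Transforms act on physical coordinates and map follow-up coordinates into
the baseline frame ("euler-zyx" intrinsic convention, degrees).

## Registration

* Metric: Pearson correlation of voxel densities over the fixed
  periosteal mask restricted to voxels that map inside the moving field
  of view (alignment is driven by bone, not air).
* Pyramid: three levels, decimation 4/2/1 with Gaussian smoothing before
  decimation; each level starts from the previous solution.
* Optimiser: Powell-style derivative-free descent (via SimpleITK's
  registration framework), parameter scales from physical shift,
  convergence on metric improvement < 1e-9 or step < 1e-5, max 200
  iterations per level. At the finest level the metric uses a regular
  25 % voxel subsample with a fixed jitter seed — measured cost drops
  ~3× while the recovery error stays below 0.05 voxel; everything is
  bit-reproducible between runs.
* Initialisation: rotations start at zero; the translation starts at the
  difference of background-suppressed intensity centroids (voxel weights
  max(I − 25th percentile, 0)). A pure zero start is only reliable within
  the correlation length of the trabecular texture (~3 voxels); the
  centroid start extends capture to tens of voxels and 10°+ rotations and
  is exactly deterministic. With this scheme, misalignments of up to
  20 voxels / 10° are recovered to ~0.03 voxel / ~0.02° on noise-free
  phantoms (the contract asserts ≤ 0.1 / 0.1; ≤ 0.5 at σ = 80).
* Rotation centre: centroid of the fixed mask (decorrelates rotation and
  translation parameters).
* The follow-up is resampled once, linearly, into the baseline grid;
  masks and label volumes use nearest-neighbour only. Resampling under an
  exact identity returns the input unchanged, so a no-change pair is
  bit-identical through the whole pipeline.
* If optimisation fails to improve the correlation, a warning is issued
  and the best transform found (possibly the identity) is returned, so
  the reported after-correlation is never below the before-correlation.

## Filtering

* Threshold default T = 225 mg HA/cm³ — the recommended operating point:
  on repeated scans it keeps falsely detected remodelling around or below
  ~0.5 % of the baseline bone volume while retaining sensitivity; the
  threshold-sweep workflow (200–275 in steps of 25) reproduces the
  trade-off curve on any pair.
* "Exceeds" is strict: |Δ| = T classifies as unchanged. Boundary voxels
  are measure-zero for continuous noise.
* Cluster filter: connected components computed separately within the
  formation and within the resorption class (never merged), components
  with < 5 voxels (default) reclassified as unchanged. Connectivity
  default 26 (faces+edges+corners) so one-voxel-thick remodelling sheets
  on oblique surfaces stay connected; 6 and 18 are available. The filter
  is idempotent and monotone in both T and the cluster minimum.
* For spatially white Gaussian noise of per-scan sd σ, the pre-cluster
  flagged fraction is exactly 2·Φ(−T/(σ√2)); at σ = 80, T = 225 the
  cluster step empirically cuts the flagged fraction a further ~18×.

## Quantification

* Baseline bone = BV/TV-matched segmentation: target fraction = mean
  density over the trabecular mask (or, with a logged caveat, the full
  periosteal mask) divided by 1200 mg HA/cm³, clamped to [0, 1]; the
  round(target·N) highest-density voxels are selected. Rank selection
  achieves the target exactly up to integer rounding with no threshold
  iteration; ties break by ascending linear index for cross-platform
  determinism.
* Percentages use a single denominator: segmented baseline bone inside
  the LCV — all analysis is confined to the common region, so the
  denominator must be too. net = formation − resorption holds exactly.
* Overlays: formation/resorption > unchanged bone > background
  precedence, fixed grey/green/magenta palette, only LCV voxels non-zero.

## The synthetic phantom

The generator emulates a distal-limb acquisition at 82 µm:

* Geometry: cylindrical periosteal region (radius 0.46 × grid width),
  closed cortical shell (default 3 voxels), trabecular compartment with a
  1-voxel endosteal margin.
* Trabecular network: Gaussian random field smoothed to a correlation
  length of 0.25 mm and thresholded at the quantile matching the target
  BV/TV (default 0.15 — osteoporotic-range trabecular bone). Morphology
  is statistical, not anatomical: it has realistic feature sizes and
  surface density but no plate/rod architecture.
* Densities: bone 900, background 50 mg HA/cm³, blurred by a Gaussian of
  σ = 0.8 voxel emulating the ~150 µm FWHM scanner point spread. This
  band-limiting matters: with unrealistically crisp edges, linear
  interpolation of the transformed follow-up systematically lowers thin
  trabecular peaks by ~150 mg HA/cm³ and produces a large false
  resorption floor that real, PSF-blurred scans do not show. With the
  PSF-like ramp the measured false-positive floor on degraded no-change
  pairs is ~0.2–0.3 % at T = 225, matching repeated-scan experience.
* Remodelling events: 6-connected blobs grown from the bone surface
  (formation outward into marrow space, resorption inward into bone;
  "cortical-pore" placement confined to the shell), ±magnitude added to
  the density, every modified voxel recorded as ground truth. Events
  keep a 1-voxel separation buffer so each detected cluster is
  attributable to one event. Events are inserted with sharp edges so the
  ground-truth bookkeeping (Δ-support = modified voxels) is exact.
* Degradation: linear resampling under a known rigid misalignment, then
  white Gaussian noise (preset "hrpqct-like": σ = 80 mg HA/cm³ — a fixed,
  documented choice for a first-generation scanner's repeated-scan
  variability), optionally laterally shifted slice slabs mimicking
  stack-shift motion artefacts. Structured CT noise (streaks, beam
  hardening, reconstruction kernels) is out of scope.
* Longitudinal series: events accumulate interval by interval (voxels
  are never remodelled twice, so cumulative ground truth stays well
  defined); each follow-up is independently degraded; the baseline is
  returned clean and degradation, where wanted, is applied explicitly.

## Validation conditions and problem sizes

The end-to-end checks run on phantoms of 96³ (pipeline floors, noise
tail, longitudinal trend) and 128³ voxels (transform recovery, event
recovery) — large enough for ~5·10⁵-voxel LCVs and stable binomial
statistics while keeping the full suite fast on one core. The
event-recovery condition inserts 40 small formation packets (12–40
voxels) and 40 larger resorption volumes (80–240 voxels) of
|Δρ| = 500 mg HA/cm³ — mirroring the "few small formation packets, many
large resorption volumes" picture of ageing bone, with per-class totals
a few percent of baseline bone volume so they sit well above the
repeated-scan noise floor, as real longitudinal remodelling does — under
σ = 80 follow-up noise and a 2-voxel/2° misalignment. The progressive-loss
series removes ~1.6 % of bone net per interval over three intervals.

Passing these tests shows the pipeline's arithmetic, registration,
filtering and bookkeeping are correct under a controlled noise model. It
does not certify performance on real scans, where motion artefacts,
calibration drift between sessions, beam hardening and anatomical change
outside the remodelling model all add error; the reproducibility
workflow exists precisely to measure that noise floor per study.

## Known limitations

* Rigid registration only; growth or soft-tissue deformation is not
  modelled (appropriate for adult peripheral skeletal sites).
* Detected event volumes are biased: small events lose rim voxels to
  partial-volume blurring (undercount, ~10–20 % for 12–40-voxel packets),
  while the noise floor adds false voxels (overcount, a few hundred
  voxels per scan pair at default settings). Net change is more accurate
  than either class alone because the biases partially cancel.
* The BV/TV-matched segmentation assumes 1200 mg HA/cm³ fully
  mineralised tissue; systematic calibration offsets shift the
  denominator, not the detected volumes.
* Quality grades are accepted as input metadata; no automatic motion
  scoring is performed.
* Proprietary scanner formats (AIM/ISQ, DICOM series) are not parsed.
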