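# Methods

## Voxel classification and the P(ABCD) score

A CT study is scored in four steps: (1) a sinonasal volume of interest
(VOI) is defined, (2) every in-VOI voxel is classified by its HU value,
(3) class volumes are extracted, (4) the opacification ratio
P(ABCD) = V_soft / (V_soft + V_air) is computed and graded.

The tissue bands are stated for integer HU — air down to −250, soft tissue
−249 to +250, bone from +251 — which leaves the half-units between them
unassigned once DICOM rescale slopes produce non-integer HU. We therefore
realise the bands as contiguous half-open intervals split at **−249.5** and
**+250.5** HU: the integer assignments are reproduced exactly and the map is
total over float HU. Voxels outside [−2000, +2000] HU (metal artefacts,
padding) are tallied as *excluded* and participate in the volume
conservation identity `v_air + v_soft + v_bone + v_excluded = v_total`;
they are never silently dropped.

Percentages: `% air` and `% soft` are reported on the **air + soft
denominator** — the patency-relevant one, consistent with the P(ABCD)
formula and with the self-consistent published post-treatment cell
(40,000 / 110,000 → 36%). Total-denominator percentages are emitted under
separate keys (`pct_air_total`, `pct_soft_total`) for users who want the
bone-inclusive reading. HU summary statistics (min/max/mean) and the
per-1-HU histogram cover in-band voxels only; the final histogram bin also
absorbs HU exactly +2000 so counts always sum to the in-band voxel count.

### Grades

The published grade bands share their printed edges (0.15 ends A and starts
B, and so on). We make the map total and deterministic by assigning each
edge to the **upper** grade: P0 iff score ≤ 10⁻⁹, A on (0, 0.15), B on
[0.15, 0.35), C on [0.35, 0.55), D on [0.55, 0.9), P1 on [0.9, 1]. The
edges are configurable (`GradeBands`).

### OMC

The ostiomeatal complex is scored from its own sub-ROI soft fraction f:
0 (patent) for f < 1/3, 2 (obstructed) for f ≥ 2/3, 1 otherwise. The
reference material shows only the extremes {0, 2} but describes a "degree
of involvement", so we keep a three-level output with configurable
thresholds defaulting to thirds. The OMC score is reported alongside — and
never added to — the [0, 1] P(ABCD) score, whose codomain it would break;
any OMC soft tissue already flows through V_soft of the total VOI.

### LMS and modified LMS

Per-sinus opacification fractions map to ordinal scores with a tolerance
ε = 0.005 at both ends: a fraction ≤ ε scores 0 and ≥ 1 − ε scores the
scale maximum (2, or 5 on the modified scale), so single-voxel noise cannot
deny a visually total opacification while a genuinely 99%-opacified sinus
still scores partial (1, respectively 4). Between the ends the modified
scale uses 25% bands closed on the right: (0, .25] → 1, (.25, .5] → 2,
(.5, .75] → 3, (.75, 1) → 4. The binary LMS OMC component is obstructed (2)
only when the three-level score reaches 2. Totals are normalised to percent
of the scale maxima, /24 and /54 — the natural maxima of the two systems
with 0/2 per OMC side; the original appendix defining the percent
conversion is not available, so these maxima are our choice.

## VOI from landmarks

The eight cephalometric landmarks are treated as the extremes of an
axis-aligned bounding box in patient-space mm; a voxel belongs to the VOI
iff its centre lies in the half-open box [lo, hi) per axis (half-open so
that adjacent boxes partition the grid without double counting). The
anatomical trimming of that box (orbits, brain) is the operator's manual
task on real data: users supply explicit masks for anything non-convex, and
explicit masks always win. Sub-ROIs are forced to be subsets of the total
VOI by intersection at construction time.

## Synthetic phantoms

The phantom emulates the imaging substrate at desk scale: a 128³ grid at
0.5 mm isotropic spacing (the slice width of the emulated scanner protocol)
of bone-density material containing ten ellipsoidal cavities — five sinus
pairs with LMS names — and two cuboid OMC channels. Each cavity is filled
with soft-tissue material **from its inferior extent upward** (voxels
ordered by z, then y, x; the first round(f·n) become soft). This
gravity-like fill mimics real opacification geometry (dependent secretions,
mucosal thickening) rather than salt-and-pepper voxel scatter, and makes
the realised fraction the closest achievable to nominal; the realised
fraction is recorded exactly from counted voxels.

Per-voxel HU is drawn from a per-class Gaussian and clipped to the class's
band:

| class | mean (HU) | SD | clip band |
|-------|-----------|----|-----------|
| air   | −1000 | 30  | [−2000, −250] |
| soft  | +40   | 50  | [−249, +250]  |
| bone  | +700  | 100 | [+251, +2000] |

Physiologically plausible values; the clipping guarantees that HU
thresholding recovers the noise-free label of every voxel, so the scored
P(ABCD) equals the counted ground truth *exactly* and recovery tests are
sharp. What the phantom deliberately does **not** model: partial-volume
averaging at air/soft/bone interfaces, beam hardening, anatomically curved
sinus walls, and inter-structure HU correlation. Passing recovery tests
therefore demonstrates correctness of the measurement chain, not robustness
to partial-volume blur on patient data, where voxels straddling interfaces
can land in the wrong band.

The total-VOI mask is the bounding box of all structures padded by 2 mm of
bone wall — bone inside the VOI exercises the conservation identity without
affecting the air+soft-based scores.

### Paired cohort generator

`default_cohort` emulates a 20-patient before-and-after design with
pre/post mean opacification fractions (0.68, 0.52), the reported cohort
effect. Per patient, the pre fraction is Beta-distributed with mean 0.68
and concentration 10 (SD ≈ 0.14, close to the reported between-patient
spread); the post fraction is the pre fraction times a Beta-distributed
response factor with mean 0.52/0.68 ≈ 0.76, concentration 20, and support
(0, 1.25) — most patients improve, a small minority worsens slightly, and
the product preserves the post mean. Per-cavity fills are Beta-jittered
around the patient fraction (concentration 60) so per-sinus scores vary
within a patient. All draws flow from one `numpy` SeedSequence, so a cohort
is bit-reproducible from its seed.

## Statistics

- **Wilcoxon signed-rank** (two-sided): zero differences are dropped
  (Wilcoxon's original policy, the common software default; the choice is
  recorded in the result's `method` metadata), average ranks for tied
  absolute differences. With ≤ 12 effective pairs and no ties the exact
  null distribution of W⁺ is computed by subset-sum dynamic programming;
  otherwise a normal approximation with tie correction and a continuity
  correction toward the mean is used. The exact path is cross-checked in
  the tests against full 2ⁿ sign-assignment enumeration, the approximate
  path against `scipy.stats.wilcoxon`.
- **Friedman**: within-subject average ranks, the standard tie-corrected
  chi-square statistic with k − 1 df, implemented directly so the fully
  tied degenerate case returns (0, 1) instead of NaN; cross-checked against
  `scipy.stats.friedmanchisquare`.
- **Bonferroni**: min(1, p·m).
- **Bland-Altman**: differences oriented first-method-minus-second (method
  names recorded in the report), bias = mean difference, limits
  bias ± 1.96·SD with the n−1 sample SD, per-subject (mean, difference)
  pairs exported for plotting.
- Report tables retain full-precision values; rounding to a table's printed
  precision is left to presentation code.

## Problem sizes and numerical choices

The test suite and the acceptance script run phantoms at 48³–128³ and
cohort simulations at 20 patients × 200 replicates — sizes chosen so the
whole validation executes in seconds on one core while every cavity still
contains 10³–10⁴ voxels, enough for fill-fraction quantisation error
(≤ 1/(2n) per cavity) to stay far below the 0.01 recovery tolerance.
Fractions are compared exactly where the pipeline is exact (clipped-noise
phantoms) and with explicit tolerances elsewhere. Thresholds and band edges
are compared in float; HU volumes are stored float32 after calibration
because rescale slopes are frequently non-integer.

## Known limitations

- The landmark-bounded VOI is a box; real studies require manual trimming,
  which is out of algorithmic scope by design.
- No texture features beyond first-order statistics are extracted.
- RTSTRUCT contours are not parsed; masks are the exchange format. DICOM is
  read, never written.
- The published per-patient volumetric appendix and raw CT data are not
  available, so cohort-level agreement statistics (e.g. the reported biases
  of +0.17 and +0.23 against LMS and modified LMS) can only be checked for
  internal arithmetic consistency, not reproduced from data.
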