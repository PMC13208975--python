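# sinuscore

Quantitative CT scoring of sinonasal opacification for chronic rhinosinusitis
with nasal polyposis (CRSwNP).

Radiologists conventionally stage sinus CT with the Lund-Mackay score (LMS):
each of five paranasal sinuses per side is rated 0/1/2 by eye
(none / partial / total opacification) plus 0/2 for each ostiomeatal complex
(OMC), to a maximum of 24. The modified (Zinreich) LMS refines the partial
range into 25% bands (0–5 per sinus, maximum 54). Both are coarse: a sinus
that is 1% opacified and one that is 99% opacified can receive the same
score. `sinuscore` implements a continuous, voxel-based alternative alongside
the classical scales, for researchers evaluating treatment response (e.g.
biologics) on paired pre/post CT studies.

## The score

Inside a sinonasal volume of interest (VOI), every voxel is classified by
its Hounsfield-unit value:

| class | HU band |
|-------|---------|
| air   | −2000 … −250 |
| soft tissue | −249 … +250 |
| bone  | +251 … +2000 |

(float HU is split at −249.5 and +250.5; HU outside ±2000 is counted as
*excluded*, never silently dropped). The opacification score is the
soft-tissue fraction of the patency-relevant volume:

```
P(ABCD) = V_soft / (V_soft + V_air)  ∈ [0, 1]
```

graded **P0** (0, no inflammation), **A** mild (0–0.15), **B** moderate
(0.15–0.35), **C** advanced (0.35–0.55), **D** severe (0.55–0.9), **P1**
pansinusitis (0.9–1). Each OMC is scored 0 (patent) to 2 (obstructed) from
its own soft-tissue fraction. When per-sinus masks are supplied, the same
fractions drive the LMS and modified-LMS scores, so all three systems come
from one classification pass.

The package also provides:

- **I/O** — DICOM series / NIfTI ingestion with exact HU calibration,
  NIfTI masks, JSON/CSV result records (volumes in both mm³ and cm³).
- **VOI construction** — rasterisation of the box bounded by eight
  cephalometric landmarks (S, N, Ba, ANS, PNS, A, MX left/right), or
  user-supplied masks, with sub-ROI intersection.
- **Synthetic phantoms** — seeded sinus phantoms (bone block, ellipsoidal
  cavities gravity-filled with soft tissue to a known fraction, Gaussian HU
  noise clipped per class) with exact counted ground truth, plus a paired
  pre/post cohort generator.
- **Cohort statistics** — percent change, Friedman and Wilcoxon signed-rank
  tests (exact small-sample null), Bonferroni correction, Bland-Altman
  agreement, descriptive tables.

## Worked example

```python
from sinuscore import default_phantom_spec, generate_phantom, score_ct

spec = default_phantom_spec(fill_fraction=0.65, seed=3)   # 128³ @ 0.5 mm
ct, truth = generate_phantom(spec)
result, lms, mlms = score_ct(ct, truth.regions)
prof = result.profile
print(f"V_air  = {prof.v_air_cm3:8.3f} cm^3")
print(f"V_soft = {prof.v_soft_cm3:8.3f} cm^3")
print(f"P(ABCD) = {result.score:.4f}  grade {result.grade}")
print(f"OMC left/right: {result.omc_left}/{result.omc_right}")
print(f"LMS total {lms.total}/24 ({lms.percent:.1f}%)")
print(f"modified LMS total {mlms.total}/54 ({mlms.percent:.1f}%)")
print(f"ground truth fraction {truth.overall_fraction:.4f}")
```

prints

```
V_air  =    3.893 cm^3
V_soft =    7.229 cm^3
P(ABCD) = 0.6500  grade D
OMC left/right: 1/1
LMS total 10/24 (41.7%)
modified LMS total 30/54 (55.6%)
ground truth fraction 0.6500
```

Every cavity was filled to 65% of its volume, so the recovered score equals
the counted ground truth exactly (the per-class HU noise is clipped to its
band); the grade D ("severe") reflects a 0.65 soft-tissue fraction, each
half-obstructed OMC scores 1, and the coarser LMS/modified-LMS land at 41.7%
and 55.6% of their scale maxima — a direct illustration of how the ordinal
scales compress a two-thirds-opacified sinonasal system.

The same pipeline is available from a shell:

```bash
sinuscore phantom --out-dir phantom/ --fill 0.65 --seed 3
sinuscore score --ct phantom/ct.nii.gz --voi phantom/voi_total.nii.gz \
    --sinus-masks phantom/ --omc-left phantom/omc_left.nii.gz \
    --omc-right phantom/omc_right.nii.gz --out score.json
sinuscore cohort --scores cohort.csv --out report.json
```

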