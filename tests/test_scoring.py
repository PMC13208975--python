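import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinuscore import (
    DensitometricProfile,
    assign_grade,
    lms_sinus_score,
    lms_total,
    modified_lms_sinus_score,
    modified_lms_total,
    omc_score,
    pabcd_score,
    score_ct,
)
from sinuscore.phantom import default_cohort, generate_phantom, nominal_overall_fraction
from sinuscore.scoring import GradeBands
from sinuscore.voi import SINUS_NAMES


def _profile(n_air, n_soft, n_bone=0, voxel_volume=1.0):
    return DensitometricProfile(
        n_air=n_air,
        n_soft=n_soft,
        n_bone=n_bone,
        n_excluded=0,
        voxel_volume_mm3=voxel_volume,
        hu_min=-1000.0,
        hu_max=700.0,
        hu_mean=0.0,
        histogram=np.zeros(4000, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# P(ABCD)


def test_pabcd_formula():
    assert pabcd_score(_profile(100, 0)) == 0.0
    assert pabcd_score(_profile(0, 100)) == 1.0
    # the published post-treatment volume means: 70,000 soft vs 40,000 air
    assert pabcd_score(_profile(40_000, 70_000)) == pytest.approx(70_000 / 110_000)


def test_pabcd_zero_denominator_rejected():
    with pytest.raises(ValueError, match="patency"):
        pabcd_score(_profile(0, 0, n_bone=50))


@given(n_air=st.integers(1, 10_000), n_soft=st.integers(1, 10_000),
       scale=st.floats(0.01, 100.0))
@settings(deadline=None, derandomize=True)
def test_pabcd_scale_invariant(n_air, n_soft, scale):
    base = pabcd_score(_profile(n_air, n_soft, voxel_volume=1.0))
    scaled = pabcd_score(_profile(n_air, n_soft, voxel_volume=scale))
    assert scaled == pytest.approx(base, rel=1e-12)


def test_pabcd_strictly_increases_in_soft_volume():
    scores = [pabcd_score(_profile(500, n)) for n in (1, 10, 100, 1000)]
    assert all(a < b for a, b in zip(scores, scores[1:]))


# ---------------------------------------------------------------------------
# grades


@pytest.mark.parametrize(
    "score,grade",
    [
        (0.0, "P0"),
        (0.10, "A"),
        (0.15, "B"),
        (0.30, "B"),
        (0.35, "C"),
        (0.45, "C"),
        (0.55, "D"),
        (0.70, "D"),
        (0.90, "P1"),
        (0.95, "P1"),
        (1.0, "P1"),
    ],
)
def test_grade_bands(score, grade):
    assert assign_grade(score) == grade


def test_grade_out_of_range_rejected():
    for bad in (-0.01, 1.01, float("nan")):
        with pytest.raises(ValueError):
            assign_grade(bad)


def test_grade_bands_configurable_and_validated():
    bands = GradeBands(a_upper=0.2, b_upper=0.4, c_upper=0.6, d_upper=0.8)
    assert assign_grade(0.17, bands) == "A"
    with pytest.raises(ValueError):
        GradeBands(a_upper=0.5, b_upper=0.4)


@given(st.floats(0.0, 1.0))
@settings(deadline=None, derandomize=True)
def test_grade_is_nondecreasing(score):
    order = ["P0", "A", "B", "C", "D", "P1"]
    g = assign_grade(score)
    h = assign_grade(min(1.0, score + 0.05))
    assert order.index(h) >= order.index(g)


# ---------------------------------------------------------------------------
# OMC


def test_omc_extremes_and_middle():
    assert omc_score(_profile(100, 0)) == 0  # patent
    assert omc_score(_profile(0, 100)) == 2  # obstructed
    assert omc_score(_profile(50, 50)) == 1


def test_omc_custom_thresholds():
    assert omc_score(_profile(50, 50), thresholds=(0.1, 0.4)) == 2
    with pytest.raises(ValueError, match="thresholds"):
        omc_score(_profile(50, 50), thresholds=(0.9, 0.1))


# ---------------------------------------------------------------------------
# LMS / modified LMS per-sinus maps


@pytest.mark.parametrize(
    "frac,lms,mlms",
    [
        (0.0, 0, 0),
        (0.002, 0, 0),  # within the total-opacification tolerance of none
        (0.10, 1, 1),
        (0.25, 1, 1),
        (0.40, 1, 2),
        (0.50, 1, 2),
        (0.60, 1, 3),
        (0.75, 1, 3),
        (0.80, 1, 4),
        (0.99, 1, 4),  # 99% opacification is still partial
        (0.999, 2, 5),
        (1.0, 2, 5),
    ],
)
def test_sinus_score_maps(frac, lms, mlms):
    assert lms_sinus_score(frac) == lms
    assert modified_lms_sinus_score(frac) == mlms


def test_sinus_score_out_of_range_rejected():
    for f in (-0.1, 1.1):
        with pytest.raises(ValueError):
            lms_sinus_score(f)
        with pytest.raises(ValueError):
            modified_lms_sinus_score(f)


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
@settings(deadline=None, derandomize=True)
def test_sinus_scores_are_nondecreasing_step_functions(f1, f2):
    lo, hi = sorted((f1, f2))
    assert lms_sinus_score(lo) <= lms_sinus_score(hi)
    assert modified_lms_sinus_score(lo) <= modified_lms_sinus_score(hi)


# ---------------------------------------------------------------------------
# totals


def test_totals_at_scale_extremes():
    zeros = lms_total([0] * 10, (0, 0))
    assert zeros.total == 0 and zeros.percent == 0.0
    full = lms_total([2] * 10, (2, 2))
    assert full.total == 24 and full.percent == 100.0
    mfull = modified_lms_total([5] * 10, (2, 2))
    assert mfull.total == 54 and mfull.percent == 100.0


def test_lms_percent_normalization():
    res = lms_total([1] * 10, (0, 2))
    assert res.total == 12 and res.percent == pytest.approx(50.0)


def test_totals_reject_bad_components():
    with pytest.raises(ValueError, match="per-sinus"):
        lms_total([1] * 9, (0, 0))
    with pytest.raises(ValueError, match="OMC"):
        lms_total([1] * 10, (1, 0))
    with pytest.raises(ValueError, match="outside"):
        modified_lms_total([6] + [0] * 9, (0, 0))
    with pytest.raises(ValueError, match="exactly"):
        lms_total({"maxillary_left": 1}, (0, 0))


# ---------------------------------------------------------------------------
# end-to-end scoring


def test_score_ct_without_sinus_masks_gives_pabcd_only(small_phantom):
    _, ct, truth = small_phantom
    from sinuscore.voi import RegionSet

    res, lms, mlms = score_ct(ct, RegionSet(total=truth.regions.total))
    assert res.score == truth.overall_fraction
    assert res.omc_left is None and lms is None and mlms is None


def test_score_ct_per_sinus_scores_match_cavity_truth(small_phantom):
    _, ct, truth = small_phantom
    res, lms, mlms = score_ct(ct, truth.regions)
    for name in SINUS_NAMES:
        f = truth.cavities[name].realized_fraction
        assert lms.per_sinus[name] == lms_sinus_score(f)
        assert mlms.per_sinus[name] == modified_lms_sinus_score(f)


def test_scored_cohort_phantoms_recover_nominal_effect():
    """Rendered paired phantoms score at their generated fill fractions."""
    pairs = default_cohort(2, seed=3, grid_shape=(48, 48, 48))
    for pre_spec, post_spec in pairs:
        for spec in (pre_spec, post_spec):
            ct, truth = generate_phantom(spec)
            res, _, _ = score_ct(ct, truth.regions)
            assert res.score == truth.overall_fraction
            assert abs(res.score - nominal_overall_fraction(spec)) < 0.05
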