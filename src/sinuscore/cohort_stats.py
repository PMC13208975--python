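"""Paired-cohort statistics for before-and-after scoring studies.

Each patient serves as their own control: the same scores (P(ABCD), LMS
percent, modified-LMS percent, plus arbitrary clinical outcome columns)
are measured pre- and post-treatment. This module provides the matching
statistical surface: percent change of means, the Friedman test across
k matched methods (tie-corrected, chi-square reference with k-1 df), the
Wilcoxon signed-rank test (exact null for small samples without ties,
normal approximation with tie and continuity corrections otherwise),
Bonferroni correction, Bland-Altman agreement, and descriptive tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedCohort",
    "AgreementReport",
    "WilcoxonResult",
    "percent_change",
    "friedman_test",
    "wilcoxon_signed_rank",
    "bonferroni",
    "bland_altman",
    "cohort_table",
]


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ : sum of ranks of positive differences
    pvalue: float
    n_effective: int
    method: str  # "exact" or "normal"


class FriedmanResult(NamedTuple):
    statistic: float
    pvalue: float


# ---------------------------------------------------------------------------


def percent_change(pre_mean: float, post_mean: float) -> float:
    """Relative change of the mean, (post - pre) / pre * 100."""
    if pre_mean == 0:
        raise ValueError("percent change is undefined for a zero baseline mean")
    return (post_mean - pre_mean) / pre_mean * 100.0


def friedman_test(columns: Sequence[Sequence[float]]) -> FriedmanResult:
    """Friedman rank test for k matched samples of n subjects.

    Within-subject ranks use average ranks for ties; the statistic carries
    the standard tie correction and is referred to chi-square with k-1
    degrees of freedom. Rows (subjects) that are entirely tied contribute
    no information; if every row is fully tied the statistic is 0 and p = 1.
    """
    data = np.asarray(columns, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need k >= 2 matched samples")
    k, n = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing or non-finite cells are not allowed in the Friedman test")

    ranks = np.apply_along_axis(sps.rankdata, 0, data)  # rank within each subject
    rank_sums = ranks.sum(axis=1)
    chisq = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)

    # tie correction: 1 - sum(t^3 - t) / (n (k^3 - k)) over tied groups per subject
    ties = 0.0
    for j in range(n):
        _, counts = np.unique(data[:, j], return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction <= 0:
        return FriedmanResult(0.0, 1.0)
    chisq /= correction
    chisq = max(chisq, 0.0)
    return FriedmanResult(float(chisq), float(sps.chi2.sf(chisq, k - 1)))


def _exact_signed_rank_p(w_plus: float, n: int) -> float:
    """Two-sided exact p for W+ with distinct ranks 1..n, by the subset-sum
    null distribution (counts of rank subsets at each sum)."""
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    counts /= counts.sum()
    w = int(round(w_plus))
    lower = counts[: w + 1].sum()
    upper = counts[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    pre: Sequence[float], post: Sequence[float], exact_n_max: int = 12
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Differences ``post - pre`` equal to zero are dropped (Wilcoxon's
    original zero policy); absolute differences are ranked with average
    ranks for ties. The exact null distribution is used when the effective
    sample is small (``n <= exact_n_max``) and there are no tied absolute
    differences; otherwise a normal approximation with tie correction and
    a continuity correction is used. When every difference is zero the test
    is degenerate and p = 1 is returned with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 1:
        raise ValueError("pre and post must be matched 1-D vectors with n >= 1")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; Wilcoxon test is degenerate")
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    if n <= exact_n_max and not has_ties:
        p = _exact_signed_rank_p(w_plus, n)
        return WilcoxonResult(w_plus, p, n, "exact")

    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return WilcoxonResult(w_plus, 1.0, n, "normal")
    dev = w_plus - mu
    cc = 0.5 * np.sign(dev)  # continuity correction toward the mean
    z = (dev - cc) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "normal")


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise (m defaults to len)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Bland-Altman agreement between two measurement methods.

    Differences are oriented first-method-minus-second. ``bias`` is the mean
    difference; the limits of agreement are ``bias +/- 1.96 * SD`` with the
    sample (n-1) standard deviation.
    """

    method_a: str
    method_b: str
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return int(self.diffs.size)

    def to_dict(self) -> dict:
        return {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
            "means": self.means.tolist(),
            "diffs": self.diffs.tolist(),
        }

    def scatter_frame(self) -> pd.DataFrame:
        """Per-subject (mean, difference) pairs for external plotting."""
        return pd.DataFrame({"mean": self.means, "diff": self.diffs})


def bland_altman(
    method_a: Sequence[float],
    method_b: Sequence[float],
    names: tuple[str, str] = ("A", "B"),
) -> AgreementReport:
    """Bland-Altman analysis of two matched measurement vectors."""
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"matched vectors required, got shapes {a.shape} and {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementReport(
        method_a=names[0],
        method_b=names[1],
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=diffs,
    )


# ---------------------------------------------------------------------------


@dataclass
class PairedCohort:
    """Long-format cohort: one row per subject and timepoint.

    The underlying frame has columns ``subject_id``, ``timepoint`` (values
    ``pre`` / ``post``) and one numeric column per outcome. Every subject
    entering a paired computation must have both timepoints.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "timepoint"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"cohort frame must contain columns {sorted(required)}")
        bad = set(self.frame["timepoint"]) - {"pre", "post"}
        if bad:
            raise ValueError(f"unknown timepoints {sorted(bad)}; expected 'pre'/'post'")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedCohort":
        return cls(pd.read_csv(path))

    @property
    def value_columns(self) -> list[str]:
        return [
            c
            for c in self.frame.columns
            if c not in ("subject_id", "timepoint")
            and pd.api.types.is_numeric_dtype(self.frame[c])
        ]

    def paired(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        """Matched (pre, post) vectors for one column, ordered by subject."""
        wide = self.frame.pivot(index="subject_id", columns="timepoint", values=column)
        if wide[["pre", "post"]].isna().any().any():
            missing = wide.index[wide[["pre", "post"]].isna().any(axis=1)].tolist()
            raise ValueError(f"subjects missing a timepoint for {column!r}: {missing}")
        return wide["pre"].to_numpy(), wide["post"].to_numpy()

    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()


def cohort_table(cohort: PairedCohort) -> pd.DataFrame:
    """Descriptive summary per outcome column: mean, SD (n-1), median, min,
    max at each timepoint plus the post-minus-pre delta of means.

    With a single subject the SD is undefined and reported as missing.
    """
    if cohort.frame.empty:
        raise ValueError("empty cohort")
    rows = []
    for col in cohort.value_columns:
        pre, post = cohort.paired(col)
        row: dict[str, float | str | None] = {"column": col}
        for tag, vals in (("pre", pre), ("post", post)):
            row[f"mean_{tag}"] = float(np.mean(vals))
            row[f"sd_{tag}"] = float(np.std(vals, ddof=1)) if vals.size > 1 else None
            row[f"median_{tag}"] = float(np.median(vals))
            row[f"min_{tag}"] = float(np.min(vals))
            row[f"max_{tag}"] = float(np.max(vals))
        row["delta_mean"] = float(np.mean(post) - np.mean(pre))
        rows.append(row)
    return pd.DataFrame(rows).set_index("column")
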