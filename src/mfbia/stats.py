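"""Cohort statistics: the gender and pooled-age group comparisons.

The procedure mirrors the study design the normative tables come from:

* samples are first screened for normality (Shapiro–Wilk) and equal
  variance (two-sided F ratio);
* age contrasts use a two-tailed unpaired pooled-variance t-test when
  both samples pass the screen, otherwise the Mann–Whitney U test;
* gender contrasts always use Mann–Whitney (a few of the original data
  sets were non-normal, so the nonparametric route was fixed for all);
* age is contrasted by pooling the two youngest decades (20s + 30s)
  against the two oldest (50s + 60s) within gender, the 40s excluded;
* percent change is computed on group means with group a (men, or the
  younger pool) as baseline;
* significance means p <= 0.05 (p > 0.05 is reported nonsignificant).

No multiple-testing correction is applied, matching the source procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .cole import DerivedParameters
from .exceptions import DomainError, IncompleteDesignError
from .reference import percent_change as _signed_percent
from .spectra import GENDERS, MUSCLES

__all__ = [
    "ComparisonResult",
    "SubjectRecord",
    "Cohort",
    "bmi",
    "test_normality",
    "equal_variance",
    "mann_whitney",
    "t_test_unpaired",
    "compare_groups",
    "age_contrast",
    "gender_contrast",
]

ALPHA = 0.05
YOUNG_DECADES = (20, 30)
OLD_DECADES = (50, 60)


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical contrast between two groups of recordings."""

    parameter: str
    muscle: str
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    test_used: str          # "t_test" or "mann_whitney"
    statistic: float
    p_value: float
    percent_change: int     # baseline = group a
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError("p_value must lie in [0, 1]")
        if self.significant != (self.p_value <= ALPHA):
            raise DomainError("significant flag inconsistent with p_value")


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m²."""
    if weight_kg <= 0.0 or height_m <= 0.0:
        raise DomainError("weight and height must be positive")
    return weight_kg / height_m**2


@dataclass
class SubjectRecord:
    """One subject: demographics plus derived parameters per muscle (and side)."""

    subject_id: str
    gender: str
    age: float
    weight_kg: float
    height_m: float
    recordings: dict[tuple[str, str], DerivedParameters] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise DomainError(f"gender must be one of {GENDERS}")
        if not 20 <= self.age <= 69:
            raise DomainError(f"age must lie in [20, 69], got {self.age}")
        for muscle, _side in self.recordings:
            if muscle not in MUSCLES:
                raise DomainError(f"unknown muscle {muscle!r}")

    @property
    def age_decade(self) -> int:
        """Decade label: 20, 30, 40, 50 or 60."""
        return int(self.age // 10) * 10

    @property
    def bmi(self) -> float:
        return bmi(self.weight_kg, self.height_m)

    def values(self, muscle: str, parameter: str, sides: str = "all") -> list[float]:
        """Parameter values for one muscle: all recordings, or side-averaged.

        sides="all" yields one value per recording (bilateral muscles
        contribute two); sides="mean" averages sides to one value per
        subject (the convention behind the n = 25 normative cells).
        """
        vals = [
            drv.as_dict()[parameter]
            for (m, _side), drv in sorted(self.recordings.items())
            if m == muscle
        ]
        if not vals:
            return []
        if sides == "mean":
            return [float(np.mean(vals))]
        return vals


@dataclass
class Cohort:
    """A set of subjects with recordings; query surface for the contrasts."""

    subjects: list[SubjectRecord]

    def __len__(self) -> int:
        return len(self.subjects)

    def collect(
        self,
        muscle: str,
        parameter: str,
        gender: str | None = None,
        decades: tuple[int, ...] | None = None,
        sides: str = "all",
    ) -> np.ndarray:
        out: list[float] = []
        for s in self.subjects:
            if gender is not None and s.gender != gender:
                continue
            if decades is not None and s.age_decade not in decades:
                continue
            out.extend(s.values(muscle, parameter, sides=sides))
        return np.asarray(out, dtype=float)

    def decades_present(self, gender: str) -> set[int]:
        return {s.age_decade for s in self.subjects if s.gender == gender}


def test_normality(sample) -> tuple[float, float, bool]:
    """Shapiro–Wilk normality screen: (W, p, is_normal).

    is_normal means p > 0.05.  A constant sample is not testable and is
    returned as non-normal so callers route it nonparametrically.
    """
    a = np.asarray(sample, dtype=float)
    if len(a) < 3:
        raise DomainError("normality test needs at least 3 observations")
    if np.ptp(a) == 0.0:
        return float("nan"), float("nan"), False
    w, p = sps.shapiro(a)
    return float(w), float(p), bool(p > ALPHA)


def equal_variance(a, b) -> tuple[float, float, bool]:
    """Two-sided F-ratio test of equal variances: (F, p, is_equal)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("variance test needs at least 2 observations per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        return float("nan"), float("nan"), True
    if vb == 0.0 or va == 0.0:
        return float("inf"), 0.0, False
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    p = min(p, 1.0)
    return float(f), p, bool(p > ALPHA)


def _has_ties(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(a, b, exact_limit: int = 16) -> tuple[float, float]:
    """Mann–Whitney U test, two-sided: (U for group a, p).

    Exact p (full permutation distribution of U) when the pooled sample
    has at most ``exact_limit`` observations and no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DomainError("both samples must be non-empty")
    method = "exact" if (len(a) + len(b) <= exact_limit and not _has_ties(a, b)) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def t_test_unpaired(a, b, *, welch: bool = False) -> tuple[float, float]:
    """Two-tailed unpaired t-test, pooled variance by default: (t, p).

    The classical pooled form is the default; Welch's unequal-variance
    form is available via ``welch=True``.  Degenerate zero-variance input
    returns p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("t-test needs at least 2 observations per group")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_groups(
    a,
    b,
    context: str,
    *,
    parameter: str = "",
    muscle: str = "",
    group_a_label: str = "a",
    group_b_label: str = "b",
    welch: bool = False,
) -> ComparisonResult:
    """Route a two-group comparison the way the study protocol does.

    context="gender": always Mann–Whitney.  context="age": pooled t-test
    when both samples pass the Shapiro–Wilk screen and the F-ratio test
    finds homogeneous variances, else Mann–Whitney.  Percent change uses
    group means with group a as baseline, whatever test was routed.
    """
    if context not in ("gender", "age"):
        raise DomainError("context must be 'gender' or 'age'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if context == "gender":
        test_used = "mann_whitney"
    else:
        _, _, norm_a = test_normality(a)
        _, _, norm_b = test_normality(b)
        _, _, var_ok = equal_variance(a, b)
        test_used = "t_test" if (norm_a and norm_b and var_ok) else "mann_whitney"
    if test_used == "t_test":
        stat, p = t_test_unpaired(a, b, welch=welch)
    else:
        stat, p = mann_whitney(a, b)
    return ComparisonResult(
        parameter=parameter,
        muscle=muscle,
        group_a_label=group_a_label,
        group_b_label=group_b_label,
        n_a=len(a),
        n_b=len(b),
        test_used=test_used,
        statistic=stat,
        p_value=p,
        percent_change=_signed_percent(float(a.mean()), float(b.mean())),
        significant=bool(p <= ALPHA),
    )


def age_contrast(cohort: Cohort, muscle: str, parameter: str, gender: str) -> ComparisonResult:
    """Pooled-decade age comparison within gender: 20s+30s vs 50s+60s.

    Bilateral recordings both contribute (the gastrocnemius yields two
    per subject), other muscles one — at the reference design size that
    is 20 vs 20 recordings for the gastrocnemius and 10 vs 10 otherwise.
    """
    present = cohort.decades_present(gender)
    needed = set(YOUNG_DECADES) | set(OLD_DECADES)
    if not needed <= present:
        raise IncompleteDesignError(
            f"cohort lacks decades {sorted(needed - present)} for {gender}"
        )
    young = cohort.collect(muscle, parameter, gender=gender, decades=YOUNG_DECADES, sides="all")
    old = cohort.collect(muscle, parameter, gender=gender, decades=OLD_DECADES, sides="all")
    return compare_groups(
        young,
        old,
        context="age",
        parameter=parameter,
        muscle=muscle,
        group_a_label=f"{gender} 20+30",
        group_b_label=f"{gender} 50+60",
    )


def gender_contrast(cohort: Cohort, muscle: str, parameter: str, sides: str = "mean") -> ComparisonResult:
    """Women-versus-men comparison over the whole cohort (men = baseline).

    Side-averaged by default so each subject contributes one value,
    matching the n = 25 per gender of the normative cells.
    """
    men = cohort.collect(muscle, parameter, gender="men", sides=sides)
    women = cohort.collect(muscle, parameter, gender="women", sides=sides)
    if len(men) == 0 or len(women) == 0:
        raise IncompleteDesignError("gender contrast needs recordings for both genders")
    return compare_groups(
        men,
        women,
        context="gender",
        parameter=parameter,
        muscle=muscle,
        group_a_label="men",
        group_b_label="women",
    )
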