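"""Cohort summary tables, group comparisons, correlations, and the oral
food challenge (OFC) dose-schedule arithmetic.

Test dispatch follows the study-style plan: two independent groups get an
unpaired t test when both pass Shapiro-Wilk normality at alpha = 0.05,
otherwise Mann-Whitney; three or more groups get one-way ANOVA with
Bonferroni-adjusted pairwise t tests, or Kruskal-Wallis with Dunn's rank
post hoc; within-subject contrasts (e.g. Pru p 3 vs Ara h 9 in the same
subject) use the Wilcoxon signed-rank test.

Percentages in summary tables are reported to 2 decimals with half-up
rounding and always carry their numerator/denominator so they can be
audited.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

from .errors import InputError
from .types import SPT_POSITIVE_AREA_MM2, SubjectRecord

__all__ = [
    "percent", "spt_positive", "ofc_cumulative_dose", "summarize_cohort",
    "compare_groups", "correlate", "CohortSummary", "GroupComparisonResult",
]


def percent(numerator: int, denominator: int, ndigits: int = 2):
    """Exact-rational percentage, rounded half-up to ``ndigits`` decimals.

    Returns None for an empty denominator (an empty group is "missing",
    never 0%).
    """
    if denominator == 0:
        return None
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def spt_positive(area_mm2: float) -> bool:
    """Skin prick test read-out: wheal area >= 7 mm² is positive."""
    if area_mm2 < 0:
        raise InputError("wheal area must be >= 0")
    return area_mm2 >= SPT_POSITIVE_AREA_MM2


def ofc_cumulative_dose(dose_volumes_ml, mg_per_ml: float):
    """Per-dose and cumulative allergen mass for an OFC schedule.

    ``dose_volumes_ml`` are the successive administered volumes (mL);
    ``mg_per_ml`` the allergen concentration of the preparation. Returns
    ``(per_dose_mg, cumulative_mg)`` arrays; an empty schedule yields empty
    arrays (cumulative total 0).
    """
    vols = np.asarray(list(dose_volumes_ml), dtype=float)
    if mg_per_ml <= 0:
        raise InputError("dose concentration must be > 0 mg/mL")
    if vols.size and np.any(vols <= 0):
        raise InputError("dose volumes must be positive")
    per_dose = vols * mg_per_ml
    return per_dose, np.cumsum(per_dose)


@dataclass
class CohortSummary:
    """Per-group descriptive statistics plus audited derived percentages."""

    groups: dict                      # group label -> stats dict
    derived: dict = field(default_factory=dict)
    # derived: name -> {"numerator": int, "denominator": int, "percent": float}

    def audit(self) -> bool:
        """Every stored percentage must recompute from its own counts."""
        for name, d in self.derived.items():
            if percent(d["numerator"], d["denominator"]) != d["percent"]:
                return False
        for g in self.groups.values():
            for key in ("percent_female", "percent_profilin"):
                d = g.get(key)
                if d and percent(d["numerator"], d["denominator"]) != d["percent"]:
                    return False
        return True


def _median_iqr(values):
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return None
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def _count_pct(flags):
    n = len(flags)
    k = int(sum(flags))
    return {"numerator": k, "denominator": n, "percent": percent(k, n)}


def summarize_cohort(subjects) -> CohortSummary:
    """Descriptive table in the study-population style.

    Per group (controls, all allergic, each severity group): n, percent
    female, mean±SD age, median (Q1-Q3) for SPT areas and IgE levels,
    percent profilin-sensitized. Derived percentages (severity shares,
    peanut-tolerance split, SPT positivity within the peanut groups) keep
    their numerator/denominator.
    """
    if not subjects:
        raise InputError("cannot summarise an empty cohort")
    by_group = {"CONTROL": [s for s in subjects if s.cohort == "CONTROL"],
                "ALLERGIC": [s for s in subjects if s.cohort == "ALLERGIC"]}
    for sev in ("OAS", "URT_ANG", "ANAPH"):
        members = [s for s in by_group["ALLERGIC"] if s.severity == sev]
        if members:
            by_group[sev] = members

    groups = {}
    for label, members in by_group.items():
        if not members:
            continue
        ages = np.asarray([s.age for s in members], dtype=float)
        groups[label] = {
            "n": len(members),
            "percent_female": _count_pct([s.sex == "F" for s in members]),
            "age_mean": float(np.mean(ages)),
            "age_sd": float(np.std(ages, ddof=1)) if len(members) > 1 else 0.0,
            "spt_peach": _median_iqr([s.spt_peach_area for s in members]),
            "spt_peanut": _median_iqr([s.spt_peanut_area for s in members]),
            "total_ige": _median_iqr([s.total_ige for s in members]),
            "sige_prup3": _median_iqr([s.sige_prup3 for s in members]),
            "sige_arah9": _median_iqr([s.sige_arah9 for s in members]),
            "percent_profilin": _count_pct([s.profilin_sensitized for s in members]),
        }

    allergic = by_group["ALLERGIC"]
    n_all = len(allergic)
    group_a = [s for s in allergic if s.peanut_group == "A_TOLERANT"]
    group_b = [s for s in allergic if s.peanut_group == "B_ALLERGIC"]
    derived = {}

    def add(name, num, den):
        if den:
            derived[name] = {"numerator": num, "denominator": den,
                             "percent": percent(num, den)}

    for sev in ("OAS", "URT_ANG", "ANAPH"):
        add(f"share_{sev.lower()}_of_allergic",
            sum(1 for s in allergic if s.severity == sev), n_all)
    add("share_group_a_of_allergic", len(group_a), n_all)
    add("share_group_b_of_allergic", len(group_b), n_all)
    add("spt_peach_positive_in_group_a",
        sum(1 for s in group_a if spt_positive(s.spt_peach_area)), len(group_a))
    add("spt_peanut_positive_in_group_a",
        sum(1 for s in group_a if spt_positive(s.spt_peanut_area)), len(group_a))
    add("spt_peanut_positive_in_group_b",
        sum(1 for s in group_b if spt_positive(s.spt_peanut_area)), len(group_b))
    return CohortSummary(groups=groups, derived=derived)


@dataclass
class GroupComparisonResult:
    variable: str
    groups: tuple
    test: str
    statistic: float
    p_value: float
    adjusted_p: float = None
    direction: str = None           # label of the group with the larger centre

    def __post_init__(self):
        for p in (self.p_value, self.adjusted_p):
            if p is not None and not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise InputError(f"p-value {p} outside [0, 1]")


def _is_normal(x, alpha=0.05):
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def _direction(values_by_group, keys):
    meds = {k: float(np.median(values_by_group[k])) for k in keys}
    return max(meds, key=meds.get)


def _dunn_posthoc(values_by_group, variable):
    """Dunn's rank-based post hoc z tests after Kruskal-Wallis, with tie
    correction and Bonferroni-style adjustment over all pairs."""
    keys = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[k], float) for k in keys])
    ranks = stats.rankdata(pooled)
    n_tot = len(pooled)
    rank_by = {}
    start = 0
    for k in keys:
        n_k = len(values_by_group[k])
        rank_by[k] = ranks[start:start + n_k]
        start += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    m = len(keys) * (len(keys) - 1) // 2
    results = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i], keys[j]
            se = np.sqrt(var_base * (1.0 / len(rank_by[a]) + 1.0 / len(rank_by[b])))
            z = (np.mean(rank_by[a]) - np.mean(rank_by[b])) / se
            p = 2.0 * stats.norm.sf(abs(z))
            results.append(GroupComparisonResult(
                variable=variable, groups=(a, b), test="Dunn",
                statistic=float(z), p_value=float(p),
                adjusted_p=float(min(1.0, m * p)),
                direction=a if z > 0 else b))
    return results


def compare_groups(values_by_group: dict, design: str = "independent",
                   scale: str = "auto", variable: str = "value"):
    """Dispatch the study's comparison battery for one variable.

    ``values_by_group`` maps group label -> 1-D values. Two independent
    groups: unpaired t (parametric) or Mann-Whitney; more: ANOVA +
    Bonferroni pairwise t, or Kruskal-Wallis + Dunn. ``design='paired'``
    (two equal-length groups) uses the Wilcoxon signed-rank test (or paired
    t when parametric). ``scale='auto'`` decides by per-group Shapiro-Wilk
    normality at alpha = 0.05; ``'parametric'``/``'nonparametric'`` force
    the family. Returns a single result for two groups, else
    ``[omnibus, *pairwise]``.
    """
    keys = list(values_by_group)
    if len(keys) < 2:
        raise InputError("need at least two groups")
    arrays = {k: np.asarray(values_by_group[k], dtype=float) for k in keys}
    for k, v in arrays.items():
        if v.size == 0:
            raise InputError(f"group {k!r} is empty")

    if scale == "auto":
        parametric = all(_is_normal(v) for v in arrays.values())
    elif scale in ("parametric", "nonparametric"):
        parametric = scale == "parametric"
    else:
        raise InputError(f"unknown scale {scale!r}")

    if design == "paired":
        if len(keys) != 2:
            raise InputError("paired design needs exactly two groups")
        a, b = arrays[keys[0]], arrays[keys[1]]
        if len(a) != len(b):
            raise InputError("paired groups must have equal length")
        if parametric:
            st = stats.ttest_rel(a, b)
            test = "paired-t"
        else:
            if np.all(a == b):
                return GroupComparisonResult(variable, tuple(keys),
                                             "Wilcoxon-paired", 0.0, 1.0,
                                             direction=keys[0])
            st = stats.wilcoxon(a, b)
            test = "Wilcoxon-paired"
        return GroupComparisonResult(
            variable, tuple(keys), test, float(st.statistic),
            float(st.pvalue), direction=_direction(arrays, keys))
    if design != "independent":
        raise InputError(f"unknown design {design!r}")

    if len(keys) == 2:
        a, b = arrays[keys[0]], arrays[keys[1]]
        if parametric:
            if min(len(a), len(b)) < 2:
                raise InputError("t test needs n >= 2 per group")
            st = stats.ttest_ind(a, b)
            test = "unpaired-t"
        else:
            if np.ptp(np.concatenate([a, b])) == 0:
                return GroupComparisonResult(variable, tuple(keys),
                                             "Mann-Whitney",
                                             float(len(a) * len(b) / 2), 1.0,
                                             direction=keys[0])
            method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
            st = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            test = "Mann-Whitney"
        return GroupComparisonResult(
            variable, tuple(keys), test, float(st.statistic), float(st.pvalue),
            direction=_direction(arrays, keys))

    # Omnibus + post hoc for >= 3 groups.
    samples = [arrays[k] for k in keys]
    if parametric:
        for k, v in arrays.items():
            if v.size < 2:
                raise InputError(f"ANOVA needs n >= 2 in group {k!r}")
        st = stats.f_oneway(*samples)
        omnibus = GroupComparisonResult(variable, tuple(keys), "ANOVA",
                                        float(st.statistic), float(st.pvalue))
        m = len(keys) * (len(keys) - 1) // 2
        posthoc = []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = keys[i], keys[j]
                t = stats.ttest_ind(arrays[a], arrays[b])
                posthoc.append(GroupComparisonResult(
                    variable, (a, b), "t+Bonferroni", float(t.statistic),
                    float(t.pvalue), adjusted_p=float(min(1.0, m * t.pvalue)),
                    direction=_direction(arrays, (a, b))))
    else:
        st = stats.kruskal(*samples)
        omnibus = GroupComparisonResult(variable, tuple(keys), "Kruskal-Wallis",
                                        float(st.statistic), float(st.pvalue))
        posthoc = _dunn_posthoc(arrays, variable)
    return [omnibus, *posthoc]


def correlate(x, y, method: str = "spearman"):
    """Correlation coefficient and two-sided p; NaN pairs dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InputError("need >= 3 complete pairs")
    if method.lower() == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method.lower() == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    return float(r), float(p)
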