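"""Summary-table arithmetic, test dispatch, correlations, OFC dosing."""
import itertools

import numpy as np
import pytest

from batdx import (
    compare_groups, correlate, ofc_cumulative_dose, percent, spt_positive,
    summarize_cohort,
)
from batdx.errors import InputError
from batdx.types import SubjectRecord


def subject(i, cohort="ALLERGIC", severity="OAS", peanut_group="A_TOLERANT",
            sex="F", spt_peach=50.0, spt_peanut=40.0, profilin=False):
    return SubjectRecord(f"S{i:03d}", cohort,
                         "NONE" if cohort == "CONTROL" else severity,
                         "NA" if cohort == "CONTROL" else peanut_group,
                         profilin, 30.0, sex, 100.0, 5.0, 2.0,
                         spt_peach, spt_peanut)


def study_flow_cohort():
    """Cohort with the group sizes and SPT-positivity counts of the study
    flow: 16 controls; 92 allergic = 23 OAS + 44 URT/ANG + 25 ANAPH;
    55 peanut-tolerant (Group A, 54/55 SPT-peach positive) and 37
    peanut-allergic (Group B, 31/37 SPT-peanut positive)."""
    subjects = [subject(i, cohort="CONTROL", spt_peach=2, spt_peanut=2)
                for i in range(16)]
    severities = ["OAS"] * 23 + ["URT_ANG"] * 44 + ["ANAPH"] * 25
    n_a = 0
    for j, sev in enumerate(severities):
        group = "A_TOLERANT" if j < 55 else "B_ALLERGIC"
        spt_peach = 50.0
        spt_peanut = 40.0
        if group == "A_TOLERANT":
            n_a += 1
            if n_a == 55:         # exactly one Group A subject SPT-peach negative
                spt_peach = 3.0
        else:
            if j >= 92 - 6:       # six Group B subjects SPT-peanut negative
                spt_peanut = 3.0
        subjects.append(subject(100 + j, severity=sev, peanut_group=group,
                                spt_peach=spt_peach, spt_peanut=spt_peanut))
    return subjects


class TestPercent:
    @pytest.mark.parametrize("num, den, expected", [
        (37, 92, 40.22), (55, 92, 59.78), (54, 55, 98.18), (23, 92, 25.0),
        (44, 92, 47.83), (25, 92, 27.17), (31, 37, 83.78), (12, 55, 21.82),
    ])
    def test_round_half_up_to_two_decimals(self, num, den, expected):
        assert percent(num, den) == expected

    def test_half_up_tie(self):
        assert percent(1, 8) == 12.5
        assert percent(125, 1000, ndigits=1) == 12.5
        assert percent(1, 16) == 6.25  # exact two-decimal value kept

    def test_empty_denominator_missing(self):
        assert percent(0, 0) is None


class TestSummarizeCohort:
    def test_study_flow_percentages(self):
        summary = summarize_cohort(study_flow_cohort())
        d = summary.derived
        assert d["share_group_b_of_allergic"]["percent"] == 40.22
        assert d["share_group_a_of_allergic"]["percent"] == 59.78
        assert d["share_oas_of_allergic"]["percent"] == 25.0
        assert d["share_urt_ang_of_allergic"]["percent"] == 47.83
        assert d["share_anaph_of_allergic"]["percent"] == 27.17
        assert d["spt_peach_positive_in_group_a"]["percent"] == 98.18
        assert d["spt_peanut_positive_in_group_b"]["percent"] == 83.78
        assert summary.groups["ALLERGIC"]["n"] == 92
        assert summary.groups["CONTROL"]["n"] == 16

    def test_self_consistency_audit(self, small_cohort):
        subjects, _ = small_cohort
        assert summarize_cohort(subjects).audit()
        assert summarize_cohort(study_flow_cohort()).audit()

    def test_single_subject(self):
        summary = summarize_cohort([subject(0, sex="M")])
        g = summary.groups["ALLERGIC"]
        assert g["n"] == 1
        assert g["percent_female"]["percent"] in (0.0, 100.0)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            summarize_cohort([])


def oracle_mannwhitney(a, b):
    """Exhaustive U and exact two-sided p by label enumeration."""
    a, b = list(a), list(b)
    u_obs = sum(x > y for x in a for y in b) + 0.5 * sum(x == y for x in a for y in b)
    pooled = a + b
    n = len(a)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(x > y for x in ga for y in gb)
                  + 0.5 * sum(x == y for x in ga for y in gb))
    mu = len(a) * len(b) / 2
    p = sum(abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us) / len(us)
    return u_obs, p


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]},
                             scale="nonparametric")
        assert res.test == "Mann-Whitney"
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_minimal_p(self):
        res = compare_groups({"lo": [1, 2, 3], "hi": [101, 102, 103]},
                             scale="nonparametric")
        # U for 'lo' over 'hi' is 0; exact two-sided p = 2 / C(6,3)
        assert res.statistic in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)
        assert res.direction == "hi"

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            # continuous draws: tie-free almost surely, so the permutation
            # oracle and the exact U distribution coincide
            a = rng.uniform(0, 10, size=5)
            b = rng.uniform(0, 10, size=4)
            res = compare_groups({"a": list(a), "b": list(b)}, scale="nonparametric")
            u, p = oracle_mannwhitney(a, b)
            assert res.statistic in (pytest.approx(u), pytest.approx(len(a) * len(b) - u))
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_statistic_matches_pairwise_count_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.integers(0, 6, size=6).astype(float)
            b = rng.integers(0, 6, size=5).astype(float)
            if np.ptp(np.r_[a, b]) == 0:
                continue
            res = compare_groups({"a": list(a), "b": list(b)}, scale="nonparametric")
            u = (sum(x > y for x in a for y in b)
                 + 0.5 * sum(x == y for x in a for y in b))
            assert res.statistic in (pytest.approx(u), pytest.approx(len(a) * len(b) - u))

    def test_anova_bonferroni_adjustment_exact(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.normal(i, 1, 12) for i, k in enumerate("abc")}
        results = compare_groups(groups, scale="parametric")
        omnibus, posthoc = results[0], results[1:]
        assert omnibus.test == "ANOVA"
        assert len(posthoc) == 3
        for r in posthoc:
            assert r.adjusted_p == pytest.approx(min(1.0, 3 * r.p_value))
            assert r.adjusted_p >= r.p_value

    def test_kruskal_dunn_pipeline(self):
        rng = np.random.default_rng(13)
        groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
                  "c": rng.normal(3, 1, 15)}
        results = compare_groups(groups, scale="nonparametric")
        omnibus, posthoc = results[0], results[1:]
        assert omnibus.test == "Kruskal-Wallis"
        assert omnibus.p_value < 0.01
        dunn = {tuple(sorted(r.groups)): r for r in posthoc}
        assert dunn[("a", "c")].adjusted_p < 0.05
        assert dunn[("a", "b")].adjusted_p > 0.05
        for r in posthoc:
            assert r.adjusted_p >= r.p_value

    def test_dunn_adjustment_monotone_in_raw_p(self):
        rng = np.random.default_rng(29)
        groups = {k: rng.normal(i * 0.8, 1, 12) for i, k in enumerate("abcd")}
        posthoc = compare_groups(groups, scale="nonparametric")[1:]
        by_raw = sorted(posthoc, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in by_raw]
        assert adj == sorted(adj)

    def test_paired_wilcoxon(self):
        x = np.arange(1.0, 13.0)
        res = compare_groups({"prup3": x + 5, "arah9": x}, design="paired",
                             scale="nonparametric")
        assert res.test == "Wilcoxon-paired"
        assert res.p_value < 0.01
        assert res.direction == "prup3"

    def test_paired_identical_p_one(self):
        res = compare_groups({"x": [1, 2, 3, 4], "y": [1, 2, 3, 4]},
                             design="paired", scale="nonparametric")
        assert res.p_value == 1.0

    def test_auto_dispatch_logged_choice(self):
        # heavily skewed data -> Shapiro fails -> nonparametric branch
        rng = np.random.default_rng(33)
        skewed = {"a": np.exp(rng.normal(0, 2, 20)), "b": np.exp(rng.normal(1, 2, 20))}
        res = compare_groups(skewed, scale="auto")
        assert res.test == "Mann-Whitney"
        normalish = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.2, 1, 30)}
        res2 = compare_groups(normalish, scale="auto")
        assert res2.test == "unpaired-t"

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups({"a": [1, 2], "b": []})


class TestCorrelate:
    def test_monotone_transform_spearman_one(self):
        x = np.arange(10.0)
        r, _ = correlate(x, 2 * x, method="spearman")
        assert r == pytest.approx(1.0)

    def test_negative(self):
        x = np.arange(10.0)
        r, _ = correlate(x, -x, method="pearson")
        assert r == pytest.approx(-1.0)

    def test_nan_pairs_dropped(self):
        x = np.array([1, 2, 3, 4, np.nan])
        y = np.array([2, 4, 6, 8, 10.0])
        r, _ = correlate(x, y, method="pearson")
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InputError):
            correlate([1, 2], [3, 4])

    def test_cdsens_auc_strongly_correlated_in_synthetic_responders(
            self, small_cohort, concentrations):
        """Basophil sensitivity (CD-sens) and reactivity (curve AUC) share a
        latent factor in the generator, so responders show a strong positive
        rank correlation (r > 0.7)."""
        from batdx import fit_curve

        subjects, series = small_cohort
        cohort = {s.subject_id: s.cohort for s in subjects}
        fits = [fit_curve(s, concentrations) for s in series
                if s.marker == "CD63" and s.allergen == "PRU_P_3"
                and cohort[s.subject_id] == "ALLERGIC"]
        pairs = [(f.cd_sens, f.curve_auc) for f in fits if np.isfinite(f.cd_sens)]
        cd, auc = map(np.asarray, zip(*pairs))
        r, p = correlate(np.log10(cd), auc, method="spearman")
        assert r > 0.7
        assert p < 0.01


class TestSptAndOfc:
    @pytest.mark.parametrize("area, expected", [
        (7.0, True), (6.99, False), (52.0, True), (0.0, False),
    ])
    def test_spt_positive_threshold(self, area, expected):
        assert spt_positive(area) is expected

    def test_ofc_starting_dose(self):
        per_dose, cumulative = ofc_cumulative_dose([5.0], 6.2)
        assert per_dose[0] == pytest.approx(31.0)
        assert cumulative[-1] == pytest.approx(31.0)

    def test_ofc_full_schedule_cumulative(self):
        # six escalating volumes totalling 250 mL at 6.2 mg/mL -> 1550 mg
        volumes = [5.0, 10.0, 20.0, 40.0, 75.0, 100.0]
        per_dose, cumulative = ofc_cumulative_dose(volumes, 6.2)
        assert sum(volumes) == 250.0
        assert cumulative[-1] == pytest.approx(1550.0)
        np.testing.assert_allclose(np.cumsum(per_dose), cumulative)

    def test_ofc_empty_schedule(self):
        per_dose, cumulative = ofc_cumulative_dose([], 6.2)
        assert per_dose.size == 0 and cumulative.size == 0
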