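import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunorhythm import (CohortTable, adjacent_comparisons, generate_cohort,
                          mann_whitney, study_params,
                          sex_matched_comparisons, star_code)
from immunorhythm.rhythms import comparisons_to_frame, significance_table

from conftest import make_cohort_frame


def mw_exact_oracle(x, y):
    """Brute-force two-sided exact Mann-Whitney p: enumerate every split of
    the pooled sample into the two groups and use the symmetric two-tail
    rule on min(U1, U2), clipped at 1."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    nm = n * m
    u_obs = min(_u_stat(x, y), _u_stat(y, x))
    count = 0
    total = 0
    idx = np.arange(n + m)
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(n + m, bool)
        mask[list(comb)] = True
        u1 = _u_stat(pooled[mask], pooled[~mask])
        total += 1
        count += (u1 <= u_obs + 1e-12) + (u1 >= nm - u_obs - 1e-12)
    return min(count / total, 1.0)


def _u_stat(x, y):
    # pairs with x > y, ties counted half
    x = np.asarray(x)[:, None]
    y = np.asarray(y)[None, :]
    return float((x > y).sum() + 0.5 * (x == y).sum())


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u == 4.5
        assert res.p == 1.0

    def test_clear_separation_small_n(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.method == "exact"
        assert math.isclose(res.p, 2 / 6, rel_tol=1e-12)

    @pytest.mark.parametrize("nx,ny,seed", [
        (3, 3, 0), (4, 5, 1), (5, 5, 2), (6, 4, 3), (8, 8, 4), (2, 7, 5),
    ])
    def test_exact_p_matches_enumeration(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=nx)
        y = rng.normal(size=ny)  # continuous: no ties
        res = mann_whitney(x, y, mode="exact")
        assert res.method == "exact"
        assert math.isclose(res.p, mw_exact_oracle(x, y), rel_tol=1e-9)

    def test_exact_mode_with_ties_falls_back(self):
        res = mann_whitney([1, 1, 2], [1, 3, 3], mode="exact")
        assert res.method == "normal"
        assert "ties" in res.note

    def test_all_identical_degenerate(self):
        res = mann_whitney([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=10),
           st.lists(st.integers(0, 5), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_u_partition_property(self, xs, ys):
        # U_x + U_y = n_x * n_y with ties counted half to each side
        ux = _u_stat(xs, ys)
        uy = _u_stat(ys, xs)
        assert ux + uy == len(xs) * len(ys)
        assert mann_whitney(xs, ys).u == min(ux, uy) or \
            mann_whitney(xs, ys).method == "degenerate"


class TestStarCode:
    @pytest.mark.parametrize("p,stars", [
        (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.03, "*"),
        (0.011, "*"), (0.01, "**"), (0.0011, "**"), (0.001, "***"),
        (0.00011, "***"), (0.0001, "****"), (1e-7, "****"), (0.0, "****"),
        (1.0, "ns"),
    ])
    def test_coding_rule_boundaries_inclusive(self, p, stars):
        assert star_code(p) == stars

    @pytest.mark.parametrize("p", [-0.1, 1.2, float("nan")])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError):
            star_code(p)


class TestAdjacentComparisons:
    def test_sixty_results_for_six_groups(self, study_cohort):
        res = adjacent_comparisons(study_cohort)
        assert len(res) == 60
        assert all(r.stratum == "ALL" for r in res)
        frame = comparisons_to_frame(res)
        assert set(frame["group_a"]) == set(study_cohort.scheme.labels[:-1])

    def test_empty_group_skipped_with_warning(self):
        params = study_params()
        params.group_sizes["3-4Yrs"] = (0, 0)
        cohort = generate_cohort(params, seed=0)
        with pytest.warns(UserWarning, match="skipping"):
            res = adjacent_comparisons(cohort)
        assert len(res) == 36  # 3 remaining adjacent pairs x 12

    def test_direction_follows_later_group_median(self, study_cohort):
        res = adjacent_comparisons(study_cohort)
        for r in res:
            med_a = np.median(study_cohort.subset(r.group_a)[r.phenotype])
            med_b = np.median(study_cohort.subset(r.group_b)[r.phenotype])
            expected = ("increase" if med_b > med_a
                        else "decrease" if med_b < med_a else "none")
            assert r.direction == expected

    def test_injected_memory_rise_detected(self):
        # the preset carries a latent EMCD4 rise from 5-7Yrs to 8-10Yrs
        params = study_params()
        for seed in range(5):
            cohort = generate_cohort(params, seed=seed)
            res = adjacent_comparisons(cohort)
            hit = next(r for r in res if r.phenotype == "EMCD4"
                       and r.group_a == "5-7Yrs")
            assert hit.p < 0.05
            assert hit.direction == "increase"

    def test_bh_adjustment_flag(self, study_cohort):
        res = adjacent_comparisons(study_cohort, adjust=True)
        assert all(r.p_adjusted is not None and r.p_adjusted >= r.p
                   for r in res)

    def test_significance_table_shape(self, study_cohort):
        tab = significance_table(adjacent_comparisons(study_cohort))
        assert tab.shape == (12, 5)


class TestSexMatched:
    def test_seventy_two_results(self, study_cohort):
        assert len(sex_matched_comparisons(study_cohort)) == 72

    def test_identical_sexes_yield_no_significance(self):
        # duplicate each male row as a female row: distributions identical
        df = make_cohort_frame(n=30, sexes=np.array(["male"] * 30))
        dup = df.copy()
        dup["sex"] = "female"
        dup["subject_id"] = dup["subject_id"] + "F"
        cohort = CohortTable(
            __import__("pandas").concat([df, dup], ignore_index=True))
        res = sex_matched_comparisons(cohort)
        assert all(r.p == 1.0 for r in res)
        assert sum(r.p < 0.05 for r in res) == 0

    def test_preset_sex_differences_detected(self):
        # the preset's only sex effects: NCD4 at 8-10Yrs, eEFCD8 at 11-18Yrs
        params = study_params()
        hits = {"NCD4": 0, "eEFCD8": 0}
        for seed in range(5):
            res = sex_matched_comparisons(generate_cohort(params, seed=seed))
            for r in res:
                if r.phenotype == "NCD4" and r.group_a.startswith("8-10") \
                        and r.p < 0.05:
                    hits["NCD4"] += 1
                if r.phenotype == "eEFCD8" and r.group_a.startswith("11-18") \
                        and r.p < 0.05:
                    hits["eEFCD8"] += 1
        assert hits["NCD4"] >= 4
        assert hits["eEFCD8"] >= 4
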