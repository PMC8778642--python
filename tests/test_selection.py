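"""Rank-sum testing, pairwise contrasts and recurrence selection.

The exact Mann-Whitney p is checked against an independent brute-force
oracle that enumerates every C(n+m, n) assignment of the pooled values and
computes U by pair counting — a different algorithm from the package's
rank-sum subset-sum recursion.
"""

import itertools
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from adaptasome import (
    SelectionConfig,
    compare_pair,
    group_medians,
    mann_whitney,
    run_selection,
    select_adaptasome,
    shapiro_wilk_diagnostic,
)
from adaptasome import default_scenario, generate_counts
from adaptasome.annotation_ingest import FamilyCountMatrix

from conftest import SPLIT_PAIRS


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_mww(x, y):
    """Exact two-sided MWW by full enumeration and pair counting."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(sample_x, sample_y):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in sample_x
            for b in sample_y
        )

    u_obs = u_of(x, y)
    center = n * (len(pooled) - n) / 2.0
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if abs(u_of(xs, ys) - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def bh_reject(pvalues, alpha):
    """Step-up Benjamini-Hochberg, written independently of statsmodels."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if pvalues[i] <= alpha * rank / m:
            kmax = rank
    rejected = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= kmax:
            rejected[i] = True
    return rejected


# ---------------------------------------------------------------------------
# mann_whitney


class TestMannWhitney:
    def test_worked_example_complete_separation(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 of 20 assignments

    def test_all_ties_degenerate(self):
        _, p = mann_whitney([2, 2], [2, 2])
        assert p == 1.0

    def test_swap_symmetry(self):
        x, y = [1.0, 5.0, 2.5, 7.0], [3.0, 4.0, 9.0]
        u_xy, p_xy = mann_whitney(x, y)
        u_yx, p_yx = mann_whitney(y, x)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)
        assert u_yx == pytest.approx(len(x) * len(y) - u_xy)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_matches_brute_force_on_seeded_samples(self):
        """Exact p equals full enumeration for all n, m <= 6 (50 seeded draws)."""
        rng = np.random.default_rng(1234)
        cases = 0
        for n in range(1, 7):
            for m in range(n, 7):
                for _ in range(2):
                    if cases >= 50:
                        break
                    x = rng.integers(0, 30, size=n).astype(float)
                    y = rng.integers(0, 30, size=m).astype(float)
                    u, p = mann_whitney(x, y, mode="exact")
                    u_ref, p_ref = brute_force_mww(x, y)
                    assert u == pytest.approx(u_ref, abs=1e-12)
                    assert p == pytest.approx(p_ref, abs=1e-12)
                    cases += 1

    def test_exact_matches_scipy_on_tie_free_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pooled = rng.choice(1000, size=9, replace=False).astype(float)
            x, y = pooled[:4], pooled[4:]
            _, p = mann_whitney(x, y, mode="exact")
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @given(
        x=st.lists(st.integers(0, 8), min_size=1, max_size=6),
        y=st.lists(st.integers(0, 8), min_size=1, max_size=6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_equals_enumeration_with_ties(self, x, y):
        u, p = mann_whitney(x, y, mode="exact")
        u_ref, p_ref = brute_force_mww(x, y)
        assert u == pytest.approx(u_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_approx_close_to_exact_for_small_tie_free(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            pooled = rng.choice(500, size=12, replace=False).astype(float)
            x, y = pooled[:6], pooled[6:]
            _, p_exact = mann_whitney(x, y, mode="exact")
            _, p_approx = mann_whitney(x, y, mode="approx")
            assert abs(p_exact - p_approx) <= 0.05

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1], [2], mode="bayes")


class TestShapiroDiagnostic:
    def test_constant_input_not_assessable(self):
        res = shapiro_wilk_diagnostic([5, 5, 5, 5])
        assert not res.assessable

    def test_tiny_sample_not_assessable(self):
        assert not shapiro_wilk_diagnostic([1.0, 2.0]).assessable

    def test_null_calibration_on_normal_draws(self):
        """False-rejection rate of normal data is near the nominal 5%."""
        rng = np.random.default_rng(42)
        rejections = sum(
            shapiro_wilk_diagnostic(rng.normal(size=2000)).p_value < 0.05
            for _ in range(200)
        )
        assert 0.01 <= rejections / 200 <= 0.09

    def test_power_on_exponential_draws(self):
        rng = np.random.default_rng(43)
        rejections = sum(
            shapiro_wilk_diagnostic(rng.exponential(size=200)).p_value < 0.05
            for _ in range(200)
        )
        assert rejections / 200 >= 0.95


# ---------------------------------------------------------------------------
# medians and contrasts


class TestGroupMedians:
    def test_even_size_midpoint(self, split_matrix):
        med = group_medians(split_matrix, ["o1", "o2", "o3", "o4"])
        assert med[("MEROPS", "F01")] == pytest.approx(1.5)

    def test_singleton(self, split_matrix):
        med = group_medians(split_matrix, ["o5"])
        assert med[("MEROPS", "F01")] == 10

    def test_permutation_invariance(self, split_matrix):
        a = group_medians(split_matrix, ["o1", "o3", "o5", "o7"])
        b = group_medians(split_matrix, ["o7", "o1", "o5", "o3"])
        assert (a == b).all()

    def test_empty_members_rejected(self, split_matrix):
        with pytest.raises(ValueError):
            group_medians(split_matrix, [])


def oracle_contrast(matrix, ecology, label_a, label_b, config):
    """Recompute one contrast with plain-Python medians, brute-force exact p
    (tie-free small samples) and a hand-rolled BH step."""
    members_a = ecology.group_members(label_a)
    members_b = ecology.group_members(label_b)
    meds, pvals, diffs = {}, {}, {}
    for key in matrix.families:
        xa = [matrix.counts(o, key) for o in members_a]
        xb = [matrix.counts(o, key) for o in members_b]
        meds[key] = (statistics.median(xa), statistics.median(xb))
        diffs[key] = abs(meds[key][0] - meds[key][1])
        pooled = xa + xb
        if len(set(pooled)) == len(pooled) and len(pooled) <= 12:
            _, pvals[key] = brute_force_mww(xa, xb)
        elif len(set(pooled)) == 1:
            pvals[key] = 1.0
        else:
            pvals[key] = float(
                stats.mannwhitneyu(
                    xa, xb, alternative="two-sided", method="asymptotic"
                ).pvalue
            )
    fams = list(matrix.families)
    if config.correction == "bh":
        sig = dict(zip(fams, bh_reject([pvals[f] for f in fams], config.alpha)))
    else:
        sig = {f: pvals[f] < config.alpha for f in fams}
    eligible = [f for f in fams if diffs[f] > 0 and (sig[f] or not config.gate_by_significance)]
    ranked = sorted(eligible, key=lambda f: (-diffs[f], pvals[f], f[1], f[0]))
    return set(ranked[: config.max_k]), pvals, sig


class TestComparePair:
    @pytest.mark.parametrize("correction", [None, "bh"])
    def test_top10_matches_oracle_on_split_fixture(
        self, split_matrix, split_ecology, correction
    ):
        config = SelectionConfig(pairs=SPLIT_PAIRS, correction=correction)
        for label_a, label_b in SPLIT_PAIRS:
            contrast = compare_pair(
                split_matrix, split_ecology, label_a, label_b, config
            )
            expected_top, pvals, _sig = oracle_contrast(
                split_matrix, split_ecology, label_a, label_b, config
            )
            assert set(contrast.top10) == expected_top
            for key, p_ref in pvals.items():
                assert contrast.table.loc[key, "p_value"] == pytest.approx(
                    p_ref, abs=1e-9
                )

    def test_main_split_crowds_out_smallest_difference(
        self, split_matrix, split_ecology, split_config
    ):
        contrast = compare_pair(
            split_matrix, split_ecology, "saprotroph", "pathogen", split_config
        )
        top = set(contrast.top10)
        assert ("MEROPS", "F01") not in top  # rank 11 by median difference
        assert len(top) == 10

    def test_identical_membership_yields_no_top10(self, split_matrix, split_ecology):
        cfg = SelectionConfig(pairs=(("pathogen", "living_in_water"),))
        contrast = compare_pair(
            split_matrix, split_ecology, "pathogen", "living_in_water", cfg
        )
        assert (contrast.table["abs_median_diff"] == 0).all()
        assert contrast.top10 == []

    def test_max_k_zero_empty_top10(self, split_matrix, split_ecology):
        cfg = SelectionConfig(max_k=0)
        contrast = compare_pair(split_matrix, split_ecology, "saprotroph", "pathogen", cfg)
        assert contrast.top10 == []

    def test_empty_group_skipped_with_warning(self, split_matrix, split_ecology, caplog):
        with caplog.at_level("WARNING", logger="adaptasome.selection"):
            contrast = compare_pair(
                split_matrix, split_ecology, "saprotroph", "endophyte"
            )
        assert contrast is None
        assert "skipped" in caplog.text

    def test_drop_shared_excludes_overlap_from_both_sides(
        self, split_matrix, split_ecology
    ):
        cfg = SelectionConfig(drop_shared=True)
        contrast = compare_pair(
            split_matrix, split_ecology, "saprotroph", "commensal", cfg
        )
        # saprotroph = o1..o4, commensal = o1,o2,o5,o6; shared o1,o2 dropped
        assert (contrast.n_a, contrast.n_b) == (2, 2)

    def test_scale_equivariance(self, split_matrix, split_ecology, split_config):
        scaled = FamilyCountMatrix(split_matrix.data * 7)
        for label_a, label_b in SPLIT_PAIRS[:2]:
            base = compare_pair(split_matrix, split_ecology, label_a, label_b, split_config)
            big = compare_pair(scaled, split_ecology, label_a, label_b, split_config)
            np.testing.assert_allclose(
                base.table["p_value"], big.table["p_value"], atol=1e-12
            )
            assert base.top10 == big.top10


class TestSelectAdaptasome:
    def test_recurrence_threshold(self, split_matrix, split_ecology, split_config):
        contrasts, selection, _ = run_selection(split_matrix, split_ecology, split_config)
        rec = dict(
            zip(
                zip(selection.table["database"], selection.table["family"]),
                selection.table["recurrence"],
            )
        )
        # F02..F11 recur in the three duplicated main-split pairs; F12 once
        for j in range(2, 12):
            db = ("MEROPS", "CAZY", "TCDB")[(j - 1) // 4]
            assert rec[(db, f"F{j:02d}")] == 3
        assert rec[("TCDB", "F12")] == 1
        assert ("MEROPS", "F01") not in rec
        assert set(selection.selected) == {
            (("MEROPS", "CAZY", "TCDB")[(j - 1) // 4], f"F{j:02d}") for j in range(2, 12)
        }

    def test_min_recurrence_monotonicity(self, split_matrix, split_ecology, split_config):
        contrasts, _, _ = run_selection(split_matrix, split_ecology, split_config)
        previous = None
        for k in range(1, 6):
            selected = set(select_adaptasome(contrasts, min_recurrence=k).selected)
            if previous is not None:
                assert selected <= previous
            previous = selected

    def test_removing_contrast_never_increases_recurrence(
        self, split_matrix, split_ecology, split_config
    ):
        contrasts, _, _ = run_selection(split_matrix, split_ecology, split_config)
        full = select_adaptasome(contrasts).table.set_index(["database", "family"])
        partial = select_adaptasome(contrasts[:-1]).table.set_index(["database", "family"])
        for key, row in partial.iterrows():
            assert row["recurrence"] <= full.loc[key, "recurrence"]

    def test_empty_contrast_list(self):
        selection = select_adaptasome([])
        assert selection.table.empty

    def test_reference_annotation_joined_but_not_selective(
        self, split_matrix, split_ecology, split_config
    ):
        import pandas as pd

        contrasts, _, _ = run_selection(split_matrix, split_ecology, split_config)
        ref = pd.DataFrame(
            {
                "family": ["F02"],
                "database": ["MEROPS"],
                "predicted_name": ["subtilisin-like"],
                "putative_role": ["Nutrition"],
            }
        )
        ann = select_adaptasome(contrasts, reference=ref)
        bare = select_adaptasome(contrasts)
        assert list(ann.table["family"]) == list(bare.table["family"])
        row = ann.table[ann.table["family"] == "F02"].iloc[0]
        assert row["predicted_name"] == "subtilisin-like"


class TestRunSelection:
    def test_row_permutation_changes_nothing(self, split_matrix, split_ecology, split_config):
        _, sel_a, summ_a = run_selection(split_matrix, split_ecology, split_config)
        shuffled = FamilyCountMatrix(split_matrix.data.iloc[::-1])
        _, sel_b, summ_b = run_selection(shuffled, split_ecology, split_config)
        assert sel_a.table.equals(sel_b.table)
        assert summ_a["selected_by_database"] == summ_b["selected_by_database"]

    def test_min_recurrence_above_pair_count_empty(
        self, split_matrix, split_ecology
    ):
        cfg = SelectionConfig(pairs=SPLIT_PAIRS, min_recurrence=10)
        _, selection, _ = run_selection(split_matrix, split_ecology, cfg)
        assert selection.selected == []

    def test_empty_pair_list_rejected(self, split_matrix, split_ecology):
        with pytest.raises(ValueError):
            run_selection(split_matrix, split_ecology, SelectionConfig(pairs=()))

    def test_summary_reports_database_breakdown(
        self, split_matrix, split_ecology, split_config
    ):
        _, _, summary = run_selection(split_matrix, split_ecology, split_config)
        assert summary["n_selected"] == 10
        assert summary["selected_by_database"] == {"CAZY": 4, "MEROPS": 3, "TCDB": 3}

    def test_planted_expansions_recovered_single_seed(self):
        """A strong planted scenario is recovered near-completely."""
        scenario = default_scenario(40, 60, n_planted=5, fold=8.0, seed=3)
        matrix, ecology, truth = generate_counts(scenario)
        _, selection, _ = run_selection(matrix, ecology)
        selected = {fam for _db, fam in selection.selected}
        assert len(selected & set(truth["family"])) >= 4
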