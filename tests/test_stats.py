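"""Inferential toolkit: U test, Spearman, pooled z, miRNA set grouping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirsig import (
    compare_signatures,
    group_mirna_sets,
    kras_stratified_tests,
    mann_whitney,
    spearman,
    two_proportion_z,
)
from mirsig.calling import CallTable, call_patients, control_ranges
from mirsig.errors import ConfigurationError, DegenerateDataError, GroupingError
from mirsig.simulate import SimConfig, generate_cohort
from tests.conftest import make_ddpcr, make_meta


def _exact_mw_p(a, b):
    """Brute-force two-sided p: enumerate all assignments of the pooled ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean_u = n1 * len(b) / 2
    stat_obs = abs(u_obs - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        hits += abs(u - mean_u) >= stat_obs - 1e-9
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 rank assignments
        assert res.method_note == "exact"

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(loc=1.0, size=5)
            res = mann_whitney(a, b)
            assert res.p_value == pytest.approx(_exact_mw_p(a, b), abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_two_sided_symmetry(self):
        a, b = [1.0, 4.0, 2.5], [3.0, 7.0, 5.5, 0.5]
        assert mann_whitney(a, b).p_value == pytest.approx(
            mann_whitney(b, a).p_value
        )

    def test_normal_approximation_close_to_exact_at_six_per_group(self):
        """|p_exact - p_approx| <= 0.02 for tie-free 6-vs-6 samples."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(loc=rng.uniform(0, 1.5), size=6)
            exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            approx = sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic")
            assert abs(exact.pvalue - approx.pvalue) <= 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(GroupingError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_relations(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30]).statistic == pytest.approx(1.0)
        assert spearman(x, [30, 16, 9, 4, 2]).statistic == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)
        assert res.method_note == "exact-permutation"

    def test_equals_pearson_on_midranks(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        y = rng.normal(size=15) + 0.5 * x
        x[3] = x[7]  # force a tie to exercise mid-ranks
        rho = spearman(x, y).statistic
        pearson = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert rho == pytest.approx(pearson, abs=1e-14)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestTwoProportionZ:
    def test_reproduces_printed_signature_statistic(self):
        """31/35 vs 23/35 flagged patients: the pooled z is 2.277, p 0.023."""
        res = two_proportion_z(31, 35, 23, 35)
        assert res.statistic == pytest.approx(2.277, abs=5e-4)
        assert res.p_value == pytest.approx(0.023, abs=5e-4)

    def test_identical_proportions_give_zero(self):
        res = two_proportion_z(7, 20, 7, 20)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_evaluated_pooled_formula(self):
        res = two_proportion_z(5, 10, 1, 10)
        assert res.statistic == pytest.approx(1.9518, abs=1e-4)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(17)
        for _ in range(20):
            n1, n2 = rng.integers(5, 60, size=2)
            x1 = rng.integers(1, n1)
            x2 = rng.integers(1, n2)
            res = two_proportion_z(int(x1), int(n1), int(x2), int(n2))
            z_ref, p_ref = proportions_ztest([x1, x2], [n1, n2])
            assert res.statistic == pytest.approx(z_ref, abs=1e-12)
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(DegenerateDataError):
            two_proportion_z(0, 10, 0, 10)
        with pytest.raises(ConfigurationError):
            two_proportion_z(11, 10, 3, 10)


def _calls_with_counts(panel: list[str], flagged_per_patient: list[int]) -> CallTable:
    rows = []
    for i, n_flagged in enumerate(flagged_per_patient):
        for j, mirna in enumerate(panel):
            rows.append(
                {
                    "sample_id": f"p{i}",
                    "mirna_id": mirna,
                    "value": np.nan,
                    "status": "UP" if j < n_flagged else "NORMAL",
                }
            )
    return CallTable(calls=pd.DataFrame(rows), panel=panel)


class TestCompareSignatures:
    def test_identical_panels_give_zero_z(self):
        table = _calls_with_counts(["a", "b", "c"], [2, 0, 3, 1])
        with pytest.warns(UserWarning, match="overlap"):
            res = compare_signatures(table, ["a", "b", "c"], ["a", "b", "c"], k=2)
        assert res.z == 0.0

    def test_reproduces_printed_z_from_constructed_coverages(self):
        """Panels engineered to 31/35 and 23/35 coverage at k=2 reproduce
        the printed comparison statistic."""
        panel_a, panel_b = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        rows = []
        for i in range(35):
            for j, m in enumerate(panel_a):
                rows.append({"sample_id": f"p{i}", "mirna_id": m, "value": np.nan,
                             "status": "UP" if (i < 31 and j < 2) else "NORMAL"})
            for j, m in enumerate(panel_b):
                rows.append({"sample_id": f"p{i}", "mirna_id": m, "value": np.nan,
                             "status": "DOWN" if (i < 23 and j < 2) else "NORMAL"})
        table = CallTable(calls=pd.DataFrame(rows), panel=panel_a + panel_b)
        res = compare_signatures(table, panel_a, panel_b, k=2)
        assert (res.x_a, res.x_b, res.n) == (31, 23, 35)
        assert res.z == pytest.approx(2.277, abs=5e-4)
        assert res.p_value == pytest.approx(0.023, abs=5e-4)

    def test_coverage_matches_brute_force_recount(self, small_cohort):
        # null miRNAs only, so neither panel saturates at full coverage
        nulls = [
            m for m in small_cohort.panel
            if small_cohort.truth.loc[m, "direction"] == "NULL"
            and not small_cohort.truth.loc[m, "kras_target"]
        ]
        panel = small_cohort.panel
        ranges = control_ranges(small_cohort.ddpcr, small_cohort.meta, panel)
        table = call_patients(small_cohort.ddpcr, ranges, panel, small_cohort.meta)
        pa, pb = nulls[:4], nulls[4:8]
        k = 2
        res = compare_signatures(table, pa, pb, k=k)
        # independent recount straight off the raw call rows
        for sub_panel, x in ((pa, res.x_a), (pb, res.x_b)):
            flagged = 0
            for patient, group in table.calls.groupby("sample_id"):
                hits = group[
                    group["mirna_id"].isin(sub_panel)
                    & group["status"].isin(["UP", "DOWN"])
                ]
                flagged += len(hits) >= k
            assert flagged == x
        assert 0 < res.x_a + res.x_b < 2 * res.n  # non-degenerate comparison


class TestGroupMirnaSets:
    def test_correlated_pair_grouped_together(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(2, 1, size=30)
        levels = pd.DataFrame(
            {
                "m1": base * rng.lognormal(0, 0.05, 30),
                "m2": base * rng.lognormal(0, 0.05, 30),
                "m3": rng.lognormal(2, 1, size=30),
            }
        )
        grouping = group_mirna_sets(levels, n_sets=2)
        sets = [set(v) for v in grouping.sets.values()]
        assert {"m1", "m2"} in sets

    def test_invariant_under_per_mirna_rescaling(self):
        rng = np.random.default_rng(6)
        levels = pd.DataFrame(rng.lognormal(1, 0.8, size=(25, 6)),
                              columns=[f"m{i}" for i in range(6)])
        a = group_mirna_sets(levels, n_sets=3)
        b = group_mirna_sets(levels * [1, 10, 100, 0.1, 5, 50], n_sets=3)
        part_a = sorted(sorted(v) for v in a.sets.values())
        part_b = sorted(sorted(v) for v in b.sets.values())
        assert part_a == part_b

    def test_recovers_three_block_correlation_structure(self):
        rng = np.random.default_rng(12)
        n = 60
        blocks = {f"b{k}": rng.normal(size=n) for k in range(3)}
        cols, truth = {}, {}
        for k, (name, factor) in enumerate(blocks.items()):
            for j in range(3):
                col = f"m{k}{j}"
                # within-block correlation ~0.9, none across blocks
                cols[col] = np.exp(factor + rng.normal(0, 0.33, n))
                truth[col] = k
        levels = pd.DataFrame(cols)
        grouping = group_mirna_sets(levels, n_sets=3)
        recovered = sorted(sorted(v) for v in grouping.sets.values())
        expected = sorted(
            sorted(c for c, t in truth.items() if t == k) for k in range(3)
        )
        assert recovered == expected

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(1)
        levels = pd.DataFrame(
            {"m1": rng.lognormal(0, 1, 20), "m2": rng.lognormal(0, 1, 20),
             "flat": np.ones(20)}
        )
        with pytest.warns(UserWarning, match="flat"):
            grouping = group_mirna_sets(levels, n_sets=2)
        assert grouping.dropped == ["flat"]


class TestKrasStratified:
    def test_identical_strata_give_p_one(self):
        meta = make_meta([], ["c1", "c2", "c3", "c4"],
                         kras={"c1": "MUT", "c2": "MUT", "c3": "WT", "c4": "WT"})
        dd = make_ddpcr({s: {"m": 5.0} for s in meta.index})
        with pytest.warns(UserWarning):
            res = kras_stratified_tests(dd, meta, ["m"])
        assert res.loc[0, "p_value"] == 1.0

    def test_empty_stratum_named(self):
        meta = make_meta([], ["c1", "c2"], kras={"c1": "WT", "c2": "WT"})
        dd = make_ddpcr({s: {"m": 5.0} for s in meta.index})
        with pytest.raises(GroupingError, match="MUT"):
            kras_stratified_tests(dd, meta, ["m"])

    def test_stratum_sizes_echo_cohort_split(self):
        """A 16-mutant / 11-wild-type / 8-unknown case cohort reports
        stratum sizes (16, 11)."""
        cases = [f"CRC{i}" for i in range(1, 36)]
        kras = {c: "MUT" for c in cases[:16]}
        kras |= {c: "WT" for c in cases[16:27]}
        meta = make_meta(["TfD1", "TfD2"], cases, kras=kras)
        rng = np.random.default_rng(3)
        dd = make_ddpcr(
            {s: {"m": float(rng.lognormal(1, 0.5))} for s in meta.index}
        )
        res = kras_stratified_tests(dd, meta, ["m"])
        assert (res.loc[0, "n_mut"], res.loc[0, "n_wt"]) == (16, 11)

    def test_planted_kras_effect_attains_smallest_p(self):
        """With a single KRAS-responsive miRNA at fold change 4, that miRNA
        yields the smallest p among the panel in >=90% of seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            config = SimConfig(n_mirnas=40, n_kras_mirnas=1, kras_effect_fc=4.0,
                               ddpcr_panel_extra=5, seed=seed)
            cohort = generate_cohort(config)
            target = cohort.truth.index[cohort.truth["kras_target"]][0]
            res = kras_stratified_tests(cohort.ddpcr, cohort.meta, cohort.panel)
            best = res.loc[res["p_value"].idxmin(), "mirna_id"]
            wins += best == target
        assert wins / n_seeds >= 0.9
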