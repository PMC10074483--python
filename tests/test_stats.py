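"""Nonparametric statistics against brute-force and scipy oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epimea.stats import (
    compare_incidence,
    compare_k_groups,
    compare_two_groups,
    experiment_report,
    incidence,
    report_text,
)

from oracles import chi2_2x2, kruskal_h, mwu_u


class TestIncidence:
    @pytest.mark.parametrize(
        "k,n,percent",
        [(4, 7, 57), (2, 6, 33), (1, 5, 20), (0, 5, 0), (6, 7, 86), (9, 10, 90)],
    )
    def test_percent_rounding(self, k, n, percent):
        flags = [True] * k + [False] * (n - k)
        res = incidence(flags)
        assert (res.n_events, res.n_total, res.percent) == (k, n, percent)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            incidence([])


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        res = compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)

    def test_disjoint_three_vs_three_exact(self):
        res = compare_two_groups([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.exact
        assert res.p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_all_tied_degenerate(self):
        res = compare_two_groups([5, 5, 5], [5, 5])
        assert res.p == pytest.approx(1.0)

    def test_exact_matches_scipy_for_all_small_sizes(self, rng):
        """Exact enumeration equals scipy's exact distribution, combined n <= 10."""
        for n_x in range(1, 9):
            for n_y in range(1, 10 - n_x + 1):
                x = rng.normal(size=n_x)
                y = rng.normal(size=n_y) + rng.normal()
                ours = compare_two_groups(x, y, exact=True)
                ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
                assert ours.u == pytest.approx(float(ref.statistic))
                assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_u_statistic_matches_pairwise_count(self, rng):
        for _ in range(20):
            x = rng.integers(0, 6, size=5).astype(float)
            y = rng.integers(0, 6, size=6).astype(float)
            assert compare_two_groups(x, y).u == pytest.approx(mwu_u(x, y))

    def test_large_shifted_normals_tiny_p(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)
        assert compare_two_groups(x, y).p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([], [1.0])


class TestKruskalDunn:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = compare_k_groups([g, g, g])
        assert res.h == pytest.approx(0.0, abs=1e-9)
        assert (res.pairwise["p_adjusted"] > 0.99).all()

    def test_disjoint_ranks_maximal_h(self):
        groups = [[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12]]
        res = compare_k_groups(groups)
        assert res.h == pytest.approx(kruskal_h([np.asarray(g, float) for g in groups]))
        # H is maximal over permutations of these 12 distinct values
        rng = np.random.default_rng(0)
        pooled = np.arange(1, 13, dtype=float)
        for _ in range(200):
            rng.shuffle(pooled)
            perm = [pooled[:4], pooled[4:8], pooled[8:]]
            assert kruskal_h(perm) <= res.h + 1e-9

    def test_h_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 4, size=6).astype(float) for _ in range(4)]
        res = compare_k_groups(groups)
        h_ref, p_ref = sps.kruskal(*groups)
        assert res.h == pytest.approx(h_ref)
        assert res.p == pytest.approx(p_ref)

    def test_dunn_z_hand_computed(self):
        # groups {1,2},{3,4},{5,6}: mean ranks 1.5/3.5/5.5, se = sqrt(3.5)
        res = compare_k_groups([[1, 2], [3, 4], [5, 6]])
        pair = res.pairwise
        z01 = pair[(pair.i == 0) & (pair.j == 1)]["z"].iloc[0]
        assert z01 == pytest.approx(-2.0 / np.sqrt(3.5))
        z02 = pair[(pair.i == 0) & (pair.j == 2)]["z"].iloc[0]
        assert z02 == pytest.approx(-4.0 / np.sqrt(3.5))
        p_un = 2 * sps.norm.sf(abs(z01))
        assert pair[(pair.i == 0) & (pair.j == 1)]["p_adjusted"].iloc[0] == pytest.approx(
            min(1.0, 3 * p_un)
        )

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="compare_two_groups"):
            compare_k_groups([[1, 2], [3, 4]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_k_groups([[1.0], [], [2.0]])


class TestChiSquare:
    def test_identical_proportions(self):
        res = compare_incidence((3, 6), (3, 6))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_full_vs_none_is_twenty(self):
        res = compare_incidence((10, 10), (0, 10))
        assert res.chi2 == pytest.approx(20.0)

    def test_matches_contingency_oracle(self):
        res = compare_incidence((4, 7), (0, 5))
        assert res.chi2 == pytest.approx(chi2_2x2(4, 7, 0, 5))
        ref = sps.chi2_contingency([[4, 3], [0, 5]], correction=False)
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_symmetry(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 12, size=2)
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            a = compare_incidence((k1, n1), (k2, n2))
            swapped = compare_incidence((k2, n2), (k1, n1))
            flipped = compare_incidence((n1 - k1, n1), (n2 - k2, n2))
            assert a.chi2 == pytest.approx(swapped.chi2)
            assert a.chi2 == pytest.approx(flipped.chi2)

    def test_yates_correction_available(self):
        res = compare_incidence((8, 10), (2, 10), yates=True)
        ref = sps.chi2_contingency([[8, 2], [2, 8]], correction=True)
        assert res.chi2 == pytest.approx(ref.statistic)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compare_incidence((0, 0), (1, 5))


def _toy_table():
    rows = []
    for cond, freqs, se in [("A", [0.1, 0.2, 0.3], [True, False, False]),
                            ("B", [0.5, 0.6, 0.7], [True, True, False])]:
        for i, (f, s) in enumerate(zip(freqs, se)):
            for window in ("T1", "T2"):
                rows.append(
                    dict(slice_id=f"{cond}{i}", condition=cond, window=window,
                         fp_freq=f, amplitude=300.0, burst_duration=1.0,
                         first_fp_latency=5.0, has_ictal=False, has_se=s)
                )
    return pd.DataFrame(rows)


class TestExperimentReport:
    def test_descriptive_block_without_contrasts(self):
        report = experiment_report(_toy_table())
        assert set(report["conditions"]) == {"A", "B"}
        a = report["conditions"]["A"]
        assert a["n_slices"] == 3
        assert a["descriptives"]["T1"]["fp_freq"]["mean"] == pytest.approx(0.2)
        assert a["incidence"]["se"]["percent"] == 33
        assert report["contrasts"] == {}

    def test_contrast_tests_and_incidence(self):
        report = experiment_report(
            _toy_table(), [{"name": "AvB", "a": "A", "b": "B", "metrics": ["fp_freq"]}]
        )
        block = report["contrasts"]["AvB"]
        assert block["tests"]["fp_freq@T1"]["test"] == "mann_whitney"
        assert block["incidence"]["has_se"]["a"]["percent"] == 33
        assert block["incidence"]["has_se"]["b"]["percent"] == 67
        text = report_text(report)
        assert "AvB" in text and "chi2" in text

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError, match="unknown condition"):
            experiment_report(_toy_table(), [{"a": "A", "b": "missing"}])

    def test_sem_uses_n_minus_one(self):
        report = experiment_report(_toy_table())
        vals = np.array([0.1, 0.2, 0.3])
        want = vals.std(ddof=1) / np.sqrt(3)
        got = report["conditions"]["A"]["descriptives"]["T1"]["fp_freq"]["sem"]
        assert got == pytest.approx(want)
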