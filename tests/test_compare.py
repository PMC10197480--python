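import numpy as np
import pytest
from scipy import stats

import traitnet as tn
from traitnet.compare import _range_quantile


def duncan_reference(samples: dict, alpha: float = 0.05) -> dict:
    """Independent recursive step-down multiple range procedure.

    Tests the widest range first and recurses into sub-ranges only when
    the parent range is significant; returns the letter display.
    Deliberately structured differently from the library's iterative
    containment-marking implementation.
    """
    names = list(samples)
    vecs = {k: np.asarray(samples[k], float) for k in names}
    means = {k: v.mean() for k, v in vecs.items()}
    ns = {k: v.size for k, v in vecs.items()}
    df = sum(n - 1 for n in ns.values())
    mse = sum((ns[k] - 1) * np.var(vecs[k], ddof=1) for k in names) / df
    n_h = len(names) / sum(1.0 / n for n in ns.values())
    order = sorted(names, key=lambda k: (-means[k], k))
    k = len(order)
    nonsig_intervals = []

    def visit(i, j):
        if i >= j:
            return
        if any(a <= i and j <= b for a, b in nonsig_intervals):
            return
        span = j - i + 1
        if mse == 0.0:
            sig = means[order[i]] != means[order[j]]
        else:
            crit = (stats.studentized_range.ppf((1 - alpha) ** (span - 1),
                                                span, min(df, 1000))
                    * np.sqrt(mse / n_h))
            sig = (means[order[i]] - means[order[j]]) > crit
        if sig:
            visit(i, j - 1)
            visit(i + 1, j)
        else:
            nonsig_intervals.append((i, j))

    visit(0, k - 1)
    # maximal nonsig runs -> letters
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and any(a <= i and j + 1 <= b
                                for a, b in nonsig_intervals):
            j += 1
        if not any(a <= i and j <= b for a, b in intervals):
            intervals.append((i, j))
    letters = {name: "" for name in order}
    for idx, (a, b) in enumerate(intervals):
        for t in range(a, b + 1):
            letters[order[t]] += chr(ord("a") + idx)
    return letters


class TestSplitGroups:
    def _matrix(self, n, life_form=None, aridity=None):
        rng = np.random.default_rng(0)
        return tn.TraitMatrix(
            np.exp(rng.standard_normal((n, 5))),
            [f"r{i}" for i in range(n)],
            [f"t{j}" for j in range(5)],
            life_form=life_form,
            aridity_index=aridity,
        )

    def test_aridity_boundary_goes_to_semi_arid(self):
        ai = np.array([0.05, 0.1, 0.15, 0.19, 0.2, 0.3, 0.4, 0.5])
        m = self._matrix(8, aridity=ai)
        parts = tn.split_groups(m, "aridity")
        assert parts["arid"].n_records == 4
        assert parts["semi-arid"].n_records == 4
        assert "r4" in parts["semi-arid"].record_ids  # AI = 0.2 exactly

    def test_all_one_life_form_errors(self):
        m = self._matrix(8, life_form=np.array(["woody"] * 8, dtype=object))
        parts = tn.split_groups(m, "life_form")
        assert list(parts) == ["woody"]  # single group is fine on its own

    def test_small_group_errors_by_name(self):
        lf = np.array(["woody"] * 6 + ["herbaceous"] * 2, dtype=object)
        m = self._matrix(8, life_form=lf)
        with pytest.raises(ValueError, match="herbaceous"):
            tn.split_groups(m, "life_form")

    def test_counts_match_labels(self):
        rng = np.random.default_rng(1)
        lf = np.array(["woody"] * 60 + ["herbaceous"] * 40, dtype=object)
        m = self._matrix(100, life_form=lf)
        parts = tn.split_groups(m, "life_form")
        assert parts["woody"].n_records == 60
        assert parts["herbaceous"].n_records == 40

    def test_missing_labels_excluded(self):
        lf = np.array(["woody"] * 5 + [None] + ["herbaceous"] * 5, dtype=object)
        m = self._matrix(11, life_form=lf)
        parts = tn.split_groups(m, "life_form")
        assert sum(p.n_records for p in parts.values()) == 10

    def test_missing_metadata_errors(self):
        m = self._matrix(8)
        with pytest.raises(ValueError, match="life_form"):
            tn.split_groups(m, "life_form")
        with pytest.raises(ValueError, match="aridity"):
            tn.split_groups(m, "aridity")


class TestWelch:
    def test_identical_vectors(self):
        r = tn.welch_ttest([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_hand_case_matches_scalar_oracle(self):
        a, b = [1.0, 2, 3, 4], [2.0, 3, 4, 5]
        r = tn.welch_ttest(a, b)
        # Welch formula by hand: se = sqrt(var_a/4 + var_b/4), both var 5/3
        se = np.sqrt(5 / 3 / 4 + 5 / 3 / 4)
        t_expect = (2.5 - 3.5) / se
        assert r.t == pytest.approx(t_expect, abs=1e-12)
        assert r.t == pytest.approx(-1.0954, abs=1e-4)
        assert r.p == pytest.approx(0.3150, abs=1e-3)

    def test_huge_effect(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(1000)
        b = rng.standard_normal(1000) + 5
        assert tn.welch_ttest(a, b).p < 1e-10

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(30), rng.standard_normal(30) + 0.5
        r1, r2 = tn.welch_ttest(a, b), tn.welch_ttest(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r1.t == pytest.approx(-r2.t)

    def test_constant_equal_convention(self):
        r = tn.welch_ttest([2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0 and r.t == 0.0

    def test_constant_unequal(self):
        r = tn.welch_ttest([2.0, 2.0], [3.0, 3.0])
        assert r.p == 0.0 and np.isinf(r.t)

    def test_pooled_flag_matches_students_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(20), rng.standard_normal(25) + 0.3
        r = tn.welch_ttest(a, b, pooled=True)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)


class TestDuncan:
    def test_identical_items_share_letter(self):
        v = [1.0, 2.0, 3.0, 2.0]
        res = tn.duncan_mrt({"a": v, "b": v})
        assert res.letters["a"] == res.letters["b"]

    def test_two_item_reduction_matches_range_test(self):
        # with two items Duncan reduces to one studentized-range test
        rng = np.random.default_rng(0)
        a = rng.standard_normal(15)
        b = rng.standard_normal(15) + 1.2
        res = tn.duncan_mrt({"a": a, "b": b})
        df = 28
        mse = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        crit = stats.studentized_range.ppf(0.95, 2, df) * np.sqrt(mse / 15)
        expect_sig = abs(a.mean() - b.mean()) > crit
        got_sig = res.letters["a"] != res.letters["b"]
        assert got_sig == expect_sig

    def test_separated_and_close_means(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(50) * 0.1
        samples = {"lo": base, "mid": base + 0.01, "hi": base + 10.0}
        res = tn.duncan_mrt(samples)
        assert res.letters["lo"] == res.letters["mid"]
        assert res.letters["hi"] != res.letters["lo"]
        assert res.letters["hi"] == "a"  # highest mean labelled first

    def test_zero_variance_distinct_means(self):
        res = tn.duncan_mrt({"a": [1.0, 1.0], "b": [2.0, 2.0],
                             "c": [2.0, 2.0]})
        assert res.letters["a"] != res.letters["b"]
        assert res.letters["b"] == res.letters["c"]

    def test_order_and_shift_invariance(self):
        rng = np.random.default_rng(4)
        samples = {f"i{j}": rng.standard_normal(12) + j * 0.4
                   for j in range(5)}
        res1 = tn.duncan_mrt(samples)
        shuffled = {k: samples[k] + 100.0
                    for k in reversed(list(samples))}
        res2 = tn.duncan_mrt(shuffled)
        assert res1.letters == res2.letters

    def test_matches_recursive_reference(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            sep = rng.uniform(0.0, 2.0)
            samples = {
                f"i{j}": rng.standard_normal(6) + rng.uniform(0, sep)
                for j in range(5)
            }
            res = tn.duncan_mrt(samples)
            ref = duncan_reference(samples)
            grouping = {frozenset(k for k in res.letters
                                  if ch in res.letters[k])
                        for ch in set("".join(res.letters.values()))}
            ref_grouping = {frozenset(k for k in ref if ch in ref[k])
                            for ch in set("".join(ref.values()))}
            assert grouping == ref_grouping, (res.letters, ref)

    def test_needs_two_items_two_reps(self):
        with pytest.raises(ValueError):
            tn.duncan_mrt({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            tn.duncan_mrt({"a": [1.0], "b": [2.0, 1.0]})


@pytest.fixture(scope="module")
def grouped_matrix():
    # widely separated correlation strengths so the planted direction is
    # unambiguous at this sample size
    cfg = tn.SyntheticConfig(
        blocks=tn.default_blocks(rho_in=0.9), rho_out=0.1,
        groups=(tn.SyntheticGroup("woody", 200, 0.3),
                tn.SyntheticGroup("herbaceous", 200, 1.0)),
        seed=23)
    return tn.log_transform(tn.generate(cfg))


class TestComparePipeline:

    def test_planted_effect_direction_and_significance(self, grouped_matrix):
        report = tn.compare_group_ptns(grouped_matrix, "life_form", B=150,
                                       seed=1)
        w = report.groups["woody"]
        h = report.groups["herbaceous"]
        assert h.metrics.edge_density > w.metrics.edge_density
        assert report.tests["edge_density"].p < 0.05
        assert set(report.tests) == {"edge_density", "modularity"}

    def test_report_contents(self, grouped_matrix):
        report = tn.compare_group_ptns(grouped_matrix, "life_form", B=60,
                                       seed=2)
        for g in report.groups.values():
            assert g.importance is not None
            assert g.duncan_degree is not None
            assert g.duncan_importance is not None
            assert set(g.duncan_importance.letters) == {
                "economic", "chemical", "structural"}
        frame = report.tests_frame()
        assert {"parameter", "t", "df", "p"} <= set(frame.columns)

    def test_single_group_no_tests(self):
        cfg = tn.SyntheticConfig(
            groups=(tn.SyntheticGroup("woody", 40, 1.0),), seed=3)
        m = tn.log_transform(tn.generate(cfg))
        report = tn.compare_group_ptns(m, "life_form", B=30, seed=0)
        assert list(report.groups) == ["woody"]
        assert report.tests == {}
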