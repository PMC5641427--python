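"""Classic tests, Steel–Dwass all-pairs comparison, percent difference."""

import json
import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from spermshape.stats import (TestResult, classic_tests, percent_difference,
                              significance_label, steel_dwass,
                              steel_dwass_table)


class TestLabels:
    @pytest.mark.parametrize("p, label", [
        (0.2, "n.s."), (0.05, "n.s."), (0.049, "*"), (0.01, "*"),
        (0.009, "**"), (0.001, "**"), (0.0009, "***"), (0.0, "***"),
    ])
    def test_convention(self, p, label):
        assert significance_label(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_label(1.5)

    def test_result_autolabels(self):
        r = TestResult("t", 1.0, 0.003, "two-sided", ("a", "b"))
        assert r.significance_label == "**"


class TestClassic:
    def test_identical_samples_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = classic_tests(x, x, kind="t_two")
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.significance_label == "n.s."

    def test_equal_variance_f_is_one(self):
        x = [1.0, 2.0, 3.0]
        r = classic_tests(x, [10.0, 11.0, 12.0], kind="f_var")
        assert r.statistic == pytest.approx(1.0)

    def test_one_tailed_halves_symmetric_p(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 30)
        two = classic_tests(x, y, kind="t_two", tail="two-sided")
        one = classic_tests(x, y, kind="t_two", tail="less")
        assert one.p_value == pytest.approx(two.p_value / 2, rel=1e-9)

    def test_welch_flag_changes_statistic_dof(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 4, 40)
        pooled = classic_tests(x, y, kind="t_two", equal_var=True)
        welch = classic_tests(x, y, kind="t_two", equal_var=False)
        assert pooled.p_value != pytest.approx(welch.p_value, rel=1e-3)

    def test_one_sample_t(self):
        r = classic_tests([4.8, 5.1, 5.3, 4.9], kind="t_one", popmean=5.0)
        ref = sps.ttest_1samp([4.8, 5.1, 5.3, 4.9], 5.0)
        assert r.p_value == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("kind, x, y", [
        ("t_two", [1.0], [1.0, 2.0]),
        ("t_two", [1.0, 1.0], [1.0, 1.0, 1.0]),
        ("shapiro", [1.0, 2.0], None),
        ("f_var", [1.0, 2.0], [3.0, 3.0]),
    ])
    def test_informative_errors(self, kind, x, y):
        with pytest.raises(ValueError):
            classic_tests(x, y, kind=kind)

    def test_unknown_kind_and_tail_rejected(self):
        with pytest.raises(ValueError):
            classic_tests([1.0, 2.0], kind="z_test")
        with pytest.raises(ValueError):
            classic_tests([1.0, 2.0], [1.0, 3.0], tail="both")


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not available for the cross-implementation oracle")
def test_p_values_match_r_reference(tmp_path):
    """t, F, KS and Shapiro-Wilk p-values agree with R within 1e-6."""
    rng = np.random.default_rng(42)
    cases = []
    for _ in range(20):
        n1, n2 = int(rng.integers(8, 40)), int(rng.integers(8, 40))
        x = np.round(rng.normal(0, 1, n1), 6)
        y = np.round(rng.normal(rng.uniform(-0.5, 0.5),
                                rng.uniform(0.5, 2.0), n2), 6)
        cases.append((x.tolist(), y.tolist()))
    (tmp_path / "cases.json").write_text(json.dumps(cases))
    rcode = """
    cases <- jsonlite::fromJSON("cases.json", simplifyVector = FALSE)
    out <- lapply(cases, function(cs) {
      x <- unlist(cs[[1]]); y <- unlist(cs[[2]])
      list(t  = t.test(x, y, var.equal = TRUE)$p.value,
           f  = var.test(x, y)$p.value,
           ks = ks.test(x, y, exact = FALSE)$p.value,
           sw = shapiro.test(x)$p.value)
    })
    cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12))
    """
    (tmp_path / "oracle.R").write_text(rcode)
    proc = subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path,
                          capture_output=True, text=True, check=True)
    oracle = json.loads(proc.stdout)
    for (x, y), ref in zip(cases, oracle):
        assert classic_tests(x, y, kind="t_two").p_value == \
            pytest.approx(ref["t"], abs=1e-6)
        assert classic_tests(x, y, kind="f_var").p_value == \
            pytest.approx(ref["f"], abs=1e-6)
        # R's asymptotic KS CDF is itself series-truncated at ~1e-5 for
        # small statistics; check R at its own accuracy and the exact
        # alternating Kolmogorov series at 1e-9
        ks = classic_tests(x, y, kind="ks_two")
        assert ks.p_value == pytest.approx(ref["ks"], abs=2e-5)
        en = np.sqrt(len(x) * len(y) / (len(x) + len(y)))
        t_stat = en * ks.statistic
        series = 2 * sum((-1) ** (k - 1) * np.exp(-2 * k * k * t_stat**2)
                         for k in range(1, 101))
        assert ks.p_value == pytest.approx(min(max(series, 0.0), 1.0),
                                           abs=1e-9)
        assert classic_tests(x, kind="shapiro").p_value == \
            pytest.approx(ref["sw"], abs=1e-6)


def steel_dwass_permutation_oracle(groups: list[np.ndarray],
                                   n_perm: int = 100_000,
                                   seed: int = 0) -> list[float]:
    """Single-step max-T permutation null for the all-pairs comparison.

    Permutes the pooled sample; the adjusted p of each pair is the
    fraction of permutations whose largest pairwise statistic
    sqrt(2)|z| reaches that pair's observed value.
    """
    from spermshape.stats import _rank_sum_z

    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    edges = np.cumsum([0] + sizes)
    pairs = [(i, j) for i in range(len(groups))
             for j in range(i + 1, len(groups))]

    def pair_stats(sample: np.ndarray) -> np.ndarray:
        parts = [sample[edges[k]:edges[k + 1]] for k in range(len(sizes))]
        return np.array([np.sqrt(2) * abs(_rank_sum_z(parts[i], parts[j]))
                         for i, j in pairs])

    observed = pair_stats(pooled)
    rng = np.random.default_rng(seed)
    count = np.zeros(len(pairs))
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += pair_stats(perm).max() >= observed - 1e-12
    return (count / n_perm).tolist()


class TestSteelDwass:
    def test_identical_groups_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        for r in steel_dwass([g, g, g]):
            assert r.p_value > 0.99

    def test_fewer_than_three_groups_advises_ranksum(self):
        with pytest.raises(ValueError, match="rank-sum"):
            steel_dwass([[1.0, 2.0], [3.0, 4.0]])

    def test_label_permutation_symmetry(self, rng):
        gs = [rng.normal(i * 0.5, 1, 8) for i in range(3)]
        p1 = sorted(r.p_value for r in steel_dwass(gs))
        p2 = sorted(r.p_value for r in steel_dwass([gs[2], gs[0], gs[1]]))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_permutation_oracle_small_groups(self):
        # small integer data with ties, k=3, n=5 per group
        groups = [np.array([1.0, 2, 2, 3, 4]),
                  np.array([2.0, 3, 4, 4, 5]),
                  np.array([4.0, 5, 5, 6, 7])]
        oracle = steel_dwass_permutation_oracle(groups, n_perm=100_000, seed=7)
        ours = [r.p_value for r in steel_dwass(groups)]
        for p_impl, p_perm in zip(ours, oracle):
            assert abs(p_impl - p_perm) <= 0.02

    def test_table_layout(self, rng):
        gs = {"caput": rng.normal(0.53, 0.03, 10),
              "corpus": rng.normal(0.50, 0.03, 10),
              "cauda": rng.normal(0.50, 0.03, 10)}
        table = steel_dwass_table(steel_dwass(gs))
        assert list(table.columns) == ["group1", "group2", "statistic",
                                       "p_value", "label"]
        assert len(table) == 3
        assert set(table["group1"]).issubset(gs)

    def test_null_familywise_error_controlled(self):
        # k=4 groups of n=20 from one distribution; at alpha = 0.05 the
        # observed family-wise rejection rate stays below 0.07
        from spermshape.stats import _rank_sum_z

        q_crit = sps.studentized_range.isf(0.05, 4, np.inf)
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            data = rng.normal(size=(4, 20))
            qmax = max(np.sqrt(2) * abs(_rank_sum_z(data[i], data[j]))
                       for i in range(4) for j in range(i + 1, 4))
            rejections += qmax >= q_crit
        assert rejections / n_sim <= 0.07


class TestPercentDifference:
    def test_definition(self):
        assert percent_difference(0.5, 0.4715) == pytest.approx(5.7)

    def test_equal_means_zero(self):
        assert percent_difference(0.5, 0.5) == 0.0

    def test_sign_convention(self):
        assert percent_difference(0.5, 0.515) == pytest.approx(-3.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 0.4)
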