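"""Spearman primitive, genome-wide screen and top-k selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from rospanel.errors import ValidationError
from rospanel.expression import ExpressionMatrix
from rospanel.screen import (
    correlate_metabolism,
    screen,
    select_top,
    spearman,
    t_approx_pvalue,
)


def brute_force_spearman(x, y):
    """Independent oracle: average-tie ranks then the explicit Pearson formula."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx * rx).sum() * (ry * ry).sum()))


class TestSpearman:
    def test_hand_computed_example(self):
        # sum of squared rank differences is 4, so r = 1 - 6*4/(5*24) = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8, abs=1e-12)

    def test_exact_permutation_p_matches_enumeration(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([2, 1, 4, 3, 5], dtype=float)
        r_obs = brute_force_spearman(x, y)
        hits = sum(
            abs(brute_force_spearman(x, np.array(p))) >= abs(r_obs) - 1e-12
            for p in itertools.permutations(y)
        )
        expected = hits / 120
        assert spearman(x, y, method="exact").p == pytest.approx(expected, abs=1e-15)

    def test_identical_vectors_give_r_one(self):
        res = spearman([3.0, 1.0, 2.0, 5.0], [3.0, 1.0, 2.0, 5.0])
        assert res.r == pytest.approx(1.0)
        assert res.p_at_bound
        assert 0 < res.p < 1e-300

    @pytest.mark.parametrize(
        "bad_x, bad_y, msg",
        [
            ([1, 2], [3, 4], "at least 3"),
            ([1, 1, 1], [1, 2, 3], "constant"),
            ([1, 2, np.nan], [1, 2, 3], "finite"),
        ],
    )
    def test_contract_violations_rejected(self, bad_x, bad_y, msg):
        with pytest.raises(ValidationError, match=msg):
            spearman(bad_x, bad_y)

    def test_exact_method_limited_to_small_n(self):
        x = np.arange(9.0)
        with pytest.raises(ValidationError, match="n <= 8"):
            spearman(x, x[::-1], method="exact")

    def test_oracle_equivalence_with_ties(self, rng):
        for _ in range(200):
            n = rng.integers(4, 40)
            x = rng.integers(0, 6, n).astype(float)  # many ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            assert spearman(x, y).r == pytest.approx(
                brute_force_spearman(x, y), abs=1e-12
            )

    def test_scipy_cross_check(self, rng):
        x, y = rng.normal(size=(2, 30))
        ours = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert ours.r == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        arrays(np.float64, st.integers(5, 25), elements=st.integers(-10, 10).map(float)),
    )
    def test_antisymmetry(self, x):
        y = np.arange(len(x), dtype=float)
        if np.ptp(x) == 0:
            return
        a = spearman(x, y)
        b = spearman(-x, y)
        assert a.r == pytest.approx(-b.r, abs=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_exact_and_approx_mostly_agree_at_alpha(self, rng):
        # documented property: same rejection decision at alpha=0.05 for
        # >= 90% of random small-n instances
        agree = 0
        trials = 60
        for _ in range(trials):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            pe = spearman(x, y, method="exact").p
            pa = spearman(x, y).p
            agree += (pe < 0.05) == (pa < 0.05)
        assert agree / trials >= 0.9


class TestTApproxPvalue:
    def test_matches_t_distribution(self):
        r, n = 0.63, 35
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert t_approx_pvalue(r, n) == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-12)

    def test_sign_independent(self):
        assert t_approx_pvalue(-0.4, 20) == pytest.approx(t_approx_pvalue(0.4, 20))


def _matrix(values: np.ndarray, lines, genes=None) -> ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=lines),
        normalized=True,
        annotation_filtered=True,
    )


class TestScreen:
    def test_self_and_anti_correlated_genes(self, rng):
        lines = [f"L{i}" for i in range(10)]
        ic25 = pd.Series(rng.uniform(1, 100, 10), index=lines)
        values = np.vstack([ic25.to_numpy(), -ic25.to_numpy(), rng.normal(size=10)])
        res = screen(_matrix(values, lines), ic25, "ox")
        rec = res.records.set_index("gene")
        assert rec.loc["g0", "r"] == pytest.approx(1.0)
        assert rec.loc["g0", "sign"] == "+"
        assert rec.loc["g1", "r"] == pytest.approx(-1.0)
        assert rec.loc["g1", "sign"] == "-"
        assert rec.loc["g0", "p"] <= rec.loc["g2", "p"]

    def test_monotone_invariance_of_ic25_transform(self, rng):
        lines = [f"L{i}" for i in range(15)]
        values = rng.normal(size=(30, 15))
        ic25 = pd.Series(rng.uniform(1, 1000, 15), index=lines)
        a = screen(_matrix(values, lines), ic25, "ox").records
        b = screen(_matrix(values, lines), np.log10(ic25) ** 3 + 7, "ox").records
        pd.testing.assert_frame_equal(a, b)

    def test_constant_gene_dropped_with_diagnostic(self, rng):
        lines = [f"L{i}" for i in range(8)]
        values = np.vstack([np.full(8, 3.0), rng.normal(size=8)])
        res = screen(_matrix(values, lines), pd.Series(np.arange(8.0), index=lines), "ox")
        assert "g0" in res.dropped
        assert "constant" in res.dropped["g0"]
        assert list(res.records["gene"]) == ["g1"]

    def test_pairwise_complete_with_missing_values(self, rng):
        lines = [f"L{i}" for i in range(14)]
        values = rng.normal(size=(2, 14))
        values[0, :3] = np.nan  # 11 paired observations remain (>= floor of 10)
        ic25 = pd.Series(rng.uniform(1, 10, 14), index=lines)
        res = screen(_matrix(values, lines), ic25, "ox")
        rec = res.records.set_index("gene")
        assert rec.loc["g0", "n"] == 11
        assert rec.loc["g1", "n"] == 14
        # below the floor the gene is dropped
        values[0, :6] = np.nan
        res2 = screen(_matrix(values, lines), ic25, "ox")
        assert "g0" in res2.dropped

    def test_requires_shared_lines(self, rng):
        lines = ["A", "B", "C"]
        mat = _matrix(rng.normal(size=(3, 3)), lines)
        with pytest.raises(ValidationError, match=">= 3 cell lines"):
            screen(mat, pd.Series({"X": 1.0, "Y": 2.0, "A": 3.0}), "ox")


class TestSelectTop:
    def _result(self):
        lines = [f"L{i}" for i in range(12)]
        rng = np.random.default_rng(5)
        ic25 = pd.Series(rng.uniform(1, 50, 12), index=lines)
        signal = np.vstack(
            [ic25 + rng.normal(0, 3, 12) for _ in range(6)]
            + [-ic25 + rng.normal(0, 3, 12) for _ in range(3)]
            + [rng.normal(size=12) for _ in range(20)]
        )
        return screen(_matrix(signal, lines), ic25, "ox")

    def test_truncation_when_few_significant(self):
        res = self._result()
        pos = select_top(res, 20, "positive")
        assert len(pos) == (res.significant["sign"] == "+").sum()
        assert set(pos) <= set(res.significant["gene"])

    def test_sort_by_p_then_absr(self):
        records = pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "r": [0.7, 0.9, 0.8],
                "p": [0.01, 0.01, 0.001],
                "n": 10,
                "p_at_bound": False,
                "sign": ["+", "+", "+"],
                "q": [0.01, 0.01, 0.003],
            }
        )
        from rospanel.screen import ScreenResult

        res = ScreenResult(treatment="ox", records=records, alpha=0.05)
        assert select_top(res, 3, "positive") == ["c", "b", "a"]

    def test_overall_interleaves_signs_by_p(self):
        res = self._result()
        overall = select_top(res, 5, "overall")
        sig = res.significant.assign(absr=lambda d: d["r"].abs())
        expected = sig.sort_values(
            ["p", "absr", "gene"], ascending=[True, False, True]
        )["gene"].head(5).tolist()
        assert overall == expected
        assert {"+", "-"} == set(
            res.significant.set_index("gene").loc[overall, "sign"]
        ) or len(set(res.significant["sign"])) == 1

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValidationError):
            select_top(self._result(), 5, "sideways")


class TestCorrelateMetabolism:
    def test_monotone_baseline_gives_perfect_correlation(self):
        lines = [f"L{i}" for i in range(10)]
        ic25 = pd.Series(np.arange(1.0, 11.0), index=lines)
        from rospanel.sensitivity import rank_sensitivity

        ranks = rank_sensitivity(ic25)
        res = correlate_metabolism(pd.Series(ic25 * 3.7, index=lines), ranks)
        assert res.r == pytest.approx(1.0)

    def test_constant_baseline_is_degenerate(self):
        lines = ["A", "B", "C", "D"]
        with pytest.raises(ValidationError, match="constant"):
            correlate_metabolism(
                pd.Series(5.0, index=lines),
                pd.Series([1.0, 2.0, 3.0, 4.0], index=lines),
            )
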