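import itertools

import numpy as np
import pytest

from splitcost.errors import DataError, DesignError
from splitcost.gammaglm import DesignSpec, fit, fit_null
from splitcost.marginal import cld, marginal_mean, mcfadden, pairwise
from splitcost.simgen import MASS_COL, TIMING_COL


@pytest.fixture(scope="module")
def median_fit(default_data):
    labels = np.where(
        default_data[TIMING_COL] < default_data[TIMING_COL].median(), "early", "late"
    )
    data = default_data.assign(category=labels)
    return fit(DesignSpec.categorical(("early", "late")), data), data


class TestMarginalMean:
    def test_interval_symmetric_on_log_scale(self, median_fit):
        res, _ = median_fit
        m = marginal_mean(res, "late")
        assert m.lower < m.mean < m.upper
        assert m.mean / m.lower == pytest.approx(m.upper / m.mean, rel=1e-9)

    def test_categorical_mean_equals_group_sample_mean(self, median_fit):
        res, data = median_fit
        for level in ("early", "late"):
            expected = data.loc[data.category == level, MASS_COL].mean()
            assert marginal_mean(res, level).mean == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_coding_scheme(self, median_fit):
        _, data = median_fit
        trt = fit(DesignSpec.categorical(("early", "late"), coding="treatment"), data)
        sum_ = fit(DesignSpec.categorical(("early", "late"), coding="sum"), data)
        for level in ("early", "late"):
            a, b = marginal_mean(trt, level), marginal_mean(sum_, level)
            assert a.mean == pytest.approx(b.mean, rel=1e-8)
            assert a.lower == pytest.approx(b.lower, rel=1e-6)

    def test_continuous_span_near_printed_value(self, default_data):
        """95% CI span at the mean predictor sits near 1.3 kg at n=120."""
        res = fit(DesignSpec.continuous(), default_data)
        m = marginal_mean(res, float(default_data[TIMING_COL].mean()))
        assert 0.9 < m.span < 1.7

    def test_unknown_level_rejected(self, median_fit):
        res, _ = median_fit
        with pytest.raises(DesignError):
            marginal_mean(res, "unheard-of")


class TestPairwise:
    def test_three_levels_three_contrasts(self, default_data):
        labels = np.array(["a", "b", "c"])[
            np.digitize(default_data[TIMING_COL], np.quantile(default_data[TIMING_COL], [1 / 3, 2 / 3]))
        ]
        res = fit(DesignSpec.categorical(("a", "b", "c")), default_data.assign(category=labels))
        assert len(pairwise(res).table) == 3

    def test_identical_groups_not_significant(self, tiny_data):
        data = tiny_data.assign(category=np.tile(["g1", "g2"], 5))
        half = data[MASS_COL].to_numpy().copy()
        half[1::2] = half[::2]  # make the two groups value-identical
        data = data.assign(**{MASS_COL: half})
        res = fit(DesignSpec.categorical(("g1", "g2")), data)
        table = pairwise(res).table
        assert table.p_adj.iloc[0] > 0.99

    def test_huge_effect_is_significant(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        y = np.concatenate([rng.gamma(400, 10 / 400, 50), rng.gamma(400, 40 / 400, 50)])
        data = pd.DataFrame({MASS_COL: y, "category": ["lo"] * 50 + ["hi"] * 50})
        res = fit(DesignSpec.categorical(("lo", "hi")), data)
        assert pairwise(res).table.p_adj.iloc[0] < 1e-6

    def test_bonferroni_never_smaller_than_raw(self, default_data):
        labels = np.array(["a", "b", "c"])[
            np.digitize(default_data[TIMING_COL], np.quantile(default_data[TIMING_COL], [1 / 3, 2 / 3]))
        ]
        res = fit(DesignSpec.categorical(("a", "b", "c")), default_data.assign(category=labels))
        table = pairwise(res, adjust="bonferroni").table
        assert (table.p_adj >= table.p - 1e-15).all()

    def test_continuous_design_rejected(self, default_data):
        res = fit(DesignSpec.continuous(), default_data)
        with pytest.raises(DesignError):
            pairwise(res)


def _pmat(n, sig_pairs):
    P = np.ones((n, n))
    for i, j in sig_pairs:
        P[i, j] = P[j, i] = 0.001
    return P


class TestCld:
    def test_all_different(self):
        letters = cld(["A", "B", "C"], _pmat(3, [(0, 1), (0, 2), (1, 2)]))
        assert letters == {"A": "a", "B": "b", "C": "c"}

    def test_none_different(self):
        letters = cld(["A", "B", "C"], _pmat(3, []))
        assert letters == {"A": "a", "B": "a", "C": "a"}

    def test_chain_shares_middle(self):
        # A-B and B-C not different, A-C different -> a, ab, b
        letters = cld(["A", "B", "C"], _pmat(3, [(0, 2)]))
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_sharing_iff_not_significant(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(2, 6))
            pairs = [
                (i, j) for i, j in itertools.combinations(range(n), 2) if rng.random() < 0.5
            ]
            P = _pmat(n, pairs)
            letters = cld(list("ABCDE")[:n], P)
            for i, j in itertools.combinations(range(n), 2):
                shared = set(letters[chr(65 + i)]) & set(letters[chr(65 + j)])
                assert bool(shared) == (P[i, j] > 0.05)

    def test_invariant_to_level_permutation(self):
        P = _pmat(4, [(0, 3), (1, 3)])
        base = cld(["A", "B", "C", "D"], P)
        perm = [2, 0, 3, 1]
        Pp = P[np.ix_(perm, perm)]
        permuted = cld([["A", "B", "C", "D"][i] for i in perm], Pp)
        for i, j in itertools.combinations(range(4), 2):
            a, b = "ABCD"[i], "ABCD"[j]
            assert bool(set(base[a]) & set(base[b])) == bool(
                set(permuted[a]) & set(permuted[b])
            )

    def test_asymmetric_matrix_rejected(self):
        P = np.array([[1.0, 0.2], [0.6, 1.0]])
        with pytest.raises(DataError):
            cld(["A", "B"], P)


class TestMcfadden:
    def test_zero_for_null_against_itself(self, default_data):
        null = fit_null(default_data)
        assert mcfadden(null, null) == 0.0

    def test_continuous_explains_more_than_median_split(self, default_data):
        null = fit_null(default_data)
        cont = fit(DesignSpec.continuous(), default_data)
        labels = np.where(
            default_data[TIMING_COL] < default_data[TIMING_COL].median(), "early", "late"
        )
        med = fit(
            DesignSpec.categorical(("early", "late")),
            default_data.assign(category=labels),
        )
        assert mcfadden(cont, null) > mcfadden(med, null) > 0

    def test_mismatched_data_rejected(self, default_data, tiny_data):
        with pytest.raises(DataError):
            mcfadden(fit(DesignSpec.continuous(), default_data), fit_null(tiny_data))
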