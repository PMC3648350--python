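import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mbmdr as mb
from mbmdr.stats import StatParams, _classify_continuous, chi2_critical, f_critical


def pearson_chi2_2x2(a, b, c, d):
    """Independent oracle: Pearson chi-squared from expected counts."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


class TestCrossCounts:
    def test_two_subjects_by_hand(self):
        cc = mb.build_cross_counts(np.array([1, 0]), np.array([0, 0]), np.array([0, 1]))
        assert cc.A.tolist() == [[1, 0]]
        assert cc.U.tolist() == [[0, 1]]
        assert cc.n_affected == 1 and cc.n_unaffected == 1

    def test_all_affected_gives_empty_unaffected(self):
        cc = mb.build_cross_counts(np.ones(6, dtype=int),
                                   np.array([0, 1, 2, 0, 1, 2]),
                                   np.array([0, 0, 1, 1, 0, 0]))
        assert not cc.U.any() and cc.n_unaffected == 0
        assert cc.A.sum() == 6

    def test_counts_reproduce_joint_histogram(self):
        rng = np.random.default_rng(7)
        g_l = rng.integers(0, 3, 200)
        g_r = rng.integers(0, 4, 200)
        trait = rng.integers(0, 2, 200)
        cc = mb.build_cross_counts(trait, g_l, g_r)
        hist, *_ = np.histogram2d(g_l, g_r, bins=[np.arange(4), np.arange(5)])
        assert np.array_equal(cc.A + cc.U, hist)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mb.build_cross_counts(np.array([1, 0]), np.array([0]), np.array([0, 1]))


class TestCellChi2:
    @pytest.mark.parametrize("table,expected", [
        ((5, 5, 5, 5), 0.0),        # ad = bc
        ((10, 0, 0, 10), 20.0),     # perfect association: chi2 = N
        ((30, 10, 70, 90), 12.5),   # Pearson value of the table
    ])
    def test_known_tables(self, table, expected):
        assert mb.cell_chi2(*table) == pytest.approx(expected, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mb.cell_chi2(-1, 2, 3, 4)

    @pytest.mark.parametrize("table", [(0, 0, 5, 5), (5, 5, 0, 0), (0, 5, 0, 5), (5, 0, 5, 0)])
    def test_degenerate_margin_is_no_evidence(self, table):
        assert mb.cell_chi2(*table) == 0.0

    @given(st.tuples(*[st.integers(1, 400)] * 4))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_pearson_on_positive_margins(self, table):
        assert mb.cell_chi2(*table) == pytest.approx(pearson_chi2_2x2(*table), abs=1e-9)


class TestClassifyCells:
    def test_small_cell_is_O_at_default_threshold(self):
        # cell (0,0) holds 3 subjects < 10 -> O regardless of association
        cc = mb.CrossCounts(A=np.array([[3, 17], [0, 0]]), U=np.array([[0, 0], [10, 10]]),
                            n_affected=20, n_unaffected=20)
        hlo = mb.classify_cells(cc)
        assert hlo.labels[0, 0] == "O"

    def test_hand_enumerated_hlo(self):
        cc = mb.CrossCounts(A=np.array([[10, 0], [0, 0]]), U=np.array([[0, 0], [0, 10]]),
                            n_affected=10, n_unaffected=10)
        hlo = mb.classify_cells(cc, StatParams(min_cell_total=1))
        assert hlo.labels.tolist() == [["H", "O"], ["O", "L"]]

    def test_balanced_cell_is_O(self):
        cc = mb.CrossCounts(A=np.array([[10, 10]]), U=np.array([[10, 10]]),
                            n_affected=20, n_unaffected=20)
        hlo = mb.classify_cells(cc, StatParams(min_cell_total=1))
        assert (hlo.labels == "O").all()

    def test_gate_uses_distribution_quantile(self):
        # chi-squared(1) upper 0.1 quantile, not a hard-coded constant
        assert chi2_critical(0.1) == pytest.approx(2.705543, abs=1e-6)
        stricter = chi2_critical(0.001)
        assert stricter > chi2_critical(0.1)

    def test_raising_min_cell_only_creates_O(self):
        rng = np.random.default_rng(3)
        A = rng.integers(0, 30, (3, 3))
        U = rng.integers(0, 30, (3, 3))
        cc = mb.CrossCounts(A=A, U=U, n_affected=int(A.sum()), n_unaffected=int(U.sum()))
        loose = mb.classify_cells(cc, StatParams(min_cell_total=1)).codes
        strict = mb.classify_cells(cc, StatParams(min_cell_total=25)).codes
        changed = loose != strict
        assert (strict[changed] == 0).all()  # only H/L -> O transitions


class TestPairStatisticBinary:
    def _fixture(self):
        # 10 affected in cell (0,0), 10 unaffected in cell (1,1)
        trait = np.array([1] * 10 + [0] * 10)
        g = np.array([0] * 10 + [1] * 10)
        return trait, g, g.copy()

    def test_hand_enumerated_T(self):
        trait, g_l, g_r = self._fixture()
        t = mb.pair_statistic_binary(trait, g_l, g_r, StatParams(min_cell_total=1))
        assert t == pytest.approx(20.0, abs=1e-12)

    def test_all_O_gives_zero(self):
        # single genotype cell: complement empty -> O everywhere -> T = 0
        trait = np.array([1, 0] * 10)
        g = np.zeros(20, dtype=int)
        assert mb.pair_statistic_binary(trait, g, g) == 0.0

    def test_snp_order_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            trait = rng.integers(0, 2, 120)
            if trait.min() == trait.max():
                continue
            g_l = rng.integers(0, 3, 120)
            g_r = rng.integers(0, 3, 120)
            assert mb.pair_statistic_binary(trait, g_l, g_r) == \
                mb.pair_statistic_binary(trait, g_r, g_l)

    def test_joint_subject_permutation_invariance(self):
        rng = np.random.default_rng(8)
        trait = rng.integers(0, 2, 150)
        g_l = rng.integers(0, 3, 150)
        g_r = rng.integers(0, 3, 150)
        perm = rng.permutation(150)
        assert mb.pair_statistic_binary(trait, g_l, g_r) == \
            mb.pair_statistic_binary(trait[perm], g_l[perm], g_r[perm])

    def test_single_class_trait_rejected(self):
        with pytest.raises(ValueError):
            mb.pair_statistic_binary(np.ones(10, dtype=int),
                                     np.zeros(10, dtype=int), np.zeros(10, dtype=int))

    def test_nonnegative(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            trait = rng.integers(0, 2, 60)
            if trait.min() == trait.max():
                continue
            t = mb.pair_statistic_binary(trait, rng.integers(0, 3, 60), rng.integers(0, 3, 60))
            assert t >= 0.0


class TestPairStatisticContinuous:
    def test_constant_trait_is_zero_with_warning(self):
        g = np.array([0, 1] * 10)
        with pytest.warns(UserWarning, match="zero variance"):
            assert mb.pair_statistic_continuous(np.full(20, 3.0), g, g) == 0.0

    def test_noiseless_separating_cell(self):
        # +10 inside one large cell, 0 elsewhere: the cell is H and the
        # split has zero within-group variance -> the two-group F diverges
        trait = np.array([10.0] * 30 + [0.0] * 70)
        g_l = np.array([0] * 30 + [1] * 70)
        g_r = np.zeros(100, dtype=int)
        params = StatParams(min_cell_total=10)
        n_cell = np.array([[30.0], [70.0]])
        s_cell = np.array([[300.0], [0.0]])
        codes = _classify_continuous(n_cell, s_cell, 100, 300.0,
                                     float(trait @ trait) - 300.0 ** 2 / 100,
                                     f_critical(0.1, 98), params)
        assert codes[0, 0] == 1 and codes[1, 0] == -1  # H and L
        assert mb.pair_statistic_continuous(trait, g_l, g_r, params) == np.inf

    def test_two_group_f_closed_form(self):
        # noisy variant: compare against the closed-form one-way F
        rng = np.random.default_rng(4)
        trait = np.concatenate([rng.normal(5, 1, 40), rng.normal(0, 1, 60)])
        g_l = np.array([0] * 40 + [1] * 60)
        g_r = np.zeros(100, dtype=int)
        t = mb.pair_statistic_continuous(trait, g_l, g_r)
        y1, y2 = trait[:40], trait[40:]
        gm = trait.mean()
        ssb = 40 * (y1.mean() - gm) ** 2 + 60 * (y2.mean() - gm) ** 2
        ssw = ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
        assert t == pytest.approx(ssb / (ssw / 98), rel=1e-10)

    def test_binary_trait_through_continuous_path_agrees_on_decided_cells(self):
        # when both per-cell tests are significant (or both are not), the
        # H/L/O labels coincide; near-threshold cells may be decided
        # differently by the chi-squared and F gates
        rng = np.random.default_rng(9)
        params = StatParams()
        for _ in range(10):
            trait = rng.integers(0, 2, 200)
            g_l = rng.integers(0, 3, 200)
            g_r = rng.integers(0, 3, 200)
            cc = mb.build_cross_counts(trait, g_l, g_r)
            bin_codes = mb.classify_cells(cc, params).codes
            t = trait.astype(float)
            n_tot, s_tot = 200, float(t.sum())
            ss_tot = float(t @ t) - s_tot ** 2 / n_tot
            n_cell = (cc.A + cc.U).astype(float)
            cl, cr = n_cell.shape
            cell = g_l * cr + g_r
            s_cell = np.bincount(cell, weights=t, minlength=cl * cr).reshape(cl, cr)
            cont_codes = _classify_continuous(n_cell, s_cell, n_tot, s_tot, ss_tot,
                                              f_critical(params.cell_alpha, n_tot - 2),
                                              params)
            decided_same = (bin_codes == 0) == (cont_codes == 0)
            assert np.array_equal(bin_codes[decided_same], cont_codes[decided_same])
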