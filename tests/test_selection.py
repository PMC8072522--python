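"""Connection-wise group contrast, seed-level FDR and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strokeconn.atlas import RoiLabel
from strokeconn.selection import classify_and_compartment, seed_level_fdr, select_connections
from strokeconn.selection import test_all_connections as contrast_all_connections
from strokeconn.selection import test_connection as contrast_connection


def brute_force_bh(p: np.ndarray, alpha: float) -> np.ndarray:
    """Textbook Benjamini-Hochberg: reject all p <= p_(k*) where k* is the
    largest k with p_(k) <= k/m * alpha."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= k / m * alpha]
    reject = np.zeros(m, bool)
    if ks:
        reject[order[: max(ks)]] = True
    return reject


class TestConnectionContrast:
    def test_identical_groups_give_null_result(self):
        z = np.array([0.1, 0.3, -0.2, 0.1, 0.3, -0.2])
        g = np.array([0, 0, 0, 1, 1, 1])
        res = contrast_connection(z, g)
        assert res.coefficient == pytest.approx(0, abs=1e-12)
        assert res.p == pytest.approx(1, abs=1e-9)

    def test_constant_fd_reduces_to_pooled_t(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(20)
        g = np.repeat([0, 1], 10)
        fd = np.full(20, 0.25)
        res = contrast_connection(z, g, fd)
        t, p = stats.ttest_ind(z[g == 1], z[g == 0])
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.df == 18

    def test_subject_order_is_irrelevant(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(16)
        g = rng.integers(0, 2, 16)
        g[:3], g[-3:] = 0, 1
        fd = rng.uniform(0.1, 0.5, 16)
        perm = rng.permutation(16)
        a = contrast_connection(z, g, fd)
        b = contrast_connection(z[perm], g[perm], fd[perm])
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_missing_subjects_excluded_pairwise(self):
        z = np.array([0.1, np.nan, 0.2, 0.8, 0.9, 1.0, 0.7])
        g = np.array([0, 0, 0, 1, 1, 1, 1])
        res = contrast_connection(z, g)
        assert res.n == 6

    def test_empty_group_raises(self):
        z = np.array([0.1, 0.2, np.nan, np.nan])
        g = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="group"):
            contrast_connection(z, g)

    def test_vectorized_matches_scalar_path(self):
        rng = np.random.default_rng(2)
        n, R = 24, 5
        z_stack = rng.standard_normal((n, R, R))
        z_stack = (z_stack + z_stack.transpose(0, 2, 1)) / 2
        for s in range(n):
            np.fill_diagonal(z_stack[s], np.nan)
        z_stack[3, 0, 1] = z_stack[3, 1, 0] = np.nan  # force slow path for (0,1)
        g = np.repeat([0, 1], 12)
        fd = rng.uniform(0.05, 0.6, n)
        res = contrast_all_connections(z_stack, g, fd)
        for i in range(R):
            for j in range(i + 1, R):
                ref = contrast_connection(z_stack[:, i, j], g, fd)
                assert res["coefficient"][i, j] == pytest.approx(
                    ref.coefficient, abs=1e-10
                )
                assert res["p"][i, j] == pytest.approx(ref.p, abs=1e-10)


class TestSeedLevelFDR:
    def _pmat(self, rows):
        n = len(rows)
        p = np.full((n, n), np.nan)
        for i, row in enumerate(rows):
            for j, v in enumerate(row):
                if i != j:
                    p[i, j] = v
        return p

    def test_three_value_row_example(self):
        # BH thresholds at alpha=0.01, m=3: 0.00333, 0.00667, 0.01
        p = np.full((4, 4), 1.0)
        np.fill_diagonal(p, np.nan)
        p[0, 1] = p[1, 0] = 0.002
        p[0, 2] = p[2, 0] = 0.004
        p[0, 3] = p[3, 0] = 0.2
        selected, _ = seed_level_fdr(p, alpha=0.01)
        assert selected[0, 1] and selected[0, 2]
        assert not selected[0, 3]

    def test_all_ones_select_nothing(self):
        p = np.full((6, 6), 1.0)
        np.fill_diagonal(p, np.nan)
        selected, _ = seed_level_fdr(p, alpha=0.01)
        assert not selected.any()

    def test_tiny_row_selects_whole_row(self):
        p = np.full((5, 5), 0.9)
        np.fill_diagonal(p, np.nan)
        p[2, :] = 1e-6
        p[2, 2] = np.nan
        selected, _ = seed_level_fdr(p, alpha=0.01)
        assert selected[2, [0, 1, 3, 4]].all()

    def test_matches_brute_force_oracle_per_row(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            p = rng.uniform(0, 0.2, size=(n, n))
            p = (p + p.T) / 2
            np.fill_diagonal(p, np.nan)
            alpha = float(rng.uniform(0.005, 0.1))
            selected, _ = seed_level_fdr(p, alpha=alpha)
            rows = np.zeros((n, n), bool)
            for i in range(n):
                mask = np.ones(n, bool)
                mask[i] = False
                rows[i, mask] = brute_force_bh(p[i, mask], alpha)
            np.testing.assert_array_equal(selected, rows | rows.T)

    def test_both_rows_mode_is_stricter(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 0.05, (8, 8))
        p = (p + p.T) / 2
        np.fill_diagonal(p, np.nan)
        any_sel, _ = seed_level_fdr(p, alpha=0.05, mode="any")
        both_sel, _ = seed_level_fdr(p, alpha=0.05, mode="both")
        assert np.all(both_sel <= any_sel)


LABELS = [
    RoiLabel(1, "a_left", "left", 2),
    RoiLabel(2, "a_right", "right", 1),
    RoiLabel(3, "b_left", "left", 4),
    RoiLabel(4, "b_right", "right", 3),
    RoiLabel(5, "mid", "midline", None),
]


class TestClassification:
    def _mats(self, n=5):
        coef = np.zeros((n, n))
        selected = np.zeros((n, n), bool)
        p = np.ones((n, n))
        return coef, selected, p

    def test_hypo_inter_pair(self):
        coef, selected, p = self._mats()
        coef[0, 1] = coef[1, 0] = -0.3
        selected[0, 1] = selected[1, 0] = True
        cs = classify_and_compartment(coef, selected, p, p, LABELS)
        row = cs.table.iloc[0]
        assert (row.cls, row.compartment) == ("hypo", "inter")
        assert cs.counts()[("hypo", "inter")] == 1

    def test_hyper_contralesional_pair(self):
        coef, selected, p = self._mats()
        coef[0, 2] = coef[2, 0] = 0.2  # two left (contralesional) ROIs
        selected[0, 2] = selected[2, 0] = True
        cs = classify_and_compartment(coef, selected, p, p, LABELS)
        assert cs.counts()[("hyper", "contra_intra")] == 1

    def test_midline_pair_excluded(self):
        coef, selected, p = self._mats()
        coef[0, 4] = coef[4, 0] = -0.5
        selected[0, 4] = selected[4, 0] = True
        cs = classify_and_compartment(coef, selected, p, p, LABELS)
        assert len(cs) == 0

    def test_zero_coefficient_dropped_with_warning(self):
        coef, selected, p = self._mats()
        selected[0, 1] = selected[1, 0] = True  # coef stays exactly 0
        with pytest.warns(RuntimeWarning, match="zero"):
            cs = classify_and_compartment(coef, selected, p, p, LABELS)
        assert len(cs) == 0

    def test_unordered_pairs_not_duplicated(self):
        coef, selected, p = self._mats()
        coef[1, 3] = coef[3, 1] = 0.4
        selected[1, 3] = selected[3, 1] = True
        cs = classify_and_compartment(coef, selected, p, p, LABELS)
        assert len(cs) == 1
        assert cs.counts()[("hyper", "ipsi_intra")] == 1


def test_full_selection_recovers_strong_planted_shift():
    from strokeconn import synthdata as sd

    pairs = [(0, 1, -0.6), (2, 3, -0.6)]
    labels = []
    for k in range(5):
        labels.append(RoiLabel(2 * k + 1, f"r{k}l", "left", 2 * k + 2))
        labels.append(RoiLabel(2 * k + 2, f"r{k}r", "right", 2 * k + 1))
    simd = sd.simulate_group_matrices(
        15, 15, 10, 160, group1_shifts=pairs, rng=np.random.default_rng(10)
    )
    conn, res = select_connections(
        simd["z_stack"], simd["groups"], simd["mean_fd"], labels, alpha=0.01
    )
    got = {(r.roi_i, r.roi_j): r.cls for r in conn.table.itertuples()}
    assert got.get((0, 1)) == "hypo"
    assert got.get((2, 3)) == "hypo"
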