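import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigrisk.diffexp import (
    DEResult,
    SAMConfig,
    bh_adjust,
    call_de,
    fold_change,
    paired_de,
    paired_t,
    sam,
    sam_statistic,
    select_s0,
)
from sigrisk.matrix import ExpressionMatrix
from sigrisk.simulate import PairedSimConfig, SimConfig, generate_kd_pair, generate_paired_tumor_normal


def _matrix(array):
    array = np.asarray(array, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            array,
            index=[f"g{i}" for i in range(array.shape[0])],
            columns=[f"s{j}" for j in range(array.shape[1])],
        )
    )


def _labels(n1, n2):
    return pd.Series(
        ["a"] * n1 + ["b"] * n2, index=[f"s{j}" for j in range(n1 + n2)]
    )


def tusher_pooled_se(x1, x2):
    """Independent reference: pooled SE of the mean difference."""
    n1, n2 = len(x1), len(x2)
    a = (1 / n1 + 1 / n2) / (n1 + n2 - 2)
    ss = np.sum((x1 - np.mean(x1)) ** 2) + np.sum((x2 - np.mean(x2)) ** 2)
    return np.sqrt(a * ss)


class TestSamStatistic:
    def test_zero_numerator_gives_zero(self):
        m = _matrix([[1, 2, 1, 2]])
        d = sam_statistic(m, _labels(2, 2), s0=0.7)
        assert d["g0"] == 0.0

    def test_toy_hand_arithmetic(self):
        # groups (1,1) vs (2,2): zero within-group variance, d = 1/s0
        m = _matrix([[1, 1, 2, 2]])
        d = sam_statistic(m, _labels(2, 2), s0=0.5)
        assert d["g0"] == pytest.approx(2.0)

    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(40, 6))
        m = _matrix(arr)
        d = sam_statistic(m, _labels(3, 3), s0=0.0)
        for i in range(40):
            x1, x2 = arr[i, :3], arr[i, 3:]
            expected = (np.mean(x2) - np.mean(x1)) / tusher_pooled_se(x1, x2)
            assert d.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(size=(10, 8)))
        labels = _labels(4, 4)
        d_ab = sam_statistic(m, labels, s0=0.2, groups=("a", "b"))
        d_ba = sam_statistic(m, labels, s0=0.2, groups=("b", "a"))
        assert np.allclose(d_ab, -d_ba)

    def test_invariant_to_constant_shift_of_a_gene(self):
        rng = np.random.default_rng(7)
        arr = rng.normal(size=(5, 6))
        shifted = arr.copy()
        shifted[2] += 100.0
        d1 = sam_statistic(_matrix(arr), _labels(3, 3), s0=0.1)
        d2 = sam_statistic(_matrix(shifted), _labels(3, 3), s0=0.1)
        assert d1["g2"] == pytest.approx(d2["g2"], rel=1e-12)

    def test_small_group_rejected_and_zero_variance_guarded(self):
        m = _matrix([[1, 2, 3]])
        with pytest.raises(ValueError, match="2 samples"):
            sam_statistic(m, pd.Series(["a", "a", "b"], index=m.samples))
        flat = _matrix([[1, 1, 1, 1]])
        with pytest.raises(ZeroDivisionError):
            sam_statistic(flat, _labels(2, 2), s0=0.0)


class TestSelectS0:
    def test_degenerate_identical_se_returns_that_value(self):
        # 5 genes with identical within-group scatter -> all s_i equal;
        # fewer than 10 genes triggers the median fallback = that common value
        base = np.array([0.0, 1.0, 0.0, 1.0])
        m = _matrix([base + k for k in range(5)])
        s0 = select_s0(m, _labels(2, 2))
        x1, x2 = base[:2], base[2:]
        assert s0 == pytest.approx(tusher_pooled_se(x1, x2))

    def test_matches_exhaustive_grid_search(self):
        # bimodal spread of s_i; the oracle re-evaluates every candidate
        rng = np.random.default_rng(8)
        low = rng.normal(0, 0.05, size=(100, 8))
        high = rng.normal(0, 2.0, size=(100, 8))
        m = _matrix(np.vstack([low, high]))
        labels = _labels(4, 4)
        chosen = select_s0(m, labels, n_windows=20)

        # independent exhaustive evaluation of the same selection criterion
        from scipy.stats import median_abs_deviation

        values = m.values.to_numpy()
        x1, x2 = values[:, :4], values[:, 4:]
        se = np.array([tusher_pooled_se(x1[i], x2[i]) for i in range(len(values))])
        num = x2.mean(axis=1) - x1.mean(axis=1)
        order = np.argsort(se, kind="stable")
        windows = np.array_split(order, 20)
        best = (np.inf, None)
        for alpha in range(0, 101, 5):
            cand = np.percentile(se, alpha)
            d = num / (se + cand)
            mads = np.array([median_abs_deviation(d[w], scale="normal") for w in windows])
            cv = mads.std(ddof=1) / mads.mean()
            if cv < best[0] - 1e-15:
                best = (cv, cand)
        assert chosen == pytest.approx(best[1])

    def test_auto_config_routes_through_selection(self):
        cfg = SimConfig(n_genes=60, n_per_group=4, seed=3)
        m, labels, _ = generate_kd_pair(cfg)
        de = sam(m, labels, SAMConfig(s0="auto", n_permutations=10, seed=0), groups=("WT", "KD"))
        assert de.params["s0"] == pytest.approx(select_s0(m, labels, groups=("WT", "KD")))


class TestSamQvalues:
    def test_null_data_yields_almost_no_discoveries(self):
        cfg = SimConfig(n_genes=500, n_per_group=5, noise_sd=0.25, seed=21)
        m, labels, _ = generate_kd_pair(cfg)
        de = sam(m, labels, SAMConfig(n_permutations=100, seed=4), groups=("WT", "KD"))
        assert (de.table["q"] < 0.05).mean() <= 0.01

    def test_extreme_gene_gets_minimum_q(self):
        cfg = SimConfig(
            n_genes=200, n_per_group=5, de_genes=("G0005",), kd_effect=6.0,
            noise_sd=0.2, seed=22,
        )
        m, labels, _ = generate_kd_pair(cfg)
        de = sam(m, labels, SAMConfig(n_permutations=100, seed=4), groups=("WT", "KD"))
        assert de.table.loc["G0005", "q"] == de.table["q"].min()

    def test_strong_planted_genes_all_recovered(self):
        eff = {f"G{i:04d}": (2.0 if i % 2 else -2.0) for i in range(1, 21)}
        cfg = SimConfig(
            n_genes=300, n_per_group=5, de_genes=tuple(eff), kd_effect=eff,
            noise_sd=0.25, seed=23,
        )
        m, labels, _ = generate_kd_pair(cfg)
        de = sam(m, labels, SAMConfig(n_permutations=100, seed=4), groups=("WT", "KD"))
        assert de.table.loc[list(eff), "significant"].all()

    def test_q_monotone_nonincreasing_in_abs_d(self):
        cfg = SimConfig(n_genes=150, n_per_group=4, seed=24)
        m, labels, _ = generate_kd_pair(cfg)
        de = sam(m, labels, SAMConfig(n_permutations=50, seed=4), groups=("WT", "KD"))
        tab = de.table.reindex(de.table["statistic"].abs().sort_values(ascending=False).index)
        assert (np.diff(tab["q"].to_numpy()) >= -1e-12).all()

    def test_small_designs_enumerate_all_assignments_with_warning(self):
        cfg = SimConfig(n_genes=30, n_per_group=3, seed=25)
        m, labels, _ = generate_kd_pair(cfg)
        with pytest.warns(UserWarning, match="distinct label assignments"):
            de = sam(m, labels, SAMConfig(n_permutations=1000, seed=4), groups=("WT", "KD"))
        assert de.params["n_permutations"] == 20  # C(6,3)


class TestPairedT:
    def test_identical_pairs_give_t0_p1(self):
        m = _matrix([[3, 4, 3, 4]])
        pairing = pd.DataFrame({"normal": ["s0", "s1"], "tumor": ["s2", "s3"]})
        res = paired_t(m, pairing)
        assert res.loc["g0", "t"] == 0.0
        assert res.loc["g0", "p"] == 1.0

    def test_differences_123_frozen_value(self):
        # differences (1,2,3): t = 2*sqrt(3) = 3.4641, p = 0.0741799 at df=2
        m = _matrix([[0, 0, 0, 1, 2, 3]])
        pairing = pd.DataFrame(
            {"normal": ["s0", "s1", "s2"], "tumor": ["s3", "s4", "s5"]}
        )
        res = paired_t(m, pairing)
        assert res.loc["g0", "t"] == pytest.approx(3.4641016, abs=1e-6)
        assert res.loc["g0", "p"] == pytest.approx(0.0741799, abs=1e-6)

    def test_sign_flip_negates_t_keeps_p(self):
        rng = np.random.default_rng(9)
        arr = rng.normal(size=(6, 8))
        m = _matrix(arr)
        fwd = pd.DataFrame({"normal": [f"s{j}" for j in range(4)], "tumor": [f"s{j}" for j in range(4, 8)]})
        rev = fwd.rename(columns={"normal": "tumor", "tumor": "normal"})
        a, b = paired_t(m, fwd), paired_t(m, rev)
        assert np.allclose(a["t"], -b["t"])
        assert np.allclose(a["p"], b["p"])

    def test_zero_variance_nonzero_mean_flagged_infinite(self):
        m = _matrix([[0, 0, 1, 1]])
        pairing = pd.DataFrame({"normal": ["s0", "s1"], "tumor": ["s2", "s3"]})
        res = paired_t(m, pairing)
        assert np.isinf(res.loc["g0", "t"])
        assert res.loc["g0", "p"] == 0.0

    def test_single_pair_rejected(self):
        m = _matrix([[1, 2]])
        with pytest.raises(ValueError, match="2 complete pairs"):
            paired_t(m, pd.DataFrame({"normal": ["s0"], "tumor": ["s1"]}))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2] * 5)
        assert np.allclose(out, 0.2)

    def test_matches_stepup_enumeration(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        out = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            # min over k >= rank of (m/k) * p_(k)
            cands = [m / (k + 1) * p[order[k]] for k in range(rank_pos, m)]
            expected[idx] = min(1.0, min(cands))
        assert np.allclose(out, expected)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_rank_preserving(self, ps):
        out = bh_adjust(ps)
        assert (out >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust([0.1, np.nan])


class TestFoldChangeAndCalling:
    def test_equal_means_fc_one(self):
        m = _matrix([[2, 2, 2, 2]])
        fc, direction = fold_change(m, _labels(2, 2))
        assert fc["g0"] == pytest.approx(1.0)
        assert direction["g0"] == 0

    def test_log2_ratio_passes_gate(self):
        m = _matrix([[0, 0, np.log2(1.2), np.log2(1.2)]])
        fc, direction = fold_change(m, _labels(2, 2))
        assert fc["g0"] == pytest.approx(1.2)
        assert direction["g0"] == 1

    def test_group_swap_inverts_fc(self):
        rng = np.random.default_rng(10)
        m = _matrix(rng.normal(size=(5, 6)))
        labels = _labels(3, 3)
        fc_ab, dir_ab = fold_change(m, labels, groups=("a", "b"))
        fc_ba, dir_ba = fold_change(m, labels, groups=("b", "a"))
        assert np.allclose(fc_ab * fc_ba, 1.0)
        assert (dir_ab == -dir_ba).all()

    @pytest.mark.parametrize(
        "q,fc,expected",
        [
            (0.01, 1.05, False),  # fold-change gate fails
            (0.01, 1.2, True),
            (0.06, 2.0, False),  # FDR gate fails
            (0.01, 1.0 / 1.3, True),  # down-regulation counted symmetrically
        ],
    )
    def test_joint_significance_rule(self, q, fc, expected):
        table = pd.DataFrame(
            {
                "statistic": [1.0],
                "fc": [fc],
                "direction": [1 if fc >= 1 else -1],
                "p": [np.nan],
                "q": [q],
                "significant": [False],
            },
            index=["g0"],
        )
        result = call_de(DEResult(table), fdr_threshold=0.05, fc_threshold=1.1)
        assert bool(result.table.loc["g0", "significant"]) is expected


class TestPairedDE:
    def test_planted_concordant_genes_found(self):
        shifts = {f"G{i:04d}": (1.5 if i % 2 else -1.5) for i in range(1, 11)}
        cfg = PairedSimConfig(
            n_genes=200, n_patients=15, concordant_genes=shifts, seed=30,
        )
        m, pairing, _ = generate_paired_tumor_normal(cfg)
        de = paired_de(m, pairing)
        assert de.table.loc[list(shifts), "significant"].all()
        assert (de.table.loc[list(shifts), "direction"] == np.sign(list(shifts.values()))).all()

    def test_null_bh_controls_discoveries(self):
        cfg = PairedSimConfig(n_genes=300, n_patients=12, seed=31)
        m, pairing, _ = generate_paired_tumor_normal(cfg)
        de = paired_de(m, pairing)
        assert de.table["significant"].mean() <= 0.01
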