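"""Differential abundance: Welch test, BH adjustment, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lipsmr import (
    PeptideIntensityTable,
    bh_adjust,
    normalize_intensities,
    test_peptides as run_differential_tests,
)
from lipsmr.stats import welch_t


def make_log2_table(veh: np.ndarray, cmp_: np.ndarray) -> PeptideIntensityTable:
    n_pep, n_rep = veh.shape
    cols = {}
    for r in range(n_rep):
        cols[f"intensity_vehicle_{r + 1}"] = veh[:, r]
    for r in range(cmp_.shape[1]):
        cols[f"intensity_compound_{r + 1}"] = cmp_[:, r]
    df = pd.DataFrame(
        {
            "peptide_id": [f"pep{i}" for i in range(n_pep)],
            "sequence": ["AAK"] * n_pep,
            **cols,
        }
    )
    return PeptideIntensityTable(df, scale="log2")


class TestWelch:
    def test_worked_example(self):
        t, df, p, degen = welch_t(
            np.array([10.0, 10.2, 9.8]), np.array([12.0, 12.2, 11.8])
        )
        assert t == pytest.approx(12.247448713915889, rel=1e-9)
        assert df == pytest.approx(4.0, rel=1e-9)
        assert p == pytest.approx(2.552167494419269e-4, rel=1e-9)
        assert not degen

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    def test_matches_scipy_oracle(self, xs, ys):
        x, y = np.array(xs), np.array(ys)
        t, df, p, degen = welch_t(x, y)
        if degen:
            return
        ref = sps.ttest_ind(y, x, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_identical_groups_are_ns(self):
        x = np.array([[10.0, 10.5, 11.0]])
        res = run_differential_tests(make_log2_table(x, x.copy()))
        assert res.loc[0, "log2fc"] == 0.0
        assert res.loc[0, "direction"] == "ns"

    def test_zero_variance_different_means_is_degenerate_p_zero(self):
        t, df, p, degen = welch_t(np.array([5.0, 5.0]), np.array([7.0, 7.0]))
        assert degen and p == 0.0 and np.isinf(t)

    def test_peptides_with_too_few_replicates_are_dropped(self):
        veh = np.array([[10.0, np.nan, np.nan], [10.0, 10.1, 9.9]])
        cmp_ = np.array([[12.0, 12.1, 11.9], [12.0, 12.1, 11.9]])
        res = run_differential_tests(make_log2_table(veh, cmp_))
        assert list(res["peptide_id"]) == ["pep1"]
        assert res.notna().all().all()


class TestBH:
    def test_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def brute_force(self, p):
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        for rank_i, i in enumerate(order, start=1):
            vals = [
                m * p[j] / rank_j
                for rank_j, j in enumerate(order, start=1)
                if rank_j >= rank_i
            ]
            q[i] = min(1.0, min(vals))
        return q

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_definition_and_statsmodels(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert np.allclose(q, self.brute_force(p))
        from statsmodels.stats.multitest import multipletests

        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)
        assert np.all(q >= p - 1e-15)  # BH never decreases a p-value

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestNormalization:
    def test_equal_medians_is_pure_log2(self):
        lin = np.exp2(np.array([[10.0, 11.0], [12.0, 12.0], [14.0, 15.0]]))
        table = PeptideIntensityTable(
            pd.DataFrame(
                {
                    "peptide_id": ["a", "b", "c"],
                    "sequence": ["AAK"] * 3,
                    "intensity_vehicle_1": lin[:, 0],
                    "intensity_compound_1": lin[:, 1],
                }
            ),
            scale="linear",
        )
        out = normalize_intensities(table)
        assert out.scale == "log2"
        assert np.allclose(out.intensity_matrix(), np.log2(lin))

    def test_scaled_sample_recentred(self, small_lip_dataset):
        _, table, _ = small_lip_dataset
        df = table.df.copy()
        df["intensity_vehicle_1"] *= 2.0  # one sample loaded twice as heavy
        out = normalize_intensities(PeptideIntensityTable(df, scale="linear"))
        med = np.nanmedian(out.intensity_matrix(), axis=0)
        assert np.allclose(med, med[0])

    def test_per_sample_medians_all_equal_after_normalization(self):
        rng = np.random.default_rng(7)
        lin = np.exp2(rng.uniform(15, 25, size=(50, 6)))
        cols = [f"intensity_vehicle_{i}" for i in (1, 2, 3)] + [
            f"intensity_compound_{i}" for i in (1, 2, 3)
        ]
        df = pd.DataFrame(lin, columns=cols)
        df.insert(0, "sequence", ["AAK"] * 50)
        df.insert(0, "peptide_id", [f"p{i}" for i in range(50)])
        out = normalize_intensities(PeptideIntensityTable(df, scale="linear"))
        log = out.intensity_matrix()
        assert np.allclose(np.median(log, axis=0), np.median(log))

    def test_non_positive_rejected_with_rows_named(self):
        df = pd.DataFrame(
            {
                "peptide_id": ["a", "b"],
                "sequence": ["AAK", "CCK"],
                "intensity_vehicle_1": [1.0, -2.0],
                "intensity_compound_1": [1.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="b"):
            PeptideIntensityTable(df, scale="linear")


class TestSymmetryAndMonotonicity:
    @pytest.fixture(scope="class")
    def random_table(self):
        rng = np.random.default_rng(3)
        veh = rng.normal(20, 1, size=(300, 3))
        cmp_ = rng.normal(20, 1, size=(300, 3))
        cmp_[:30] += 2.5  # some true shifts
        return veh, cmp_

    def test_label_swap_negates_log2fc_and_swaps_directions(self, random_table):
        veh, cmp_ = random_table
        res = run_differential_tests(make_log2_table(veh, cmp_))
        res_swapped = run_differential_tests(make_log2_table(cmp_, veh))
        assert np.allclose(res["log2fc"], -res_swapped["log2fc"])
        assert np.allclose(res["p"], res_swapped["p"])
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert list(res["direction"].map(swap)) == list(res_swapped["direction"])

    def test_stricter_alpha_never_adds_significant_peptides(self, random_table):
        veh, cmp_ = random_table
        table = make_log2_table(veh, cmp_)
        counts = [
            (run_differential_tests(table, alpha=a)["direction"] != "ns").sum()
            for a in (0.2, 0.1, 0.05, 0.01)
        ]
        assert counts == sorted(counts, reverse=True)
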