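import numpy as np
import pytest

from haplopop import MISSING, amova, pairwise_fst
from conftest import make_dataset
from oracles import amova_ss_brute


def two_pop_data(calls1, calls2, region=None):
    calls = calls1 + calls2
    pops = ["P1"] * len(calls1) + ["P2"] * len(calls2)
    regions = region or {"P1": "R", "P2": "R"}
    return make_dataset([[c] for c in calls], pops, regions=regions)


class TestTwoLevelToys:
    def test_complete_fixation_gives_phi_one(self):
        data = two_pop_data([100, 100], [102, 102])
        res = amova(data, n_perm=0)
        assert res.phi_st == pytest.approx(1.0)
        within = res.table[res.table["stratum"] == "Within populations"]
        assert within["sigma2"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_quadratic_forms(self):
        # pop1={A,A}, pop2={A,B}: SS_total=0.75, SS_within=0.5,
        # SS_among=0.25, s2_within=0.25, s2_among=0, Phi_ST=0
        data = two_pop_data([100, 100], [100, 102])
        res = amova(data, n_perm=0)
        t = res.table.set_index("stratum")
        assert t.loc["Total", "SS"] == pytest.approx(0.75, abs=1e-12)
        assert t.loc["Within populations", "SS"] == pytest.approx(0.5, abs=1e-12)
        assert t.loc["Among populations", "SS"] == pytest.approx(0.25, abs=1e-12)
        assert t.loc["Within populations", "sigma2"] == pytest.approx(0.25)
        assert t.loc["Among populations", "sigma2"] == pytest.approx(0.0, abs=1e-12)
        assert res.phi_st == pytest.approx(0.0, abs=1e-12)


class TestThreeLevel:
    def test_df_on_paper_design(self, paper_sim):
        """220 individuals in 11 populations and 2 regions give the
        textbook degrees of freedom 1 / 9 / 209 / 219."""
        data, *_ = paper_sim
        res = amova(data, n_perm=0)
        assert list(res.table["df"]) == [1, 9, 209, 219]

    def test_ss_additivity_and_brute_force(self):
        """Stratum sums of squares add to the total (1e-9) and match the
        explicit pairwise-distance oracle, with missing data."""
        rng = np.random.default_rng(8)
        calls = rng.integers(100, 106, size=(24, 3))
        calls[rng.random(calls.shape) < 0.1] = MISSING
        pops = (["P1"] * 6 + ["P2"] * 6 + ["P3"] * 6 + ["P4"] * 6)
        data = make_dataset(calls, pops,
                            regions={"P1": "R1", "P2": "R1",
                                     "P3": "R2", "P4": "R2"})
        res = amova(data, n_perm=0)
        t = res.table.set_index("stratum")
        ss = t["SS"]
        assert abs(ss["Among regions"] + ss["Among populations within regions"]
                   + ss["Within populations"] - ss["Total"]) < 1e-9
        ss_t, ss_w = amova_ss_brute(calls, data.pop_labels())
        assert ss["Total"] == pytest.approx(ss_t, abs=1e-9)
        assert ss["Within populations"] == pytest.approx(ss_w, abs=1e-9)
        _, ss_wr = amova_ss_brute(calls, data.region_labels())
        assert ss["Among regions"] == pytest.approx(ss_t - ss_wr, abs=1e-9)

    def test_percentages_sum_to_hundred(self, paper_sim):
        data, *_ = paper_sim
        res = amova(data, n_perm=0)
        pct = res.table["pct"].iloc[:3]
        assert pct.sum() == pytest.approx(100.0)
        assert res.phi["phi_st"] == pytest.approx(
            (res.table["sigma2"].iloc[0] + res.table["sigma2"].iloc[1])
            / res.table["sigma2"].iloc[3])

    def test_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(100, 105, size=(20, 3))
        pops = ["P1"] * 5 + ["P2"] * 5 + ["P3"] * 5 + ["P4"] * 5
        regions = {"P1": "R1", "P2": "R1", "P3": "R2", "P4": "R2"}
        a = amova(make_dataset(calls, pops, regions=regions), n_perm=0)
        b = amova(make_dataset(7 * calls + 13, pops, regions=regions), n_perm=0)
        for k in a.phi:
            assert a.phi[k] == pytest.approx(b.phi[k], nan_ok=True)

    def test_permutation_p_small_for_fixed_structure(self):
        calls = np.array([[100]] * 10 + [[102]] * 10)
        pops = ["P1"] * 5 + ["P2"] * 5 + ["P3"] * 5 + ["P4"] * 5
        regions = {"P1": "R1", "P2": "R1", "P3": "R2", "P4": "R2"}
        res = amova(make_dataset(calls, pops, regions=regions),
                    n_perm=199, seed=0)
        assert res.p["phi_st"] < 0.02


class TestPairwiseFst:
    def test_structural_properties(self, paper_sim):
        data, *_ = paper_sim
        res = pairwise_fst(data, n_perm=0)
        m = res.fst.values
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 0.0)

    def test_fixed_disjoint_pair_gives_one(self):
        data = two_pop_data([100, 100, 100], [102, 102, 102])
        res = pairwise_fst(data, n_perm=99, seed=0)
        assert res.fst.loc["P1", "P2"] == pytest.approx(1.0)
        assert res.pvalues.loc["P1", "P2"] < 0.11

    def test_null_pair_is_near_zero(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(100, 120, size=(60, 6))
        data = make_dataset(calls, ["P1"] * 30 + ["P2"] * 30)
        res = pairwise_fst(data, n_perm=0)
        assert abs(res.fst.loc["P1", "P2"]) < 0.02

    def test_singleton_population_skipped(self):
        data = make_dataset([[100], [102], [104]], ["P1", "P1", "P2"])
        res = pairwise_fst(data, n_perm=0)
        assert np.isnan(res.fst.loc["P1", "P2"])


def test_one_region_reduction_consistency():
    """With a single region, the hierarchical entry point reports the
    two-level partition (among / within populations) whose SS match the
    brute-force quadratic forms."""
    rng = np.random.default_rng(9)
    calls = rng.integers(100, 104, size=(18, 2))
    data = make_dataset(calls, ["P1"] * 6 + ["P2"] * 6 + ["P3"] * 6)
    res = amova(data, n_perm=0)
    assert list(res.table["stratum"]) == [
        "Among populations", "Within populations", "Total"]
    ss_t, ss_w = amova_ss_brute(calls, data.pop_labels())
    t = res.table.set_index("stratum")
    assert t.loc["Total", "SS"] == pytest.approx(ss_t, abs=1e-9)
    assert t.loc["Within populations", "SS"] == pytest.approx(ss_w, abs=1e-9)
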