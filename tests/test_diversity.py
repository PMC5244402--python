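import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplopop import (MISSING, allele_frequencies, default_g,
                      rarefied_allelic_richness, regional_pooling,
                      unbiased_haploid_diversity)
from conftest import make_dataset
from oracles import rarefaction_enumerate, rarefaction_monte_carlo


def freqs_of(calls, pops):
    return allele_frequencies(make_dataset(calls, pops))


class TestUnbiasedHaploidDiversity:
    def test_two_distinct_haploids(self):
        res = unbiased_haploid_diversity(freqs_of([[100], [102]], ["P", "P"]))
        assert res.per_locus.loc["P", "L1"] == pytest.approx(1.0)

    def test_monomorphic_locus_is_zero(self):
        res = unbiased_haploid_diversity(freqs_of([[100]] * 5, ["P"] * 5))
        assert res.per_locus.loc["P", "L1"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # n=4, counts {2,1,1}: h = 1 - (4+1+1)/16 = 0.625, uh = 4/3 * h
        res = unbiased_haploid_diversity(
            freqs_of([[100], [100], [102], [104]], ["P"] * 4))
        assert res.per_locus.loc["P", "L1"] == pytest.approx(0.625 * 4 / 3)

    def test_undefined_below_two_calls(self):
        freqs = freqs_of([[100, 100], [MISSING, 102]], ["P", "P"])
        with pytest.warns(UserWarning):
            res = unbiased_haploid_diversity(freqs)
        assert np.isnan(res.per_locus.loc["P", "L1"])
        assert res.mean["P"] == pytest.approx(res.per_locus.loc["P", "L2"])

    def test_invariant_to_allele_relabeling(self):
        calls = np.array([[100], [100], [102], [104], [102]])
        relabeled = np.where(calls == 100, 900,
                             np.where(calls == 102, 500, 710))
        a = unbiased_haploid_diversity(freqs_of(calls, ["P"] * 5))
        b = unbiased_haploid_diversity(freqs_of(relabeled, ["P"] * 5))
        assert a.per_locus.loc["P", "L1"] == pytest.approx(
            b.per_locus.loc["P", "L1"])


class TestRarefaction:
    def test_worked_example_11_over_6(self):
        # N=4, counts {a:2, b:1, c:1}, g=2: all C(4,2)=6 subsets average 11/6
        freqs = freqs_of([[100], [100], [102], [104]], ["P"] * 4)
        res = rarefied_allelic_richness(freqs, 2)
        assert res.alpha.loc["P", "L1"] == pytest.approx(11 / 6)

    def test_full_sample_recovers_distinct_count(self):
        freqs = freqs_of([[100], [100], [102], [104]], ["P"] * 4)
        res = rarefied_allelic_richness(freqs, 4)
        assert res.alpha.loc["P", "L1"] == pytest.approx(3.0)

    def test_private_by_construction(self):
        freqs = freqs_of([[100]] * 3 + [[102]] * 3, ["P"] * 3 + ["Q"] * 3)
        res = rarefied_allelic_richness(freqs, 1)
        assert res.pi.loc["P", "L1"] == pytest.approx(1.0)
        assert res.pi.loc["Q", "L1"] == pytest.approx(1.0)

    def test_closed_form_matches_enumeration(self):
        """alpha_g equals exhaustive subset enumeration for random small
        samples (the rarefaction oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(3, 13))
            calls = rng.integers(100, 105, size=(n, 1))
            g = int(rng.integers(1, n + 1))
            freqs = freqs_of(calls, ["P"] * n)
            res = rarefied_allelic_richness(freqs, g)
            counts = freqs.counts[("P", "L1")]
            assert res.alpha.loc["P", "L1"] == pytest.approx(
                rarefaction_enumerate(counts, g), abs=1e-10)

    def test_closed_form_matches_monte_carlo_at_larger_n(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(100, 112, size=(60, 1))
        freqs = freqs_of(calls, ["P"] * 60)
        res = rarefied_allelic_richness(freqs, 8)
        mc, se = rarefaction_monte_carlo(freqs.counts[("P", "L1")], 8,
                                         5000, rng)
        assert abs(res.alpha.loc["P", "L1"] - mc) < 3 * se

    def test_alpha_nondecreasing_in_g(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(100, 108, size=(12, 1))
        freqs = freqs_of(calls, ["P"] * 12)
        values = [rarefied_allelic_richness(freqs, g).alpha.loc["P", "L1"]
                  for g in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_pi_zero_when_alleles_shared_at_full_size(self):
        """pi_g = 0 when every allele occurs in both strata and g equals
        each stratum's full size."""
        calls = [[100], [102], [100], [102]]
        freqs = freqs_of(calls, ["P", "P", "Q", "Q"])
        res = rarefied_allelic_richness(freqs, 2)
        assert res.pi.loc["P", "L1"] == pytest.approx(0.0)
        assert res.pi.loc["Q", "L1"] == pytest.approx(0.0)

    def test_pi_bounded_by_alpha(self, paper_sim):
        data, *_ = paper_sim
        freqs = allele_frequencies(data)
        res = rarefied_allelic_richness(freqs, 8)
        alpha = res.alpha.values.ravel()
        pi = res.pi.values.ravel()
        ok = ~np.isnan(alpha)
        assert np.all(pi[ok] <= alpha[ok] + 1e-12)
        assert np.all(pi[ok] >= -1e-12)

    def test_small_strata_excluded(self):
        calls = [[100], [102], [104], [100], [102]]
        freqs = freqs_of(calls, ["P", "P", "P", "Q", "Q"])
        res = rarefied_allelic_richness(freqs, 3)
        assert np.isnan(res.alpha.loc["Q", "L1"])
        assert res.alpha.loc["P", "L1"] == pytest.approx(3.0)

    def test_invalid_g_rejected(self):
        freqs = freqs_of([[100], [102]], ["P", "P"])
        with pytest.raises(ValueError):
            rarefied_allelic_richness(freqs, 0)


class TestRegionalPooling:
    def test_additivity(self):
        data = make_dataset([[100], [100], [100], [102]],
                            ["P", "P", "Q", "Q"],
                            regions={"P": "R", "Q": "R"})
        reg = regional_pooling(data)
        assert reg.counts[("R", "L1")] == {100: 3, 102: 1}

    def test_single_population_region_is_identity(self):
        data = make_dataset([[100], [102]], ["P", "P"],
                            regions={"P": "R"})
        reg = regional_pooling(data)
        pop = allele_frequencies(data)
        assert reg.counts[("R", "L1")] == pop.counts[("P", "L1")]


def test_default_g_rule(paper_sim):
    data, *_ = paper_sim
    freqs = allele_frequencies(data)
    g = default_g(freqs)
    mins = []
    for s in freqs.strata:
        mins.append(min(freqs.n(s, l) for l in freqs.loci))
    assert g == min(mins)


@settings(max_examples=25, deadline=None)
@given(counts=st.lists(st.integers(1, 5), min_size=1, max_size=4),
       g=st.integers(1, 6))
def test_presence_probability_matches_enumeration(counts, g):
    """Property: the closed-form alpha_g agrees with enumeration for any
    small allele-count configuration."""
    from haplopop.diversity import presence_probability
    n = sum(counts)
    if g > n:
        g = n
    q = presence_probability(n, np.array(counts), g)
    expected = rarefaction_enumerate(
        {i: c for i, c in enumerate(counts)}, g)
    assert float(q.sum()) == pytest.approx(expected, abs=1e-10)
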