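import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haplopop import (MISSING, SitesTable, allele_frequencies, detect_gra,
                      distance_pair_kde, edwards_distance, geo_distance_matrix,
                      haversine_km, mantel_ibd, sasha)
from conftest import make_dataset


def sites_for(pops, coords):
    return SitesTable(pd.DataFrame({
        "population": pops,
        "region": ["all"] * len(pops),
        "latitude": [c[0] for c in coords],
        "longitude": [c[1] for c in coords],
    }))


class TestEdwardsDistance:
    def test_identical_frequencies_give_zero(self):
        data = make_dataset([[100], [102], [100], [102]],
                            ["P", "P", "Q", "Q"])
        d = edwards_distance(allele_frequencies(data))
        assert d.loc["P", "Q"] == pytest.approx(0.0)

    def test_disjoint_monomorphic_give_one(self):
        data = make_dataset([[100], [100], [102], [102]],
                            ["P", "P", "Q", "Q"])
        d = edwards_distance(allele_frequencies(data))
        assert d.loc["P", "Q"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # freqs (1, 0) vs (0.5, 0.5): D = sqrt(1 - sqrt(0.5))
        data = make_dataset([[100], [100], [100], [102]],
                            ["P", "P", "Q", "Q"])
        d = edwards_distance(allele_frequencies(data))
        assert d.loc["P", "Q"] == pytest.approx(np.sqrt(1 - np.sqrt(0.5)))

    def test_empty_locus_excluded(self):
        data = make_dataset([[100, MISSING], [100, MISSING],
                             [100, 200], [102, 200]],
                            ["P", "P", "Q", "Q"])
        d = edwards_distance(allele_frequencies(data))
        # locus 2 unscored in P: only locus 1 contributes
        assert d.loc["P", "Q"] == pytest.approx(np.sqrt(1 - np.sqrt(0.5)))


class TestMantel:
    def test_perfect_linear_association(self):
        geo = np.abs(np.subtract.outer(np.arange(6.0), np.arange(6.0)))
        gen = 0.01 * geo
        res = mantel_ibd(gen, geo, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_matches_scikit_bio(self):
        """Cross-check r and permutation p against the independent
        scikit-bio implementation."""
        from skbio.stats.distance import DistanceMatrix, mantel
        rng = np.random.default_rng(2)
        a = rng.random((7, 7)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = a + 0.3 * rng.random((7, 7)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        res = mantel_ibd(a, b, n_perm=0)
        r_ref, p_ref, _ = mantel(DistanceMatrix(a), DistanceMatrix(b),
                                 method="pearson", permutations=999,
                                 alternative="greater")
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        res_p = mantel_ibd(a, b, n_perm=999, seed=1)
        assert res_p.p_perm == pytest.approx(p_ref, abs=0.05)

    def test_null_p_is_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(30):
            a = rng.random((8, 8)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
            b = rng.random((8, 8)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
            ps.append(mantel_ibd(a, b, n_perm=99,
                                 seed=int(rng.integers(2 ** 31))).p_perm)
        assert 0.25 < np.mean(ps) < 0.75
        assert np.mean(np.array(ps) <= 0.05) <= 0.2

    def test_constant_matrix_undefined(self):
        m = np.zeros((4, 4))
        assert np.isnan(mantel_ibd(m, m, n_perm=0).r)


class TestKde:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8)) * 100; a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = rng.random((8, 8)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        kde = distance_pair_kde(b, a, grid=120)
        assert kde.integral() == pytest.approx(1.0, abs=0.01)

    def test_identical_pairs_give_single_mode(self):
        gen = np.full((5, 5), 0.3); np.fill_diagonal(gen, 0)
        geo = np.full((5, 5), 50.0); np.fill_diagonal(geo, 0)
        kde = distance_pair_kde(gen, geo)
        iy, ix = np.unravel_index(np.argmax(kde.density), kde.density.shape)
        assert kde.x[ix] == pytest.approx(50.0, abs=5)
        assert kde.y[iy] == pytest.approx(0.3, abs=0.05)

    def test_continuous_cline_gives_connected_ridge(self):
        """A linear genetic-geographic cline produces one connected
        above-half-max region (a single cloud, not patches)."""
        from scipy import ndimage
        geo = np.abs(np.subtract.outer(np.arange(10.0), np.arange(10.0))) * 30
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.01, geo.shape); noise = (noise + noise.T) / 2
        gen = 0.002 * geo + noise; np.fill_diagonal(gen, 0)
        kde = distance_pair_kde(gen, geo)
        mask = kde.density > 0.5 * kde.density.max()
        _, n_components = ndimage.label(mask)
        assert n_components == 1


class TestGeodesy:
    def test_known_distance(self):
        # Madrid to Barcelona is ~505 km
        d = float(haversine_km(40.42, -3.70, 41.39, 2.17))
        assert d == pytest.approx(505, abs=15)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-80, 80), st.floats(-179, 179)),
                    min_size=3, max_size=3))
    def test_metric_properties(self, pts):
        (a, b, c) = pts
        dab = float(haversine_km(a[0], a[1], b[0], b[1]))
        dba = float(haversine_km(b[0], b[1], a[0], a[1]))
        dac = float(haversine_km(a[0], a[1], c[0], c[1]))
        dcb = float(haversine_km(c[0], c[1], b[0], b[1]))
        assert dab == pytest.approx(dba, abs=1e-9)
        assert dab >= 0
        assert dab <= dac + dcb + 1e-6
        assert float(haversine_km(a[0], a[1], a[0], a[1])) == 0.0


class TestSasha:
    def universal_data(self):
        # one locus where everyone shares allele 100, one variable locus
        calls = [[100, 200], [100, 202], [100, 200], [100, 202]]
        data = make_dataset(calls, ["P", "P", "Q", "Q"])
        sites = sites_for(["P", "Q"], [(40, -5), (42, 3)])
        return data, sites

    def test_universal_allele_observed_equals_expected(self):
        data, sites = self.universal_data()
        res = sasha(data, sites, n_perm=0,
                    subset={("L1", 100)})
        assert res.observed_mean_km == pytest.approx(res.expected_mean_km)
        assert sorted(res.observed) == pytest.approx(sorted(res.expected))

    def test_private_alleles_give_zero_observed_mean(self):
        calls = [[100], [100], [102], [102]]
        data = make_dataset(calls, ["P", "P", "Q", "Q"])
        sites = sites_for(["P", "Q"], [(40, -5), (42, 3)])
        res = sasha(data, sites, n_perm=999, seed=0)
        assert res.observed_mean_km == pytest.approx(0.0)
        assert res.expected_mean_km > 0
        # only C(4,2)=6 label arrangements exist; 2 of them co-locate both
        # alleles, so the true one-sided p is 1/3
        assert res.p_perm == pytest.approx(1 / 3, abs=0.06)

    def test_expected_invariant_under_allele_permutation(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(100, 104, size=(12, 2))
        pops = ["P"] * 4 + ["Q"] * 4 + ["R"] * 4
        data = make_dataset(calls, pops)
        sites = sites_for(["P", "Q", "R"], [(40, -5), (42, 3), (38, 1)])
        base = sasha(data, sites, n_perm=0)
        permuted = calls.copy()
        for j in range(2):
            permuted[:, j] = permuted[rng.permutation(12), j]
        res = sasha(make_dataset(permuted, pops), sites, n_perm=0)
        assert np.array_equal(np.sort(base.expected), np.sort(res.expected))

    def test_null_permutation_means_center_on_expected(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(100, 106, size=(30, 3))
        pops = ["P"] * 10 + ["Q"] * 10 + ["R"] * 10
        data = make_dataset(calls, pops)
        sites = sites_for(["P", "Q", "R"], [(40, -5), (42, 3), (36, -8)])
        res = sasha(data, sites, n_perm=300, seed=1)
        se = res.perm_means.std() / np.sqrt(len(res.perm_means))
        assert abs(res.perm_means.mean() - res.expected_mean_km) < max(3 * se, 1.0)


class TestGra:
    def scattered_design(self, rng, n_sites=6, per_site=8):
        pops = [f"S{i}" for i in range(n_sites)]
        coords = [(35 + 2.0 * i, -10 + 3.5 * i) for i in range(n_sites)]
        sites = sites_for(pops, coords)
        labels = [p for p in pops for _ in range(per_site)]
        return sites, labels

    def test_universal_allele_never_restricted(self):
        rng = np.random.default_rng(0)
        sites, labels = self.scattered_design(rng)
        calls = np.full((len(labels), 1), 100)
        data = make_dataset(calls, labels)
        res = detect_gra(data, sites, n_boot=300, seed=1)
        assert not res.table["restricted"].any()

    def test_peripheral_private_allele_is_restricted(self):
        """An allele confined to the most peripheral site, far beyond the
        null centroid spread, is flagged."""
        rng = np.random.default_rng(1)
        sites, labels = self.scattered_design(rng)
        calls = np.array([[100]] * 40 + [[102]] * 8)  # S5 carries 102 only
        data = make_dataset(calls, labels)
        res = detect_gra(data, sites, n_boot=1000, seed=2)
        row = res.table[res.table["allele"] == 102].iloc[0]
        assert bool(row["restricted"])

    def test_translation_invariance_of_flags(self):
        rng = np.random.default_rng(3)
        sites, labels = self.scattered_design(rng)
        calls = rng.integers(100, 106, size=(len(labels), 2))
        data = make_dataset(calls, labels)
        a = detect_gra(data, sites, n_boot=400, seed=7)
        shifted = SitesTable(sites.table.assign(
            latitude=sites.table["latitude"] - 3,
            longitude=sites.table["longitude"] + 8))
        b = detect_gra(data, shifted, n_boot=400, seed=7)
        assert list(a.table["restricted"]) == list(b.table["restricted"])

    def test_gra_percentage_bookkeeping(self):
        table = pd.DataFrame({
            "locus": ["L1"] * 220, "allele": range(220),
            "n_carriers": 2, "cx": 0.0, "cy": 0.0,
            "ci_x_lo": -1.0, "ci_x_hi": 1.0, "ci_y_lo": -1.0, "ci_y_hi": 1.0,
            "restricted": [True] * 29 + [False] * 191,
        })
        from haplopop import GraResult
        res = GraResult(table, n_boot=1000)
        assert res.n_restricted == 29 and res.n_alleles == 220
        assert round(res.pct_restricted, 2) == 13.18
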