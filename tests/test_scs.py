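"""SCS construction, outside-share statistics, likelihood, country tables."""

import numpy as np
import pytest

from scspace import indicators as ind
from scspace import scs as scs_mod
from scspace import synthetic as syn
from scspace import triangle as tri


def _chart(inds):
    return tri.to_triangle(np.asarray(inds["P"]), np.asarray(inds["pet_ratio"]))


@pytest.fixture(scope="module")
def known_scenario():
    return syn.make_known_outside_scenario(
        0.3, syn.ScenarioSpec(nlat=60, nlon=120, seed=21, n_gcms=3))


def _scenario_shares(sc, coverage=0.95, bins=60):
    base_pts = _chart(ind.indicators_from_climate(sc.baseline))
    fut_xy = []
    for fut in sc.futures:
        pts = _chart(ind.indicators_from_climate(fut))
        fut_xy.append((pts.x, pts.y))
    crop = np.asarray(sc.production["crop"])
    mask = scs_mod.build_scs(base_pts.x, base_pts.y, crop,
                             coverage=coverage, bins=bins)
    return scs_mod.outside_scs_share(fut_xy, crop, mask,
                                     (base_pts.x, base_pts.y)), mask


class TestBuildSCS:
    def test_single_occupied_bin(self):
        x = np.full(10, 0.41)
        y = np.full(10, 0.12)
        mask = scs_mod.build_scs(x, y, np.ones(10))
        assert mask.member.sum() == 1
        assert mask.achieved == 1.0

    def test_two_bins_96_4_split(self):
        x = np.array([0.2, 0.8])
        y = np.array([0.0, 0.0])
        mask = scs_mod.build_scs(x, y, np.array([96.0, 4.0]), coverage=0.95)
        assert mask.member.sum() == 1
        assert scs_mod.is_inside(mask, np.array([0.2]), np.array([0.0]))[0]
        assert not scs_mod.is_inside(mask, np.array([0.8]), np.array([0.0]))[0]

    def test_coverage_and_minimality(self, triangle_baseline, production):
        crop = np.asarray(production["crop"])
        mask = scs_mod.build_scs(triangle_baseline.x, triangle_baseline.y, crop)
        total = mask.bin_mass.sum()
        inside_mass = mask.bin_mass[mask.member].sum()
        assert inside_mass / total >= 0.95
        # dropping the smallest retained bin breaks coverage
        smallest = mask.bin_mass[mask.member].min()
        assert (inside_mass - smallest) / total < 0.95

    def test_minimality_across_coverages_and_bins(self, triangle_baseline, production):
        crop = np.asarray(production["crop"])
        for coverage in (0.5, 0.8, 0.99):
            for bins in (20, 60):
                mask = scs_mod.build_scs(triangle_baseline.x, triangle_baseline.y,
                                         crop, coverage=coverage, bins=bins)
                total = mask.bin_mass.sum()
                inside = mask.bin_mass[mask.member].sum()
                assert inside / total >= coverage
                assert (inside - mask.bin_mass[mask.member].min()) / total < coverage

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            scs_mod.build_scs(np.array([0.5]), np.array([0.5]), np.array([0.0]))
        with pytest.raises(ValueError):
            scs_mod.build_scs(np.array([0.5]), np.array([0.5]), np.array([1.0]),
                              coverage=1.5)


class TestOutsideShare:
    def test_future_equals_baseline_share_zero(self, triangle_baseline, production):
        crop = np.asarray(production["crop"])
        mask = scs_mod.build_scs(triangle_baseline.x, triangle_baseline.y, crop)
        shares = scs_mod.outside_scs_share(
            [(triangle_baseline.x, triangle_baseline.y)] * 3, crop, mask,
            (triangle_baseline.x, triangle_baseline.y))
        assert np.all(shares.per_gcm == 0.0)
        assert shares.median == 0.0

    def test_all_cells_displaced_share_one(self, triangle_baseline, production):
        crop = np.asarray(production["crop"])
        mask = scs_mod.build_scs(triangle_baseline.x, triangle_baseline.y, crop)
        # every cell pushed to the chart apex, far beyond the production cloud
        far = (np.full_like(triangle_baseline.x, 0.5),
               np.full_like(triangle_baseline.y, 0.999))
        shares = scs_mod.outside_scs_share([far], crop, mask,
                                           (triangle_baseline.x, triangle_baseline.y))
        assert shares.per_gcm[0] == 1.0

    def test_known_fraction_recovered(self, known_scenario):
        shares, mask = _scenario_shares(known_scenario)
        truth = known_scenario.ground_truth.fraction
        assert shares.median == pytest.approx(truth, abs=0.02)
        assert abs(shares.median - 0.3) <= 0.02

    def test_share_monotone_nonincreasing_in_coverage(self, known_scenario):
        shares = [
            _scenario_shares(known_scenario, coverage=c)[0].median
            for c in (0.80, 0.90, 0.95, 0.99)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(shares, shares[1:]))

    def test_misaligned_future_rejected(self, triangle_baseline, production):
        crop = np.asarray(production["crop"])
        mask = scs_mod.build_scs(triangle_baseline.x, triangle_baseline.y, crop)
        with pytest.raises(ValueError):
            scs_mod.outside_scs_share(
                [(np.zeros(3), np.zeros(3))], crop, mask,
                (triangle_baseline.x, triangle_baseline.y))


class TestLikelihood:
    @pytest.mark.parametrize(
        "count, label",
        [(0, "very likely inside"), (1, "likely inside"), (3, "likely inside"),
         (4, "potentially outside"), (5, "potentially outside"),
         (6, "potentially outside"), (7, "likely outside"), (8, "likely outside")],
    )
    def test_category_bins(self, count, label):
        stack = np.zeros((8, 1, 1), dtype=bool)
        stack[:count] = True
        counts, cats = scs_mod.likelihood_map(stack)
        assert counts[0, 0] == count
        assert scs_mod.LIKELIHOOD_LABELS[int(cats[0, 0])] == label

    def test_gcm_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scs_mod.likelihood_map(np.zeros((5, 2, 2), dtype=bool), n_gcms=8)

    def test_invariant_to_gcm_ordering(self):
        rng = np.random.default_rng(2)
        stack = rng.random((8, 6, 6)) > 0.5
        _, cats = scs_mod.likelihood_map(stack)
        _, cats_perm = scs_mod.likelihood_map(stack[rng.permutation(8)])
        assert np.array_equal(cats, cats_perm)


class TestCountryAggregate:
    def _setup(self):
        production = np.array([[7.0, 3.0]])
        categories = np.array([[3, 0]])  # likely outside / very likely inside
        stack = np.array([[[True, False]]] * 8)
        base_inside = np.array([[True, True]])
        return categories, stack, production, base_inside

    def test_single_country_equals_global(self):
        categories, stack, production, base_inside = self._setup()
        table = scs_mod.country_aggregate(categories, stack, production,
                                          np.array([[1, 1]]), base_inside)
        assert len(table) == 1
        assert table["likely_outside"].iloc[0] == pytest.approx(70.0)
        assert table["share_outside"].iloc[0] == pytest.approx(70.0)

    def test_two_country_split(self):
        categories, stack, production, base_inside = self._setup()
        table = scs_mod.country_aggregate(categories, stack, production,
                                          np.array([[1, 2]]), base_inside)
        c1 = table[table.country == 1].iloc[0]
        c2 = table[table.country == 2].iloc[0]
        assert c1["share_outside"] == pytest.approx(100.0)
        assert c2["share_outside"] == pytest.approx(0.0)

    def test_category_shares_sum_to_100(self):
        rng = np.random.default_rng(4)
        production = rng.uniform(0, 5, (10, 20))
        categories = rng.integers(0, 4, (10, 20))
        stack = rng.random((8, 10, 20)) > 0.5
        base_inside = rng.random((10, 20)) > 0.2
        countries = syn.generate_countries(1, 10, 20, n_countries=4)
        table = scs_mod.country_aggregate(categories, stack, production,
                                          countries, base_inside)
        cat_cols = [l.replace(" ", "_") for l in scs_mod.LIKELIHOOD_LABELS.values()]
        sums = table[cat_cols + ["no_or_minor"]].sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_misaligned_country_raster_rejected(self):
        categories, stack, production, base_inside = self._setup()
        with pytest.raises(ValueError):
            scs_mod.country_aggregate(categories, stack, production,
                                      np.array([[1, 2, 3]]), base_inside)


def test_triangle_density_plot_smoke(triangle_baseline, production, tmp_path):
    crop = np.asarray(production["crop"])
    mask = scs_mod.build_scs(triangle_baseline.x, triangle_baseline.y, crop)
    ax = scs_mod.plot_triangle_density(
        mask, future_xy=(triangle_baseline.x, triangle_baseline.y), production=crop)
    ax.figure.savefig(tmp_path / "triangle.png")
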