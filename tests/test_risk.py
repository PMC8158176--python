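"""Animal units, cell areas, area-weighted quantile classes, risk matrix."""

import numpy as np
import pandas as pd
import pytest

from scspace import risk


def brute_force_weighted_threshold(values, weights, prob):
    """Smallest value whose weighted cumulative share reaches prob."""
    total = weights.sum()
    for v in np.sort(values):
        if weights[values <= v].sum() / total >= prob:
            return v
    return np.max(values)


class TestAnimalUnits:
    def test_single_species_coefficients(self):
        assert risk.to_animal_units({"buffalo": np.array([1.0])})[0] == 0.7
        assert risk.to_animal_units({"chickens": np.array([100.0])})[0] == pytest.approx(1.0)

    def test_empty_grids_give_zero(self):
        out = risk.to_animal_units({"cattle": np.zeros((3, 3))})
        assert np.all(out == 0)

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError, match="llamas"):
            risk.to_animal_units({"llamas": np.ones(2)})

    def test_negative_headcount_rejected(self):
        with pytest.raises(ValueError):
            risk.to_animal_units({"pigs": np.array([-1.0])})

    def test_conversion_is_linear(self):
        rng = np.random.default_rng(1)
        a = {s: rng.uniform(0, 50, (4, 4)) for s in risk.AU_PER_HEAD}
        b = {s: rng.uniform(0, 50, (4, 4)) for s in risk.AU_PER_HEAD}
        both = {s: a[s] + b[s] for s in a}
        assert np.allclose(
            risk.to_animal_units(both),
            risk.to_animal_units(a) + risk.to_animal_units(b),
        )


class TestCellAreas:
    def test_symmetric_about_equator(self):
        areas = risk.cell_areas(np.array([40.0, -40.0]), 1.0, 1.0)
        assert areas[0] == pytest.approx(areas[1])

    def test_cosine_ratio(self):
        areas = risk.cell_areas(np.array([60.0, 0.0]), 2.0, 2.0)
        assert areas[0] / areas[1] == pytest.approx(np.cos(np.deg2rad(60)), rel=1e-6)

    def test_full_sphere_total(self):
        nlat, nlon = 180, 360
        lats = 90 - (np.arange(nlat) + 0.5)
        grid = np.repeat(risk.cell_areas(lats, 1.0, 1.0)[:, None], nlon, axis=1)
        earth = 4 * np.pi * risk.EARTH_RADIUS_KM**2
        assert grid.sum() == pytest.approx(earth, rel=5e-3)
        assert grid.sum() == pytest.approx(5.1e8, rel=5e-3)

    def test_latitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            risk.cell_areas(np.array([95.0]), 1.0, 1.0)


class TestQuantileClasses:
    def test_thresholds_match_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            values = rng.normal(size=400)
            weights = rng.uniform(0.1, 3.0, size=400)
            thr = risk.weighted_thresholds(values, weights)
            for t, p in zip(thr, (0.25, 0.5, 0.75)):
                assert t == brute_force_weighted_threshold(values, weights, p)

    def test_equal_weights_1_to_100(self):
        values = np.arange(1.0, 101.0)
        thr = risk.weighted_thresholds(values, np.ones(100))
        assert thr.tolist() == [25.0, 50.0, 75.0]

    def test_constant_field_all_low(self):
        field = np.full((5, 5), 3.0)
        classes, scheme = risk.quantile_classes(field, np.ones((5, 5)))
        assert np.all(classes == 0)
        assert np.all(scheme.thresholds == 3.0)

    def test_reference_scheme_reused_not_rederived(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1, (10, 10))
        areas = np.ones_like(a)
        classes_a, scheme_a = risk.quantile_classes(a, areas, reference="lowem")
        b = 2.0 * a
        classes_b, scheme_b = risk.quantile_classes(b, areas, scheme=scheme_a)
        assert scheme_b is scheme_a  # no re-derivation
        # every cell of B classified against A's thresholds
        expected = np.sum(b[..., None] > scheme_a.thresholds, axis=-1)
        assert np.array_equal(classes_b, expected)
        # doubling pushes mass upward relative to A's own classes
        assert classes_b.mean() >= classes_a.mean()

    def test_lowest_class_area_share_quarter(self):
        rng = np.random.default_rng(7)
        nlat, nlon = 40, 80
        lats = 85 - (np.arange(nlat) + 0.5) * 170 / nlat
        areas = np.repeat(
            risk.cell_areas(lats, 170 / nlat, 360 / nlon)[:, None], nlon, axis=1
        )
        field = rng.normal(size=(nlat, nlon))
        classes, _ = risk.quantile_classes(field, areas)
        share = areas[classes == 0].sum() / areas.sum()
        one_cell = areas.max() / areas.sum()
        assert abs(share - 0.25) <= one_cell
        # each class holds ~25% of area
        for k in range(4):
            assert abs(areas[classes == k].sum() / areas.sum() - 0.25) <= one_cell

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError):
            risk.quantile_classes(np.full((3, 3), np.nan), np.ones((3, 3)))


class TestRiskCrosstab:
    def _full_spread(self):
        # engineered 4x4 spread: one cell per combined class
        change = np.repeat(np.arange(4), 4).reshape(4, 4)
        resil = np.tile(np.arange(4), 4).reshape(4, 4)
        return change, resil

    def test_all_production_in_one_class(self):
        change = np.zeros((3, 3), dtype=int)
        resil = np.full((3, 3), 2)
        crop = np.ones((3, 3))
        table = risk.risk_crosstab(change, resil, crop, crop)
        assert table.share("crop", "low", "high") == pytest.approx(100.0)
        assert table.crop.values.sum() == pytest.approx(100.0)

    def test_sixteen_classes_populated_and_normalized(self):
        change, resil = self._full_spread()
        crop = np.arange(1.0, 17.0).reshape(4, 4)
        table = risk.risk_crosstab(change, resil, crop, crop[::-1])
        assert np.all(table.crop.values > 0)
        assert (table.crop.values > 0).sum() == 16
        assert table.crop.values.sum() == pytest.approx(100.0, abs=1e-6)
        assert table.livestock.values.sum() == pytest.approx(100.0, abs=1e-6)

    def test_marginals_match_independent_class_shares(self):
        rng = np.random.default_rng(8)
        change = rng.integers(0, 4, (12, 12))
        resil = rng.integers(0, 4, (12, 12))
        crop = rng.uniform(0, 5, (12, 12))
        table = risk.risk_crosstab(change, resil, crop, crop)
        marg = table.crop.sum(axis=1).to_numpy()
        for k in range(4):
            expected = 100.0 * crop[change == k].sum() / crop.sum()
            assert marg[k] == pytest.approx(expected)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            risk.risk_crosstab(np.zeros((2, 2), int), np.zeros((3, 3), int),
                               np.ones((2, 2)), np.ones((2, 2)))


class TestRiskZones:
    @pytest.mark.parametrize(
        "change_label, resil_label, expected",
        [
            ("very high", "low", "critical"),
            ("very high", "moderate", "high"),
            ("high", "low", "high"),
            ("low", "very high", "other"),
            ("high", "moderate", "other"),
        ],
    )
    def test_zone_definitions(self, change_label, resil_label, expected):
        assert risk.risk_zone_label(change_label, resil_label) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            risk.risk_zone_label("extreme", "low")

    def test_zone_matrix_mutually_exclusive(self):
        matrix = risk.risk_zone_table()
        assert (matrix.values == "critical").sum() == 1
        assert (matrix.values == "high").sum() == 2
        grid = risk.risk_zone_grid(np.array([[3]]), np.array([[0]]))
        assert grid[0, 0] == risk.RISK_CRITICAL


class TestResilienceSensitivity:
    def _inputs(self):
        rng = np.random.default_rng(9)
        shape = (20, 30)
        change = rng.integers(0, 4, shape)
        resil = rng.uniform(-1, 1, shape)
        areas = np.ones(shape)
        crop = rng.uniform(0, 10, shape)
        return change, resil, areas, crop

    def test_percentile_25_matches_crosstab_critical_share(self):
        change, resil, areas, crop = self._inputs()
        resil_cls, _ = risk.quantile_classes(resil, areas)
        table = risk.risk_crosstab(change, resil_cls, crop, crop)
        sens = risk.resilience_sensitivity(change, resil, areas, crop, crop,
                                           percentiles=[25])
        assert sens["crop_share"].iloc[0] == pytest.approx(
            table.share("crop", "very high", "low")
        )

    def test_shares_nondecreasing_in_percentile(self):
        change, resil, areas, crop = self._inputs()
        sens = risk.resilience_sensitivity(change, resil, areas, crop, crop,
                                           percentiles=range(20, 31))
        assert len(sens) == 11
        assert (np.diff(sens["crop_share"]) >= -1e-12).all()
        assert (np.diff(sens["livestock_share"]) >= -1e-12).all()

    def test_single_percentile_and_empty_list(self):
        change, resil, areas, crop = self._inputs()
        sens = risk.resilience_sensitivity(change, resil, areas, crop, crop,
                                           percentiles=[22])
        assert len(sens) == 1 and sens["percentile"].iloc[0] == 22
        with pytest.raises(ValueError):
            risk.resilience_sensitivity(change, resil, areas, crop, crop,
                                        percentiles=[])
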