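import numpy as np
import pandas as pd
import pytest

from flaps import census as cs
from flaps._util import unit_rng
from flaps.disaggregate import FarmDraft
from flaps.placement import (
    PlacementError,
    neighborhood,
    place_farms,
    presence_probability_pool,
    records_to_frame,
    run_flaps,
)
from flaps.raster import GeoTransform, ProbabilitySurface
from flaps.sdm import builtin_swine_model, predict_surface
from flaps.synthetic import SynthConfig, make_census, make_landscape, sample_pa


def flat_surface(n=5, p=0.5, fips="00000"):
    return ProbabilitySurface(
        grid=np.full((n, n), p),
        available=np.ones((n, n), bool),
        transform=GeoTransform(0.0, 0.0, 1.0, 1.0),
        county_index=np.zeros((n, n), np.int32),
        county_fips=[fips],
    )


class TestNeighborhood:
    @pytest.mark.parametrize("bin,half,pixels", [
        (7, 2, 25),
        (6, 1, 9), (5, 1, 9), (4, 1, 9), (3, 1, 9), (2, 1, 9),
        (1, 0, 1),
    ])
    def test_window_sizes(self, bin, half, pixels):
        assert neighborhood(bin) == half
        assert (2 * half + 1) ** 2 == pixels

    def test_invalid_bin(self):
        with pytest.raises(ValueError):
            neighborhood(8)


class TestPresencePool:
    def test_point_mass_for_identical_presences(self):
        m = builtin_swine_model()
        df = pd.DataFrame({"y": [1, 1, 0]} | {c: [1.0, 1.0, 2.0] for c in m.term_forms})
        pool = presence_probability_pool(m, df)
        assert pool.size == 2 and pool[0] == pool[1]

    def test_pool_is_exactly_the_presence_predictions(self, pa_sample):
        m = builtin_swine_model()
        pool = presence_probability_pool(m, pa_sample)
        pres = pa_sample[pa_sample["y"] == 1]
        np.testing.assert_array_equal(pool, m.predict(pres))

    def test_presences_score_higher_than_absences_on_average(self, pa_sample):
        m = builtin_swine_model()
        pool = presence_probability_pool(m, pa_sample)
        absent = m.predict(pa_sample[pa_sample["y"] == 0])
        assert pool.mean() > absent.mean()

    def test_no_presences_is_an_error(self):
        m = builtin_swine_model()
        df = pd.DataFrame({"y": [0, 0]} | {c: [0.0, 1.0] for c in m.term_forms})
        with pytest.raises(ValueError, match="presence"):
            presence_probability_pool(m, df)


class TestPlaceFarms:
    def test_one_farm_one_pixel(self):
        surf = flat_surface(1)
        recs = place_farms([FarmDraft("00000", 1, 5)], surf, np.array([0.5]),
                           np.random.default_rng(0))
        assert len(recs) == 1
        assert (recs[0].lon, recs[0].lat) == (0.5, -0.5)

    def test_top_bin_exclusion_forces_relaxation_on_tiny_county(self):
        surf = flat_surface(5)
        drafts = [FarmDraft("00000", 7, 2000), FarmDraft("00000", 7, 1500)]
        recs = place_farms(drafts, surf, np.array([0.5]), np.random.default_rng(1))
        # both placed, on distinct pixels, only via the relaxation ladder
        assert len(recs) == 2
        assert (recs[0].lon, recs[0].lat) != (recs[1].lon, recs[1].lat)

    def test_intermediate_bins_respect_windows_without_relaxation(self):
        surf = flat_surface(9)
        drafts = [FarmDraft("00000", 4, 150) for _ in range(4)]
        recs = place_farms(drafts, surf, np.array([0.5]), np.random.default_rng(2))
        pts = [(int(-r.lat - 0.5), int(r.lon - 0.5)) for r in recs]
        for i, (ri, ci) in enumerate(pts):
            for rj, cj in pts[i + 1:]:
                assert max(abs(ri - rj), abs(ci - cj)) > 1  # outside 3x3

    def test_exhausted_county_raises_with_unplaced_farms(self):
        surf = flat_surface(2)
        drafts = [FarmDraft("00000", 1, 5) for _ in range(5)]
        with pytest.raises(PlacementError) as e:
            place_farms(drafts, surf, np.array([0.5]), np.random.default_rng(3))
        assert len(e.value.unplaced) == 1

    def test_no_masked_pixel_placements_and_no_sharing(self):
        rng = np.random.default_rng(4)
        grid = rng.uniform(size=(40, 40))
        avail = rng.uniform(size=(40, 40)) > 0.3
        surf = ProbabilitySurface(
            grid=grid, available=avail, transform=GeoTransform(0, 0, 1, 1),
            county_index=np.zeros((40, 40), np.int32), county_fips=["00000"],
        )
        drafts = [FarmDraft("00000", 1, 3) for _ in range(300)]
        recs = place_farms(drafts, surf, rng.uniform(size=100), np.random.default_rng(5))
        pix = [(int(-r.lat - 0.5), int(r.lon - 0.5)) for r in recs]
        assert len(set(pix)) == len(pix)
        assert all(avail[r, c] for r, c in pix)

    def test_coordinates_round_trip_through_geotransform(self):
        surf = flat_surface(6)
        drafts = [FarmDraft("00000", 1, 2) for _ in range(10)]
        recs = place_farms(drafts, surf, np.array([0.5]), np.random.default_rng(6))
        lons = np.array([r.lon for r in recs])
        lats = np.array([r.lat for r in recs])
        rows, cols = surf.transform.to_pixel(lons, lats)
        lon2, lat2 = surf.transform.pixel_center(rows, cols)
        np.testing.assert_allclose(lon2, lons)
        np.testing.assert_allclose(lat2, lats)

    def test_chosen_probabilities_match_presence_pool(self):
        cfg = SynthConfig(seed=3, n_states=1, counties_per_state=1,
                          sample_size=3000, landscape_shape=(300, 300))
        land = make_landscape(cfg)
        model = builtin_swine_model()
        pa = sample_pa(cfg, land)
        pool = presence_probability_pool(model, pa)
        surf = predict_surface(
            model, land.covariates, mask=land.mask, transform=land.transform,
            county_index=land.surface.county_index,
            county_fips=land.surface.county_fips,
        )
        fips = surf.county_fips[0]
        drafts = [FarmDraft(fips, 1, 10) for _ in range(5000)]
        recs = place_farms(drafts, surf, pool, unit_rng(7, fips))
        rows, cols = surf.transform.to_pixel(
            np.array([r.lon for r in recs]), np.array([r.lat for r in recs])
        )
        chosen = surf.grid[rows, cols]
        from scipy.stats import ks_2samp

        assert ks_2samp(chosen, pool).pvalue > 0.01


@pytest.fixture(scope="module")
def pipeline_inputs():
    cfg = SynthConfig(seed=21, n_states=2, counties_per_state=3,
                      sample_size=2000, landscape_shape=(100, 140))
    truth, observed = make_census(cfg)
    land = make_landscape(
        cfg, county_fips=[u.unit_id for u in truth.at_level(cs.Level.COUNTY)]
    )
    pa = sample_pa(cfg, land, truth)
    model = builtin_swine_model()
    surf = predict_surface(
        model, land.covariates, mask=land.mask, transform=land.transform,
        county_index=land.surface.county_index,
        county_fips=land.surface.county_fips,
    )
    return observed, surf, model, pa


class TestRunFlaps:

    def test_county_scope_record_count(self, pipeline_inputs):
        observed, surf, model, pa = pipeline_inputs
        from flaps.impute import impute_all

        county = impute_all(observed).at_level(cs.Level.COUNTY)[0]
        records, report = run_flaps(
            observed, surf, model, pa, scope="county",
            scope_id=county.unit_id, seed=3,
        )
        assert len(records) == county.n_farms

    def test_national_run_reaggregates_exactly(self, pipeline_inputs):
        observed, surf, model, pa = pipeline_inputs
        records, report = run_flaps(observed, surf, model, pa, seed=3)
        assert report.mean_apd == 0.0
        df = records_to_frame(records)
        assert set(df.columns) == {"fips", "state", "lat", "lon", "population",
                                   "commodity"}

    def test_same_seed_is_bit_identical(self, pipeline_inputs):
        observed, surf, model, pa = pipeline_inputs
        a, _ = run_flaps(observed, surf, model, pa, seed=9)
        b, _ = run_flaps(observed, surf, model, pa, seed=9)
        assert a == b
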