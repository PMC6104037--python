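"""Region assignment, nuclear density, weighted aggregation, maps."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from indentmap.regions import (
    RegionGeometry,
    assign_region,
    reconstruct_map,
    region_summaries,
    relative_nuclear_area,
    slice_region_stats,
    weighted_region_mean,
)


@pytest.fixture
def adjacent_geometry():
    return RegionGeometry(
        [
            ("GCL", Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])),
            ("ML", Polygon([(100, 0), (200, 0), (200, 100), (100, 100)])),
        ]
    )


class TestAssignRegion:
    def test_centroid_gets_its_label(self, adjacent_geometry):
        assert assign_region((50, 50), adjacent_geometry) == "GCL"
        assert assign_region((150, 50), adjacent_geometry) == "ML"

    def test_outside_all_polygons(self, adjacent_geometry):
        assert assign_region((500, 500), adjacent_geometry) == "outside"

    def test_shared_boundary_first_listed_and_stable(self, adjacent_geometry):
        # (100, 50) lies exactly on the shared edge
        labels = {assign_region((100.0, 50.0), adjacent_geometry) for _ in range(20)}
        assert labels == {"GCL"}


class TestNuclearArea:
    def test_full_and_half_coverage(self):
        poly = Polygon([(0, 0), (50, 0), (50, 50), (0, 50)])
        ones = np.ones((60, 60), dtype=bool)
        assert relative_nuclear_area(ones, poly).A_rel == 1.0
        half = np.zeros((60, 60), dtype=bool)
        half[:, :25] = True   # left half of the region covered
        nd = relative_nuclear_area(half, poly)
        assert nd.A_rel == pytest.approx(0.5, abs=0.02)

    def test_density_grouping(self):
        poly = Polygon([(0, 0), (40, 0), (40, 40), (0, 40)])
        low = np.zeros((50, 50), dtype=bool)
        low[:8, :] = True
        high = np.ones((50, 50), dtype=bool)
        high[:8, :] = False
        assert relative_nuclear_area(low, poly).density_group == "low"
        assert relative_nuclear_area(high, poly).density_group == "high"

    def test_disjoint_polygon_rejected(self):
        poly = Polygon([(1000, 1000), (1010, 1000), (1010, 1010), (1000, 1010)])
        with pytest.raises(ValueError, match="intersect"):
            relative_nuclear_area(np.ones((20, 20)), poly)


class TestAggregation:
    def test_slice_stats_hand_values(self, adjacent_geometry):
        df = pd.DataFrame(
            {
                "slice_id": ["s1"] * 3,
                "protocol": ["oscillatory_ramp"] * 3,
                "x_um": [10, 20, 30],
                "y_um": [10, 20, 30],
                "freq_hz": [5.62] * 3,
                "strain": [0.073] * 3,
                "E_storage_Pa": [1000.0, 2000.0, 3000.0],
                "qc_pass": [True] * 3,
            }
        )
        out = slice_region_stats(df, adjacent_geometry)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_Pa"] == pytest.approx(2000.0)
        assert row["se_Pa"] == pytest.approx(577.35, abs=0.01)
        assert row["n"] == 3

    def test_single_point_cell_flagged(self, adjacent_geometry):
        df = pd.DataFrame(
            {
                "slice_id": ["s1"],
                "protocol": ["oscillatory_ramp"],
                "x_um": [10.0],
                "y_um": [10.0],
                "freq_hz": [5.62],
                "strain": [0.073],
                "E_storage_Pa": [1234.0],
                "qc_pass": [True],
            }
        )
        out = slice_region_stats(df, adjacent_geometry)
        assert out.iloc[0]["mean_Pa"] == 1234.0
        assert out.iloc[0]["se_Pa"] == 0.0
        assert not out.iloc[0]["se_defined"]

    def test_rejected_points_excluded(self, adjacent_geometry):
        df = pd.DataFrame(
            {
                "slice_id": ["s1"] * 2,
                "protocol": ["oscillatory_ramp"] * 2,
                "x_um": [10, 20],
                "y_um": [10, 20],
                "freq_hz": [5.62] * 2,
                "strain": [0.073] * 2,
                "E_storage_Pa": [1000.0, 9999.0],
                "qc_pass": [True, False],
            }
        )
        out = slice_region_stats(df, adjacent_geometry)
        assert out.iloc[0]["mean_Pa"] == 1000.0

    def test_weighted_mean_hand_value(self):
        s = weighted_region_mean([(1000.0, 50.0, 10), (2000.0, 30.0, 30)], label="SR")
        assert s.weighted_mean_E == pytest.approx(1750.0)
        assert s.n_points == 40 and s.n_slices == 2

    def test_weighted_mean_invariances(self):
        same = weighted_region_mean([(1500.0, 10.0, 5), (1500.0, 20.0, 50)])
        assert same.weighted_mean_E == pytest.approx(1500.0)
        single = weighted_region_mean([(1200.0, 33.0, 7)])
        assert single.weighted_mean_E == 1200.0
        assert single.se_weighted_mean == pytest.approx(33.0)

    def test_point_weighting_equals_pooled_mean(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(1500, 200, n) for n in (5, 17, 31)]
        per_slice = [(float(g.mean()), float(g.std(ddof=1) / np.sqrt(g.size)), g.size) for g in groups]
        pooled = float(np.concatenate(groups).mean())
        s = weighted_region_mean(per_slice)
        assert s.weighted_mean_E == pytest.approx(pooled, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_region_mean([])


class TestReconstructMap:
    def test_two_region_raster_levels(self, adjacent_geometry):
        summaries = pd.DataFrame(
            {
                "region": ["GCL", "ML"],
                "protocol": ["oscillatory_ramp"] * 2,
                "weighted_mean_Pa": [900.0, 1800.0],
            }
        )
        raster, extent = reconstruct_map(adjacent_geometry, summaries, resolution=10.0)
        assert set(np.unique(raster[~np.isnan(raster)])) == {900.0, 1800.0}
        # left half soft, right half stiff
        assert np.nanmean(raster[:, :5]) == pytest.approx(900.0)
        assert np.nanmean(raster[:, -5:]) == pytest.approx(1800.0)

    def test_region_without_summary_is_nan(self, adjacent_geometry):
        summaries = pd.DataFrame(
            {"region": ["GCL"], "protocol": ["oscillatory_ramp"], "weighted_mean_Pa": [900.0]}
        )
        raster, _ = reconstruct_map(adjacent_geometry, summaries, resolution=10.0)
        assert np.isnan(raster[:, -3:]).all()

    def test_unknown_region_rejected(self, adjacent_geometry):
        summaries = pd.DataFrame(
            {"region": ["nope"], "protocol": ["oscillatory_ramp"], "weighted_mean_Pa": [1.0]}
        )
        with pytest.raises(ValueError, match="unknown regions"):
            reconstruct_map(adjacent_geometry, summaries)


def test_region_summaries_group_by_protocol(adjacent_geometry):
    stats = pd.DataFrame(
        {
            "slice_id": ["s1", "s2", "s1"],
            "region": ["GCL", "GCL", "GCL"],
            "protocol": ["oscillatory_ramp", "oscillatory_ramp", "frequency_sweep"],
            "mean_Pa": [1000.0, 2000.0, 1500.0],
            "se_Pa": [10.0, 10.0, 10.0],
            "n": [10, 30, 20],
        }
    )
    out = region_summaries(stats)
    assert len(out) == 2
    or_row = out[out["protocol"] == "oscillatory_ramp"].iloc[0]
    assert or_row["weighted_mean_Pa"] == pytest.approx(1750.0)
    assert or_row["n_slices"] == 2
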