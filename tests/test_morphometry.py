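"""Octant partition, counts, volumes, densities and mitosis assignment."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from otoquant import (
    NEUROGENIC_LABEL,
    build_cuboid_partition,
    count_cells_by_region,
    count_mitoses_by_region,
    region_density,
    region_stats,
    tissue_volume,
    tissue_volume_from_labels,
)


def brute_force_assign(points, partition):
    """Oracle: explicit point-in-box test against each region's bounds."""
    out = np.full(len(points), -1)
    for k, label in enumerate(partition.labels):
        lo, hi = partition.region_bounds(label)
        # lower-inclusive, upper-exclusive except at the cuboid's outer faces
        hi_ok = np.where(np.isclose(hi, partition.cuboid_max_um), np.inf, hi)
        inside = np.all((points >= lo) & (points < hi_ok), axis=1)
        inside &= np.all(points <= partition.cuboid_max_um, axis=1)
        out[inside] = k
    return out


def test_partition_arithmetic_80_60_40():
    part = build_cuboid_partition(np.array([[0, 0, 0], [80, 60, 40]]))
    assert part.region_volume_um3 == pytest.approx(24_000.0)  # 40 * 30 * 20
    for label in part.labels:
        lo, hi = part.region_bounds(label)
        assert np.allclose(hi - lo, [40, 30, 20])


def test_midplane_point_goes_to_upper_half():
    part = build_cuboid_partition(np.array([[0, 0, 0], [80, 60, 40]]))
    label = part.assign_labels(np.array([[40.0, 10.0, 10.0]]))[0]
    assert label.startswith("posterior")  # lower-inclusive tie-break


def test_degenerate_cuboid_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        build_cuboid_partition(np.array([[0, 0, 0], [10, 0, 10]]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_assignment_matches_brute_force_and_tiles_exactly(seed):
    rng = np.random.default_rng(seed)
    lo = rng.uniform(-50, 0, 3)
    hi = lo + rng.uniform(5, 100, 3)
    part = build_cuboid_partition(np.stack([lo, hi]))
    pts = rng.uniform(lo - 5, hi + 5, size=(400, 3))
    np.testing.assert_array_equal(part.assign(pts), brute_force_assign(pts, part))
    vols = [np.prod(np.subtract(*part.region_bounds(l)[::-1])) for l in part.labels]
    assert np.allclose(vols, np.prod(hi - lo) / 8.0)


def test_counts_fractions_and_paper_style_ratio():
    part = build_cuboid_partition(np.array([[0, 0, 0], [80, 60, 40]]))
    rng = np.random.default_rng(0)
    neuro_lo, neuro_hi = part.region_bounds(NEUROGENIC_LABEL)
    other_lo, other_hi = part.region_bounds("posterior-medial-dorsal")
    pts = np.vstack(
        [
            rng.uniform(neuro_lo + 0.1, neuro_hi - 0.1, (49, 3)),
            rng.uniform(other_lo + 0.1, other_hi - 0.1, (262, 3)),
        ]
    )
    stats = count_cells_by_region(pts, part).set_index("region")
    assert stats.loc[NEUROGENIC_LABEL, "cell_count"] == 49
    assert stats.loc[NEUROGENIC_LABEL, "fraction_of_total"] == pytest.approx(49 / 311)
    assert stats["fraction_of_total"].sum() == pytest.approx(1.0, abs=1e-9)


def test_all_nuclei_in_one_region():
    part = build_cuboid_partition(np.array([[0, 0, 0], [8, 8, 8]]))
    pts = np.full((10, 3), 1.0)
    stats = count_cells_by_region(pts, part).set_index("region")
    assert stats["fraction_of_total"].max() == 1.0
    assert (stats["cell_count"] > 0).sum() == 1


def test_outside_nuclei_excluded_with_warning(caplog):
    part = build_cuboid_partition(np.array([[0, 0, 0], [8, 8, 8]]))
    pts = np.array([[1, 1, 1], [100, 1, 1]])
    with caplog.at_level(logging.WARNING, logger="otoquant"):
        stats = count_cells_by_region(pts, part)
    assert stats["cell_count"].sum() == 1
    assert "outside" in caplog.text


def test_empty_input_reports_missing_fractions(caplog):
    part = build_cuboid_partition(np.array([[0, 0, 0], [8, 8, 8]]))
    with caplog.at_level(logging.WARNING, logger="otoquant"):
        stats = count_cells_by_region(np.empty((0, 3)), part)
    assert (stats["cell_count"] == 0).all()
    assert stats["fraction_of_total"].isna().all()


def test_monotonicity_adding_a_nucleus():
    part = build_cuboid_partition(np.array([[0, 0, 0], [80, 60, 40]]))
    rng = np.random.default_rng(1)
    pts = rng.uniform([0, 0, 0], [80, 60, 40], (50, 3))
    before = count_cells_by_region(pts, part)["cell_count"].to_numpy()
    extra = np.vstack([pts, [[10.0, 50.0, 35.0]]])  # anterior-lateral-ventral
    after = count_cells_by_region(extra, part).set_index("region")
    diff = after["cell_count"].to_numpy() - before
    assert diff.sum() == 1
    assert after.loc[NEUROGENIC_LABEL, "cell_count"] == before[
        part.labels.index(NEUROGENIC_LABEL)
    ] + 1


def test_translation_invariance_of_counts_and_density():
    part = build_cuboid_partition(np.array([[0, 0, 0], [80, 60, 40]]))
    rng = np.random.default_rng(2)
    pts = rng.uniform([0, 0, 0], [80, 60, 40], (200, 3))
    shift = np.array([13.0, -7.0, 3.5])
    part2 = build_cuboid_partition(np.array([[0, 0, 0], [80, 60, 40]]) + shift)
    c1 = count_cells_by_region(pts, part)["cell_count"]
    c2 = count_cells_by_region(pts + shift, part2)["cell_count"]
    pd.testing.assert_series_equal(c1, c2)
    vols = np.full(8, 1000.0)
    assert np.allclose(region_density(c1, vols), region_density(c2, vols))


def test_tissue_volume_arithmetic_and_errors():
    assert tissue_volume([1000, 1000, 1000], 2.0, 500.0) == pytest.approx(5500.0)
    assert tissue_volume([1000, 1000, 1000], 2.0, 0.0) == pytest.approx(6000.0)
    with pytest.raises(ValueError):
        tissue_volume([1000], 0.0)
    with pytest.raises(ValueError):
        tissue_volume([1000], 1.0, lumen_volume_um3=2000.0)


def test_label_stack_volume_matches_analytic_ellipsoid():
    a, b, c = 20.0, 15.0, 10.0
    vox = 0.5
    zs = np.arange(-12, 12.01, vox)
    ys = np.arange(-17, 17.01, vox)
    xs = np.arange(-22, 22.01, vox)
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    mask = (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0
    measured = tissue_volume_from_labels(mask, (vox, vox, vox))
    analytic = 4.0 / 3.0 * np.pi * a * b * c
    assert abs(measured - analytic) / analytic < 0.02


def test_region_density_values_and_errors():
    assert region_density([48], [24_000.0])[0] == pytest.approx(2.0)
    assert region_density([0], [24_000.0])[0] == 0.0
    with pytest.raises(ValueError):
        region_density([1], [0.0])


def test_mitoses_counted_in_mothers_region_at_anaphase():
    part = build_cuboid_partition(np.array([[0, 0, 0], [80, 60, 40]]))
    neuro_mid = np.mean(part.region_bounds(NEUROGENIC_LABEL), axis=0)
    other_mid = np.mean(part.region_bounds("posterior-medial-dorsal"), axis=0)
    events = pd.DataFrame(
        {
            "event_type": ["division"] * 10 + ["onset"],
            "t_min": list(np.linspace(10, 90, 10)) + [50.0],
            "track_id": list(range(10)) + [99],
            "payload": [
                {"position_um": list(neuro_mid if i < 4 else other_mid)}
                for i in range(10)
            ]
            + [{}],
        }
    )
    out = count_mitoses_by_region(events, part, (0.0, 100.0))
    assert out.attrs["neurogenic_percent"] == pytest.approx(40.0)
    assert out.attrs["total_mitoses"] == 10
    empty = count_mitoses_by_region(events, part, (200.0, 300.0))
    assert empty["mitosis_count"].sum() == 0
    assert empty.attrs["neurogenic_percent"] == 0.0


def test_region_stats_combines_counts_volumes_densities(wt_sim, wt_partition):
    snap = wt_sim.positions_at(420.0)
    pts = snap[["x_um", "y_um", "z_um"]].to_numpy()
    vols = np.full(8, wt_sim.geometry.tissue_volume_um3() / 8.0)
    stats = region_stats(pts, wt_partition, vols, wt_sim.events, (120.0, 390.0))
    assert {"cell_count", "tissue_volume_um3", "density_per_1e3um3",
            "mitosis_count"} <= set(stats.columns)
    dens = stats["density_per_1e3um3"]
    np.testing.assert_allclose(
        dens * stats["tissue_volume_um3"] / 1e3, stats["cell_count"], rtol=1e-9
    )
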