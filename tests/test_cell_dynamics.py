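"""Delamination detection/statistics, division classes, ingression counts."""

import numpy as np
import pandas as pd
import pytest

import otoquant as oq
from otoquant import (
    classify_division,
    count_ingressed,
    delamination_records,
    delamination_trigger_stats,
    detect_delamination,
    lineage_onset_times,
    photoconvert,
)


def test_detected_delaminations_match_event_log_exactly(wt_sim):
    """Event-log oracle: on noiseless tracks with ground-truth compartments,
    detection recovers every logged delamination at the exact time."""
    logged = (
        wt_sim.events.query("event_type == 'delamination'")
        .set_index("track_id")["t_min"]
    )
    recs = delamination_records(
        wt_sim.tracks, wt_sim.geometry, threshold_au=10.0
    ).set_index("track_id")
    detected = recs[recs["source"] == "compartment"]
    assert set(detected.index) <= set(logged.index)
    for tid, row in detected.iterrows():
        assert row["delam_t_min"] == pytest.approx(logged[tid], abs=1e-9)
    # every logged delamination of a reporter-positive cell is found
    for tid, t in logged.items():
        track = wt_sim.tracks[wt_sim.tracks["track_id"] == tid]
        if (track["F_true_au"] > 10.0).any():
            assert tid in detected.index


def test_track_never_leaving_apical_half_yields_none(wt_sim):
    geom = wt_sim.geometry
    t = np.arange(0.0, 100.0, 2.0)
    apical = pd.DataFrame(
        {
            "track_id": 1, "t_min": t,
            "x_um": 0.0, "y_um": 0.0,
            "z_um": geom.inner_rho * geom.semi_axes_um[2] + 2.0,  # near lumen
            "F_true_au": 0.3 * t, "labeled": False,
        }
    )
    assert detect_delamination(apical, geom) is None


def test_position_based_detection_requires_sustained_basal_run(wt_sim):
    geom = wt_sim.geometry
    t = np.arange(0.0, 60.0, 2.0)
    depth = np.where(t >= 30.0, 0.85, 0.55)
    blip = depth.copy()
    blip[5] = 0.9  # single-frame excursion must not trigger
    ax = np.asarray(geom.semi_axes_um)

    def track_from_depth(d):
        rho = geom.inner_rho + d * (1 - geom.inner_rho)
        return pd.DataFrame(
            {
                "track_id": 1, "t_min": t,
                "x_um": 0.0, "y_um": 0.0, "z_um": rho * ax[2],
                "F_true_au": 1.0 * t, "labeled": False,
            }
        )

    rec = detect_delamination(track_from_depth(depth), geom)
    assert rec is not None and rec.source == "position"
    assert rec.delam_t_min == pytest.approx(30.0)
    rec2 = detect_delamination(track_from_depth(blip), geom)
    assert rec2.delam_t_min == pytest.approx(30.0)


def test_level_triggered_cohort_has_tight_levels_and_loose_timing(local_spec_sim):
    recs = delamination_records(local_spec_sim.tracks, local_spec_sim.geometry)
    assert len(recs) == 11
    stats = delamination_trigger_stats(recs, n_perm=10_000, seed=0)
    assert stats["cv_normalized_F"] < stats["cv_normalized_elapsed"]
    assert stats["p_value"] < 0.05


def test_timer_triggered_variant_reverses_the_dispersion():
    sim = oq.simulate_local_specification(11, seed=3, trigger="timer")
    recs = delamination_records(sim.tracks, sim.geometry)
    stats = delamination_trigger_stats(recs, n_perm=2000, seed=0)
    assert stats["cv_normalized_elapsed"] < stats["cv_normalized_F"]


def test_trigger_stats_invariant_to_global_rescaling(local_spec_sim):
    tracks = local_spec_sim.tracks.copy()
    recs1 = delamination_records(tracks, local_spec_sim.geometry)
    tracks["F_true_au"] *= 5.0
    recs2 = delamination_records(tracks, local_spec_sim.geometry, threshold_au=50.0)
    s1 = delamination_trigger_stats(recs1, n_perm=500, seed=4)
    s2 = delamination_trigger_stats(recs2, n_perm=500, seed=4)
    assert s1["cv_normalized_F"] == pytest.approx(s2["cv_normalized_F"])
    assert s1["p_value"] == s2["p_value"]


def test_identical_cells_give_zero_dispersion():
    recs = pd.DataFrame(
        {
            "normalized_F": np.ones(5),
            "normalized_elapsed": np.ones(5),
        }
    )
    stats = delamination_trigger_stats(recs, n_perm=200, seed=0)
    assert stats["cv_normalized_F"] == 0.0
    assert stats["cv_normalized_elapsed"] == 0.0
    with pytest.raises(ValueError):
        delamination_trigger_stats(recs.iloc[:2])


def _neurogenic_divisions(sim, partition):
    out = []
    for ev in sim.events.query("event_type == 'division'").itertuples(index=False):
        pos = np.asarray(ev.payload["position_um"])
        if partition.labels[partition.assign(pos[None, :])[0]] == oq.NEUROGENIC_LABEL:
            out.append({"event_type": "division", "t_min": ev.t_min,
                        "track_id": ev.track_id, "payload": ev.payload})
    return out


def test_neurogenic_divisions_classified_symmetric_perpendicular(wt_sim, wt_partition):
    onset = lineage_onset_times(wt_sim.events)
    events = _neurogenic_divisions(wt_sim, wt_partition)
    assert events, "fixture embryo should have neurogenic divisions"
    for ev in events:
        c = classify_division(ev, wt_sim.tracks, wt_sim.geometry, onset)
        assert c.fate_class == "symmetric"
        assert c.orientation_class == "perpendicular"
        assert 0.0 <= c.cleavage_angle_deg <= 90.0
        assert c.position_class in ("luminal", "peripheral-apical")
        assert c.timing_class in ("before_onset", "after_onset")


def test_classification_symmetric_under_daughter_relabelling(wt_sim, wt_partition):
    onset = lineage_onset_times(wt_sim.events)
    ev = _neurogenic_divisions(wt_sim, wt_partition)[0]
    swapped = dict(ev)
    swapped["payload"] = dict(ev["payload"], daughters=ev["payload"]["daughters"][::-1])
    c1 = classify_division(ev, wt_sim.tracks, wt_sim.geometry, onset)
    c2 = classify_division(swapped, wt_sim.tracks, wt_sim.geometry, onset)
    assert (c1.fate_class, c1.orientation_class, c1.timing_class) == (
        c2.fate_class, c2.orientation_class, c2.timing_class
    )


def test_apical_nonexpressing_daughter_makes_division_asymmetric(wt_sim):
    geom = wt_sim.geometry
    t = np.arange(100.0, 200.0, 2.0)
    ax = np.asarray(geom.semi_axes_um)

    def daughter(tid, depth, delam=False):
        rho = geom.inner_rho + depth * (1 - geom.inner_rho)
        comp = "delaminated" if delam else "epithelial"
        return pd.DataFrame(
            {
                "track_id": tid, "parent_id": 1, "t_min": t,
                "x_um": -0.5 * rho * ax[0], "y_um": 0.3 * rho * ax[1],
                "z_um": 0.6 * rho * ax[2],
                "compartment": comp, "F_true_au": 0.0, "labeled": False,
            }
        )

    tracks = pd.concat([daughter(2, 0.2), daughter(3, 0.9, delam=True)])
    pos = tracks[["x_um", "y_um", "z_um"]].iloc[0].to_numpy()
    normal = geom.apical_normal(pos[None, :])[0]
    # spindle along the apical normal -> cleavage plane parallel to surface
    ev = {
        "event_type": "division", "t_min": 100.0, "track_id": 1,
        "payload": {"daughters": [2, 3], "spindle_axis": normal.tolist(),
                    "position_um": pos.tolist()},
    }
    c = classify_division(ev, tracks, geom, {})
    assert c.fate_class == "asymmetric"
    assert c.orientation_class == "oblique"
    assert c.cleavage_angle_deg == pytest.approx(0.0, abs=1e-6)
    assert c.timing_class == "before_onset"
    missing = dict(ev, payload=dict(ev["payload"], daughters=[2, 99]))
    with pytest.raises(ValueError, match="missing"):
        classify_division(missing, tracks, geom, {})


def test_ingression_count_matches_event_log(wt_sim, wt_config):
    roi = wt_sim.geometry.anterior_roi()
    labeled, ids = photoconvert(wt_sim.tracks, roi, wt_config.minutes(13.0))
    count = count_ingressed(labeled, wt_sim.geometry, wt_config.minutes(18.0))
    ing = wt_sim.events.query("event_type == 'ingression'")
    expected = ing[ing["track_id"].isin(ids)]
    assert count == len(expected)


def test_count_ingressed_requires_labels(wt_sim):
    with pytest.raises(ValueError, match="labels"):
        count_ingressed(wt_sim.tracks, wt_sim.geometry, 360.0)
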