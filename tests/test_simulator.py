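"""Behavioural contracts of the agent-based embryo simulator."""

import numpy as np
import pandas as pd
import pytest

import otoquant as oq
from otoquant import make_scenario, simulate_embryo


def test_seed_reproducibility_is_bit_exact(wt_config, wt_sim):
    again = simulate_embryo(wt_config)
    pd.testing.assert_frame_equal(wt_sim.tracks, again.tracks)
    pd.testing.assert_frame_equal(
        wt_sim.events.drop(columns="payload"), again.events.drop(columns="payload")
    )
    assert list(wt_sim.events["payload"]) == list(again.events["payload"])


def test_different_seeds_differ(wt_sim):
    other = simulate_embryo(make_scenario("wildtype", {"seed": 12}))
    assert not wt_sim.tracks.equals(other.tracks)


def test_vesicle_cell_count_in_calibrated_range(wt_sim, wt_config):
    n = len(wt_sim.positions_at(wt_config.minutes(19.0)))
    assert 311 - 3 * 16 <= n <= 311 + 3 * 16


def test_track_conservation_and_lineage(wt_sim):
    cells = wt_sim.cells
    n_div = len(wt_sim.events.query("event_type == 'division'"))
    initial = (cells["kind"] != "daughter").sum()
    assert len(cells) == initial + 2 * n_div
    # every division record points at two existing daughter tracks
    ids = set(cells["track_id"])
    for p in wt_sim.events.query("event_type == 'division'")["payload"]:
        d1, d2 = p["daughters"]
        assert d1 in ids and d2 in ids and d1 != d2


def test_each_cell_divides_at_most_once(wt_sim):
    div = wt_sim.events.query("event_type == 'division'")
    assert div["track_id"].is_unique
    # daughters never divide within the window
    daughters = {d for p in div["payload"] for d in p["daughters"]}
    assert daughters.isdisjoint(set(div["track_id"]))


def test_track_samples_strictly_increasing_and_F_monotone(wt_sim):
    for _, tr in wt_sim.tracks.groupby("track_id"):
        t = tr["t_min"].to_numpy()
        assert np.all(np.diff(t) > 0)
        f = tr["F_true_au"].to_numpy()
        assert np.all(f >= 0)
        assert np.all(np.diff(f) >= -1e-9)


def test_compartment_transitions_are_one_way(wt_sim):
    rank = {"outside": 0, "epithelial": 1, "delaminated": 2}
    for _, tr in wt_sim.tracks.groupby("track_id"):
        r = tr["compartment"].map(rank).to_numpy()
        assert np.all(np.diff(r) >= 0)


def test_ingressions_only_before_anterior_folding(wt_sim, wt_config):
    ing = wt_sim.events.query("event_type == 'ingression'")
    fold = wt_config.minutes(wt_config.anterior_fold_time_hpf)
    assert len(ing) > 0
    assert (ing["t_min"] < fold).all()


def test_delamination_only_after_onset_same_track(wt_sim):
    onsets = (
        wt_sim.events.query("event_type == 'onset'")
        .groupby("track_id")["t_min"].min()
    )
    delams = wt_sim.events.query("event_type == 'delamination'")
    for row in delams.itertuples(index=False):
        assert row.track_id in onsets.index
        assert row.t_min >= onsets[row.track_id]


def test_fgf_block_abolishes_ingression_and_advances_folding():
    cfg = make_scenario("fgf_block", {"seed": 5})
    sim = simulate_embryo(cfg)
    assert cfg.anterior_fold_time_hpf < cfg.ingression_window_hpf[0]
    assert (sim.events["event_type"] != "ingression").all()


def test_proliferation_block_has_zero_divisions():
    sim = simulate_embryo(make_scenario("proliferation_block", {"seed": 1}))
    assert (sim.events["event_type"] != "division").all()


def test_ablation_removes_two_to_three_pioneers_per_pulse():
    cfg = make_scenario("ablation", {"seed": 1, "ablation_pulses": 1})
    sim = simulate_embryo(cfg)
    abl = sim.events.query("event_type == 'ablation'")
    assert 2 <= len(abl) <= 3
    t_abl = cfg.minutes(cfg.ablation_time_hpf)
    for tid in abl["track_id"]:
        tr = sim.tracks[sim.tracks["track_id"] == tid]
        assert tr["t_min"].max() == pytest.approx(t_abl)  # terminated, kept in log
        assert (tr["compartment"] == "outside").all()


def test_no_instruction_gain_means_no_non_autonomous_effect():
    """With both gains at 1, removing pioneers must not change resident
    specification statistics (the coupling knob is the sole source of the
    non-autonomous ablation phenotype)."""
    over = {"instruction_gain": 1.0, "instruction_gain_amplitude": 1.0}
    rates = {}
    for scen in ("wildtype", "ablation"):
        onsets = []
        for s in range(40):
            sim = simulate_embryo(make_scenario(scen, {**over, "seed": 9000 + s}))
            res = sim.cells.query("kind in ('resident', 'daughter')")
            neuro = res[res["region"] == oq.NEUROGENIC_LABEL]
            onsets.append(neuro["expr_start"].notna().mean())
        rates[scen] = np.array(onsets)
    diff = rates["wildtype"].mean() - rates["ablation"].mean()
    pooled_sem = np.sqrt(
        rates["wildtype"].var(ddof=1) / 40 + rates["ablation"].var(ddof=1) / 40
    )
    assert abs(diff) < 3 * pooled_sem


def test_neurogenic_daughters_are_basal_or_delaminating(wt_sim, wt_config):
    """Ground truth behind symmetric division: by the end of the window both
    daughters of a neurogenic division have delaminated or sit in the basal
    half of the epithelium."""
    geom = wt_sim.geometry
    div = wt_sim.events.query("event_type == 'division'")
    cells = wt_sim.cells.set_index("track_id")
    checked = 0
    for p in div["payload"]:
        for d in p["daughters"]:
            if cells.loc[d, "region"] != oq.NEUROGENIC_LABEL:
                continue
            tr = wt_sim.tracks[wt_sim.tracks["track_id"] == d]
            if (tr["compartment"] == "delaminated").any():
                checked += 1
                continue
            last = tr.iloc[-1]
            depth = geom.depth(np.array([[last.x_um, last.y_um, last.z_um]]))[0]
            assert depth > 0.5
            checked += 1
    assert checked > 0


def test_delamination_events_carry_threshold_level(wt_sim, wt_config):
    lo, hi = wt_config.delamination_threshold_range_au
    cells = wt_sim.cells.set_index("track_id")
    for row in wt_sim.events.query("event_type == 'delamination'").itertuples():
        kind = cells.loc[row.track_id, "kind"]
        if kind in ("resident", "daughter"):
            f = row.payload["F_at_delam_au"]
            # cells born above their level delaminate rapidly at a higher F
            if cells.loc[row.track_id, "F_start"] < cells.loc[row.track_id, "delam_threshold"]:
                assert lo <= f <= hi
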