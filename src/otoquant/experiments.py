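"""End-to-end in-silico experiment protocols.

Each function runs one of the study's cohort experiments on synthetic
embryos — morphometry at 19 hpf, the Fig-3-style single-cell expression
followup, division classification, unilateral ablation with contralateral
controls, anterior photoconversion with ingression counting, and the
proliferation-block (aphidicolin/hydroxyurea, "AH") comparison — and
returns the summary quantities the study reports.  They are the
building blocks of both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from . import cell_dynamics, fluor_quant, morphometry
from .synthetic_data import (
    NEUROGENIC_LABEL,
    make_scenario,
    photoconvert,
    simulate_embryo,
    simulate_embryo_pair,
    simulate_local_specification,
)


def morphometry_cohort(seeds: Sequence[int], t_hpf: float = 19.0,
                       mitosis_window_hpf: tuple[float, float] = (14.0, 18.5)) -> dict:
    """Octant morphometry over a wild-type cohort.

    Returns per-embryo means of the neurogenic cell fraction and the
    neurogenic / mean non-neurogenic densities, plus the pooled neurogenic
    share of mitoses.
    """
    fracs, dens_neuro, dens_other = [], [], []
    mit_neuro = mit_total = 0
    for s in seeds:
        cfg = make_scenario("wildtype", {"seed": int(s)})
        sim = simulate_embryo(cfg)
        lo, hi = sim.geometry.bounding_box()
        part = morphometry.build_cuboid_partition(np.array([lo, hi]))
        snap = sim.positions_at(cfg.minutes(t_hpf))
        counts = morphometry.count_cells_by_region(
            snap[["x_um", "y_um", "z_um"]].to_numpy(), part
        ).set_index("region")
        fracs.append(counts.loc[NEUROGENIC_LABEL, "fraction_of_total"] * 100.0)
        vols = np.full(8, sim.geometry.tissue_volume_um3() / 8.0)
        dens = morphometry.region_density(
            counts["cell_count"].to_numpy(), vols
        )
        i = part.labels.index(NEUROGENIC_LABEL)
        dens_neuro.append(dens[i])
        dens_other.append(float(np.mean(np.delete(dens, i))))
        mit = morphometry.count_mitoses_by_region(
            sim.events, part,
            (cfg.minutes(mitosis_window_hpf[0]), cfg.minutes(mitosis_window_hpf[1])),
        )
        mit_neuro += mit.set_index("region").loc[NEUROGENIC_LABEL, "mitosis_count"]
        mit_total += mit.attrs["total_mitoses"]
    return {
        "neurogenic_fraction_percent": float(np.mean(fracs)),
        "neurogenic_density_per_1e3um3": float(np.mean(dens_neuro)),
        "other_density_per_1e3um3": float(np.mean(dens_other)),
        "neurogenic_mitosis_percent": float(mit_neuro / mit_total * 100.0),
        "n_embryos": len(list(seeds)),
        "n_mitoses": int(mit_total),
    }


def expression_dynamics(n_cells: int = 11, seed: int = 3,
                        n_perm: int = 10_000) -> dict:
    """Single-cell reporter followup of locally specified cells.

    Per-cell ΔF/Δt estimates, reporter level at delamination, and the
    level-versus-timer dispersion statistic with its permutation p value.
    """
    sim = simulate_local_specification(n_cells, seed=seed)
    rates = []
    for _, tr in sim.tracks.groupby("track_id"):
        on = tr[tr["F_true_au"] > 0]
        rates.append(
            fluor_quant.expression_rate(
                on["t_min"].to_numpy(), on["F_true_au"].to_numpy()
            )
        )
    records = cell_dynamics.delamination_records(
        sim.tracks, sim.geometry, threshold_au=sim.config.analysis_threshold_au
    )
    stats = cell_dynamics.delamination_trigger_stats(
        records, n_perm=n_perm, seed=seed
    )
    return {
        "rates_au_per_min": rates,
        "f_at_delam_au": records["F_at_delam_au"].tolist(),
        "min_f_at_delam_au": float(records["F_at_delam_au"].min()),
        "trigger_stats": stats,
    }


def division_classification_pool(n_divisions: int = 27, base_seed: int = 0) -> dict:
    """Pool tracked neurogenic-domain divisions across embryos (mirroring a
    multi-video 4D analysis) until ``n_divisions`` events are collected,
    then classify each from its daughters' outcomes over the full window."""
    classes = []
    offset = 0
    repeat_divisions = 0
    while len(classes) < n_divisions and offset < 200:
        cfg = make_scenario("wildtype", {"seed": int(base_seed) + offset})
        offset += 1
        sim = simulate_embryo(cfg)
        lo, hi = sim.geometry.bounding_box()
        part = morphometry.build_cuboid_partition(np.array([lo, hi]))
        onset = cell_dynamics.lineage_onset_times(sim.events)
        div = sim.events[sim.events["event_type"] == "division"]
        repeat_divisions += int(div["track_id"].duplicated().sum())
        for ev in div.sort_values("t_min").itertuples(index=False):
            pos = np.asarray(ev.payload["position_um"])
            if part.labels[part.assign(pos[None, :])[0]] != NEUROGENIC_LABEL:
                continue
            classes.append(
                cell_dynamics.classify_division(
                    {"event_type": "division", "t_min": ev.t_min,
                     "track_id": ev.track_id, "payload": ev.payload},
                    sim.tracks, sim.geometry, onset,
                )
            )
            if len(classes) >= n_divisions:
                break
    n_sym = sum(c.fate_class == "symmetric" for c in classes)
    return {
        "n_divisions": len(classes),
        "n_symmetric": int(n_sym),
        "n_perpendicular": sum(c.orientation_class == "perpendicular" for c in classes),
        "n_before_onset": sum(c.timing_class == "before_onset" for c in classes),
        "tracks_with_repeat_division": repeat_divisions,
    }


def ablation_experiment(pair_seeds: Iterable[int], t_hpf: float = 18.5) -> dict:
    """Unilateral ablation with the contralateral vesicle as control.

    Per-embryo specification summaries on both sides; the high-expresser
    cutoff always uses the control side's F̄_cell."""
    wt = make_scenario("wildtype")
    ab = make_scenario("ablation")
    thr = wt.analysis_threshold_au
    per_side: dict[str, list] = {"control": [], "ablated": []}
    for s in pair_seeds:
        ctrl, trt = simulate_embryo_pair(wt, ab, int(s))
        t = wt.minutes(t_hpf)
        f_c = fluor_quant.measurements_from_tracks(ctrl.tracks, t)["F_cell_au"]
        f_t = fluor_quant.measurements_from_tracks(trt.tracks, t)["F_cell_au"]
        s_c = fluor_quant.vesicle_summary(f_c, thr)
        s_c = fluor_quant.vesicle_summary(f_c, thr, s_c.mean_fcell_au)
        s_t = fluor_quant.vesicle_summary(f_t, thr, s_c.control_mean_fcell_au)
        per_side["control"].append(s_c)
        per_side["ablated"].append(s_t)

    def mean(side, attr):
        vals = [getattr(s, attr) or 0.0 for s in per_side[side]]
        return float(np.mean(vals))

    out = {"threshold_au": thr, "n_pairs": len(per_side["control"])}
    for side in ("control", "ablated"):
        out[side] = {
            "n_pos": mean(side, "n_pos"),
            "global_au": mean(side, "global_au"),
            "mean_fcell_au": mean(side, "mean_fcell_au"),
            "n_hi": mean(side, "n_hi"),
        }
    out["deltas"] = {
        k: out["ablated"][k] - out["control"][k] for k in out["control"]
    }
    out["summaries"] = per_side
    return out


def photoconversion_experiment(seeds: Iterable[int], scenario: str = "wildtype",
                               convert_t_hpf: float = 13.0,
                               count_t_hpf: float = 18.0) -> dict:
    """Anterior-ROI photoconversion and vesicle ingression counting."""
    labels, counts = [], []
    for s in seeds:
        cfg = make_scenario(scenario, {"seed": int(s)})
        sim = simulate_embryo(cfg)
        roi = sim.geometry.anterior_roi(
            gap_um=cfg.anterior_roi_gap_um, size_um=cfg.anterior_roi_size_um
        )
        labeled, ids = photoconvert(sim.tracks, roi, cfg.minutes(convert_t_hpf))
        labels.append(len(ids))
        counts.append(
            cell_dynamics.count_ingressed(
                labeled, sim.geometry, cfg.minutes(count_t_hpf)
            )
        )
    return {
        "mean_labeled": float(np.mean(labels)),
        "mean_ingressed": float(np.mean(counts)),
        "labeled": labels,
        "ingressed": counts,
    }


def ah_experiment(treated_seeds: Iterable[int], control_seeds: Iterable[int],
                  t_hpf: float = 20.0, boot_seed: int = 0) -> dict:
    """Proliferation-block (AH) versus control fold changes at 20 hpf."""
    def group(scenario, seeds):
        n_pos, mean_f = [], []
        for s in seeds:
            cfg = make_scenario(scenario, {"seed": int(s)})
            sim = simulate_embryo(cfg)
            f = fluor_quant.measurements_from_tracks(
                sim.tracks, cfg.minutes(t_hpf)
            )["F_cell_au"]
            su = fluor_quant.vesicle_summary(f, cfg.analysis_threshold_au)
            n_pos.append(su.n_pos)
            mean_f.append(su.mean_fcell_au or 0.0)
        return np.asarray(n_pos, dtype=float), np.asarray(mean_f, dtype=float)

    np_t, f_t = group("proliferation_block", treated_seeds)
    np_c, f_c = group("wildtype", control_seeds)
    return {
        "n_pos_fold": fluor_quant.fold_change(np_t, np_c, seed=boot_seed),
        "mean_fcell_fold": fluor_quant.fold_change(f_t, f_c, seed=boot_seed + 1),
        "n_treated": len(np_t),
        "n_control": len(np_c),
    }
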