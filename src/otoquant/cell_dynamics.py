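"""Event detection and classification on cell tracks.

Covers delamination detection (ground-truth compartment transitions when
present, otherwise a basal-displacement criterion on positions), the
level-versus-timer delamination statistic, division classification
(position, cleavage-plane orientation, daughter fate, timing relative to
specification onset) and photoconverted-ingression counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import VesicleGeometry, tracks_at

logger = logging.getLogger("otoquant")

#: cleavage planes at or above this angle to the apical surface count as
#: perpendicular (the source observations report a binary judgement)
PERPENDICULAR_TOL_DEG = 75.0

#: basal criterion: cell body deeper than this fraction of the local
#: epithelial thickness, sustained over MIN_BASAL_RUN frames
BASAL_DEPTH_FRACTION = 0.70
MIN_BASAL_RUN = 3


@dataclass
class DelaminationRecord:
    track_id: int
    onset_t_min: float
    delam_t_min: float
    F_at_delam_au: float
    source: str  # "compartment" or "position"

    @property
    def elapsed_min(self) -> float:
        return self.delam_t_min - self.onset_t_min


@dataclass
class DivisionClassification:
    event_track_id: int
    t_min: float
    position_class: str  # "luminal" | "peripheral-apical"
    cleavage_angle_deg: float
    orientation_class: str  # "perpendicular" | "oblique"
    fate_class: str  # "symmetric" | "asymmetric"
    timing_class: str  # "before_onset" | "after_onset"
    daughters: tuple[int, int]


# ---------------------------------------------------------------------------
# delamination
# ---------------------------------------------------------------------------


def detect_delamination(
    track: pd.DataFrame,
    geometry: VesicleGeometry | None = None,
    threshold_au: float = 10.0,
    basal_fraction: float = BASAL_DEPTH_FRACTION,
    min_run: int = MIN_BASAL_RUN,
) -> DelaminationRecord | None:
    """Delamination record for one track, or ``None``.

    Uses the ground-truth compartment transition when the track carries
    one; otherwise the first run of at least ``min_run`` consecutive
    samples with the cell body deeper than ``basal_fraction`` of the
    local epithelial thickness.  Onset is the first sample classified
    reporter-positive (strict threshold).
    """
    tr = track.sort_values("t_min")
    t = tr["t_min"].to_numpy()
    f = tr["F_true_au"].to_numpy()
    pos_mask = f > threshold_au
    onset_t = float(t[pos_mask][0]) if pos_mask.any() else np.nan

    delam_t = None
    source = None
    if "compartment" in tr.columns and (tr["compartment"] == "delaminated").any():
        delam_t = float(t[(tr["compartment"] == "delaminated").to_numpy()][0])
        source = "compartment"
    else:
        if geometry is None:
            raise ValueError("geometry required when tracks carry no compartment")
        depth = geometry.depth(tr[["x_um", "y_um", "z_um"]].to_numpy())
        basal = depth > basal_fraction
        run = 0
        for i, b in enumerate(basal):
            run = run + 1 if b else 0
            if run >= min_run:
                delam_t = float(t[i - min_run + 1])
                break
        source = "position"
    if delam_t is None:
        return None
    f_at = float(np.interp(delam_t, t, f))
    return DelaminationRecord(
        track_id=int(tr["track_id"].iloc[0]),
        onset_t_min=onset_t,
        delam_t_min=delam_t,
        F_at_delam_au=f_at,
        source=source,
    )


def delamination_records(
    tracks: pd.DataFrame,
    geometry: VesicleGeometry | None = None,
    threshold_au: float = 10.0,
) -> pd.DataFrame:
    """Cohort table of delamination records with group-normalised values.

    ``normalized_F`` and ``normalized_elapsed`` divide each cell's value
    by the cell-group mean, so both carry group mean 1.
    """
    recs = []
    for _, tr in tracks.groupby("track_id"):
        r = detect_delamination(tr, geometry, threshold_au=threshold_au)
        if r is not None and np.isfinite(r.onset_t_min):
            recs.append(r)
    if not recs:
        return pd.DataFrame(
            columns=["track_id", "onset_t_min", "delam_t_min", "elapsed_min",
                     "F_at_delam_au", "normalized_elapsed", "normalized_F",
                     "source"]
        )
    df = pd.DataFrame(
        {
            "track_id": [r.track_id for r in recs],
            "onset_t_min": [r.onset_t_min for r in recs],
            "delam_t_min": [r.delam_t_min for r in recs],
            "elapsed_min": [r.elapsed_min for r in recs],
            "F_at_delam_au": [r.F_at_delam_au for r in recs],
            "source": [r.source for r in recs],
        }
    )
    df["normalized_elapsed"] = df["elapsed_min"] / df["elapsed_min"].mean()
    df["normalized_F"] = df["F_at_delam_au"] / df["F_at_delam_au"].mean()
    return df


def delamination_trigger_stats(
    records: pd.DataFrame, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """Is delamination tied to the reporter level or to elapsed time?

    Compares the dispersion (CV and variance) of the group-normalised
    reporter level at delamination against the normalised elapsed time
    since onset, with a seeded per-cell label-swap permutation test of
    the CV difference.  A level-triggered exit gives a tight F and a
    broad elapsed-time distribution.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 delamination records")
    f = records["normalized_F"].to_numpy(dtype=float)
    e = records["normalized_elapsed"].to_numpy(dtype=float)

    def cv(x: np.ndarray) -> float:
        m = x.mean()
        return float(x.std(ddof=1) / m) if m else 0.0

    cv_f, cv_e = cv(f), cv(e)
    diff = cv_e - cv_f
    rng = np.random.default_rng(seed)
    n = len(records)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        fp = np.where(swap, e, f)
        ep = np.where(swap, f, e)
        if cv(ep) - cv(fp) >= diff:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {
        "cv_normalized_F": cv_f,
        "cv_normalized_elapsed": cv_e,
        "cv_difference": diff,
        "var_normalized_F": float(f.var(ddof=1)),
        "var_normalized_elapsed": float(e.var(ddof=1)),
        "p_value": float(p),
        "n_perm": n_perm,
        "seed": seed,
        "n_cells": n,
    }


# ---------------------------------------------------------------------------
# divisions
# ---------------------------------------------------------------------------


def lineage_onset_times(events: pd.DataFrame) -> dict[int, float]:
    """First non-inherited specification onset per track id."""
    out: dict[int, float] = {}
    ons = events[events["event_type"] == "onset"]
    for row in ons.itertuples(index=False):
        if isinstance(row.payload, dict) and row.payload.get("inherited"):
            continue
        tid = int(row.track_id)
        if tid not in out or row.t_min < out[tid]:
            out[tid] = float(row.t_min)
    return out


def classify_division(
    event,
    tracks: pd.DataFrame,
    geometry: VesicleGeometry,
    onset_times: dict[int, float] | None = None,
    window_end_min: float | None = None,
    perpendicular_tol_deg: float = PERPENDICULAR_TOL_DEG,
    luminal_depth: float = 0.30,
    basal_half: float = 0.50,
) -> DivisionClassification:
    """Classify one division event from its daughters' outcomes.

    Fate is symmetric when both daughters delaminate within the analysis
    window or sit in the basal half of the epithelium (positioned to
    delaminate) at its end.  The cleavage plane is perpendicular to the
    cleavage (spindle) axis; its angle to the local apical surface is the
    angle between the two plane normals, mapped to [0, 90] degrees.
    Timing compares the division time with the mother lineage's own
    specification onset.
    """
    payload = event["payload"] if isinstance(event, (dict, pd.Series)) else event.payload
    t_div = float(event["t_min"] if isinstance(event, (dict, pd.Series)) else event.t_min)
    mother = int(
        event["track_id"] if isinstance(event, (dict, pd.Series)) else event.track_id
    )
    d1, d2 = (int(d) for d in payload["daughters"])
    spindle = np.asarray(payload["spindle_axis"], dtype=float)
    div_pos = np.asarray(payload["position_um"], dtype=float)

    if window_end_min is None:
        window_end_min = float(tracks["t_min"].max())

    normal = geometry.apical_normal(div_pos[None, :])[0]
    cosang = abs(float(np.dot(spindle / np.linalg.norm(spindle), normal)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    orientation = "perpendicular" if angle >= perpendicular_tol_deg else "oblique"

    depth_div = float(geometry.depth(div_pos[None, :])[0])
    position_class = "luminal" if depth_div < luminal_depth else "peripheral-apical"

    def daughter_outcome(tid: int) -> bool:
        tr = tracks[tracks["track_id"] == tid]
        if tr.empty:
            raise ValueError(f"daughter track {tid} missing from tracks")
        tr = tr[tr["t_min"] <= window_end_min + 1e-9].sort_values("t_min")
        if tr.empty:
            raise ValueError(f"daughter track {tid} has no samples in window")
        if (tr["compartment"] == "delaminated").any():
            return True
        last = tr.iloc[-1]
        depth = float(
            geometry.depth(np.array([[last.x_um, last.y_um, last.z_um]]))[0]
        )
        return depth > basal_half  # positioned to delaminate

    outcomes = [daughter_outcome(d) for d in (d1, d2)]  # both must exist
    sym = all(outcomes)

    onset_times = onset_times or {}
    mother_onset = onset_times.get(mother)
    timing = (
        "after_onset"
        if mother_onset is not None and mother_onset < t_div
        else "before_onset"
    )

    return DivisionClassification(
        event_track_id=mother,
        t_min=t_div,
        position_class=position_class,
        cleavage_angle_deg=angle,
        orientation_class=orientation,
        fate_class="symmetric" if sym else "asymmetric",
        timing_class=timing,
        daughters=(d1, d2),
    )


# ---------------------------------------------------------------------------
# ingression
# ---------------------------------------------------------------------------


def count_ingressed(
    tracks: pd.DataFrame,
    geometry: VesicleGeometry | None,
    t_eval_min: float,
) -> int:
    """Number of photoconverted nuclei inside the vesicle at ``t_eval``.

    Counts labelled tracks whose nucleus sits in the otic epithelium
    (or has delaminated from it) at the evaluation time.
    """
    if not bool(tracks["labeled"].any()):
        raise ValueError("no photoconversion labels present in tracks")
    snap = tracks_at(tracks, t_eval_min, vesicle_only=False)
    inside = snap["compartment"].isin(["epithelial", "delaminated"])
    return int((snap["labeled"] & inside).sum())
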