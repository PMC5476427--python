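"""Single-cell reporter scoring and vesicle-level specification summaries.

``F_cell`` is the mean of three background-subtracted cytosol readings
taken at distinct x, y and z positions around the nucleus.  A cell is
``neurog1``-positive when ``F_cell`` strictly exceeds the run's empirical
threshold; per-vesicle summaries report the number of positives, their
mean (F̄_cell), the global reporter level (the sum of ``F_cell`` over
positives) and the number of high expressers (``F_cell`` strictly above
1.5x the control F̄_cell).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import ImageStack, tracks_at

logger = logging.getLogger("otoquant")


@dataclass
class FCellMeasurement:
    """One cell's three-sample cytosolic reporter measurement."""

    track_id: int
    t_min: float
    samples_au: tuple[float, float, float]
    background_au: tuple[float, float, float]
    clamped: bool = False

    @property
    def F_cell_au(self) -> float:
        return float(np.mean(self.samples_au))


@dataclass
class SpecificationSummary:
    """Per-vesicle neuronal-specification scores."""

    vesicle_id: str
    threshold_au: float
    n_pos: int
    global_au: float
    mean_fcell_au: float | None
    n_hi: int
    control_mean_fcell_au: float | None = None

    def to_dict(self) -> dict:
        return {
            "vesicle_id": self.vesicle_id,
            "threshold_au": self.threshold_au,
            "n_pos": self.n_pos,
            "global_au": self.global_au,
            "mean_fcell_au": self.mean_fcell_au,
            "n_hi": self.n_hi,
            "control_mean_fcell_au": self.control_mean_fcell_au,
        }


# ---------------------------------------------------------------------------
# image-based measurement
# ---------------------------------------------------------------------------

#: fixed angular offsets (deg) and z-slice offsets of the three cytosol sites
_SITE_ANGLES_DEG = (0.0, 120.0, 240.0)
_SITE_DZ_VOXELS = (-1, 0, 1)


def empirical_threshold(
    stack: ImageStack, background_region: tuple, n_sd: float = 5.0
) -> float:
    """Positivity threshold for rendered data: ``n_sd`` background
    standard deviations (after background subtraction the background
    itself scores ~0, so this is a pure noise floor)."""
    bg = _region_values(stack.channels["reporter"], stack, background_region)
    return float(n_sd * bg.std())


def _region_values(img: np.ndarray, stack: ImageStack, region: tuple) -> np.ndarray:
    lo, hi = (np.asarray(r, dtype=float) for r in region)
    i0 = stack.world_to_index(lo)
    i1 = stack.world_to_index(hi)
    sl = tuple(slice(min(a, b), max(a, b) + 1) for a, b in zip(i0, i1))
    return img[sl]


def measure_fcell(
    stack: ImageStack,
    nucleus_center_um: tuple[float, float, float],
    background_region: tuple,
    track_id: int = -1,
    nucleus_radius_um: float = 2.5,
    cell_radius_um: float = 4.5,
) -> FCellMeasurement:
    """Three-site cytosolic reporter reading around one nucleus.

    Sites sit at fixed angular offsets in the cytosolic annulus midway
    between nucleus and membrane, on three distinct z slices; each
    reading is background-subtracted (negative readings are clamped at
    zero and flagged).
    """
    img = stack.channels["reporter"]
    bg_vals = _region_values(img, stack, background_region)
    bg = float(bg_vals.mean())
    r_site = 0.5 * (nucleus_radius_um + cell_radius_um)
    cx, cy, cz = nucleus_center_um
    dz_um = stack.voxel_size_um[0]
    samples, backs = [], []
    for ang, dz in zip(_SITE_ANGLES_DEG, _SITE_DZ_VOXELS):
        a = math.radians(ang)
        site = (cx + r_site * math.cos(a), cy + r_site * math.sin(a), cz + dz * dz_um)
        iz, iy, ix = stack.world_to_index(site)
        if not (
            0 <= iz < img.shape[0] and 0 <= iy < img.shape[1] and 0 <= ix < img.shape[2]
        ):
            raise ValueError(
                f"cytosol site outside the stack for cell at {nucleus_center_um}"
            )
        samples.append(float(img[iz, iy, ix]))
        backs.append(bg)
    sub = [s - b for s, b in zip(samples, backs)]
    clamped = any(v < 0 for v in sub)
    sub = [max(v, 0.0) for v in sub]
    return FCellMeasurement(
        track_id=track_id, t_min=stack.t_min,
        samples_au=tuple(sub), background_au=tuple(backs), clamped=clamped,
    )


# ---------------------------------------------------------------------------
# track-based (noiseless ground-truth) measurement
# ---------------------------------------------------------------------------


def measurements_from_tracks(
    tracks: pd.DataFrame, t_min: float, vesicle_only: bool = True
) -> pd.DataFrame:
    """Per-cell F_cell table straight from ground-truth tracks.

    The noiseless analogue of the image measurement: all three cytosol
    samples equal the track's true reporter level, background zero.
    """
    snap = tracks_at(tracks, t_min, vesicle_only=vesicle_only)
    return pd.DataFrame(
        {
            "track_id": snap["track_id"].to_numpy(),
            "t_min": t_min,
            "F_cell_au": snap["F_true_au"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# classification and summaries
# ---------------------------------------------------------------------------


def classify_positive(F_cell_au: float, threshold_au: float) -> bool:
    """Strictly-greater positivity rule; the threshold is recorded with
    every summary so runs remain comparable."""
    if threshold_au < 0:
        raise ValueError("threshold must be non-negative")
    return F_cell_au > threshold_au


def vesicle_summary(
    f_cells_au: np.ndarray | pd.Series,
    threshold_au: float,
    control_mean_fcell_au: float | None = None,
    vesicle_id: str = "",
) -> SpecificationSummary:
    """Vesicle-level specification scores from one F_cell per cell.

    The high-expresser cutoff is 1.5x the control F̄_cell (strictly
    greater); with no control mean given, the vesicle's own mean is used.
    With no positive cell, F̄_cell is reported missing and the counts are
    zero.
    """
    if threshold_au < 0:
        raise ValueError("threshold must be non-negative")
    f = np.asarray(f_cells_au, dtype=float)
    pos = f[f > threshold_au]
    n_pos = int(pos.size)
    global_au = float(pos.sum())
    mean_f = float(pos.mean()) if n_pos else None
    ctrl = control_mean_fcell_au if control_mean_fcell_au is not None else mean_f
    n_hi = int((pos > 1.5 * ctrl).sum()) if (n_pos and ctrl is not None) else 0
    return SpecificationSummary(
        vesicle_id=vesicle_id, threshold_au=float(threshold_au),
        n_pos=n_pos, global_au=global_au, mean_fcell_au=mean_f, n_hi=n_hi,
        control_mean_fcell_au=None if ctrl is None else float(ctrl),
    )


def expression_rate(t_min: np.ndarray, f_au: np.ndarray) -> float:
    """Mean rate of reporter increase, ΔF/Δt, over a post-onset ramp."""
    t = np.asarray(t_min, dtype=float)
    f = np.asarray(f_au, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two timepoints")
    if t[-1] == t[0]:
        raise ValueError("zero time span")
    return float((f[-1] - f[0]) / (t[-1] - t[0]))


def fold_change(
    treated: np.ndarray,
    control: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Treated/control ratio of group means, in percent, with a seeded
    bootstrap confidence interval (resampling vesicles within groups)."""
    tr = np.asarray(treated, dtype=float)
    ct = np.asarray(control, dtype=float)
    if ct.size == 0 or ct.mean() == 0:
        raise ValueError("control mean must be nonzero")
    point = tr.mean() / ct.mean() * 100.0
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bt = rng.choice(tr, size=tr.size, replace=True)
        bc = rng.choice(ct, size=ct.size, replace=True)
        boots[i] = bt.mean() / bc.mean() * 100.0 if bc.mean() != 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {
        "fold_percent": float(point),
        "ci95_percent": (float(lo), float(hi)),
        "n_boot": n_boot,
        "seed": seed,
    }
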