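"""Octant morphometry of the otic vesicle.

A rectangular cuboid spanning the vesicle's extreme points is split at the
midpoint of every axis into eight equal-volume, axis-labelled regions
(anterior/posterior x medial/lateral x dorsal/ventral); cell counts,
tissue volumes, nuclear densities and mitotic events are then quantified
per region.  The ventro-antero-lateral region is the neurogenic domain.

Boxes are half-open and lower-inclusive: a nucleus exactly on a midplane
belongs to the upper (e.g. posterior) half, so every point inside the
cuboid maps to exactly one region.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import AXIS_LABELS, NEUROGENIC_LABEL, octant_labels

logger = logging.getLogger("otoquant")


@dataclass
class RegionPartition:
    """Eight equal-volume octants of the vesicle-bounding cuboid."""

    cuboid_min_um: np.ndarray
    cuboid_max_um: np.ndarray
    neurogenic_label: str = NEUROGENIC_LABEL

    def __post_init__(self):
        self.cuboid_min_um = np.asarray(self.cuboid_min_um, dtype=float)
        self.cuboid_max_um = np.asarray(self.cuboid_max_um, dtype=float)
        if np.any(self.cuboid_max_um <= self.cuboid_min_um):
            raise ValueError("degenerate cuboid: zero extent on some axis")

    @property
    def midpoint_um(self) -> np.ndarray:
        return 0.5 * (self.cuboid_min_um + self.cuboid_max_um)

    @property
    def labels(self) -> list[str]:
        return octant_labels()

    @property
    def region_volume_um3(self) -> float:
        ext = self.cuboid_max_um - self.cuboid_min_um
        return float(np.prod(ext)) / 8.0

    def region_bounds(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """The axis-aligned box of one region."""
        idx = self.labels.index(label)
        bits = ((idx >> 2) & 1, (idx >> 1) & 1, idx & 1)
        lo = np.where(bits, self.midpoint_um, self.cuboid_min_um)
        hi = np.where(bits, self.cuboid_max_um, self.midpoint_um)
        return lo, hi

    def assign(self, points_um: np.ndarray) -> np.ndarray:
        """Region index per point; -1 for points outside the cuboid.

        Index encodes the octant as ``4*ix + 2*iy + iz`` matching
        :func:`otoquant.synthetic_data.octant_labels` order.
        """
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        inside = np.all(
            (p >= self.cuboid_min_um) & (p <= self.cuboid_max_um), axis=1
        )
        upper = (p >= self.midpoint_um).astype(int)  # lower-inclusive rule
        idx = 4 * upper[:, 0] + 2 * upper[:, 1] + upper[:, 2]
        idx[~inside] = -1
        return idx

    def assign_labels(self, points_um: np.ndarray) -> np.ndarray:
        idx = self.assign(points_um)
        lut = np.asarray(self.labels + ["outside"], dtype=object)
        return lut[idx]

    def to_dict(self) -> dict:
        return {
            "cuboid_min_um": self.cuboid_min_um.tolist(),
            "cuboid_max_um": self.cuboid_max_um.tolist(),
            "neurogenic_label": self.neurogenic_label,
            "labels": self.labels,
        }


def build_cuboid_partition(vertices_um: np.ndarray) -> RegionPartition:
    """Rectangular cuboid spanned by the vesicle's extreme points.

    ``vertices_um`` is an (n >= 2, 3) array of external vertices; the
    cuboid is their axis-aligned bounding box, split at the midpoints.
    """
    v = np.atleast_2d(np.asarray(vertices_um, dtype=float))
    if v.shape[0] < 2 or v.shape[1] != 3:
        raise ValueError("need at least two 3D vertices")
    return RegionPartition(v.min(axis=0), v.max(axis=0))


def count_cells_by_region(
    nuclei_positions_um: np.ndarray, partition: RegionPartition
) -> pd.DataFrame:
    """Per-region nucleus counts and fractions of the total inside.

    Nuclei outside the cuboid are excluded and logged; with no nuclei at
    all, counts are zero and fractions are reported missing.
    """
    pts = np.atleast_2d(np.asarray(nuclei_positions_um, dtype=float))
    if pts.size == 0:
        logger.warning("count_cells_by_region: empty input, returning zeros")
        return pd.DataFrame(
            {"region": partition.labels, "cell_count": 0, "fraction_of_total": np.nan}
        )
    idx = partition.assign(pts)
    n_out = int((idx < 0).sum())
    if n_out:
        logger.warning(
            "count_cells_by_region: %d nuclei outside the cuboid were excluded",
            n_out,
        )
    counts = np.bincount(idx[idx >= 0], minlength=8)
    total = counts.sum()
    frac = counts / total if total else np.full(8, np.nan)
    return pd.DataFrame(
        {"region": partition.labels, "cell_count": counts, "fraction_of_total": frac}
    )


def tissue_volume(
    plane_areas_um2: np.ndarray, z_spacing_um: float, lumen_volume_um3: float = 0.0
) -> float:
    """Tissue volume from per-plane x-y areas: sum(area) * dz - lumen."""
    if z_spacing_um <= 0:
        raise ValueError("z spacing must be positive")
    if lumen_volume_um3 < 0:
        raise ValueError("lumen volume must be non-negative")
    gross = float(np.sum(np.asarray(plane_areas_um2, dtype=float))) * z_spacing_um
    if lumen_volume_um3 >= gross and gross > 0:
        raise ValueError("lumen volume exceeds gross tissue volume")
    return gross - lumen_volume_um3


def tissue_volume_from_labels(
    label_stack: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    lumen_volume_um3: float = 0.0,
) -> float:
    """Tissue volume from a boolean/label z-stack (arrays are z, y, x)."""
    stack = np.asarray(label_stack) > 0
    dz, dy, dx = voxel_size_um
    areas = stack.reshape(stack.shape[0], -1).sum(axis=1) * (dy * dx)
    return tissue_volume(areas, dz, lumen_volume_um3)


def region_density(
    counts: np.ndarray, volumes_um3: np.ndarray
) -> np.ndarray:
    """Nuclear density per region in nuclei / 10^3 um^3."""
    c = np.asarray(counts, dtype=float)
    v = np.asarray(volumes_um3, dtype=float)
    if np.any((v <= 0) & (c > 0)):
        raise ValueError("zero region volume with a nonzero count")
    out = np.zeros_like(c)
    nz = v > 0
    out[nz] = c[nz] / v[nz] * 1.0e3
    return out


def count_mitoses_by_region(
    events: pd.DataFrame,
    partition: RegionPartition,
    window_min: tuple[float, float],
) -> pd.DataFrame:
    """Division events per region within a time window.

    A division is assigned to the region containing the mother's position
    at anaphase (the event's ``position_um`` payload).  The returned frame
    also carries the neurogenic share (percent) as an attribute
    ``neurogenic_percent``.
    """
    t0, t1 = window_min
    div = events[events["event_type"] == "division"]
    div = div[(div["t_min"] >= t0) & (div["t_min"] <= t1)]
    counts = np.zeros(8, dtype=int)
    if len(div):
        pos = np.array([p["position_um"] for p in div["payload"]])
        idx = partition.assign(pos)
        counts = np.bincount(idx[idx >= 0], minlength=8)
    total = counts.sum()
    out = pd.DataFrame({"region": partition.labels, "mitosis_count": counts})
    neuro = counts[partition.labels.index(partition.neurogenic_label)]
    out.attrs["neurogenic_percent"] = float(neuro / total * 100.0) if total else 0.0
    out.attrs["total_mitoses"] = int(total)
    return out


def region_stats(
    nuclei_positions_um: np.ndarray,
    partition: RegionPartition,
    region_tissue_volumes_um3: np.ndarray | None = None,
    events: pd.DataFrame | None = None,
    mitosis_window_min: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Combined per-region statistics table (counts, fractions, volume,
    density, mitoses) mirroring the per-vesicle morphometric analysis."""
    out = count_cells_by_region(nuclei_positions_um, partition)
    if region_tissue_volumes_um3 is not None:
        v = np.asarray(region_tissue_volumes_um3, dtype=float)
        out["tissue_volume_um3"] = v
        out["density_per_1e3um3"] = region_density(
            out["cell_count"].to_numpy(), v
        )
    if events is not None and mitosis_window_min is not None:
        mit = count_mitoses_by_region(events, partition, mitosis_window_min)
        out = out.merge(mit, on="region")
        out.attrs.update(mit.attrs)
    return out
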