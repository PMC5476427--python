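"""Agent-based synthetic 4D data generator for otic neurogenesis.

Produces ground-truth cell tracks, typed event logs and rendered
multi-channel image stacks for a folding otic vesicle, with the cell
behaviours the downstream quantification modules assume:

* a vesicle of ~311 cells at 19 hpf whose ventro-antero-lateral octant is
  the neurogenic domain (denser, more proliferative);
* an anterior pool of migrating ``neurog1``-positive pioneer cells, a
  subset of which ingress into the forming neurogenic domain before the
  anterior epithelium folds;
* local specification of resident cells: stochastic onset of reporter
  expression followed by linear accumulation at per-cell rates in
  0.15-0.54 a.u./min, with delamination triggered when the reporter
  crosses a per-cell level drawn from 45.5-52.5 a.u.;
* symmetric apical divisions (each cell divides at most once), with the
  reporter protein split between daughters;
* instruction coupling: ingressed pioneers raise both the specification
  hazard and the expression amplitude of resident cells;
* perturbations: laser-ablation pulses (2-3 pioneers per pulse),
  FGF blockade (advanced anterior folding, no ingression) and
  aphidicolin/hydroxyurea (no divisions, reduced starting pool).

All simulation times are minutes from ``t_start_hpf``; hours post
fertilisation appear only in the configuration.  Coordinates are
right-handed micrometres with x increasing anterior->posterior,
y medial->lateral and z dorsal->ventral, centred on the vesicle.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("otoquant")

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: octant axis labels, low-coordinate half first
AXIS_LABELS = (("anterior", "posterior"), ("medial", "lateral"), ("dorsal", "ventral"))

#: the neurogenic domain is the ventro-antero-lateral octant
NEUROGENIC_LABEL = "anterior-lateral-ventral"

COMPARTMENTS = ("outside", "epithelial", "delaminated")

PERTURBATIONS = ("none", "ablation", "fgf_block", "proliferation_block")


@dataclass
class ScenarioConfig:
    """Full parameterisation of one synthetic embryo.

    Defaults are the wild-type calibration: quantities printed in the
    source observations (cell counts, rate and threshold ranges, ablation
    pulse sizes, ROI geometry) are used verbatim; free parameters (onset
    hazard, instruction gains, pioneer ramp range, the AH pool scale) were
    fitted once by ``scripts/calibrate_coupling.py`` against the published
    cohort statistics and frozen here.
    """

    name: str = "wildtype"
    seed: int = 0

    # time base
    t_start_hpf: float = 12.0
    t_end_hpf: float = 20.5
    dt_min: float = 2.0

    # geometry (ellipsoidal shell epithelium around a lumen)
    vesicle_axes_um: tuple[float, float, float] = (42.0, 36.0, 32.0)
    lumen_fraction: float = 0.08

    # cell placement
    n_cells_target: int = 311
    initial_neurogenic_cells: float = 35.5
    initial_other_cells: float = 35.8
    neurogenic_octant: str = NEUROGENIC_LABEL
    neurogenic_depth_range: tuple[float, float] = (0.50, 0.70)
    other_depth_range: tuple[float, float] = (0.25, 0.75)
    resident_scale: float = 1.0

    # pioneer pool and ingression
    pioneer_pool_size: int = 8
    pioneer_ingression_prob: float = 0.59
    ingression_window_hpf: tuple[float, float] = (13.75, 15.5)
    anterior_fold_time_hpf: float = 16.0
    pioneer_travel_min: tuple[float, float] = (30.0, 45.0)
    pioneer_onset_hpf: float = 11.0
    pioneer_ramp_rate_range_au_per_min: tuple[float, float] = (0.22, 0.31)
    pioneer_delam_delay_min: tuple[float, float] = (30.0, 90.0)
    anterior_field_cells: float = 50.0
    anterior_roi_gap_um: float = 25.0
    anterior_roi_size_um: tuple[float, float, float] = (40.0, 50.0, 50.0)

    # local specification kinetics
    onset_start_hpf: float = 13.5
    onset_rate_per_min: float = 0.0026
    ramp_rate_range_au_per_min: tuple[float, float] = (0.15, 0.54)
    delamination_threshold_range_au: tuple[float, float] = (45.5, 52.5)

    # instruction coupling (per ingressed pioneer, relative to the typical
    # wild-type complement so the configured ramp range stays the observed one)
    instruction_gain: float = 1.24
    instruction_gain_amplitude: float = 1.10
    instruction_reference_pioneers: float = 4.7

    # divisions
    division_prob_neurogenic: float = 0.24
    division_prob_other: float = 0.0475
    division_window_hpf: tuple[float, float] = (14.0, 18.5)
    division_luminal_prob: float = 0.6
    daughter_offset_um: float = 3.0
    rapid_delam_delay_min: float = 10.0

    # delamination basal drift (relative depth per minute, capped)
    basal_drift_per_min: float = 0.004
    basal_depth_cap: float = 1.10

    # perturbation
    perturbation: str = "none"
    ablation_pulses: int = 3
    ablation_time_hpf: float = 12.5
    ablation_cells_per_pulse: tuple[int, int] = (2, 3)

    # analysis defaults echoed into outputs
    analysis_threshold_au: float = 10.0

    # rendering noise
    noise_model: dict = field(default_factory=lambda: {"name": "none"})

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on any invariant violation."""
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        if self.t_end_hpf <= self.t_start_hpf:
            raise ValueError("t_end_hpf must exceed t_start_hpf")
        for nm in (
            "ingression_window_hpf",
            "division_window_hpf",
            "ramp_rate_range_au_per_min",
            "pioneer_ramp_rate_range_au_per_min",
            "delamination_threshold_range_au",
            "pioneer_travel_min",
            "pioneer_delam_delay_min",
            "ablation_cells_per_pulse",
            "neurogenic_depth_range",
            "other_depth_range",
        ):
            lo, hi = getattr(self, nm)
            if lo > hi:
                raise ValueError(f"{nm} bounds must be ordered (low <= high)")
        for nm in ("division_prob_neurogenic", "division_prob_other", "pioneer_ingression_prob"):
            p = getattr(self, nm)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must be a probability in [0, 1]")
        if not 0.0 < self.lumen_fraction < 1.0:
            raise ValueError("lumen_fraction must be in (0, 1)")
        if self.instruction_gain < 1.0 or self.instruction_gain_amplitude < 1.0:
            raise ValueError("instruction gains must be >= 1")
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if min(self.vesicle_axes_um) <= 0:
            raise ValueError("vesicle semi-axes must be positive")
        if self.neurogenic_octant not in octant_labels():
            raise ValueError(f"unknown octant label {self.neurogenic_octant!r}")
        if not isinstance(self.noise_model, Mapping) or "name" not in self.noise_model:
            raise ValueError("noise_model must be a mapping with a 'name'")
        if self.noise_model["name"] not in ("none", "poisson_gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model['name']!r}")

    # convenience conversions ------------------------------------------------
    def minutes(self, t_hpf: float) -> float:
        """Convert an hpf timestamp to minutes from ``t_start_hpf``."""
        return (t_hpf - self.t_start_hpf) * 60.0

    @property
    def t_end_min(self) -> float:
        return self.minutes(self.t_end_hpf)

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end_min / self.dt_min))
        return np.arange(n + 1) * self.dt_min


#: per-scenario overrides applied on top of the wild-type defaults
SCENARIOS: dict[str, dict] = {
    "wildtype": {},
    "ablation": {"perturbation": "ablation"},
    "fgf_block": {
        "perturbation": "fgf_block",
        # FGF blockade advances anterior folding to the posterior fold time,
        # which precedes the ingression window: no pioneer can ingress.
        "anterior_fold_time_hpf": 13.0,
    },
    "proliferation_block": {
        "perturbation": "proliferation_block",
        "division_prob_neurogenic": 0.0,
        "division_prob_other": 0.0,
        # aphidicolin/hydroxyurea acts from well before the simulated window,
        # so the pools entering it are already reduced (calibrated): the
        # resident pool roughly halves and the anterior pioneer pool, partly
        # built by pre-window proliferation, shrinks slightly.
        "resident_scale": 0.6,
        "pioneer_pool_size": 7,
    },
    "custom": {},
}


def make_scenario(name: str, overrides: Mapping | None = None) -> ScenarioConfig:
    """Build a validated :class:`ScenarioConfig` for a shipped scenario.

    ``name`` must be one of ``wildtype``, ``ablation``, ``fgf_block``,
    ``proliferation_block`` or ``custom``; ``overrides`` are applied on top
    of the scenario defaults and re-validated.
    """
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    params: dict = {"name": name}
    params.update(SCENARIOS[name])
    valid = {f.name for f in dataclasses.fields(ScenarioConfig)}
    for key, value in dict(overrides or {}).items():
        if key not in valid:
            raise ValueError(f"unknown config field {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        params[key] = value
    cfg = ScenarioConfig(**params)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def octant_labels() -> list[str]:
    """The eight octant labels in index order ``(ix, iy, iz)``."""
    out = []
    for ix in (0, 1):
        for iy in (0, 1):
            for iz in (0, 1):
                out.append(
                    f"{AXIS_LABELS[0][ix]}-{AXIS_LABELS[1][iy]}-{AXIS_LABELS[2][iz]}"
                )
    return out


@dataclass
class VesicleGeometry:
    """Ellipsoidal-shell abstraction of the otic vesicle epithelium.

    The epithelium occupies ellipsoidal radii between the lumen surface
    (apical) and the outer surface (basal); ``depth`` is the relative
    apicobasal coordinate, 0 at the lumen and 1 at the basal surface.
    """

    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes_um: tuple[float, float, float] = (42.0, 36.0, 32.0)
    lumen_fraction: float = 0.08

    @property
    def inner_rho(self) -> float:
        return float(self.lumen_fraction ** (1.0 / 3.0))

    def rho(self, points_um: np.ndarray) -> np.ndarray:
        """Ellipsoidal radius: 0 at the centre, 1 on the outer surface."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        rel = (p - np.asarray(self.center_um)) / np.asarray(self.semi_axes_um)
        return np.sqrt((rel**2).sum(axis=1))

    def depth(self, points_um: np.ndarray) -> np.ndarray:
        """Relative apicobasal depth (0 apical/lumen, 1 basal surface)."""
        return (self.rho(points_um) - self.inner_rho) / (1.0 - self.inner_rho)

    def apical_normal(self, points_um: np.ndarray) -> np.ndarray:
        """Outward unit normal of the local apical surface."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        n = (p - np.asarray(self.center_um)) / np.asarray(self.semi_axes_um) ** 2
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def tissue_volume_um3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * math.pi * a * b * c * (1.0 - self.lumen_fraction)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_um)
        a = np.asarray(self.semi_axes_um)
        return c - a, c + a

    def anterior_roi(
        self, volume_um3: float = 1.0e5, gap_um: float = 25.0,
        size_um: tuple[float, float, float] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Standard photoconversion ROI anterior to the epithelium.

        An axis-aligned box of about ``volume_um3`` whose posterior face
        sits ``gap_um`` anterior of the vesicle's anterior limit.
        """
        if size_um is None:
            lx = 40.0
            side = math.sqrt(volume_um3 / lx)
            size_um = (lx, side, side)
        sx, sy, sz = size_um
        cx, cy, cz = self.center_um
        x_hi = cx - self.semi_axes_um[0] - gap_um
        lo = np.array([x_hi - sx, cy - sy / 2.0, cz - sz / 2.0])
        hi = np.array([x_hi, cy + sy / 2.0, cz + sz / 2.0])
        return lo, hi


# ---------------------------------------------------------------------------
# simulation result containers
# ---------------------------------------------------------------------------

TRACK_COLUMNS = [
    "track_id", "parent_id", "t_min", "x_um", "y_um", "z_um",
    "compartment", "F_true_au", "labeled",
]

EVENT_COLUMNS = ["event_type", "t_min", "track_id", "payload"]


@dataclass
class SimulationResult:
    """Tracks, event log and geometry of one simulated vesicle."""

    config: ScenarioConfig
    geometry: VesicleGeometry
    tracks: pd.DataFrame
    events: pd.DataFrame
    cells: pd.DataFrame  # per-cell ground-truth parameter table

    def positions_at(self, t_min: float, vesicle_only: bool = True) -> pd.DataFrame:
        """Per-cell sample nearest below ``t_min`` for cells alive then."""
        return tracks_at(self.tracks, t_min, vesicle_only=vesicle_only)


def tracks_at(tracks: pd.DataFrame, t_min: float, vesicle_only: bool = True) -> pd.DataFrame:
    """One row per track: the latest sample at or before ``t_min``,
    restricted to tracks still alive (their last sample is not earlier than
    ``t_min`` minus one nominal frame).  ``vesicle_only`` keeps cells whose
    compartment is epithelial or delaminated."""
    sel = tracks[tracks["t_min"] <= t_min + 1e-9]
    if sel.empty:
        return sel
    idx = sel.groupby("track_id")["t_min"].idxmax()
    snap = tracks.loc[idx]
    last = tracks.groupby("track_id")["t_min"].max()
    alive = last[last >= t_min - 1e-9].index
    snap = snap[snap["track_id"].isin(alive)]
    if vesicle_only:
        snap = snap[snap["compartment"] != "outside"]
    return snap.reset_index(drop=True)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


def _sample_octant_position(
    rng: np.random.Generator,
    geometry: VesicleGeometry,
    signs: np.ndarray,
    depth_range: tuple[float, float],
) -> np.ndarray:
    """Nucleus position inside one octant of the epithelial shell."""
    u = np.abs(rng.normal(size=3))
    u /= np.linalg.norm(u)
    d = rng.uniform(*depth_range)
    rho = geometry.inner_rho + d * (1.0 - geometry.inner_rho)
    return np.asarray(geometry.center_um) + signs * u * rho * np.asarray(
        geometry.semi_axes_um
    )


def _octant_signs(label: str) -> np.ndarray:
    parts = label.split("-")
    signs = []
    for axis, part in enumerate(parts):
        signs.append(-1.0 if part == AXIS_LABELS[axis][0] else 1.0)
    return np.asarray(signs)


def _perp_unit(rng: np.random.Generator, normal: np.ndarray) -> np.ndarray:
    """Random unit vector perpendicular to ``normal``."""
    while True:
        v = rng.normal(size=3)
        v -= v.dot(normal) * normal
        n = np.linalg.norm(v)
        if n > 1e-8:
            return v / n


def simulate_embryo(config: ScenarioConfig) -> SimulationResult:
    """Run one embryo and return tracks, events and geometry.

    Deterministic given ``config.seed``: identical configs produce
    bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    geometry = VesicleGeometry(
        semi_axes_um=config.vesicle_axes_um, lumen_fraction=config.lumen_fraction
    )
    grid = config.time_grid
    dt = config.dt_min
    t_end = config.t_end_min

    cells: list[dict] = []  # per-cell parameter records
    events: list[dict] = []
    next_id = 0

    def new_id() -> int:
        nonlocal next_id
        next_id += 1
        return next_id

    labels = octant_labels()
    neuro = config.neurogenic_octant

    # ---- resident epithelial cells -----------------------------------
    for label in labels:
        mean = (
            config.initial_neurogenic_cells
            if label == neuro
            else config.initial_other_cells
        )
        n = rng.poisson(mean * config.resident_scale)
        depth_range = (
            config.neurogenic_depth_range if label == neuro else config.other_depth_range
        )
        signs = _octant_signs(label)
        for _ in range(n):
            pos = _sample_octant_position(rng, geometry, signs, depth_range)
            cells.append(
                dict(
                    track_id=new_id(), parent_id=None, kind="resident",
                    region=label, x=pos[0], y=pos[1], z=pos[2],
                    birth_t=0.0, end_t=t_end, t_ing=np.nan,
                    expr_start=np.nan, F_start=0.0, rate=np.nan,
                    delam_threshold=np.nan, delam_t=np.nan,
                    division_t=np.nan, ablated=False,
                )
            )

    # ---- anterior pioneer pool and passive anterior field ------------
    roi_lo, roi_hi = geometry.anterior_roi(
        gap_um=config.anterior_roi_gap_um, size_um=config.anterior_roi_size_um
    )
    core_lo = roi_lo + 0.2 * (roi_hi - roi_lo)
    core_hi = roi_hi - 0.2 * (roi_hi - roi_lo)
    fold_min = config.minutes(config.anterior_fold_time_hpf)
    ing_lo, ing_hi = (config.minutes(h) for h in config.ingression_window_hpf)
    neuro_signs = _octant_signs(neuro)

    # The migrating pool behaves as a stream with a fated subpopulation:
    # a fixed-size subset carries ingression competence (the rest settle in
    # the non-ingressing anterior pool), and each competent cell ingresses
    # with high probability.  The expected ingression count is exactly
    # pool_size * ingression_prob while embryo-to-embryo dispersion stays
    # close to the stream's structure rather than a pure coin flip per cell.
    target_ing = config.pioneer_pool_size * config.pioneer_ingression_prob
    n_fated = int(math.ceil(target_ing)) if target_ing > 0 else 0
    p_success = target_ing / n_fated if n_fated else 0.0
    fated = np.zeros(config.pioneer_pool_size, dtype=bool)
    if n_fated:
        fated[rng.permutation(config.pioneer_pool_size)[:n_fated]] = True

    pioneers = []
    for j in range(config.pioneer_pool_size):
        start = rng.uniform(core_lo, core_hi)
        will_ingress = bool(fated[j]) and rng.random() < p_success
        t_ing = rng.uniform(ing_lo, ing_hi)
        travel = rng.uniform(*config.pioneer_travel_min)
        target = _sample_octant_position(
            rng, geometry, neuro_signs, config.neurogenic_depth_range
        )
        rate = rng.uniform(*config.pioneer_ramp_rate_range_au_per_min)
        delay = rng.uniform(*config.pioneer_delam_delay_min)
        rec = dict(
            track_id=new_id(), parent_id=None, kind="pioneer", region=neuro,
            x=start[0], y=start[1], z=start[2],
            birth_t=0.0, end_t=t_end,
            t_ing=t_ing if (will_ingress and t_ing < fold_min) else np.nan,
            expr_start=config.minutes(config.pioneer_onset_hpf),
            F_start=0.0, rate=rate,
            delam_threshold=np.nan, delam_t=np.nan, division_t=np.nan,
            ablated=False,
            _target=target, _travel=travel, _delay=delay,
        )
        pioneers.append(rec)
        cells.append(rec)

    # ablation removes the pioneers nearest the placode, 2-3 per pulse,
    # before any ingression has taken place
    if config.perturbation == "ablation":
        t_abl = config.minutes(config.ablation_time_hpf)
        alive = sorted(pioneers, key=lambda c: -c["x"])  # nearest placode first
        k = 0
        for pulse in range(config.ablation_pulses):
            lo, hi = config.ablation_cells_per_pulse
            n_abl = int(rng.integers(lo, hi + 1))
            for _ in range(n_abl):
                if k >= len(alive):
                    break
                c = alive[k]
                k += 1
                c["ablated"] = True
                c["end_t"] = t_abl
                c["t_ing"] = np.nan
                events.append(
                    dict(event_type="ablation", t_min=t_abl, track_id=c["track_id"],
                         payload={"pulse": pulse + 1})
                )

    for c in pioneers:
        # pioneers express from before the simulated window
        events.append(
            dict(event_type="onset", t_min=0.0, track_id=c["track_id"],
                 payload={"pioneer": True,
                          "onset_t_true_min": c["expr_start"],
                          "rate_au_per_min": c["rate"]})
        )
        if not np.isnan(c["t_ing"]):
            events.append(
                dict(event_type="ingression", t_min=float(c["t_ing"]),
                     track_id=c["track_id"], payload={})
            )
            # pioneers delaminate shortly after ingression
            c["delam_t"] = float(c["t_ing"]) + float(c["_delay"])

    n_field = rng.poisson(config.anterior_field_cells)
    for _ in range(n_field):
        pos = rng.uniform(roi_lo, roi_hi)
        cells.append(
            dict(
                track_id=new_id(), parent_id=None, kind="field", region="",
                x=pos[0], y=pos[1], z=pos[2], birth_t=0.0, end_t=t_end,
                t_ing=np.nan, expr_start=np.nan, F_start=0.0, rate=np.nan,
                delam_threshold=np.nan, delam_t=np.nan, division_t=np.nan,
                ablated=False,
            )
        )

    # ---- instruction coupling: ingressed-pioneer count over time ------
    ing_times = np.sort(
        np.array([c["t_ing"] for c in pioneers if not np.isnan(c["t_ing"])])
    )

    def pioneers_present(t: np.ndarray) -> np.ndarray:
        return np.searchsorted(ing_times, np.atleast_1d(t), side="right").astype(float)

    p_ref = config.instruction_reference_pioneers
    g_h = config.instruction_gain
    g_a = config.instruction_gain_amplitude

    # ---- local specification: onset hazard on the grid ----------------
    onset_start = config.minutes(config.onset_start_hpf)
    mod_h = g_h ** (pioneers_present(grid) - p_ref)
    lam = config.onset_rate_per_min * mod_h * (grid >= onset_start)
    cum_h = np.concatenate([[0.0], np.cumsum(lam[:-1] * dt)])  # integral to grid[k]

    def draw_onset(birth_t: float) -> float:
        """Inverse-CDF sample of the inhomogeneous onset hazard."""
        h0 = float(np.interp(birth_t, grid, cum_h))
        target = h0 + rng.exponential()
        if target > cum_h[-1]:
            return np.nan
        k = int(np.searchsorted(cum_h, target))
        t_lo = grid[k - 1]
        rate_here = lam[k - 1]
        if rate_here <= 0:
            return float(grid[k])
        return float(t_lo + (target - cum_h[k - 1]) / rate_here)

    def draw_ramp(onset_t: float) -> float:
        base = rng.uniform(*config.ramp_rate_range_au_per_min)
        amp = g_a ** (float(pioneers_present(onset_t)[0]) - p_ref)
        return max(base * amp, 1e-3)

    residents = [c for c in cells if c["kind"] == "resident"]
    for c in residents:
        if c["region"] != neuro:
            continue
        t0 = draw_onset(0.0)
        if not np.isnan(t0):
            c["expr_start"] = t0
            c["rate"] = draw_ramp(t0)
            c["delam_threshold"] = rng.uniform(*config.delamination_threshold_range_au)

    # ---- divisions -----------------------------------------------------
    div_lo, div_hi = (config.minutes(h) for h in config.division_window_hpf)
    daughters: list[dict] = []
    for c in residents:
        p_div = (
            config.division_prob_neurogenic
            if c["region"] == neuro
            else config.division_prob_other
        )
        if rng.random() >= p_div:
            continue
        t_div = rng.uniform(div_lo, div_hi)
        t_div = float(np.round(t_div / dt) * dt)  # anaphase snapped to the grid
        c["division_t"] = t_div
        c["end_t"] = t_div

        pos = np.array([c["x"], c["y"], c["z"]])
        # interkinetic migration: anaphase happens at an apical surface,
        # either the central lumen or the peripheral apical scaffold
        luminal = rng.random() < (
            config.division_luminal_prob if c["region"] == neuro else 1.0
        )
        d_div = 0.02 if luminal else float(np.clip(geometry.depth(pos)[0], 0.05, 0.95))
        direction = (pos - np.asarray(geometry.center_um)) / np.asarray(
            geometry.semi_axes_um
        )
        direction /= np.linalg.norm(direction)
        rho_div = geometry.inner_rho + d_div * (1.0 - geometry.inner_rho)
        div_pos = np.asarray(geometry.center_um) + direction * rho_div * np.asarray(
            geometry.semi_axes_um
        )
        normal = geometry.apical_normal(div_pos)[0]
        spindle = _perp_unit(rng, normal)

        mother_expressing = (
            not np.isnan(c["expr_start"]) and c["expr_start"] < t_div
        )
        f_div = c["rate"] * (t_div - c["expr_start"]) if mother_expressing else 0.0
        # a cell scheduled to both delaminate and divide divides first
        # (its daughters then delaminate); see delamination pass below

        kid_ids = []
        depth_range = (
            config.neurogenic_depth_range
            if c["region"] == neuro
            else config.other_depth_range
        )
        for sgn in (+1.0, -1.0):
            offset = sgn * config.daughter_offset_um * spindle
            kpos = pos + offset
            # keep daughters in the mother's octant and depth band
            for shrink in (1.0, 0.3, 0.0):
                kpos = pos + shrink * offset
                dep = float(geometry.depth(kpos)[0])
                same_oct = np.all(np.sign(kpos - np.asarray(geometry.center_um))
                                  == np.sign(pos - np.asarray(geometry.center_um)))
                if depth_range[0] - 0.05 <= dep <= depth_range[1] + 0.05 and same_oct:
                    break
            kid = dict(
                track_id=new_id(), parent_id=c["track_id"], kind="daughter",
                region=c["region"], x=kpos[0], y=kpos[1], z=kpos[2],
                birth_t=t_div, end_t=t_end, t_ing=np.nan,
                expr_start=np.nan, F_start=0.0, rate=np.nan,
                delam_threshold=np.nan, delam_t=np.nan, division_t=np.nan,
                ablated=False,
            )
            if mother_expressing:
                # mean cytosolic intensity reads out concentration, which
                # cytokinesis preserves: daughters inherit the mother's level
                kid["expr_start"] = t_div
                kid["F_start"] = f_div
                kid["rate"] = c["rate"]
                kid["delam_threshold"] = rng.uniform(
                    *config.delamination_threshold_range_au
                )
                events.append(
                    dict(event_type="onset", t_min=t_div, track_id=kid["track_id"],
                         payload={"inherited": True,
                                  "lineage_onset_t_min": float(c["expr_start"])})
                )
            elif c["region"] == neuro:
                t0 = draw_onset(t_div)
                if not np.isnan(t0):
                    kid["expr_start"] = t0
                    kid["rate"] = draw_ramp(t0)
                    kid["delam_threshold"] = rng.uniform(
                        *config.delamination_threshold_range_au
                    )
            kid_ids.append(kid["track_id"])
            daughters.append(kid)
            cells.append(kid)

        events.append(
            dict(event_type="division", t_min=t_div, track_id=c["track_id"],
                 payload={
                     "daughters": kid_ids,
                     "spindle_axis": [float(v) for v in spindle],
                     "position_um": [float(v) for v in div_pos],
                     "position_class": "luminal" if luminal else "peripheral-apical",
                 })
        )

    # onset events for expressing residents (non-inherited)
    for c in residents:
        if np.isnan(c["expr_start"]):
            continue
        if not np.isnan(c["division_t"]) and c["expr_start"] >= c["division_t"]:
            # the lineage divides before specification; onset is re-drawn in
            # the daughters, the mother never expresses
            c["expr_start"] = np.nan
            c["rate"] = np.nan
            c["delam_threshold"] = np.nan
            continue
        events.append(
            dict(event_type="onset", t_min=float(c["expr_start"]),
                 track_id=c["track_id"],
                 payload={"rate_au_per_min": float(c["rate"])})
        )
    for kid in daughters:
        if np.isnan(kid["expr_start"]) or kid["F_start"] > 0:
            continue  # inherited onsets already logged
        events.append(
            dict(event_type="onset", t_min=float(kid["expr_start"]),
                 track_id=kid["track_id"],
                 payload={"rate_au_per_min": float(kid["rate"])})
        )

    # ---- delamination --------------------------------------------------
    for c in cells:
        if c["kind"] == "pioneer":
            if not np.isnan(c["delam_t"]) and c["delam_t"] <= t_end:
                events.append(
                    dict(event_type="delamination", t_min=float(c["delam_t"]),
                         track_id=c["track_id"],
                         payload={"F_at_delam_au": float(
                             c["rate"] * (c["delam_t"] - c["expr_start"])
                         )})
                )
            else:
                c["delam_t"] = np.nan
            continue
        if c["kind"] not in ("resident", "daughter"):
            continue
        if np.isnan(c["expr_start"]) or np.isnan(c["delam_threshold"]):
            continue
        u = c["delam_threshold"]
        if c["F_start"] >= u:
            # daughter born above its level: rapid coordinated delamination
            t_delam = c["birth_t"] + config.rapid_delam_delay_min
            f_at = c["F_start"] + c["rate"] * config.rapid_delam_delay_min
        else:
            t_delam = c["expr_start"] + (u - c["F_start"]) / c["rate"]
            f_at = u
        if t_delam >= c["end_t"]:  # divides first, or window ends first
            continue
        c["delam_t"] = float(t_delam)
        events.append(
            dict(event_type="delamination", t_min=float(t_delam),
                 track_id=c["track_id"], payload={"F_at_delam_au": float(f_at)})
        )

    # ---- emit samples ---------------------------------------------------
    box_lo, box_hi = geometry.bounding_box()
    rows_id, rows_parent, rows_t = [], [], []
    rows_xyz, rows_comp, rows_f = [], [], []

    for c in cells:
        t0, t1 = c["birth_t"], c["end_t"]
        ts = grid[(grid >= t0 - 1e-9) & (grid <= t1 + 1e-9)]
        if not np.isnan(c["delam_t"]) and c["delam_t"] <= t1:
            if not np.any(np.isclose(ts, c["delam_t"])):
                ts = np.sort(np.append(ts, c["delam_t"]))
        n = len(ts)
        if n == 0:
            continue

        pos = np.tile([c["x"], c["y"], c["z"]], (n, 1))
        comp = np.full(n, "epithelial", dtype=object)

        if c["kind"] in ("pioneer", "field"):
            if np.isnan(c["t_ing"]):
                comp[:] = "outside"
            else:
                t_ing = float(c["t_ing"])
                travel = c.get("_travel", 40.0)
                target = c["_target"]
                start = np.array([c["x"], c["y"], c["z"]])
                t_mig = t_ing - travel
                frac = np.clip((ts - t_mig) / travel, 0.0, 1.0)
                pos = start[None, :] + frac[:, None] * (target - start)[None, :]
                comp = np.where(ts < t_ing, "outside", "epithelial").astype(object)

        if not np.isnan(c["delam_t"]):
            after = ts >= c["delam_t"] - 1e-9
            comp[after] = "delaminated"
            # basal drift: the cell body moves out of the epithelium
            base_depth = float(geometry.depth(pos[after][:1])[0]) if after.any() else 0.0
            drift = np.minimum(
                base_depth
                + config.basal_drift_per_min * (ts[after] - c["delam_t"]),
                config.basal_depth_cap,
            )
            if after.any():
                centre = np.asarray(geometry.center_um)
                rel = pos[after] - centre
                rho_now = geometry.rho(pos[after])
                rho_new = geometry.inner_rho + drift * (1.0 - geometry.inner_rho)
                scale = np.where(rho_now > 1e-9, rho_new / rho_now, 1.0)
                pos[after] = centre + rel * scale[:, None]

        inside = comp != "outside"
        pos[inside] = np.clip(pos[inside], box_lo + 1e-6, box_hi - 1e-6)

        f = np.zeros(n)
        if not np.isnan(c["expr_start"]) and not np.isnan(c["rate"]):
            on = ts >= c["expr_start"] - 1e-9
            f[on] = c["F_start"] + c["rate"] * (ts[on] - c["expr_start"])
            f = np.maximum(f, 0.0)

        rows_id.append(np.full(n, c["track_id"]))
        rows_parent.append(np.full(n, c["parent_id"] if c["parent_id"] else -1))
        rows_t.append(ts)
        rows_xyz.append(pos)
        rows_comp.append(comp)
        rows_f.append(f)

    xyz = np.concatenate(rows_xyz)
    tracks = pd.DataFrame(
        {
            "track_id": np.concatenate(rows_id).astype(int),
            "parent_id": np.concatenate(rows_parent).astype(int),
            "t_min": np.concatenate(rows_t),
            "x_um": xyz[:, 0],
            "y_um": xyz[:, 1],
            "z_um": xyz[:, 2],
            "compartment": np.concatenate(rows_comp),
            "F_true_au": np.concatenate(rows_f),
            "labeled": False,
        }
    )
    tracks = tracks.sort_values(["track_id", "t_min"], kind="mergesort").reset_index(
        drop=True
    )

    events_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    events_df = events_df.sort_values(
        ["t_min", "track_id"], kind="mergesort"
    ).reset_index(drop=True)

    drop = ("_target", "_travel", "_delay")
    cells_df = pd.DataFrame(
        [{k: v for k, v in c.items() if k not in drop} for c in cells]
    )

    if config.perturbation == "fgf_block" and len(ing_times):
        raise AssertionError("fgf_block must yield zero ingressions")

    return SimulationResult(
        config=config, geometry=geometry, tracks=tracks, events=events_df,
        cells=cells_df,
    )


def simulate_embryo_pair(
    config_control: ScenarioConfig, config_treated: ScenarioConfig, seed: int
) -> tuple[SimulationResult, SimulationResult]:
    """Two vesicles of one embryo: a control side and a treated side.

    Side seeds are derived from ``seed`` so pairs are reproducible."""
    c0 = dataclasses.replace(config_control, seed=int(seed) * 2 + 1)
    c1 = dataclasses.replace(config_treated, seed=int(seed) * 2 + 2)
    return simulate_embryo(c0), simulate_embryo(c1)


# ---------------------------------------------------------------------------
# the Fig-3-style local-specification experiment
# ---------------------------------------------------------------------------


def simulate_local_specification(
    n_cells: int = 11,
    seed: int = 0,
    config: ScenarioConfig | None = None,
    trigger: str = "level",
    elapsed_range_min: tuple[float, float] = (150.0, 170.0),
) -> SimulationResult:
    """Simulate a cohort of locally specified cells followed individually.

    Emulates dynamic single-cell reporter quantification: each cell turns
    on, accumulates reporter linearly at a per-cell rate drawn from the
    configured range, and delaminates.  ``trigger`` selects the
    ground-truth rule: ``"level"`` delaminates when the reporter crosses a
    per-cell threshold from the configured window (the observed
    behaviour); ``"timer"`` delaminates at a fixed elapsed time after
    onset (the alternative model, used as a contrast).
    """
    if trigger not in ("level", "timer"):
        raise ValueError("trigger must be 'level' or 'timer'")
    cfg = config or make_scenario("wildtype", {"seed": seed})
    rng = np.random.default_rng(seed)
    geometry = VesicleGeometry(
        semi_axes_um=cfg.vesicle_axes_um, lumen_fraction=cfg.lumen_fraction
    )
    signs = _octant_signs(cfg.neurogenic_octant)
    dt = cfg.dt_min
    events: list[dict] = []
    frames = []
    t_end = 480.0
    for i in range(n_cells):
        onset = float(i * 6.0 + rng.uniform(0.0, 4.0))
        rate = rng.uniform(*cfg.ramp_rate_range_au_per_min)
        if trigger == "level":
            u = rng.uniform(*cfg.delamination_threshold_range_au)
            t_delam = onset + u / rate
            f_at = u
        else:
            elapsed = rng.uniform(*elapsed_range_min)
            t_delam = onset + elapsed
            f_at = rate * elapsed
        pos = _sample_octant_position(rng, geometry, signs, cfg.neurogenic_depth_range)
        ts = np.arange(0.0, t_end + dt / 2, dt)
        if not np.any(np.isclose(ts, t_delam)):
            ts = np.sort(np.append(ts, t_delam))
        f = np.maximum(rate * (ts - onset), 0.0)
        comp = np.where(ts >= t_delam - 1e-9, "delaminated", "epithelial")
        depth0 = float(geometry.depth(pos[None, :])[0])
        drift = np.minimum(
            depth0 + cfg.basal_drift_per_min * np.maximum(ts - t_delam, 0.0),
            cfg.basal_depth_cap,
        )
        centre = np.asarray(geometry.center_um)
        rel = pos - centre
        rho0 = float(geometry.rho(pos[None, :])[0])
        rho_new = geometry.inner_rho + drift * (1.0 - geometry.inner_rho)
        positions = centre + rel[None, :] * (rho_new / rho0)[:, None]
        frames.append(
            pd.DataFrame(
                {
                    "track_id": i + 1, "parent_id": -1, "t_min": ts,
                    "x_um": positions[:, 0], "y_um": positions[:, 1],
                    "z_um": positions[:, 2], "compartment": comp,
                    "F_true_au": f, "labeled": False,
                }
            )
        )
        events.append(dict(event_type="onset", t_min=onset, track_id=i + 1,
                           payload={"rate_au_per_min": float(rate)}))
        events.append(dict(event_type="delamination", t_min=float(t_delam),
                           track_id=i + 1,
                           payload={"F_at_delam_au": float(f_at)}))
    tracks = pd.concat(frames, ignore_index=True)
    events_df = pd.DataFrame(events, columns=EVENT_COLUMNS).sort_values(
        ["t_min", "track_id"], kind="mergesort"
    ).reset_index(drop=True)
    return SimulationResult(
        config=cfg, geometry=geometry, tracks=tracks, events=events_df,
        cells=pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# photoconversion
# ---------------------------------------------------------------------------


def photoconvert(
    tracks: pd.DataFrame,
    roi: tuple[Sequence[float], Sequence[float]],
    t_min: float,
) -> tuple[pd.DataFrame, list[int]]:
    """Label exactly the nuclei inside ``roi`` at ``t_min``.

    ``roi`` is an axis-aligned box ``(lo, hi)`` in micrometres.  Labels
    persist for the rest of each track and are inherited by daughters.
    Returns the labelled copy of ``tracks`` and the directly labelled
    track ids.
    """
    lo = np.asarray(roi[0], dtype=float)
    hi = np.asarray(roi[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("ROI must have positive volume")
    pts = tracks[["x_um", "y_um", "z_um"]].to_numpy()
    dom_lo, dom_hi = pts.min(axis=0) - 5.0, pts.max(axis=0) + 5.0
    if np.any(hi < dom_lo) or np.any(lo > dom_hi):
        raise ValueError("ROI lies outside the simulated space")

    snap = tracks_at(tracks, t_min, vesicle_only=False)
    p = snap[["x_um", "y_um", "z_um"]].to_numpy()
    inside = np.all((p >= lo) & (p < hi), axis=1)
    labeled_ids = [int(i) for i in snap.loc[inside, "track_id"]]

    # propagate to descendants born after conversion
    children: dict[int, list[int]] = {}
    for tid, pid in (
        tracks[["track_id", "parent_id"]].drop_duplicates().itertuples(index=False)
    ):
        if pid > 0:
            children.setdefault(int(pid), []).append(int(tid))
    all_labeled = set(labeled_ids)
    stack = list(labeled_ids)
    while stack:
        for kid in children.get(stack.pop(), []):
            if kid not in all_labeled:
                all_labeled.add(kid)
                stack.append(kid)

    out = tracks.copy()
    mask = out["track_id"].isin(all_labeled) & (out["t_min"] >= t_min - 1e-9)
    out.loc[mask, "labeled"] = True
    return out, labeled_ids


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """Multi-channel voxel stack (arrays are z, y, x; values in a.u.)."""

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]  # (z, y, x)
    origin_um: tuple[float, float, float]  # position of voxel (0,0,0) in x,y,z
    t_min: float

    def __post_init__(self):
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel sizes must be positive")

    def world_to_index(self, point_um: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index (z, y, x) of a world-coordinate point."""
        x, y, z = point_um
        ox, oy, oz = self.origin_um
        dz, dy, dx = self.voxel_size_um
        return (
            int(round((z - oz) / dz)),
            int(round((y - oy) / dy)),
            int(round((x - ox) / dx)),
        )


DEFAULT_RENDER = dict(
    nucleus_radius_um=2.5,
    cell_radius_um=4.5,
    membrane_amp=200.0,
    nucleus_amp=400.0,
    reporter_background=20.0,
)


def render_stack(
    tracks: pd.DataFrame,
    geometry: VesicleGeometry,
    t_min: float,
    noise_model: Mapping | None = None,
    voxel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5),
    margin_um: float = 8.0,
    rng: np.random.Generator | None = None,
    render_params: Mapping | None = None,
) -> ImageStack:
    """Render membrane / nuclei / reporter channels at one timepoint.

    Cells are drawn as spherical membrane shells with a nuclear blob; the
    reporter channel holds ``background + F_true`` in the nucleus-adjacent
    cytosol (identity calibration), so with ``noise_model`` ``none`` a
    background-subtracted cytosol reading equals the track's ground
    truth exactly, and under Poisson-Gaussian noise it equals it in
    expectation.
    """
    params = dict(DEFAULT_RENDER)
    params.update(render_params or {})
    noise = dict(noise_model or {"name": "none"})
    snap = tracks_at(tracks, t_min, vesicle_only=False)
    if snap.empty:
        raise ValueError(f"no cells alive at t={t_min}")
    pts = snap[["x_um", "y_um", "z_um"]].to_numpy()
    lo = pts.min(axis=0) - margin_um
    hi = pts.max(axis=0) + margin_um
    dz, dy, dx = voxel_size_um
    nx = int(np.ceil((hi[0] - lo[0]) / dx)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / dy)) + 1
    nz = int(np.ceil((hi[2] - lo[2]) / dz)) + 1
    shape = (nz, ny, nx)
    membrane = np.zeros(shape, dtype=np.float32)
    nuclei = np.zeros(shape, dtype=np.float32)
    reporter = np.zeros(shape, dtype=np.float32)

    r_nuc = params["nucleus_radius_um"]
    r_cell = params["cell_radius_um"]
    zs = lo[2] + np.arange(nz) * dz
    ys = lo[1] + np.arange(ny) * dy
    xs = lo[0] + np.arange(nx) * dx

    for row in snap.itertuples(index=False):
        cx, cy, cz, f = row.x_um, row.y_um, row.z_um, row.F_true_au
        iz = np.flatnonzero(np.abs(zs - cz) <= r_cell + 1.0)
        iy = np.flatnonzero(np.abs(ys - cy) <= r_cell + 1.0)
        ix = np.flatnonzero(np.abs(xs - cx) <= r_cell + 1.0)
        if not (len(iz) and len(iy) and len(ix)):
            continue
        dzv = (zs[iz] - cz)[:, None, None]
        dyv = (ys[iy] - cy)[None, :, None]
        dxv = (xs[ix] - cx)[None, None, :]
        dist = np.sqrt(dzv**2 + dyv**2 + dxv**2)
        sub = np.ix_(iz, iy, ix)
        nuclei[sub] = np.maximum(
            nuclei[sub], params["nucleus_amp"] * (dist <= r_nuc)
        )
        membrane[sub] = np.maximum(
            membrane[sub],
            params["membrane_amp"] * (np.abs(dist - r_cell) <= 0.75),
        )
        cytosol = (dist > r_nuc) & (dist <= r_cell - 0.5)
        reporter[sub] = np.maximum(reporter[sub], np.float32(f) * cytosol)

    reporter = reporter + np.float32(params["reporter_background"])

    if noise["name"] == "poisson_gaussian":
        rng = rng or np.random.default_rng(int(noise.get("seed", 0)))
        gain = float(noise.get("gain", 4.0))
        read_sd = float(noise.get("read_sd", 1.5))

        def _noisy(img: np.ndarray) -> np.ndarray:
            shot = rng.poisson(np.maximum(img, 0.0) * gain) / gain
            return (shot + rng.normal(0.0, read_sd, img.shape)).astype(np.float32)

        membrane, nuclei, reporter = _noisy(membrane), _noisy(nuclei), _noisy(reporter)
    elif noise["name"] != "none":
        raise ValueError(f"unknown noise model {noise['name']!r}")

    return ImageStack(
        channels={"membrane": membrane, "nuclei": nuclei, "reporter": reporter},
        voxel_size_um=voxel_size_um,
        origin_um=(float(lo[0]), float(lo[1]), float(lo[2])),
        t_min=float(t_min),
    )
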