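"""Group comparisons and figure-style reports.

The t statistics are computed from first principles (formulas below);
only the Student-t distribution function comes from scipy.  Two-sided
p values throughout; no multiple-testing correction by default, with an
optional Holm adjustment.

one-sample:  t = (x̄ - mu0) / (s / sqrt(n)),            df = n - 1
unpaired:    t = (x̄_a - x̄_b) / (s_p sqrt(1/n_a + 1/n_b)),
             s_p^2 = ((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a + n_b - 2)
paired:      one-sample t on the per-pair differences against 0
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("otoquant")

TEST_KINDS = ("one_sample_t", "unpaired_t", "paired_t")

#: the four per-vesicle specification metrics compared between sides
ABLATION_METRICS = ("global_au", "n_pos", "mean_fcell_au", "n_hi")


@dataclass
class ComparisonResult:
    statistic: str
    group_labels: tuple[str, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    n: tuple[int, ...]
    t_value: float
    p_value: float
    df: float
    reference: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "group_labels": list(self.group_labels),
            "means": list(self.means),
            "sems": list(self.sems),
            "n": list(self.n),
            "t_value": self.t_value,
            "p_value": self.p_value,
            "df": self.df,
            "reference": self.reference,
            "degenerate": self.degenerate,
        }


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    m = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
    return m, sem


def compare_groups(
    values_a,
    values_b=None,
    kind: str = "unpaired_t",
    reference: float | None = None,
    labels: tuple[str, ...] = ("a", "b"),
) -> ComparisonResult:
    """One-sample, unpaired or paired t comparison.

    ``reference`` is required for (and only for) the one-sample test.
    A zero-variance one-sample group equal to the reference returns
    t = 0 with p = 1 and the ``degenerate`` flag set.
    """
    if kind not in TEST_KINDS:
        raise ValueError(f"kind must be one of {TEST_KINDS}")
    a = np.asarray(values_a, dtype=float)

    if kind == "one_sample_t":
        if reference is None:
            raise ValueError("one-sample test needs a reference value")
        if a.size < 2:
            raise ValueError("need n >= 2")
        m, sem = _mean_sem(a)
        sd = a.std(ddof=1)
        if sd == 0:
            if m == reference:
                return ComparisonResult(
                    kind, labels[:1], (m,), (0.0,), (a.size,),
                    0.0, 1.0, a.size - 1, reference, degenerate=True,
                )
            raise ValueError("zero variance in one-sample test")
        t = (m - reference) / (sd / math.sqrt(a.size))
        df = a.size - 1
        p = 2.0 * sps.t.sf(abs(t), df)
        return ComparisonResult(
            kind, labels[:1], (m,), (sem,), (a.size,), float(t), float(p),
            float(df), reference,
        )

    if reference is not None:
        raise ValueError("reference is only valid for the one-sample test")
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")

    if kind == "paired_t":
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        d = a - b
        ma, sa = _mean_sem(a)
        mb, sb = _mean_sem(b)
        sd = d.std(ddof=1)
        if sd == 0:
            return ComparisonResult(
                kind, labels, (ma, mb), (sa, sb), (a.size, b.size),
                0.0, 1.0, a.size - 1, degenerate=True,
            )
        t = d.mean() / (sd / math.sqrt(d.size))
        df = d.size - 1
        p = 2.0 * sps.t.sf(abs(t), df)
        return ComparisonResult(
            kind, labels, (ma, mb), (sa, sb), (a.size, b.size),
            float(t), float(p), float(df),
        )

    # unpaired Student t with pooled variance
    ma, sema = _mean_sem(a)
    mb, semb = _mean_sem(b)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return ComparisonResult(
            kind, labels, (ma, mb), (sema, semb), (na, nb),
            0.0, 1.0, na + nb - 2, degenerate=True,
        )
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(
        kind, labels, (ma, mb), (sema, semb), (na, nb), float(t), float(p),
        float(df),
    )


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (optional; off by default elsewhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def ablation_report(
    summaries_treated: pd.DataFrame,
    summaries_control: pd.DataFrame,
    metrics: tuple[str, ...] = ABLATION_METRICS,
    holm: bool = False,
) -> dict:
    """Side-by-side specification report for paired vesicles.

    Expects one row per embryo (matched ``embryo_id`` on both sides) with
    the four per-vesicle metrics.  Reports per-metric means ± sem per
    side, paired and unpaired comparisons (the pairing convention is
    reported rather than assumed), and per-embryo deltas
    (treated - control).
    """
    t = summaries_treated.set_index("embryo_id").sort_index()
    c = summaries_control.set_index("embryo_id").sort_index()
    if list(t.index) != list(c.index):
        raise ValueError("embryo ids on the two sides do not match")
    report: dict = {"n_embryos": int(len(t)), "metrics": {}}
    pvals = []
    for m in metrics:
        a = t[m].to_numpy(dtype=float)
        b = c[m].to_numpy(dtype=float)
        paired = compare_groups(a, b, kind="paired_t", labels=("treated", "control"))
        unpaired = compare_groups(a, b, kind="unpaired_t", labels=("treated", "control"))
        deltas = (a - b).tolist()
        report["metrics"][m] = {
            "treated_mean": paired.means[0],
            "treated_sem": paired.sems[0],
            "control_mean": paired.means[1],
            "control_sem": paired.sems[1],
            "paired": paired.to_dict(),
            "unpaired": unpaired.to_dict(),
            "deltas": deltas,
        }
        pvals.append(paired.p_value)
    if holm:
        adj = holm_adjust(np.array(pvals))
        for m, q in zip(metrics, adj):
            report["metrics"][m]["paired_p_holm"] = float(q)
    return report


# ---------------------------------------------------------------------------
# figure panels (optional; return matplotlib figures)
# ---------------------------------------------------------------------------


def plot_group_bars(groups: dict[str, np.ndarray], ylabel: str = ""):
    """Bar ± sem panel for a few groups of per-vesicle values."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    names = list(groups)
    means = [np.mean(groups[k]) for k in names]
    sems = [
        np.std(groups[k], ddof=1) / math.sqrt(len(groups[k])) if len(groups[k]) > 1 else 0
        for k in names
    ]
    ax.bar(names, means, yerr=sems, capsize=3, color="#b22222", alpha=0.8)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return fig


def plot_cell_dots(groups: dict[str, np.ndarray], ylabel: str = "F_cell (a.u.)"):
    """Per-cell dot plot with group means, one column per condition."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    rng = np.random.default_rng(0)
    for i, (name, vals) in enumerate(groups.items()):
        x = i + rng.uniform(-0.15, 0.15, size=len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.6)
        ax.hlines(np.mean(vals), i - 0.25, i + 0.25, color="green")
    ax.set_xticks(range(len(groups)), list(groups))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return fig


def plot_normalized_box(records: pd.DataFrame):
    """Box plot of group-normalised elapsed time vs reporter level at
    delamination."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.boxplot(
        [records["normalized_elapsed"], records["normalized_F"]],
        tick_labels=["elapsed time", "F at delamination"],
    )
    ax.set_ylabel("value / group mean")
    fig.tight_layout()
    return fig


def plot_projected_tracks(tracks, plane: str = "xy", ax=None):
    """2D projection of 3D cell trajectories with a temporal colour key.

    ``plane`` picks the two projected axes ("xy", "xz" or "yz"); each
    track is drawn as a poly-line coloured from early (dark) to late
    (bright) timepoints."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    cols = {"x": "x_um", "y": "y_um", "z": "z_um"}
    try:
        cx, cy = (cols[c] for c in plane)
    except KeyError:
        raise ValueError(f"plane must combine two of x, y, z, got {plane!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    t0, t1 = tracks["t_min"].min(), tracks["t_min"].max()
    norm = plt.Normalize(t0, t1)
    for _, tr in tracks.groupby("track_id"):
        pts = tr[[cx, cy]].to_numpy().reshape(-1, 1, 2)
        if len(pts) < 2:
            continue
        segs = np.concatenate([pts[:-1], pts[1:]], axis=1)
        lc = LineCollection(segs, cmap="viridis", norm=norm)
        lc.set_array(tr["t_min"].to_numpy()[:-1])
        lc.set_linewidth(1.0)
        ax.add_collection(lc)
    ax.autoscale()
    ax.set_xlabel(f"{plane[0]} (um)")
    ax.set_ylabel(f"{plane[1]} (um)")
    ax.figure.colorbar(
        plt.cm.ScalarMappable(norm=norm, cmap="viridis"), ax=ax,
        label="time (min)",
    )
    return ax.figure
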