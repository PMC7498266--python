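"""Directed-migration quantification.

Displacement angles of neighboring cells relative to an inducible-cell
group: 0° is motion directly toward the group center, 180° directly away;
angles are folded to [0, 180] because the toward/away statistic is
symmetric about the center axis. Significance between angle distributions
uses the study's subsampling procedure: many iterations of a two-sample
Kolmogorov-Smirnov test on random sub-samples, summarized by the median
p-value — which keeps enormous pooled angle samples from producing
vanishing p-values for trivial differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mapkdyn.errors import MapkdynError, ParameterError

__all__ = [
    "AngleSample",
    "SubsamplingKSResult",
    "find_inducible_center",
    "select_neighbors_in_window",
    "interval_displacements",
    "migration_angle",
    "collect_angle_sample",
    "radial_histogram",
    "subsampled_ks_test",
    "significance_stars",
]


@dataclass
class AngleSample:
    """Per-cell, per-interval migration angles for one condition/epoch."""

    condition: str
    epoch: str  # e.g. "before" / "after"
    angles_deg: np.ndarray
    n_cells: int = 0

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.size and (
            self.angles_deg.min() < 0 or self.angles_deg.max() > 180
        ):
            raise ParameterError("angles must lie in [0, 180] degrees")

    @property
    def n_observations(self) -> int:
        return int(self.angles_deg.size)


@dataclass
class SubsamplingKSResult:
    """Median-p summary of the subsampled two-sample KS procedure."""

    median_p: float
    n_iterations: int
    subsample_size: int
    d_statistics: np.ndarray = field(repr=False, default=None)
    p_values: np.ndarray = field(repr=False, default=None)

    @property
    def stars(self) -> str:
        return significance_stars(self.median_p)


def significance_stars(p: float) -> str:
    """Figure-legend star convention: ns, *p<0.05, **p<0.01, ***p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def find_inducible_center(tracks: pd.DataFrame, frame: int) -> np.ndarray:
    """Centroid of inducible-cell positions at a reference frame."""
    sel = tracks[(tracks["population"] == "inducible") & (tracks["frame"] == frame)]
    if sel.empty:
        raise MapkdynError(f"no inducible cells at frame {frame}")
    return np.array([sel["x_um"].mean(), sel["y_um"].mean()])


def select_neighbors_in_window(
    tracks: pd.DataFrame,
    center_xy,
    frame: int,
    half_width_um: float = 100.0,
) -> list:
    """Neighboring cells inside the square window around the group center.

    A cell qualifies if its position at ``frame`` lies within
    [center ± half_width] on both axes (default 200 µm x 200 µm window);
    inducible cells are always excluded.
    """
    cx, cy = center_xy
    sel = tracks[(tracks["frame"] == frame) & (tracks["population"] != "inducible")]
    inside = sel[
        (sel["x_um"].sub(cx).abs() <= half_width_um)
        & (sel["y_um"].sub(cy).abs() <= half_width_um)
    ]
    return sorted(inside["cell_id"].unique())


def interval_displacements(
    track: pd.DataFrame,
    interval_min: float = 20.0,
    epoch: tuple[float, float] | None = None,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Non-overlapping displacement vectors over fixed time intervals.

    Returns (t_start, start_position, displacement) triples. The frame
    interval must divide ``interval_min``; an interval whose endpoint frame
    is missing from the track is skipped.
    """
    df = track.sort_values("frame")
    t = df["time_min"].to_numpy(float)
    pos = df[["x_um", "y_um"]].to_numpy(float)
    if len(t) < 2:
        return []
    dt = np.diff(t).min()
    step = interval_min / dt
    if abs(step - round(step)) > 1e-9:
        raise ParameterError("frame interval must divide interval_min")
    by_time = {round(ti, 6): i for i, ti in enumerate(t)}
    t0, t1 = (t[0], t[-1]) if epoch is None else epoch
    out = []
    start = max(t0, t[0])
    while start + interval_min <= t1 + 1e-9:
        i = by_time.get(round(start, 6))
        j = by_time.get(round(start + interval_min, 6))
        if i is not None and j is not None:
            out.append((float(start), pos[i].copy(), pos[j] - pos[i]))
        start += interval_min
    return out


def migration_angle(position_xy, displacement_xy, center_xy) -> float:
    """Angle in [0, 180] between a displacement and the direction to center.

    0° = directly toward the center, 180° = directly away. Raises on zero
    displacement (the angle is undefined; callers drop and log those).
    """
    d = np.asarray(displacement_xy, float)
    norm_d = np.hypot(*d)
    if norm_d == 0:
        raise MapkdynError("zero displacement: angle undefined")
    u = np.asarray(center_xy, float) - np.asarray(position_xy, float)
    norm_u = np.hypot(*u)
    if norm_u == 0:
        raise MapkdynError("cell sits on the center: direction undefined")
    cosang = np.clip(np.dot(d, u) / (norm_d * norm_u), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def collect_angle_sample(
    tracks: pd.DataFrame,
    epoch: tuple[float, float],
    condition: str = "",
    epoch_label: str = "",
    interval_min: float = 20.0,
    half_width_um: float = 100.0,
    center_frame: int | None = None,
) -> AngleSample:
    """End-to-end angle collection for one condition and epoch.

    Finds the inducible-group center at the epoch-start frame, selects
    neighbors in the 2x half_width window at that frame, computes
    non-overlapping interval displacements within the epoch and converts
    each to a toward/away angle. Zero displacements are dropped.
    """
    dt = float(np.diff(np.sort(tracks["time_min"].unique())).min())
    if center_frame is None:
        center_frame = int(round(epoch[0] / dt))
    center = find_inducible_center(tracks, center_frame)
    neighbor_ids = select_neighbors_in_window(tracks, center, center_frame, half_width_um)
    angles = []
    for cid in neighbor_ids:
        track = tracks[tracks["cell_id"] == cid]
        for _, p0, disp in interval_displacements(track, interval_min, epoch):
            if np.hypot(*disp) == 0:
                continue
            angles.append(migration_angle(p0, disp, center))
    return AngleSample(condition, epoch_label, np.asarray(angles), n_cells=len(neighbor_ids))


def radial_histogram(sample: AngleSample, n_bins: int = 12):
    """Equal-width angle histogram over [0°, 180°].

    Bins are right-open except the last (180° lands in the final bin);
    counts always sum to the number of observations.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    counts, edges = np.histogram(sample.angles_deg, bins=n_bins, range=(0.0, 180.0))
    return edges, counts


def subsampled_ks_test(
    a: AngleSample,
    b: AngleSample,
    n_iter: int = 1000,
    n_sub: int = 1000,
    seed: int = 0,
) -> SubsamplingKSResult:
    """Median-p subsampled two-sample Kolmogorov-Smirnov test.

    Each iteration draws min(n_sub, sample size) angles without replacement
    independently from each sample and runs a two-sample KS test; the
    summary is the median p over iterations. Iteration RNGs are derived
    from ``seed`` so the median p is reproducible. With n_iter = 1 and
    n_sub at least both sample sizes this reduces to the classical test.
    """
    if a.n_observations == 0 or b.n_observations == 0:
        raise MapkdynError("empty angle sample")
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    xa, xb = a.angles_deg, b.angles_deg
    ka = min(n_sub, xa.size)
    kb = min(n_sub, xb.size)
    ds = np.empty(n_iter)
    ps = np.empty(n_iter)
    for it in range(n_iter):
        sa = xa if ka == xa.size else rng.choice(xa, size=ka, replace=False)
        sb = xb if kb == xb.size else rng.choice(xb, size=kb, replace=False)
        res = stats.ks_2samp(sa, sb)
        ds[it] = res.statistic
        ps[it] = res.pvalue
    return SubsamplingKSResult(
        median_p=float(np.median(ps)),
        n_iterations=n_iter,
        subsample_size=min(ka, kb),
        d_statistics=ds,
        p_values=ps,
    )
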