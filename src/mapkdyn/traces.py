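"""Single-cell ERK activity traces: construction, cleaning, peak calling,
dynamics classification and per-cell fold-change metrics.

The activity proxy is the cytoplasm/nucleus intensity ratio of a kinase
translocation reporter (KTR): active ERK exports the reporter from the
nucleus, so higher ratio = higher activity. The localization channel is the
tagged kinase itself, read as a nucleus/cytoplasm ratio (sustained activity
drives nuclear accumulation).

Peak calling follows a findPeaks-style scheme: candidate local extrema on a
lightly smoothed trace are refined by least-squares Gaussian fits in a small
window (sub-frame extremum time and value), and a candidate maximum is
called a peak only if the rise from the preceding fitted minimum, the rate
of change over that rise, and a subsequent fall all clear configurable
thresholds. A plateau without the required fall is not a peak, which is what
separates pulsatile from sustained traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mapkdyn.errors import EmptyTraceError, ParameterError

__all__ = [
    "ActivityTrace",
    "LocalizationTrace",
    "PeakSet",
    "PeakConfig",
    "DynamicsCall",
    "DynamicsThresholds",
    "compute_activity_trace",
    "compute_localization_trace",
    "clean_traces",
    "count_peaks",
    "scan_peaks_reference",
    "classify_dynamics",
    "localization_fold_change",
    "migration_fold_change",
    "summarize_population",
]


@dataclass
class ActivityTrace:
    """One cell's time-resolved KTR cytoplasm/nucleus activity ratio."""

    cell_id: str
    time_min: np.ndarray
    ratio: np.ndarray
    coverage: float = 1.0
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time_min.shape != self.ratio.shape:
            raise ParameterError("time_min and ratio must have equal length")
        if self.time_min.size and np.any(np.diff(self.time_min) <= 0):
            raise ParameterError("time_min must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.time_min.size)


@dataclass
class LocalizationTrace:
    """One cell's nucleus/cytoplasm ratio of the tagged kinase channel."""

    cell_id: str
    time_min: np.ndarray
    nc_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.nc_ratio = np.asarray(self.nc_ratio, dtype=float)


@dataclass
class PeakSet:
    """Called activity peaks for one cell."""

    cell_id: str
    peak_times_min: list
    peak_amplitudes: list

    @property
    def count(self) -> int:
        return len(self.peak_times_min)


@dataclass(frozen=True)
class PeakConfig:
    """Peak-caller thresholds.

    min_amplitude is the minimum rise (ratio units) from the preceding
    fitted minimum; min_slope the minimum rate of change (ratio units per
    minute) over that rise; fall_fraction the fraction of the rise that must
    be lost again before the trace ends for the maximum to count as a peak.
    """

    smooth_window: int = 3
    fit_halfwidth: int = 2
    min_amplitude: float = 0.2
    min_slope: float = 0.001
    fall_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ParameterError("smooth_window must be odd and >= 1")
        if self.fit_halfwidth < 1:
            raise ParameterError("fit_halfwidth must be >= 1")


@dataclass(frozen=True)
class DynamicsThresholds:
    """Feature thresholds for the pulsatile/sustained/quiescent call.

    duty_cycle is the fraction of frames with ratio above an adaptive
    activity level (low-percentile baseline estimate + activity_delta).
    """

    duty_min: float = 0.8
    min_peaks: int = 2
    activity_delta: float = 0.2
    baseline_percentile: float = 10.0


@dataclass
class DynamicsCall:
    cell_id: str
    label: str  # pulsatile | sustained | quiescent
    features: dict


# ---------------------------------------------------------------------------
# trace construction and cleaning

def compute_activity_trace(
    cell_rows: pd.DataFrame,
    n_frames_total: int | None = None,
    jump_threshold_um: float = 20.0,
) -> ActivityTrace:
    """Build one cell's activity trace from its tracking-table rows.

    ratio[t] = cyt_ktr / nuc_ktr. Frames with nonpositive intensities are
    excluded from the ratio and flag the trace ``segmentation_error``; a
    frame-to-frame jump larger than ``jump_threshold_um`` flags
    ``track_switch`` (the track likely hopped to another object).
    """
    df = cell_rows.sort_values("frame")
    cell_id = str(df["cell_id"].iloc[0])
    nuc = df["nuc_ktr"].to_numpy(float)
    cyt = df["cyt_ktr"].to_numpy(float)
    ok = (nuc > 0) & (cyt > 0)
    flags: set = set()
    if not ok.all():
        flags.add("segmentation_error")
    if not ok.any():
        raise EmptyTraceError(f"cell {cell_id}: all frames invalid")
    if {"x_um", "y_um"}.issubset(df.columns) and len(df) > 1:
        steps = np.hypot(np.diff(df["x_um"].to_numpy(float)),
                         np.diff(df["y_um"].to_numpy(float)))
        if np.any(steps > jump_threshold_um):
            flags.add("track_switch")
    if n_frames_total is None:
        n_frames_total = int(df["frame"].max()) + 1
    coverage = float(ok.sum()) / float(n_frames_total)
    t = df["time_min"].to_numpy(float)[ok]
    return ActivityTrace(cell_id, t, cyt[ok] / nuc[ok], coverage, flags)


def compute_localization_trace(cell_rows: pd.DataFrame) -> LocalizationTrace:
    """Nucleus/cytoplasm ratio of the kinase localization channel."""
    df = cell_rows.sort_values("frame")
    nuc = df["nuc_loc"].to_numpy(float)
    cyt = df["cyt_loc"].to_numpy(float)
    ok = (nuc > 0) & (cyt > 0)
    return LocalizationTrace(
        str(df["cell_id"].iloc[0]),
        df["time_min"].to_numpy(float)[ok],
        nuc[ok] / cyt[ok],
    )


#: exclusion reasons, in precedence order
_REASONS = (("track_switch", "switch"), ("segmentation_error", "segmentation"))


def clean_traces(
    traces, min_coverage: float = 2.0 / 3.0
):
    """Apply the minimal trace-cleaning rules.

    Excludes traces whose track switched between objects, whose ratios were
    affected by segmentation errors, or that cover less than ``min_coverage``
    of the time course (default two thirds; relax for fast-moving
    conditions). Returns (retained, exclusions) where exclusions is a list of
    (cell_id, reason) with reason in {"switch", "segmentation", "short"}.
    Idempotent: cleaning a cleaned set changes nothing.
    """
    retained, exclusions = [], []
    for tr in traces:
        reason = None
        for flag, name in _REASONS:
            if flag in tr.flags:
                reason = name
                break
        if reason is None and tr.coverage < min_coverage:
            reason = "short"
        if reason is None:
            retained.append(tr)
        else:
            exclusions.append((tr.cell_id, reason))
    return retained, exclusions


# ---------------------------------------------------------------------------
# peak calling

def _moving_mean(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with edge windows shrunk to the available span."""
    if window <= 1 or y.size < 2:
        return y.astype(float, copy=True)
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(y, dtype=float)))
    n = y.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _plateau_extrema(y: np.ndarray):
    """Plateau-aware interior local extrema.

    Returns [(index, kind)] with kind in {"max", "min"}; a plateau run is
    represented by its first (earliest) frame. Endpoint runs are never
    extrema. Consecutive extrema alternate by construction.
    """
    n = y.size
    runs = []
    s = 0
    for j in range(1, n + 1):
        if j == n or y[j] != y[s]:
            runs.append(s)
            s = j
    ext = []
    for k in range(1, len(runs) - 1):
        v = y[runs[k]]
        prev_v = y[runs[k - 1]]
        next_v = y[runs[k + 1]]
        if v > prev_v and v > next_v:
            ext.append((runs[k], "max"))
        elif v < prev_v and v < next_v:
            ext.append((runs[k], "min"))
    return ext


def _gauss(t, amp, mu, sigma, off):
    return off + amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _refine_extremum(t, y, idx, kind, halfwidth):
    """Sub-frame extremum (time, value) via a local Gaussian fit.

    Fits amplitude*exp(-(t-mu)^2/(2 sigma^2)) + offset (inverted for
    minima) over +-halfwidth frames. The fit is constrained to stay
    identifiable from the few points available: sigma is bounded below by
    half the local frame spacing and the refined extremum value is clamped
    to the window's data range (a Gaussian narrower than the sampling
    interval, or an extremum outside the observed values, cannot be
    supported by the window). Degenerate or failed fits fall back to the
    raw frame value.
    """
    lo = max(idx - halfwidth, 0)
    hi = min(idx + halfwidth + 1, y.size)
    tw, yw = t[lo:hi], y[lo:hi]
    if tw.size < 4 or np.ptp(yw) == 0:
        return float(t[idx]), float(y[idx])
    span = tw[-1] - tw[0]
    dt = span / (tw.size - 1)
    sign = 1.0 if kind == "max" else -1.0
    # constrained least squares on a (mu, sigma) grid with closed-form
    # amplitude/offset: the extremum must lie within one frame of the
    # candidate, the bump must open the right way, and sigma may not shrink
    # below one frame interval (a narrower Gaussian just interpolates a
    # single noisy sample instead of averaging the window)
    mu_grid = np.clip(t[idx] + np.linspace(-dt, dt, 9), tw[0], tw[-1])
    sigma_grid = dt * np.array([1.0, 1.5, 2.0, 3.0])
    g = np.exp(-0.5 * ((tw[None, None, :] - mu_grid[:, None, None])
                       / sigma_grid[None, :, None]) ** 2)
    n = tw.size
    sg = g.sum(axis=2)
    sgg = (g * g).sum(axis=2)
    sy = yw.sum()
    sgy = (g * yw).sum(axis=2)
    det = n * sgg - sg * sg
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = (n * sgy - sg * sy) / det
        off = (sy - amp * sg) / n
    rss = ((yw[None, None, :] - amp[..., None] * g - off[..., None]) ** 2).sum(axis=2)
    rss = np.where((sign * amp > 0) & np.isfinite(rss), rss, np.inf)
    if not np.isfinite(rss).any():
        return float(t[idx]), float(y[idx])
    i_mu, i_sg = np.unravel_index(np.argmin(rss), rss.shape)
    value = float(np.clip(amp[i_mu, i_sg] + off[i_mu, i_sg], yw.min(), yw.max()))
    return float(mu_grid[i_mu]), value


def count_peaks(trace: ActivityTrace, config: PeakConfig = PeakConfig()) -> PeakSet:
    """Call activity peaks on one cleaned trace.

    Pipeline: (i) centered moving-mean smoothing; (ii) plateau-aware local
    maxima/minima; (iii) Gaussian refinement of each extremum; (iv) a
    maximum is a peak iff rise from the preceding refined minimum >=
    min_amplitude, rise rate >= min_slope, and a subsequent fall of at least
    fall_fraction * rise occurs before the trace end.
    """
    t, y = trace.time_min, trace.ratio
    if t.size < 5:
        raise ParameterError("trace shorter than the fit window")
    ys = _moving_mean(y, config.smooth_window)
    ext = _plateau_extrema(ys)
    maxima = [e for e in ext if e[1] == "max"]
    if not maxima:
        return PeakSet(trace.cell_id, [], [])

    # bracket each maximum with refined minima (sentinels at trace ends)
    refined = {}

    def _ref(idx, kind):
        # candidates come from the smoothed trace; amplitudes are measured
        # on fits to the raw values so smoothing cannot bias rise/fall sizes
        key = (idx, kind)
        if key not in refined:
            refined[key] = _refine_extremum(t, y, idx, kind, config.fit_halfwidth)
        return refined[key]

    seq = [(0, "min")] + ext + [(y.size - 1, "min")]
    times, amps = [], []
    for i, (idx, kind) in enumerate(seq):
        if kind != "max":
            continue
        prev_idx = next(seq[j][0] for j in range(i - 1, -1, -1) if seq[j][1] == "min")
        next_idx = next(seq[j][0] for j in range(i + 1, len(seq)) if seq[j][1] == "min")
        t_max, v_max = _ref(idx, "max")
        t_min, v_min = _ref(prev_idx, "min") if prev_idx > 0 else (t[0], float(y[0]))
        _, v_next = _ref(next_idx, "min") if next_idx < y.size - 1 else (t[-1], float(y[-1]))
        rise = v_max - v_min
        dt = t_max - t_min
        slope = rise / dt if dt > 0 else np.inf
        fall = v_max - v_next
        if rise >= config.min_amplitude and slope >= config.min_slope \
                and fall >= config.fall_fraction * rise:
            times.append(t_max)
            amps.append(rise)
    return PeakSet(trace.cell_id, times, amps)


def scan_peaks_reference(
    time_min: np.ndarray,
    ratio: np.ndarray,
    min_amplitude: float = 0.15,
    fall_fraction: float = 0.5,
    min_slope: float = 0.0,
):
    """Brute-force peak scan used as an independent validation oracle.

    No smoothing, no fitting: candidate maxima are strict plateau-aware
    local maxima of the raw trace; for each candidate the rise is measured
    from the raw minimum since the previous candidate (or trace start) and
    the fall toward the raw minimum before the next candidate (or trace
    end). Intended for noiseless traces.
    """
    t = np.asarray(time_min, float)
    y = np.asarray(ratio, float)
    n = y.size
    cands = []
    for i in range(n):
        j = i - 1
        while j >= 0 and y[j] == y[i]:
            j -= 1
        k = i + 1
        while k < n and y[k] == y[i]:
            k += 1
        if j >= 0 and k < n and y[j] < y[i] and y[k] < y[i] and (j == i - 1):
            cands.append(i)
    times = []
    for c, i in enumerate(cands):
        left = cands[c - 1] if c > 0 else 0
        right = cands[c + 1] if c + 1 < len(cands) else n - 1
        seg_prev = y[left:i + 1]
        j_min = left + int(np.argmin(seg_prev))
        rise = y[i] - y[j_min]
        fall = y[i] - np.min(y[i:right + 1])
        dt = t[i] - t[j_min]
        slope = rise / dt if dt > 0 else np.inf
        if rise >= min_amplitude and fall >= fall_fraction * rise and slope >= min_slope:
            times.append(float(t[i]))
    return times


# ---------------------------------------------------------------------------
# classification and fold changes

def classify_dynamics(
    peaks: PeakSet,
    trace: ActivityTrace,
    thresholds: DynamicsThresholds = DynamicsThresholds(),
) -> DynamicsCall:
    """Label a trace pulsatile, sustained or quiescent.

    sustained iff duty_cycle >= duty_min; else pulsatile iff peak count >=
    min_peaks; else quiescent. A pure, total function of the features.
    """
    y = trace.ratio
    base = np.percentile(y, thresholds.baseline_percentile)
    duty = float(np.mean(y > base + thresholds.activity_delta))
    final_mask = trace.time_min >= trace.time_min[-1] - 60.0
    features = {
        "peak_count": peaks.count,
        "duty_cycle": duty,
        "final_window_mean": float(np.mean(y[final_mask])),
    }
    if duty >= thresholds.duty_min:
        label = "sustained"
    elif peaks.count >= thresholds.min_peaks:
        label = "pulsatile"
    else:
        label = "quiescent"
    return DynamicsCall(trace.cell_id, label, features)


def _window_mean(t, v, start, end):
    m = (t >= start) & (t <= end)
    if not m.any():
        raise ParameterError("empty window")
    return float(np.mean(v[m]))


def localization_fold_change(
    loc: LocalizationTrace,
    basal_window_min: float = 60.0,
    final_window_min: float = 60.0,
) -> float:
    """Final N/C ratio over basal N/C ratio for one cell.

    Basal window = first ``basal_window_min`` minutes of the trace; final
    window = last ``final_window_min`` minutes.
    """
    t = loc.time_min
    basal = _window_mean(t, loc.nc_ratio, t[0], t[0] + basal_window_min)
    final = _window_mean(t, loc.nc_ratio, t[-1] - final_window_min, t[-1])
    if basal <= 0:
        raise ParameterError("nonpositive basal N/C mean")
    return final / basal


def migration_fold_change(
    track: pd.DataFrame,
    basal_window_min: float = 60.0,
    final_window_min: float = 60.0,
) -> float:
    """Final over basal distance traveled for one cell.

    Distance is the summed frame-to-frame step length within each window.
    Returns NaN (undefined) when the basal path length is zero.
    """
    df = track.sort_values("frame")
    t = df["time_min"].to_numpy(float)
    x = df["x_um"].to_numpy(float)
    y = df["y_um"].to_numpy(float)

    def _path(start, end):
        m = (t >= start) & (t <= end)
        if m.sum() < 2:
            return 0.0
        return float(np.sum(np.hypot(np.diff(x[m]), np.diff(y[m]))))

    basal = _path(t[0], t[0] + basal_window_min)
    final = _path(t[-1] - final_window_min, t[-1])
    if basal == 0.0:
        return float("nan")
    return final / basal


def summarize_population(traces) -> pd.DataFrame:
    """Per-frame population mean and 25th/75th percentile band.

    Traces are aligned on their time stamps; cells absent at a frame are
    omitted from that frame's statistics.
    """
    frames = {}
    for tr in traces:
        for ti, ri in zip(tr.time_min, tr.ratio):
            frames.setdefault(float(ti), []).append(float(ri))
    rows = []
    for ti in sorted(frames):
        vals = np.asarray(frames[ti])
        rows.append({
            "time_min": ti,
            "mean": float(vals.mean()),
            "p25": float(np.percentile(vals, 25)),
            "p75": float(np.percentile(vals, 75)),
            "n": int(vals.size),
        })
    return pd.DataFrame(rows)
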