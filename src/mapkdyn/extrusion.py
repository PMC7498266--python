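"""Apical-extrusion quantification from two-channel confocal z-stacks.

For each imaging position the per-channel total pixel intensity versus z
height is fit to a Gaussian; the extrusion statistic ΔZ is the difference
between the fitted means of the inducible-cell channel and the all-cell
channel (positive = inducible nuclei sit apical to the monolayer).
Condition values are baseline-corrected by subtracting the mean ΔZ of a
reference (parental) condition and compared by Welch's two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from mapkdyn.errors import FitError, MapkdynError, ParameterError
from mapkdyn.migration import significance_stars

__all__ = [
    "ZIntensityProfile",
    "GaussianFit",
    "ExtrusionResult",
    "z_intensity_histogram",
    "fit_gaussian",
    "delta_z",
    "normalize_condition",
    "flag_outliers",
    "compare_conditions",
]


@dataclass
class ZIntensityProfile:
    """Background-corrected total intensity per z plane for one channel."""

    position_id: str
    channel: str  # "inducible" | "all"
    z_um: np.ndarray
    total_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.total_intensity = np.asarray(self.total_intensity, dtype=float)
        if self.z_um.size < 5:
            raise ParameterError("profile needs at least 5 z planes")
        steps = np.diff(self.z_um)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ParameterError("z grid must be ascending with constant step")


@dataclass
class GaussianFit:
    mean_um: float
    sigma_um: float
    amplitude: float
    offset: float
    rss: float
    converged: bool


@dataclass
class ExtrusionResult:
    position_id: str
    delta_z_um: float
    normalized_delta_z_um: float = float("nan")
    outlier: bool = False


def z_intensity_histogram(
    stack: np.ndarray,
    channel: int,
    z_step_um: float = 1.0,
    z_min_um: float = 0.0,
    position_id: str = "pos0",
    channel_label: str | None = None,
) -> ZIntensityProfile:
    """Per-plane summed intensity for one channel of a (C, Z, Y, X) stack.

    A per-stack background (median of the lowest-decile pixels of the
    channel) is subtracted from every pixel and negative values clipped at
    zero before summing each plane.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 4:
        raise MapkdynError("stack must be indexed [channel][z][y][x]")
    chan = arr[channel]
    flat = chan.ravel()
    decile = np.quantile(flat, 0.1)
    low = flat[flat <= decile]
    background = float(np.median(low)) if low.size else 0.0
    corrected = np.clip(chan - background, 0.0, None)
    totals = corrected.sum(axis=(1, 2))
    z = z_min_um + z_step_um * np.arange(chan.shape[0])
    if channel_label is None:
        channel_label = "inducible" if channel == 0 else "all"
    return ZIntensityProfile(position_id, channel_label, z, totals)


def _gauss(z, amp, mu, sigma, off):
    return off + amp * np.exp(-0.5 * ((z - mu) / sigma) ** 2)


def moment_estimates(profile: ZIntensityProfile) -> tuple[float, float]:
    """Intensity-weighted z centroid and weighted sd (fit initialization
    and non-convergence fallback)."""
    w = np.clip(profile.total_intensity, 0.0, None)
    total = w.sum()
    if total <= 0:
        z = profile.z_um
        return float(0.5 * (z[0] + z[-1])), float((z[-1] - z[0]) / 4.0)
    mu = float(np.sum(w * profile.z_um) / total)
    var = float(np.sum(w * (profile.z_um - mu) ** 2) / total)
    return mu, float(np.sqrt(max(var, 1e-12)))


def fit_gaussian(profile: ZIntensityProfile) -> GaussianFit:
    """Least-squares Gaussian fit of an intensity-vs-z profile.

    Model amplitude*exp(-(z-mean)^2 / (2 sigma^2)) + offset, initialized at
    the moment estimates. Zero-mass profiles raise; a failed optimization
    returns the moment estimates with converged=False.
    """
    z = profile.z_um
    y = profile.total_intensity
    if np.sum(np.clip(y, 0, None)) <= 0:
        raise FitError(f"{profile.position_id}/{profile.channel}: zero-mass profile")
    mu0, sd0 = moment_estimates(profile)
    step = z[1] - z[0]
    off0 = float(y.min())
    amp0 = max(float(y.max()) - off0, 1e-9)
    sd0 = float(np.clip(sd0, step / 4.0, z[-1] - z[0]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss, z, y, p0=[amp0, mu0, sd0, off0],
                bounds=([0.0, z[0] - step, step / 10.0, -np.inf],
                        [np.inf, z[-1] + step, 4.0 * (z[-1] - z[0]), np.inf]),
                maxfev=2000,
            )
        resid = y - _gauss(z, *popt)
        return GaussianFit(
            mean_um=float(popt[1]), sigma_um=float(popt[2]),
            amplitude=float(popt[0]), offset=float(popt[3]),
            rss=float(np.sum(resid ** 2)), converged=True,
        )
    except Exception:
        return GaussianFit(mean_um=mu0, sigma_um=sd0, amplitude=amp0,
                           offset=off0, rss=float("nan"), converged=False)


def delta_z(fit_inducible: GaussianFit, fit_all: GaussianFit) -> float:
    """Extrusion statistic: inducible-channel mean minus all-cell mean (µm).

    Positive ΔZ = apical displacement of inducible nuclei. Raises when
    either fit did not converge (such positions are excluded from
    condition statistics).
    """
    if not (fit_inducible.converged and fit_all.converged):
        raise MapkdynError("delta_z requires two converged fits")
    return float(fit_inducible.mean_um - fit_all.mean_um)


def normalize_condition(
    results: list[ExtrusionResult],
    baseline: list[ExtrusionResult],
) -> list[ExtrusionResult]:
    """Baseline-correct ΔZ by subtracting the mean of a reference condition.

    The reference (parental) condition normalized against itself has mean
    exactly 0 — the dashed line of the condition plots. Outlier-flagged
    baseline observations are ignored when forming the baseline mean.
    """
    base_vals = [r.delta_z_um for r in baseline if not r.outlier]
    if not base_vals:
        raise MapkdynError("empty baseline condition")
    shift = float(np.mean(base_vals))
    return [
        ExtrusionResult(r.position_id, r.delta_z_um, r.delta_z_um - shift, r.outlier)
        for r in results
    ]


def flag_outliers(
    results: list[ExtrusionResult],
    n_mad: float = 3.0,
) -> list[ExtrusionResult]:
    """Flag observations more than ``n_mad`` MAD-based sds from the median.

    Uses the normal-consistent MAD scale (1.4826 x MAD). Flagged
    observations stay in the output but are excluded from condition means
    and tests. Idempotent; with fewer than 4 observations nothing is
    flagged.
    """
    vals = np.array([r.delta_z_um for r in results])
    if vals.size < 4:
        return [ExtrusionResult(r.position_id, r.delta_z_um,
                                r.normalized_delta_z_um, False) for r in results]
    med = np.median(vals)
    sd = 1.4826 * np.median(np.abs(vals - med))
    flagged = np.abs(vals - med) > n_mad * sd if sd > 0 else np.zeros(vals.size, bool)
    return [
        ExtrusionResult(r.position_id, r.delta_z_um, r.normalized_delta_z_um, bool(f))
        for r, f in zip(results, flagged)
    ]


def compare_conditions(
    a: list[ExtrusionResult],
    b: list[ExtrusionResult],
    use_normalized: bool = True,
):
    """Welch's two-sided two-sample t-test between conditions.

    Outlier-flagged observations are excluded. Returns (t, p, stars) with
    the figure-legend star convention.
    """
    def _vals(rs):
        out = [r.normalized_delta_z_um if use_normalized else r.delta_z_um
               for r in rs if not r.outlier]
        return np.asarray(out, float)

    va, vb = _vals(a), _vals(b)
    if va.size < 2 or vb.size < 2:
        raise MapkdynError("need >= 2 non-outlier observations per condition")
    if np.array_equal(va, vb) and np.ptp(va) == 0:
        return 0.0, 1.0, "ns"
    t, p = stats.ttest_ind(va, vb, equal_var=False)
    if np.isnan(p):  # identical constant groups
        t, p = 0.0, 1.0
    return float(t), float(p), significance_stars(float(p))
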