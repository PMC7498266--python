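"""Seeded synthetic-data generators with ground truth.

Each generator emulates one of the study's imaging outputs — single-cell
activity/localization traces, coculture migration trajectories, two-channel
confocal z-stacks, EdU count tables, and shed-protein abundance tables —
and returns the hidden parameters used (true peak times, bias
concentration, true ΔZ, ...) as a :class:`~mapkdyn.params.GroundTruth` for
recovery tests. All generators are deterministic given (params, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mapkdyn.errors import ParameterError
from mapkdyn.params import (
    FWHM_PER_SIGMA,
    GroundTruth,
    MigrationSimParams,
    PulseTrainParams,
    SustainedParams,
    WaveParams,
    ZStackSimParams,
)
from mapkdyn.traces import ActivityTrace

__all__ = [
    "pulse_template",
    "sustained_template",
    "draw_pulse_times",
    "simulate_trace",
    "simulate_track_population",
    "simulate_zstack",
    "simulate_edu_table",
    "simulate_shed_table",
]

#: conserved total reporter intensity per cell (arbitrary units)
KTR_TOTAL = 2000.0
LOC_TOTAL = 1000.0


# ---------------------------------------------------------------------------
# activity traces

def pulse_template(t: np.ndarray, peak_times, amplitude: float, sigma: float,
                   baseline: float = 0.0) -> np.ndarray:
    """Sum of symmetric Gaussian bumps on a baseline."""
    y = np.full_like(np.asarray(t, float), baseline)
    for pt in peak_times:
        y = y + amplitude * np.exp(-0.5 * ((t - pt) / sigma) ** 2)
    return y


def sustained_template(t: np.ndarray, p: SustainedParams) -> np.ndarray:
    """Logistic step: 10-90% rise spans rise_time_min, starting at onset."""
    k = np.log(81.0) / p.rise_time_min
    center = p.onset_min + p.rise_time_min / 2.0
    return p.baseline + (p.plateau - p.baseline) / (1.0 + np.exp(-k * (t - center)))


def draw_pulse_times(p: PulseTrainParams, rng: np.random.Generator) -> np.ndarray:
    """Poisson event times thinned by the refractory period.

    The event count is Poisson(mean_rate x duration); event times are
    uniform over the recording inset by one pulse width at each end (so
    every ground-truth pulse is a whole, in-window bump), then sorted and
    thinned front-to-back: an event closer than refractory_min to the last
    kept event is dropped.
    """
    lam = p.mean_rate / 60.0 * p.duration_min
    n = rng.poisson(lam)
    margin = p.pulse_width_min
    lo, hi = margin, max(p.duration_min - margin, margin)
    times = np.sort(rng.uniform(lo, hi, size=n))
    kept: list[float] = []
    for ev in times:
        if not kept or ev - kept[-1] >= p.refractory_min:
            kept.append(float(ev))
    return np.asarray(kept)


def simulate_trace(
    params: PulseTrainParams | SustainedParams,
    cell_id: str = "c0000",
    rng: np.random.Generator | None = None,
) -> tuple[ActivityTrace, GroundTruth]:
    """Simulate one cell's activity trace plus its ground truth.

    Pulsatile params yield Gaussian bumps at Poisson-thinned times;
    sustained params yield a logistic baseline-to-plateau step. Gaussian
    noise of sd ``noise_sd`` is added; with noise_sd = 0 the trace equals
    its closed-form template exactly.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = params.frame_interval_min * np.arange(params.n_frames)
    gt = GroundTruth()
    if isinstance(params, PulseTrainParams):
        times = draw_pulse_times(params, rng)
        y = pulse_template(t, times, params.pulse_amplitude,
                           params.pulse_sigma_min, params.baseline)
        gt.peak_times_min[cell_id] = [float(v) for v in times]
        gt.labels[cell_id] = "pulsatile" if times.size else "quiescent"
    elif isinstance(params, SustainedParams):
        y = sustained_template(t, params)
        gt.onset_times_min[cell_id] = float(params.onset_min)
        gt.labels[cell_id] = "sustained"
        gt.loc_folds[cell_id] = float(params.loc_fold)
    else:
        raise ParameterError(f"unsupported trace params: {type(params)!r}")
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=y.shape)
    y = np.maximum(y, 1e-6)  # ratios are positive
    return ActivityTrace(cell_id, t, y), gt


# ---------------------------------------------------------------------------
# tracked populations

def _ratio_to_intensities(ratio: np.ndarray, total: float):
    """Split a conserved total into (nuclear, cytoplasmic) at a given
    cytoplasm/nucleus ratio."""
    nuc = total / (1.0 + ratio)
    return nuc, total - nuc


def simulate_track_population(
    trace_params: PulseTrainParams | SustainedParams | None,
    motion_params: MigrationSimParams,
    wave: WaveParams | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a coculture tracking table (positions + reporter channels).

    Inducible cells form a compact group around ``center_xy`` and follow
    ``trace_params`` dynamics; neighbors are scattered uniformly, move with
    optional von Mises heading bias toward the group center, and — when
    ``wave`` is given — receive one activity pulse delayed by
    distance/wave-speed from the trigger (a kinematic stand-in for the
    paracrine activity wave). Returns exactly n_cells x n_frames rows.
    """
    mp = motion_params
    rng = np.random.default_rng(mp.seed)
    n_ind = int(round(mp.inducible_fraction * mp.n_cells))
    t = mp.frame_interval_min * np.arange(mp.n_frames)
    center = np.asarray(mp.center_xy, float)
    gt = GroundTruth(bias_kappa=float(mp.bias_kappa))

    noise_sd = trace_params.noise_sd if trace_params is not None else 0.0
    baseline = trace_params.baseline if trace_params is not None else 0.5

    rows = []
    for ci in range(mp.n_cells):
        cell_id = f"c{ci:04d}"
        inducible = ci < n_ind
        if inducible:
            pos = center + rng.normal(0.0, mp.cluster_sd_um, size=2)
        else:
            pos = rng.uniform(0.0, mp.field_size_um, size=2)
        d0 = float(np.hypot(*(pos - center)))

        # --- dynamics
        loc_fold = 1.0
        if inducible and trace_params is not None:
            trace, cgt = simulate_trace(trace_params, cell_id, rng)
            ratio = trace.ratio
            gt.peak_times_min.update(cgt.peak_times_min)
            gt.onset_times_min.update(cgt.onset_times_min)
            gt.labels[cell_id] = cgt.labels[cell_id]
            loc_fold = cgt.loc_folds.get(cell_id, 1.0)
        elif not inducible and wave is not None:
            onset = wave.trigger_min + d0 / wave.speed_um_per_min
            sigma = wave.pulse_width_min / FWHM_PER_SIGMA
            ratio = pulse_template(t, [onset], wave.pulse_amplitude, sigma, baseline)
            if noise_sd > 0:
                ratio = ratio + rng.normal(0.0, noise_sd, size=t.shape)
            gt.onset_times_min[cell_id] = float(onset)
            gt.labels[cell_id] = "wave"
        else:
            ratio = np.full_like(t, baseline)
            if noise_sd > 0:
                ratio = ratio + rng.normal(0.0, noise_sd, size=t.shape)
            gt.labels[cell_id] = gt.labels.get(cell_id, "quiescent")
        ratio = np.maximum(ratio, 1e-6)

        # --- localization channel (N/C of the tagged kinase)
        if loc_fold != 1.0 and isinstance(trace_params, SustainedParams):
            k = np.log(81.0) / trace_params.rise_time_min
            c0 = trace_params.onset_min + trace_params.rise_time_min / 2.0
            nc_loc = 1.0 + (loc_fold - 1.0) / (1.0 + np.exp(-k * (t - c0)))
        else:
            nc_loc = np.ones_like(t)
        if noise_sd > 0:
            nc_loc = np.maximum(nc_loc + rng.normal(0.0, noise_sd, size=t.shape), 1e-6)
        gt.loc_folds[cell_id] = float(loc_fold)

        # --- motion
        xy = np.empty((mp.n_frames, 2))
        xy[0] = pos
        for fi in range(1, mp.n_frames):
            now = t[fi - 1]
            to_center = center - xy[fi - 1]
            dist = np.hypot(*to_center)
            biased = (not inducible and mp.bias_kappa > 0
                      and now >= mp.bias_start_min and dist > 1e-9)
            if biased:
                mu = np.arctan2(to_center[1], to_center[0])
                heading = rng.vonmises(mu, mp.bias_kappa)
            else:
                heading = rng.uniform(-np.pi, np.pi)
            speed = mp.speed_um_per_frame
            if mp.speed_change_min is not None and now >= mp.speed_change_min:
                speed *= mp.speed_factor_after
            xy[fi] = xy[fi - 1] + speed * np.array([np.cos(heading), np.sin(heading)])
        obs = xy
        if mp.position_noise_sd_um > 0:
            obs = xy + rng.normal(0.0, mp.position_noise_sd_um, size=xy.shape)

        nuc_k, cyt_k = _ratio_to_intensities(ratio, KTR_TOTAL)
        cyt_l, nuc_l = _ratio_to_intensities(nc_loc, LOC_TOTAL)  # N/C ratio
        for fi in range(mp.n_frames):
            rows.append((
                cell_id, fi, float(t[fi]), float(obs[fi, 0]), float(obs[fi, 1]),
                float(nuc_k[fi]), float(cyt_k[fi]),
                float(nuc_l[fi]), float(cyt_l[fi]),
                "inducible" if inducible else "neighbor", True,
            ))
    table = pd.DataFrame(rows, columns=[
        "cell_id", "frame", "time_min", "x_um", "y_um",
        "nuc_ktr", "cyt_ktr", "nuc_loc", "cyt_loc", "population", "valid",
    ])
    return table, gt


# ---------------------------------------------------------------------------
# z-stacks

def simulate_zstack(params: ZStackSimParams) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a two-channel confocal z-stack of nuclear labels.

    Output shape is (2, nz, ny, nx), float32: channel 0 contains only
    inducible nuclei, channel 1 all nuclei. Nuclei are 3-D Gaussian blobs
    with lateral sigma ``nucleus_sigma_xy_um`` and axial sigma
    ``nucleus_sigma_um``; inducible z-centers are shifted apically by
    ``extrusion_offset_um``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    z = p.z_grid_um
    nz = z.size
    x = (np.arange(p.nx) + 0.5) * p.pixel_size_um
    y = (np.arange(p.ny) + 0.5) * p.pixel_size_um
    stack = np.zeros((2, nz, p.ny, p.nx), dtype=np.float64)
    n_ind = int(round(p.inducible_fraction * p.n_nuclei))
    gt = GroundTruth(extrusion_offset_um=float(p.extrusion_offset_um))
    if p.monolayer_z_mean_um + p.extrusion_offset_um + 2 * p.monolayer_z_sd_um > p.z_max_um:
        gt.warnings.append("extrusion offset places nuclear mass near the upper z bound")

    sx = p.nucleus_sigma_xy_um
    sz = p.nucleus_sigma_um
    for ni in range(p.n_nuclei):
        inducible = ni < n_ind
        cx = rng.uniform(0.0, p.nx * p.pixel_size_um)
        cy = rng.uniform(0.0, p.ny * p.pixel_size_um)
        mean_z = p.monolayer_z_mean_um + (p.extrusion_offset_um if inducible else 0.0)
        cz = rng.normal(mean_z, p.monolayer_z_sd_um)
        cz = float(np.clip(cz, p.z_min_um, p.z_max_um))
        gt.nucleus_z_um[f"n{ni:04d}"] = cz
        gt.nucleus_xy_um[f"n{ni:04d}"] = [float(cx), float(cy)]
        gt.labels[f"n{ni:04d}"] = "inducible" if inducible else "neighbor"
        gx = np.exp(-0.5 * ((x - cx) / sx) ** 2)
        gy = np.exp(-0.5 * ((y - cy) / sx) ** 2)
        gz = np.exp(-0.5 * ((z - cz) / sz) ** 2)
        blob = p.nucleus_amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        if inducible:
            stack[0] += blob
        stack[1] += blob
    if p.intensity_noise_sd > 0:
        stack += rng.normal(0.0, p.intensity_noise_sd, size=stack.shape)
    return stack.astype(np.float32), gt


# ---------------------------------------------------------------------------
# EdU tables

def simulate_edu_table(
    n_positions: int,
    fractions: dict,
    n_nuclei: dict | int = 1000,
    condition: str = "coculture",
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-position EdU-positive counts.

    ``fractions`` maps population -> {"nodox": p, "dox": p} (a bare float is
    used for both Dox states); ``n_nuclei`` is either one count or a
    mapping population -> count. Counts are Binomial(n_nuclei, fraction)
    per position, population and Dox state.
    """
    rng = np.random.default_rng(seed)
    gt = GroundTruth()
    rows = []
    for pop, entry in fractions.items():
        if isinstance(entry, dict):
            per_state = {"nodox": float(entry["nodox"]), "dox": float(entry["dox"])}
        else:
            per_state = {"nodox": float(entry), "dox": float(entry)}
        for state, frac in per_state.items():
            if not 0.0 <= frac <= 1.0:
                raise ParameterError("EdU fractions must lie in [0, 1]")
            gt.sphase_fractions[f"{pop}|{state}"] = frac
        n_pop = n_nuclei[pop] if isinstance(n_nuclei, dict) else int(n_nuclei)
        for pos in range(n_positions):
            for state, frac in per_state.items():
                k = int(rng.binomial(n_pop, frac))
                rows.append((f"p{pos:03d}", condition, pop, state == "dox", n_pop, k))
    df = pd.DataFrame(rows, columns=[
        "position", "condition", "population", "dox", "n_nuclei", "n_edu_positive",
    ])
    return df, gt


# ---------------------------------------------------------------------------
# shed-protein tables

def simulate_shed_table(
    n_proteins: int = 200,
    n_hits: int = 10,
    effect_lnfc: float = 1.0,
    replicate_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a supernatant-proteomics abundance table.

    Four conditions (WT/KO genotype x +/-Dox) with ``n_replicates``
    replicates each; log-abundances are N(base_i, replicate_cv) and the
    first ``n_hits`` proteins gain ``effect_lnfc`` in the WT +Dox condition
    only (sheddase-dependent, induction-dependent release).
    """
    if n_hits > n_proteins:
        raise ParameterError("n_hits must not exceed n_proteins")
    rng = np.random.default_rng(seed)
    gt = GroundTruth()
    rows = []
    for pi in range(n_proteins):
        pid = f"P{pi:04d}"
        hit = pi < n_hits
        base = rng.normal(10.0, 1.0)
        gt.protein_lnfc[pid] = effect_lnfc if hit else 0.0
        if hit:
            gt.hit_proteins.append(pid)
        for genotype in ("WT", "KO"):
            for dox in (False, True):
                shift = effect_lnfc if (hit and genotype == "WT" and dox) else 0.0
                ln_abund = base + shift + rng.normal(0.0, replicate_cv, size=n_replicates)
                for ri, v in enumerate(ln_abund):
                    rows.append((pid, genotype, dox, ri, float(np.exp(v))))
    df = pd.DataFrame(rows, columns=[
        "protein", "genotype", "dox", "replicate", "abundance",
    ])
    return df, gt
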