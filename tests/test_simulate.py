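"""Generator behavior: closed-form templates, seeded determinism,
distributional properties, and ground-truth bookkeeping."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import erf

from mapkdyn.errors import ParameterError
from mapkdyn.params import (
    MigrationSimParams,
    PulseTrainParams,
    SustainedParams,
    WaveParams,
    ZStackSimParams,
)
from mapkdyn import simulate


class TestTraceGenerator:
    def test_zero_rate_gives_flat_baseline(self):
        params = PulseTrainParams(mean_rate=0.0, noise_sd=0.0, baseline=0.7)
        trace, gt = simulate.simulate_trace(params)
        assert np.allclose(trace.ratio, 0.7)
        assert gt.peak_times_min["c0000"] == []

    def test_same_seed_is_deterministic(self):
        params = PulseTrainParams(seed=42)
        t1, g1 = simulate.simulate_trace(params)
        t2, g2 = simulate.simulate_trace(params)
        assert np.array_equal(t1.ratio, t2.ratio)
        assert g1.peak_times_min == g2.peak_times_min

    def test_poisson_mean_peak_count(self):
        # with no refractory thinning the event count is Poisson with mean
        # rate x duration = 2/h x 6 h = 12; check the Monte-Carlo mean
        # against the closed form within 3 standard errors
        counts = []
        rng = np.random.default_rng(0)
        for _ in range(500):
            params = PulseTrainParams(
                mean_rate=2.0, refractory_min=0.0,
                seed=int(rng.integers(2**31)),
            )
            _, gt = simulate.simulate_trace(params)
            counts.append(len(gt.peak_times_min["c0000"]))
        mean = np.mean(counts)
        se = np.sqrt(12.0 / 500)
        assert abs(mean - 12.0) < 3 * se

    def test_noiseless_pulse_trace_equals_template(self, pulse_trace_noiseless):
        trace, gt, params = pulse_trace_noiseless
        t = params.frame_interval_min * np.arange(params.n_frames)
        template = simulate.pulse_template(
            t, gt.peak_times_min["c0000"], params.pulse_amplitude,
            params.pulse_sigma_min, params.baseline)
        assert np.allclose(trace.ratio, template)

    def test_refractory_enforced(self):
        for seed in range(30):
            _, gt = simulate.simulate_trace(PulseTrainParams(mean_rate=6.0, seed=seed))
            times = np.asarray(gt.peak_times_min["c0000"])
            if times.size > 1:
                assert np.diff(times).min() >= 30.0

    def test_sustained_template_hits_baseline_and_plateau(self, sustained_trace_noiseless):
        trace, gt, params = sustained_trace_noiseless
        assert trace.ratio[0] == pytest.approx(params.baseline, abs=0.01)
        assert trace.ratio[-1] == pytest.approx(params.plateau, abs=0.01)
        assert gt.labels["c0000"] == "sustained"

    @pytest.mark.parametrize("bad", [
        dict(duration_min=0.0),
        dict(frame_interval_min=-5.0),
        dict(noise_sd=-0.1),
        dict(pulse_width_min=1.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            PulseTrainParams(**bad)

    def test_sustained_onset_must_precede_end(self):
        with pytest.raises(ParameterError):
            SustainedParams(onset_min=400.0, duration_min=360.0)


class TestTrackGenerator:
    def test_row_conservation(self, small_track_table):
        table, _ = small_track_table
        assert len(table) == 40 * 36
        assert table.groupby("cell_id").size().nunique() == 1

    def test_unbiased_headings_are_uniform(self):
        # chi-square GOF on non-overlapping 20-min displacement headings
        motion = MigrationSimParams(n_cells=400, n_frames=52, bias_kappa=0.0,
                                    inducible_fraction=0.0, seed=7)
        table, _ = simulate.simulate_track_population(None, motion)
        angles = []
        for _, grp in table.groupby("cell_id"):
            grp = grp.sort_values("frame")
            x = grp["x_um"].to_numpy()
            y = grp["y_um"].to_numpy()
            for k in range(0, len(x) - 4, 4):
                angles.append(np.degrees(np.arctan2(y[k + 4] - y[k],
                                                    x[k + 4] - x[k])) % 360)
        counts, _ = np.histogram(np.asarray(angles)[:5000], bins=12, range=(0, 360))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_strong_bias_concentrates_headings(self):
        motion = MigrationSimParams(n_cells=50, n_frames=9, bias_kappa=500.0,
                                    inducible_fraction=0.0, seed=3,
                                    speed_um_per_frame=1.0)
        table, _ = simulate.simulate_track_population(None, motion)
        center = np.array(motion.center_xy)
        for _, grp in table.groupby("cell_id"):
            grp = grp.sort_values("frame")
            pos = grp[["x_um", "y_um"]].to_numpy()
            d0 = pos[0]
            if np.hypot(*(center - d0)) < 50:  # too close: direction unstable
                continue
            disp = pos[4] - pos[0]
            to_c = center - pos[0]
            cos = np.dot(disp, to_c) / (np.hypot(*disp) * np.hypot(*to_c))
            assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 10.0

    def test_wave_onset_is_trigger_plus_distance_over_speed(self):
        motion = MigrationSimParams(n_cells=20, n_frames=72,
                                    inducible_fraction=0.1, seed=9)
        wave = WaveParams(trigger_min=60.0, speed_um_per_min=2.0)
        quiet = PulseTrainParams(mean_rate=0.0, noise_sd=0.0)
        table, gt = simulate.simulate_track_population(quiet, motion, wave)
        center = np.array(motion.center_xy)
        for cid, grp in table.groupby("cell_id"):
            if grp["population"].iloc[0] != "neighbor":
                continue
            p0 = grp.sort_values("frame")[["x_um", "y_um"]].iloc[0].to_numpy()
            d = float(np.hypot(*(p0 - center)))
            assert gt.onset_times_min[cid] == pytest.approx(60.0 + d / 2.0)

    def test_reporter_ratio_consistency(self, small_track_table):
        # cytoplasm/nucleus intensities must reproduce the simulated ratio
        # and conserve the per-cell total
        table, _ = small_track_table
        total = table["nuc_ktr"] + table["cyt_ktr"]
        assert np.allclose(total, total.iloc[0])
        assert (table["cyt_ktr"] > 0).all() and (table["nuc_ktr"] > 0).all()

    def test_bad_inducible_fraction_rejected(self):
        with pytest.raises(ParameterError):
            MigrationSimParams(inducible_fraction=1.5)


def _axis_mass(c, sigma, lo, hi, step):
    """Analytic truncated-Gaussian mass along one axis, in grid units."""
    return (0.5 * (erf((hi - c) / (np.sqrt(2) * sigma))
                   - erf((lo - c) / (np.sqrt(2) * sigma)))
            * np.sqrt(2 * np.pi) * sigma / step)


class TestZStackGenerator:
    def test_seeded_determinism_voxel_identical(self):
        params = ZStackSimParams(seed=5, n_nuclei=20, intensity_noise_sd=2.0)
        s1, _ = simulate.simulate_zstack(params)
        s2, _ = simulate.simulate_zstack(params)
        assert np.array_equal(s1, s2)

    def test_zero_offset_profiles_align(self):
        params = ZStackSimParams(extrusion_offset_um=0.0, monolayer_z_sd_um=0.0,
                                 seed=2, n_nuclei=30)
        stack, _ = simulate.simulate_zstack(params)
        prof_i = stack[0].sum(axis=(1, 2))
        prof_a = stack[1].sum(axis=(1, 2))
        assert np.argmax(prof_i) == np.argmax(prof_a)

    def test_offset_six_shifts_mode_by_six(self):
        params = ZStackSimParams(extrusion_offset_um=6.0, monolayer_z_sd_um=0.0,
                                 seed=1, n_nuclei=40)
        stack, _ = simulate.simulate_zstack(params)
        z_mode_i = np.argmax(stack[0].sum(axis=(1, 2)))
        z_mode_a = np.argmax(stack[1].sum(axis=(1, 2)))
        assert z_mode_i - z_mode_a == 6

    def test_total_intensity_matches_blob_integrals(self):
        params = ZStackSimParams(extrusion_offset_um=6.0, seed=1, n_nuclei=40)
        stack, gt = simulate.simulate_zstack(params)
        expect_all = expect_ind = 0.0
        for nid, z in gt.nucleus_z_um.items():
            cx, cy = gt.nucleus_xy_um[nid]
            m = (params.nucleus_amplitude
                 * _axis_mass(cx, params.nucleus_sigma_xy_um, 0.0,
                              params.nx * params.pixel_size_um, params.pixel_size_um)
                 * _axis_mass(cy, params.nucleus_sigma_xy_um, 0.0,
                              params.ny * params.pixel_size_um, params.pixel_size_um)
                 * _axis_mass(z, params.nucleus_sigma_um,
                              params.z_min_um - params.z_step_um / 2,
                              params.z_max_um + params.z_step_um / 2,
                              params.z_step_um))
            expect_all += m
            if gt.labels[nid] == "inducible":
                expect_ind += m
        assert stack[1].sum() == pytest.approx(expect_all, rel=0.01)
        assert stack[0].sum() == pytest.approx(expect_ind, rel=0.01)

    def test_offset_near_bound_sets_warning(self):
        params = ZStackSimParams(extrusion_offset_um=16.0, monolayer_z_mean_um=8.0,
                                 z_max_um=25.0, seed=0, n_nuclei=10)
        _, gt = simulate.simulate_zstack(params)
        assert gt.warnings

    def test_offset_outside_volume_rejected(self):
        with pytest.raises(ParameterError):
            ZStackSimParams(extrusion_offset_um=30.0)


class TestTableGenerators:
    @pytest.mark.parametrize("frac,expect", [(0.0, 0), (1.0, None)])
    def test_degenerate_edu_fractions(self, frac, expect):
        table, _ = simulate.simulate_edu_table(
            4, {"neighbor": frac}, n_nuclei=100, seed=0)
        if frac == 0.0:
            assert (table["n_edu_positive"] == 0).all()
        else:
            assert (table["n_edu_positive"] == table["n_nuclei"]).all()

    def test_edu_binomial_sampling(self):
        table, _ = simulate.simulate_edu_table(
            50, {"neighbor": 0.2}, n_nuclei=1000, seed=1)
        frac = table["n_edu_positive"].sum() / table["n_nuclei"].sum()
        n = table["n_nuclei"].sum()
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * se

    def test_edu_fraction_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            simulate.simulate_edu_table(2, {"neighbor": 1.2})

    def test_shed_table_deterministic(self):
        t1, _ = simulate.simulate_shed_table(n_proteins=20, n_hits=2, seed=9)
        t2, _ = simulate.simulate_shed_table(n_proteins=20, n_hits=2, seed=9)
        assert t1.equals(t2)

    def test_shed_hits_elevated_only_in_wt_dox(self):
        table, gt = simulate.simulate_shed_table(
            n_proteins=10, n_hits=3, effect_lnfc=2.0, replicate_cv=0.01, seed=4)
        for pid in gt.hit_proteins:
            grp = table[table["protein"] == pid]
            wt_dox = grp[(grp["genotype"] == "WT") & grp["dox"]]["abundance"].mean()
            rest = grp[~((grp["genotype"] == "WT") & grp["dox"])]["abundance"].mean()
            assert wt_dox > 3 * rest

    def test_shed_too_many_hits_rejected(self):
        with pytest.raises(ParameterError):
            simulate.simulate_shed_table(n_proteins=5, n_hits=6)
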