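"""Z-profile construction, Gaussian fits (with a grid-search oracle), the
ΔZ statistic, normalization, outlier flagging and condition tests."""

import numpy as np
import pytest

from mapkdyn.errors import FitError, MapkdynError
from mapkdyn import extrusion as ext
from mapkdyn.params import ZStackSimParams
from mapkdyn import simulate


def _profile(z, y, pid="p", chan="inducible"):
    return ext.ZIntensityProfile(pid, chan, z, y)


def _gauss(z, amp, mu, sigma, off=0.0):
    return off + amp * np.exp(-0.5 * ((z - mu) / sigma) ** 2)


def _grid_rss(z, y, mus, sgs):
    """RSS surface over a (mu, sigma) grid with closed-form amplitude and
    offset at each grid point."""
    n = z.size
    g = np.exp(-0.5 * ((z[None, None, :] - mus[:, None, None])
                       / sgs[None, :, None]) ** 2)
    s_g = g.sum(axis=2)
    s_gg = (g * g).sum(axis=2)
    s_y = y.sum()
    s_gy = (g * y).sum(axis=2)
    det = n * s_gg - s_g * s_g
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = (n * s_gy - s_g * s_y) / det
        off = (s_y - amp * s_g) / n
        rss = ((y[None, None, :] - amp[..., None] * g
                - off[..., None]) ** 2).sum(axis=2)
    return np.where(np.isfinite(rss), rss, np.inf)


def grid_search_gaussian(profile):
    """Dense grid-search oracle over (mean, sigma), coarse-to-fine down to
    0.005 µm resolution — independent of the package's optimizer."""
    z, y = profile.z_um, profile.total_intensity
    mus = np.arange(z[0], z[-1] + 1e-9, 0.05)
    sgs = np.arange(0.5, (z[-1] - z[0]) / 2, 0.05)
    rss = _grid_rss(z, y, mus, sgs)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    mu0, sg0 = mus[i], sgs[j]
    mus = np.clip(np.arange(mu0 - 0.06, mu0 + 0.0601, 0.005), z[0], z[-1])
    sgs = np.clip(np.arange(sg0 - 0.06, sg0 + 0.0601, 0.005), 0.25, None)
    rss = _grid_rss(z, y, mus, sgs)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(mus[i]), float(sgs[j])


class TestZProfile:
    def test_single_bright_plane_is_delta(self):
        stack = np.zeros((2, 10, 8, 8))
        stack[0, 5] = 7.0
        prof = ext.z_intensity_histogram(stack, 0)
        assert np.argmax(prof.total_intensity) == 5
        assert prof.total_intensity[np.arange(10) != 5].sum() == \
            pytest.approx(0.0)

    def test_two_equal_nuclei_symmetric_bimodal(self):
        z = np.arange(13.0)
        stack = np.zeros((2, 13, 4, 4))
        for zi in range(13):
            stack[0, zi] = _gauss(z[zi], 10.0, 3.0, 1.0) + \
                _gauss(z[zi], 10.0, 9.0, 1.0)
        prof = ext.z_intensity_histogram(stack, 0)
        lo = prof.total_intensity[:6]
        hi = prof.total_intensity[7:]
        assert lo.sum() == pytest.approx(hi.sum(), rel=1e-6)

    def test_profile_mass_equals_corrected_stack_mass(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 5, size=(2, 8, 6, 6))
        prof = ext.z_intensity_histogram(stack, 1)
        chan = stack[1]
        decile = np.quantile(chan, 0.1)
        bg = np.median(chan[chan <= decile])
        assert prof.total_intensity.sum() == \
            pytest.approx(np.clip(chan - bg, 0, None).sum())

    def test_too_few_planes_rejected(self):
        with pytest.raises(Exception):
            _profile(np.arange(3.0), np.ones(3))


class TestFitGaussian:
    def test_exact_gaussian_recovered(self):
        z = np.arange(26.0)
        prof = _profile(z, _gauss(z, 100.0, 12.0, 3.0))
        fit = ext.fit_gaussian(prof)
        assert fit.converged
        assert fit.mean_um == pytest.approx(12.0, abs=0.01)
        assert fit.sigma_um == pytest.approx(3.0, abs=0.01)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        z = np.arange(26.0)
        for _ in range(50):
            mu = rng.uniform(5.0, 20.0)
            sg = rng.uniform(1.5, 4.0)
            amp = rng.uniform(50.0, 200.0)
            off = rng.uniform(0.0, 10.0)
            prof = _profile(z, _gauss(z, amp, mu, sg, off))
            fit = ext.fit_gaussian(prof)
            omu, osg = grid_search_gaussian(prof)
            assert abs(fit.mean_um - omu) < 0.05
            assert abs(fit.sigma_um - osg) < 0.05

    def test_symmetric_profile_mean_at_center(self):
        z = np.arange(21.0)
        y = _gauss(z, 10.0, 10.0, 2.0) + _gauss(z, 10.0, 10.0, 5.0)
        fit = ext.fit_gaussian(_profile(z, y))
        assert fit.mean_um == pytest.approx(10.0, abs=1e-6)

    def test_flat_profile_falls_back_to_midrange_centroid(self):
        z = np.arange(11.0)
        fit = ext.fit_gaussian(_profile(z, np.full(11, 5.0)))
        assert fit.mean_um == pytest.approx(5.0, abs=0.5)

    def test_zero_mass_profile_raises(self):
        z = np.arange(11.0)
        with pytest.raises(FitError):
            ext.fit_gaussian(_profile(z, np.zeros(11)))


class TestDeltaZ:
    def _fit(self, mean, converged=True):
        return ext.GaussianFit(mean, 2.0, 10.0, 0.0, 0.0, converged)

    def test_identical_profiles_give_zero(self):
        assert ext.delta_z(self._fit(8.0), self._fit(8.0)) == 0.0

    def test_channel_swap_negates(self):
        a, b = self._fit(14.0), self._fit(8.0)
        assert ext.delta_z(a, b) == -ext.delta_z(b, a) == 6.0

    def test_unconverged_fit_rejected(self):
        with pytest.raises(MapkdynError):
            ext.delta_z(self._fit(14.0), self._fit(8.0, converged=False))

    def test_simulated_offset_recovered(self):
        rng = np.random.default_rng(31)
        vals = []
        for _ in range(10):
            params = ZStackSimParams(extrusion_offset_um=6.0,
                                     seed=int(rng.integers(2**31)))
            stack, _ = simulate.simulate_zstack(params)
            fi = ext.fit_gaussian(ext.z_intensity_histogram(stack, 0))
            fa = ext.fit_gaussian(ext.z_intensity_histogram(stack, 1))
            vals.append(ext.delta_z(fi, fa))
        assert abs(np.mean(vals) - 6.0) < 0.5


class TestNormalizationAndOutliers:
    def _results(self, values):
        return [ext.ExtrusionResult(f"p{i}", v) for i, v in enumerate(values)]

    def test_baseline_subtraction(self):
        res = ext.normalize_condition(self._results([6.4]),
                                      self._results([0.3, 0.5]))
        assert res[0].normalized_delta_z_um == pytest.approx(6.0)

    def test_baseline_normalizes_to_exact_zero_mean(self):
        base = self._results([0.2, 0.6, -0.1, 0.5])
        normed = ext.normalize_condition(base, base)
        assert np.mean([r.normalized_delta_z_um for r in normed]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_global_z_shift_invariance(self):
        # ΔZ is a within-stack difference: shifting the whole z origin
        # (stage offset) moves both channel means equally and cancels
        params = ZStackSimParams(extrusion_offset_um=4.0, seed=77, n_nuclei=40)
        stack, _ = simulate.simulate_zstack(params)
        def dz(z0):
            fi = ext.fit_gaussian(ext.z_intensity_histogram(stack, 0, z_min_um=z0))
            fa = ext.fit_gaussian(ext.z_intensity_histogram(stack, 1, z_min_um=z0))
            return ext.delta_z(fi, fa)
        assert dz(0.0) == pytest.approx(dz(5.0), abs=1e-9)

    def test_equal_values_never_flagged(self):
        flagged = ext.flag_outliers(self._results([2.0] * 6))
        assert not any(r.outlier for r in flagged)

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(2)
        vals = list(rng.normal(0.0, 1.0, 19)) + [10.0]
        flagged = ext.flag_outliers(self._results(vals))
        assert flagged[-1].outlier
        assert sum(r.outlier for r in flagged) <= 2

    def test_flagging_idempotent(self):
        vals = [0.0, 0.1, 0.2, 0.1, 5.0]
        once = ext.flag_outliers(self._results(vals))
        twice = ext.flag_outliers(once)
        assert [r.outlier for r in once] == [r.outlier for r in twice]


class TestCompareConditions:
    def test_identical_groups(self):
        a = [ext.ExtrusionResult(f"p{i}", v, v) for i, v in
             enumerate([1.0, 2.0, 3.0])]
        t, p, stars = ext.compare_conditions(a, list(a))
        assert t == 0.0 and p == 1.0 and stars == "ns"

    def test_separated_groups_highly_significant(self):
        hits = 0
        for r in range(30):
            rng = np.random.default_rng(50 + r)
            a = [ext.ExtrusionResult(f"a{i}", v, v)
                 for i, v in enumerate(rng.normal(0.0, 1.0, 16))]
            b = [ext.ExtrusionResult(f"b{i}", v, v)
                 for i, v in enumerate(rng.normal(5.0, 1.0, 16))]
            _, p, _ = ext.compare_conditions(a, b)
            hits += p < 0.001
        assert hits / 30 >= 0.99

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(9)
        a = [ext.ExtrusionResult(f"a{i}", v, v)
             for i, v in enumerate(rng.normal(0.0, 1.0, 10))]
        b = [ext.ExtrusionResult(f"b{i}", v, v)
             for i, v in enumerate(rng.normal(1.0, 1.0, 10))]
        t1, p1, _ = ext.compare_conditions(a, b)
        t2, p2, _ = ext.compare_conditions(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_insufficient_observations_raise(self):
        a = [ext.ExtrusionResult("a", 1.0, 1.0)]
        with pytest.raises(MapkdynError):
            ext.compare_conditions(a, a)
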