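import numpy as np
import pytest

import arccheck_qa as aq
from arccheck_qa.errors import ArcCheckError
from arccheck_qa.qa_metrics import GAMMA_CAP


# ----------------------------------------------------------------------------
# Independent brute-force oracle: plain python loops + hand-rolled linear
# interpolation over the same search lattice definition (step dta/10).
# ----------------------------------------------------------------------------

def _interp_1d(axis, values, x):
    if x < axis[0] or x > axis[-1]:
        return None
    j = np.searchsorted(axis, x) - 1
    j = min(max(j, 0), len(axis) - 2)
    t = (x - axis[j]) / (axis[j + 1] - axis[j])
    return (1 - t) * values[j] + t * values[j + 1]

def _interp_2d(axes, values, p):
    ay, ax = axes
    y, x = p
    if y < ay[0] or y > ay[-1] or x < ax[0] or x > ax[-1]:
        return None
    i = min(max(np.searchsorted(ay, y) - 1, 0), len(ay) - 2)
    j = min(max(np.searchsorted(ax, x) - 1, 0), len(ax) - 2)
    u = (y - ay[i]) / (ay[i + 1] - ay[i])
    v = (x - ax[j]) / (ax[j + 1] - ax[j])
    return ((1 - u) * (1 - v) * values[i, j] + (1 - u) * v * values[i, j + 1]
            + u * (1 - v) * values[i + 1, j] + u * v * values[i + 1, j + 1])

def oracle_gamma(ref_pts, ref_dose, axes, values, criteria, norm=None):
    norm = norm if norm is not None else max(ref_dose)
    step = criteria.dta / 10.0
    n = int(round(3.0 * criteria.dta / step))
    ndim = len(axes) if isinstance(axes, tuple) else 1
    gammas = []
    for p, d in zip(ref_pts, ref_dose):
        if d < criteria.threshold / 100.0 * norm:
            gammas.append(None)
            continue
        tol = criteria.dose_tol / 100.0 * (norm if criteria.mode == "global" else d)
        best = np.inf
        if ndim == 1:
            for a in range(-n, n + 1):
                off = a * step
                if abs(off) > 3.0 * criteria.dta + 1e-12:
                    continue
                ev = _interp_1d(axes, values, p[0] + off)
                if ev is None:
                    continue
                g2 = (off / criteria.dta) ** 2 + ((ev - d) / tol) ** 2
                best = min(best, g2)
        else:
            for a in range(-n, n + 1):
                for b in range(-n, n + 1):
                    off = np.array([a * step, b * step])
                    if np.hypot(*off) > 3.0 * criteria.dta + 1e-12:
                        continue
                    ev = _interp_2d(axes, values, p + off)
                    if ev is None:
                        continue
                    g2 = (np.hypot(*off) / criteria.dta) ** 2 + ((ev - d) / tol) ** 2
                    best = min(best, g2)
        gammas.append(min(np.sqrt(best), GAMMA_CAP))
    evaluated = [g for g in gammas if g is not None]
    rate = 100.0 * np.mean([g <= 1.0 + 1e-12 for g in evaluated])
    return gammas, rate


def triangle_profile(xs, center=0.0, width=40.0, peak=2.0):
    return np.clip(peak * (1 - np.abs(xs - center) / width), 0.0, None)


class TestEEDR:
    def test_arithmetic(self, array):
        values = np.zeros(1386)
        for c in [(-5.0, 0.0), (5.0, 0.0)]:
            values[array.chart_index(*c)] = 2.0
        for c in [(325.0, 10.0), (325.0, 0.0), (-325.0, 0.0), (-325.0, -10.0)]:
            values[array.chart_index(*c)] = 0.64
        res = aq.compute_eedr(aq.DetectorDoses(values), array)
        assert res.eedr == pytest.approx(0.32)
        assert res.entrance_mean == pytest.approx(2.0)

    def test_equal_doses_give_unity(self, array):
        res = aq.compute_eedr(aq.DetectorDoses(np.full(1386, 1.7)), array)
        assert res.eedr == pytest.approx(1.0)

    def test_relative_difference_printed_values(self):
        assert aq.eedr_relative_difference(0.3342, 0.3207) == pytest.approx(4.21, abs=0.005)
        assert aq.eedr_relative_difference(0.5, 0.5) == 0.0
        assert aq.eedr_relative_difference(0.3229, 0.3207) == pytest.approx(0.686, abs=0.005)

    def test_relative_difference_zero_measured_errors(self):
        with pytest.raises(ArcCheckError):
            aq.eedr_relative_difference(0.3, 0.0)


class TestRescaleMU:
    def test_arithmetic(self):
        assert aq.rescale_mu(2.0, 2.0, 200.0) == 200.0
        assert aq.rescale_mu(2.1, 2.0, 200.0) == pytest.approx(210.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ArcCheckError):
            aq.rescale_mu(0.0, 2.0, 200.0)
        with pytest.raises(ArcCheckError):
            aq.rescale_mu(2.0, -1.0, 200.0)

    def test_engine_linearity_in_mu(self, five_layer_volume, engine_config, array):
        b1 = aq.BeamSpec(mu=200.0)
        b2 = aq.BeamSpec(mu=aq.rescale_mu(2.1, 2.0, 200.0))
        d1 = aq.detector_doses(five_layer_volume, b1, engine_config, array).values
        d2 = aq.detector_doses(five_layer_volume, b2, engine_config, array).values
        assert np.allclose(d2, d1 * 1.05, rtol=1e-12)


class TestGammaBasics:
    def test_identical_maps_all_pass(self):
        xs = np.linspace(-50, 50, 41)
        dose = triangle_profile(xs)
        crit = aq.GammaCriteria(2.0, 2.0, mode="global")
        res = aq.gamma_analysis(xs[:, None], dose, (xs, dose), crit)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma) == pytest.approx(0.0, abs=1e-9)

    def test_pure_dose_offset_passes_both_modes(self):
        xs = np.linspace(-50, 50, 41)
        dose = triangle_profile(xs) + 0.5
        crit_l = aq.GammaCriteria(2.0, 2.0, mode="local")
        crit_g = aq.GammaCriteria(2.0, 2.0, mode="global")
        for crit in (crit_l, crit_g):
            res = aq.gamma_analysis(xs[:, None], dose, (xs, dose * 1.01), crit)
            assert res.pass_rate == 100.0
        # at the max point in global mode, gamma <= 0.5 for a 1% offset at 2% tol
        res = aq.gamma_analysis(xs[:, None], dose, (xs, dose * 1.01), crit_g)
        assert res.gamma[np.argmax(dose)] <= 0.5 + 1e-9

    def test_shifted_triangle_vs_dta(self):
        xs = np.linspace(-60, 60, 121)
        ref = triangle_profile(xs) + 0.2
        crit = aq.GammaCriteria(2.0, 2.0, mode="global")
        ok = aq.gamma_analysis(xs[:, None], ref, (xs, triangle_profile(xs, center=1.0) + 0.2), crit)
        assert ok.pass_rate == 100.0
        bad = aq.gamma_analysis(xs[:, None], ref, (xs, triangle_profile(xs, center=5.0) + 0.2), crit)
        assert bad.pass_rate < 100.0

    def test_threshold_excludes_low_dose(self):
        xs = np.linspace(-60, 60, 61)
        ref = triangle_profile(xs)  # zero outside |x| > 40
        crit = aq.GammaCriteria(2.0, 2.0, threshold=10.0)
        res = aq.gamma_analysis(xs[:, None], ref, (xs, ref), crit)
        assert res.n_evaluated == int((ref >= 0.1 * ref.max()).sum())

    def test_all_below_threshold_errors(self):
        xs = np.linspace(0, 10, 11)
        with pytest.raises(ArcCheckError):
            aq.gamma_analysis(xs[:, None], np.ones(11), (xs, np.ones(11)),
                              aq.GammaCriteria(2, 2), norm_dose=1000.0)


class TestGammaOracle:
    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_1d_oracle_equivalence(self, mode):
        rng = np.random.default_rng(11)
        xs = np.linspace(-40, 40, 33)
        ref = triangle_profile(xs, width=50.0) + 0.3
        ev = ref * (1 + 0.01 * rng.standard_normal(xs.size))
        crit = aq.GammaCriteria(2.0, 2.0, mode=mode)
        res = aq.gamma_analysis(xs[:, None], ref, (xs, ev), crit)
        gam_o, rate_o = oracle_gamma(xs[:, None], ref, xs, ev, crit)
        valid = [i for i, g in enumerate(gam_o) if g is not None]
        assert np.allclose(res.gamma[valid], [gam_o[i] for i in valid], atol=1e-6)
        assert res.pass_rate == pytest.approx(rate_o, abs=1e-9)

    def test_2d_oracle_equivalence(self):
        rng = np.random.default_rng(5)
        ay = np.linspace(-20, 20, 21)
        ax = np.linspace(-20, 20, 21)
        yy, xx = np.meshgrid(ay, ax, indexing="ij")
        ref_map = 1.0 + np.exp(-(xx**2 + yy**2) / 300.0)
        ev_map = ref_map * (1 + 0.015 * rng.standard_normal(ref_map.shape))
        # reference points on a sparse subset of the lattice
        pts = np.column_stack([yy[::4, ::4].ravel(), xx[::4, ::4].ravel()])
        ref = ref_map[::4, ::4].ravel()
        crit = aq.GammaCriteria(2.0, 2.0, mode="local")
        res = aq.gamma_analysis(pts, ref, ((ay, ax), ev_map), crit)
        gam_o, rate_o = oracle_gamma(pts, ref, (ay, ax), ev_map, crit)
        assert np.allclose(res.gamma, gam_o, atol=1e-6)
        assert res.pass_rate == pytest.approx(rate_o, abs=1e-9)


class TestGammaProperties:
    def _noisy_case(self, seed=2, n=61):
        rng = np.random.default_rng(seed)
        xs = np.linspace(-60, 60, n)
        ref = triangle_profile(xs, width=70.0) + 0.3
        ev = ref * (1 + 0.02 * rng.standard_normal(n)) + 0.01 * rng.standard_normal(n)
        return xs, ref, np.clip(ev, 0, None)

    def test_monotone_in_criteria(self):
        xs, ref, ev = self._noisy_case()
        rates = []
        for dose_tol, dta in [(1.0, 1.0), (2.0, 1.0), (2.0, 2.0), (3.0, 2.0), (3.0, 3.0)]:
            crit = aq.GammaCriteria(dose_tol, dta, mode="local")
            rates.append(aq.gamma_analysis(xs[:, None], ref, (xs, ev), crit).pass_rate)
        assert all(a <= b + 1e-9 for a, b in zip(rates, rates[1:]))

    def test_local_pass_rate_not_above_global(self):
        for seed in range(5):
            xs, ref, ev = self._noisy_case(seed=seed)
            loc = aq.gamma_analysis(xs[:, None], ref, (xs, ev), aq.GammaCriteria(2, 2, mode="local"))
            glo = aq.gamma_analysis(xs[:, None], ref, (xs, ev), aq.GammaCriteria(2, 2, mode="global"))
            # every reference dose <= the global normalization dose here
            assert loc.pass_rate <= glo.pass_rate + 1e-9
            assert np.all(loc.gamma[~np.isnan(loc.gamma)] >= glo.gamma[~np.isnan(glo.gamma)] - 1e-12)

    def test_gamma_capped(self):
        xs = np.linspace(-10, 10, 21)
        ref = np.full(21, 2.0)
        res = aq.gamma_analysis(xs[:, None], ref, (xs, np.full(21, 0.5)),
                                aq.GammaCriteria(1.0, 1.0, mode="global"))
        assert np.nanmax(res.gamma) == GAMMA_CAP


class TestDTA:
    def test_identical_maps_pass(self):
        xs = np.linspace(-50, 50, 41)
        dose = triangle_profile(xs) + 0.2
        res = aq.dta_analysis(xs[:, None], dose, (xs, dose), aq.GammaCriteria(2, 2))
        assert res.pass_rate == 100.0

    def test_flat_field_pure_offset_fails_everywhere(self):
        xs = np.linspace(-50, 50, 41)
        ref = np.full(41, 2.0)
        res = aq.dta_analysis(xs[:, None], ref, (xs, ref * 1.05), aq.GammaCriteria(2, 2))
        assert res.pass_rate == 0.0

    def test_small_shift_of_gradient_passes(self):
        xs = np.linspace(-60, 60, 121)
        ev = triangle_profile(xs, center=1.5, width=70.0) + 0.3
        # reference points stay a search radius away from the map edge
        ref_x = xs[(xs >= -55) & (xs <= 55)]
        ref = triangle_profile(ref_x, width=70.0) + 0.3
        res = aq.dta_analysis(ref_x[:, None], ref, (xs, ev), aq.GammaCriteria(2, 2, mode="local"))
        assert res.pass_rate == 100.0

    def test_large_shift_fails_at_gradients(self):
        xs = np.linspace(-60, 60, 121)
        ref = triangle_profile(xs, width=70.0) + 0.3
        ev = triangle_profile(xs, center=5.0, width=70.0) + 0.3
        res = aq.dta_analysis(xs[:, None], ref, (xs, ev), aq.GammaCriteria(1.0, 2.0, mode="local"))
        assert res.pass_rate < 100.0
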