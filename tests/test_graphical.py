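"""Secondary plots, line intersection, parallelism test, mechanism verdict."""

import dataclasses
import math
import warnings

import numpy as np
import pytest

from inhibkin import (
    KineticParameters,
    Mechanism,
    build_rate_table,
    classify_mechanism,
    closest_neighbor_intersection,
    consistency_check,
    cornish_bowden_lines,
    dixon_lines,
    fit_michaelis_menten,
    parallelism_test,
    simulate_plate,
)
from inhibkin.fitting import MMFitResult
from inhibkin.graphical import SecondaryLine

from conftest import noiseless_table

KM0, VMAX0 = 93.9, 33.02


def synthetic_line(slope, intercept, kind="dixon", s=10.0, n=5, jitter=0.0, rng=None):
    i = np.linspace(0.0, 25.0, n)
    y = slope * i + intercept
    if jitter:
        y = y + (rng or np.random.default_rng(0)).normal(0, jitter, n)
    res_slope, res_int = np.polyfit(i, y, 1)
    return SecondaryLine(
        s=s, kind=kind, slope=float(res_slope), intercept=float(res_int),
        se_slope=0.0, se_intercept=0.0, cov_slope_intercept=0.0,
        i_values=i, y_values=y,
    )


class TestSecondaryLines:
    def test_dixon_slopes_equal_under_uncompetitive_truth(self, uncompetitive_table):
        lines = dixon_lines(uncompetitive_table)
        expected = 1.0 / (VMAX0 * 44.3)  # 6.836e-4, independent of S
        for ln in lines:
            assert ln.slope == pytest.approx(expected, rel=1e-6)

    def test_dixon_lines_meet_at_minus_ki_for_competitive(self, competitive_table,
                                                          competitive_truth):
        est = closest_neighbor_intersection(dixon_lines(competitive_table))
        assert est.finite
        assert est.x == pytest.approx(-competitive_truth.ki, rel=1e-6)

    def test_s_over_v_coefficients_uncompetitive(self, uncompetitive_table):
        # slope = S_nM/(Vmax Ki'), intercept = (KM_nM + S_nM)/Vmax
        for ln in cornish_bowden_lines(uncompetitive_table):
            s_nm = ln.s * 1e3
            assert ln.slope == pytest.approx(s_nm / (VMAX0 * 44.3), rel=1e-6)
            assert ln.intercept == pytest.approx((KM0 * 1e3 + s_nm) / VMAX0, rel=1e-6)

    def test_doubling_velocities_halves_coefficients(self, uncompetitive_table):
        doubled = dataclasses.replace(
            uncompetitive_table,
            data=uncompetitive_table.data.assign(
                v_pmol_min_ug=2 * uncompetitive_table.data["v_pmol_min_ug"]
            ),
        )
        for a, b in zip(cornish_bowden_lines(uncompetitive_table),
                        cornish_bowden_lines(doubled)):
            assert b.slope == pytest.approx(a.slope / 2, rel=1e-9)
            assert b.intercept == pytest.approx(a.intercept / 2, rel=1e-9)

    def test_nonpositive_velocity_excludes_level(self, uncompetitive_table):
        data = uncompetitive_table.data.copy()
        data.loc[data["S_uM"] == 12.5, "v_pmol_min_ug"] = 0.0
        broken = dataclasses.replace(uncompetitive_table, data=data)
        with pytest.warns(UserWarning, match="excluding"):
            lines = dixon_lines(broken)
        assert all(ln.s != 12.5 for ln in lines)


class TestClosestNeighborIntersection:
    def test_crossing_diagonals(self):
        lines = [synthetic_line(1.0, 0.0), synthetic_line(-1.0, 0.0)]
        est = closest_neighbor_intersection(lines)
        assert (est.x, est.y) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert est.residual == pytest.approx(0.0, abs=1e-12)

    def test_two_lines_exact(self):
        lines = [synthetic_line(2.0, 1.0), synthetic_line(-0.5, 4.0)]
        est = closest_neighbor_intersection(lines)
        x_exact = (4.0 - 1.0) / (2.0 + 0.5)
        assert est.x == pytest.approx(x_exact, rel=1e-12)
        assert est.y == pytest.approx(2.0 * x_exact + 1.0, rel=1e-12)
        assert est.residual == pytest.approx(0.0, abs=1e-12)

    def test_three_line_triangle_matches_grid_search(self):
        lines = [
            synthetic_line(0.0, 1.0),
            synthetic_line(1.0, -2.0),
            synthetic_line(-1.0, 2.5),
        ]
        est = closest_neighbor_intersection(lines)
        # brute-force oracle on a fine grid
        xs = np.arange(-1.0, 4.0, 1e-3)
        ys = np.arange(-1.0, 4.0, 1e-3)
        xg, yg = np.meshgrid(xs, ys)
        total = np.zeros_like(xg)
        for ln in lines:
            total += (ln.a * xg - yg + ln.c) ** 2 / (ln.a**2 + 1.0)
        k = np.unravel_index(np.argmin(total), total.shape)
        assert est.x == pytest.approx(xg[k], abs=2e-3)
        assert est.y == pytest.approx(yg[k], abs=2e-3)
        assert est.residual <= total[k] + 1e-12

    def test_parallel_family_has_no_finite_intersection(self):
        lines = [synthetic_line(1.0, c) for c in (0.0, 1.0, 2.0)]
        est = closest_neighbor_intersection(lines)
        assert not est.finite
        assert math.isnan(est.x)

    def test_uncompetitive_truth_gives_printed_crossing(self, uncompetitive_table):
        est = closest_neighbor_intersection(cornish_bowden_lines(uncompetitive_table))
        assert est.x == pytest.approx(-44.3, rel=1e-6)
        assert est.y == pytest.approx(KM0 * 1e3 / VMAX0, rel=1e-6)
        assert round(est.y, 2) == 2843.73  # the worked-example ordinate


class TestParallelismTest:
    def test_identical_slopes_parallel(self):
        lines = [synthetic_line(1.0, c) for c in (0.0, 1.0, 2.0)]
        assert parallelism_test(lines).parallel

    def test_distinct_slopes_with_tiny_noise_not_parallel(self):
        rng = np.random.default_rng(0)
        lines = [
            synthetic_line(s, 1.0, jitter=1e-6, rng=rng) for s in (1.0, 2.0, 3.0)
        ]
        res = parallelism_test(lines)
        assert not res.parallel
        assert res.p_value < 1e-6

    def test_borderline_matches_permutation_oracle(self):
        # slopes within 1% at 5% proportional point noise: the F verdict
        # should agree with a permutation null of the same statistic in
        # >= 95% of seeds. The oracle permutes the relative residuals of
        # the weighted shared-slope fit (relative residuals are the
        # exchangeable quantity under proportional errors).
        from inhibkin.graphical import parallelism_test as ptest

        def make_line(slope, intercept, rng, npts=5):
            i = np.linspace(0.0, 25.0, npts)
            y = (slope * i + intercept) * (1 + rng.normal(0, 0.05, npts))
            sl, ic = np.polyfit(i, y, 1)
            return SecondaryLine(
                s=10.0, kind="dixon", slope=float(sl), intercept=float(ic),
                se_slope=0.0, se_intercept=0.0, cov_slope_intercept=0.0,
                i_values=i, y_values=y,
            )

        agree = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            lines = [make_line(1.0 + 0.01 * j / 2, 5.0, rng) for j in range(3)]
            res = ptest(lines, alpha=0.05)
            # weighted shared-slope fit, as in the statistic under test
            sxx = sxy = 0.0
            moments = []
            for ln in lines:
                x, y = ln.i_values, ln.y_values
                w = 1.0 / y**2
                xw = np.sum(w * x) / np.sum(w)
                yw = np.sum(w * y) / np.sum(w)
                sxx += np.sum(w * (x - xw) ** 2)
                sxy += np.sum(w * (x - xw) * (y - yw))
                moments.append((x, y, xw, yw))
            b = sxy / sxx
            fitted, rel_resid = [], []
            for x, y, xw, yw in moments:
                f = b * x + (yw - b * xw)
                fitted.append(f)
                rel_resid.append((y - f) / f)
            rel = np.concatenate(rel_resid)
            exceed = 0
            n_perm = 200
            for _ in range(n_perm):
                perm = rng.permutation(rel)
                k = 0
                plines = []
                for ln, f in zip(lines, fitted):
                    y_p = f * (1 + perm[k:k + f.size])
                    k += f.size
                    sl, ic = np.polyfit(ln.i_values, y_p, 1)
                    plines.append(
                        dataclasses.replace(ln, slope=float(sl), intercept=float(ic),
                                            y_values=y_p)
                    )
                exceed += ptest(plines).f_stat >= res.f_stat
            p_perm = (exceed + 1) / (n_perm + 1)
            agree += (p_perm > 0.05) == (res.p_value > 0.05)
        assert agree / n_seeds >= 0.95


class TestClassifier:
    def test_noiseless_uncompetitive_verdict(self, uncompetitive_table):
        zero = mm_fit_at_zero(uncompetitive_table)
        call = classify_mechanism(
            dixon_lines(uncompetitive_table),
            cornish_bowden_lines(uncompetitive_table),
            zero_i_fit=zero,
        )
        assert call.verdict is Mechanism.UNCOMPETITIVE
        assert call.ki_prime == pytest.approx(44.3, rel=1e-6)
        assert math.isinf(call.ki)
        assert call.consistency_pct == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_competitive_verdict(self, competitive_table, competitive_truth):
        call = classify_mechanism(
            dixon_lines(competitive_table), cornish_bowden_lines(competitive_table)
        )
        assert call.verdict is Mechanism.COMPETITIVE
        assert call.ki == pytest.approx(competitive_truth.ki, rel=1e-6)

    def test_noiseless_noncompetitive_verdict(self, noncompetitive_table,
                                              noncompetitive_truth):
        call = classify_mechanism(
            dixon_lines(noncompetitive_table),
            cornish_bowden_lines(noncompetitive_table),
        )
        assert call.verdict is Mechanism.NONCOMPETITIVE
        assert call.ki == pytest.approx(noncompetitive_truth.ki, rel=1e-4)
        assert call.ki_prime == pytest.approx(call.ki)

    def test_noiseless_mixed_verdict(self):
        truth = KineticParameters(km=KM0, vmax=VMAX0, ki=30.0, ki_prime=90.0)
        table = noiseless_table(truth)
        call = classify_mechanism(dixon_lines(table), cornish_bowden_lines(table))
        assert call.verdict is Mechanism.MIXED
        assert call.ki == pytest.approx(30.0, rel=1e-4)
        assert call.ki_prime == pytest.approx(90.0, rel=1e-4)

    def test_sv_lines_concurrent_at_mixed_crossing(self):
        # all S/v lines pass through (-Ki', KM_nM (1 - Ki'/Ki) / Vmax)
        truth = KineticParameters(km=KM0, vmax=VMAX0, ki=30.0, ki_prime=90.0)
        table = noiseless_table(truth)
        x_pred = -90.0
        y_pred = KM0 * 1e3 * (1 - 90.0 / 30.0) / VMAX0
        for ln in cornish_bowden_lines(table):
            assert ln.slope * x_pred + ln.intercept == pytest.approx(y_pred, rel=1e-6)

    def test_verdict_invariant_to_level_order_and_gain(self, uncompetitive_truth):
        table = noiseless_table(uncompetitive_truth)
        shuffled = dataclasses.replace(
            table, data=table.data.sample(frac=1.0, random_state=1)
        )
        rescaled = noiseless_table(uncompetitive_truth, gain=900.0)
        for t in (table, shuffled, rescaled):
            call = classify_mechanism(dixon_lines(t), cornish_bowden_lines(t))
            assert call.verdict is Mechanism.UNCOMPETITIVE
            assert call.ki_prime == pytest.approx(44.3, rel=1e-6)


def mm_fit_at_zero(table):
    sub = table.at_inhibitor(0.0)
    return fit_michaelis_menten(
        sub["S_uM"].to_numpy(float), sub["v_pmol_min_ug"].to_numpy(float), i=0.0
    )


class TestConsistencyCheck:
    def zero_fit(self):
        return MMFitResult(0.0, KM0, 0.0, VMAX0, 0.0, 0.0, 6, True)

    def test_identity_gives_zero(self):
        assert consistency_check(KM0 * 1e3 / VMAX0, self.zero_fit()) == 0.0

    def test_printed_values_reproduce_reported_difference(self):
        # KM/Vmax = 2843.73 min ug vs crossing ordinate 3116.68 min ug
        pct = consistency_check(3116.68, self.zero_fit())
        assert pct == pytest.approx(9.16, abs=5e-3)
        assert pct == pytest.approx(9.15, abs=0.02)  # printed, within rounding

    def test_doubled_ordinate_closed_form(self):
        r = KM0 * 1e3 / VMAX0
        assert consistency_check(2 * r, self.zero_fit()) == pytest.approx(200.0 / 3, rel=1e-9)
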