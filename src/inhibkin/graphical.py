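"""Dixon / substrate-over-velocity discrimination of the inhibition mechanism.

The general inhibitor model rearranges into two families of straight lines
in the inhibitor concentration I, one line per fixed substrate level S:

* Dixon plot, y = 1/v:
  ``1/v = (KM + S)/(Vmax S) + I (KM/Ki + S/Ki') / (Vmax S)``
  — all lines cross at I = -Ki (so parallel lines mean Ki is infinite,
  i.e. an uncompetitive inhibitor);
* substrate-over-velocity plot, y = S/v:
  ``S/v = (KM + S)/Vmax + I (KM/Ki + S/Ki') / Vmax`` (per-line S fixed)
  — all lines cross at I = -Ki' with ordinate KM (1 - Ki'/Ki) / Vmax
  (so parallel lines mean Ki' is infinite, i.e. a competitive inhibitor).

For an uncompetitive inhibitor (Ki infinite) the S/v ordinate at the
crossing is exactly KM/Vmax, which provides an internal consistency check
between the crossing estimate and the uninhibited Michaelis–Menten fit.

With noisy lines there is no single crossing; the common point is
estimated as the closest-neighbour intersection, the (x, y) minimising the
summed squared perpendicular distances to all lines,

    min_{x,y}  sum_i (a_i x + b_i y + c_i)^2 / (a_i^2 + b_i^2),

solved in closed form from the 2x2 normal equations. Parallelism of a line
family is judged by an extra-sum-of-squares F-test (shared slope vs free
slopes) combined with a relative slope-spread guard.

Unit convention: substrate enters the S/v ordinate in nM while v stays in
pmol min^-1 ug^-1, so S/v carries units of min ug; this is the convention
under which KM = 93.9 uM, Vmax = 33.02 pmol min^-1 ug^-1 gives
KM/Vmax = 2843.73 min ug.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Mechanism
from .fitting import MMFitResult
from .rates import RateTable

__all__ = [
    "SecondaryLine",
    "IntersectionEstimate",
    "ParallelismResult",
    "MechanismCall",
    "dixon_lines",
    "cornish_bowden_lines",
    "closest_neighbor_intersection",
    "intersection_se",
    "parallelism_test",
    "classify_mechanism",
    "consistency_check",
]

#: relative slope spread below which lines count as exactly parallel
EXACT_PARALLEL_TOL = 1e-8
#: guard: families whose relative slope spread exceeds this are never
#: declared parallel, whatever the F-test says (protects against gross
#: slope disparity the small-sample F-test might miss; generous because
#: near-zero mean slopes make the relative spread a noisy statistic)
SLOPE_SPREAD_GUARD = 2.0
#: fallback multiplier for the crossing compatibility interval when no
#: residual dof is available (otherwise a t quantile at the pooled dof)
COMPAT_Z = 1.96


@dataclass(frozen=True)
class SecondaryLine:
    """OLS line of a transformed velocity quantity versus I at fixed S.

    Implicit form a x + b y + c = 0 normalised to b = -1, i.e.
    a = slope, c = intercept. ``kind`` is "dixon" (y = 1/v, min ug pmol^-1)
    or "s_over_v" (y = S/v with S in nM, min ug).
    """

    s: float  # uM, the fixed substrate level
    kind: str
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    cov_slope_intercept: float
    i_values: np.ndarray = field(repr=False)
    y_values: np.ndarray = field(repr=False)

    @property
    def a(self) -> float:
        return self.slope

    @property
    def b(self) -> float:
        return -1.0

    @property
    def c(self) -> float:
        return self.intercept


@dataclass(frozen=True)
class IntersectionEstimate:
    """Closest-neighbour intersection of a family of lines."""

    x: float  # uM (NaN when no finite intersection exists)
    y: float
    residual: float  # summed squared perpendicular distances
    n_lines: int
    finite: bool = True


@dataclass(frozen=True)
class ParallelismResult:
    parallel: bool
    f_stat: float
    p_value: float
    slope_spread: float  # (max-min)/mean |slope|
    alpha: float


@dataclass(frozen=True)
class MechanismCall:
    """Classifier verdict with its supporting evidence."""

    verdict: Mechanism
    ki: float  # uM, inf when the EI complex does not form
    ki_prime: float  # uM, inf when the ESI complex does not form
    dixon_parallel: ParallelismResult | None
    sv_parallel: ParallelismResult | None
    intersection_dixon: IntersectionEstimate | None
    intersection_sv: IntersectionEstimate | None
    consistency_pct: float = math.nan


def _fit_lines(table: RateTable, kind: str) -> list[SecondaryLine]:
    df = table.data
    i_levels = np.sort(df["I_uM"].unique())
    if len(i_levels) < 2:
        raise ValueError("secondary plots need >= 2 inhibitor levels")
    lines = []
    for s in np.sort(df["S_uM"].unique()):
        sub = df[np.isclose(df["S_uM"], s)].sort_values("I_uM")
        v = sub["v_pmol_min_ug"].to_numpy(float)
        if np.any(v <= 0):
            warnings.warn(
                f"excluding S={s:g} uM from the {kind} plot: non-positive velocity"
            )
            continue
        i_arr = sub["I_uM"].to_numpy(float)
        y = 1.0 / v if kind == "dixon" else (s * 1e3) / v  # S in nM for S/v
        n = i_arr.size
        if n < 2:
            continue
        res = stats.linregress(i_arr, y)
        # OLS covariance of (slope, intercept)
        sxx = float(np.sum((i_arr - i_arr.mean()) ** 2))
        dof = n - 2
        if dof > 0:
            resid = y - (res.slope * i_arr + res.intercept)
            s2 = float(np.sum(resid**2)) / dof
        else:
            s2 = 0.0
        lines.append(
            SecondaryLine(
                s=float(s),
                kind=kind,
                slope=float(res.slope),
                intercept=float(res.intercept),
                se_slope=math.sqrt(s2 / sxx) if sxx > 0 else math.nan,
                se_intercept=math.sqrt(s2 * (1.0 / n + i_arr.mean() ** 2 / sxx))
                if sxx > 0
                else math.nan,
                cov_slope_intercept=-i_arr.mean() * s2 / sxx if sxx > 0 else math.nan,
                i_values=i_arr,
                y_values=y,
            )
        )
    if len(lines) < 2:
        raise ValueError(f"fewer than 2 usable substrate levels for the {kind} plot")
    return lines


def dixon_lines(table: RateTable) -> list[SecondaryLine]:
    """One OLS line of 1/v versus I per substrate level."""
    return _fit_lines(table, "dixon")


def cornish_bowden_lines(table: RateTable) -> list[SecondaryLine]:
    """One OLS line of S/v (S in nM) versus I per substrate level."""
    return _fit_lines(table, "s_over_v")


def _slope_spread(slopes: np.ndarray) -> float:
    scale = float(np.mean(np.abs(slopes)))
    if scale == 0:
        return 0.0 if np.ptp(slopes) == 0 else math.inf
    return float(np.ptp(slopes)) / scale


def closest_neighbor_intersection(
    lines: list[SecondaryLine], *, parallel_tol: float = EXACT_PARALLEL_TOL
) -> IntersectionEstimate:
    """Point minimising summed squared perpendicular distances to the lines.

    Solves the 2x2 normal equations in closed form. For two non-parallel
    lines this is their exact algebraic intersection (residual 0). A family
    that is mutually parallel (relative slope spread below ``parallel_tol``,
    or a numerically singular normal matrix) yields an explicit
    non-finite result rather than an exception.
    """
    if len(lines) < 2:
        raise ValueError("need >= 2 lines")
    abc = np.array([[ln.a, ln.b, ln.c] for ln in lines], float)
    slopes = abc[:, 0]
    if _slope_spread(slopes) < parallel_tol:
        return IntersectionEstimate(math.nan, math.nan, math.nan, len(lines), finite=False)
    w = 1.0 / (abc[:, 0] ** 2 + abc[:, 1] ** 2)
    ab = abc[:, :2]
    m = (ab * w[:, None]).T @ ab
    rhs = -(ab * w[:, None]).T @ abc[:, 2]
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if not math.isfinite(det) or abs(det) <= 1e-14 * m[0, 0] * m[1, 1]:
        return IntersectionEstimate(math.nan, math.nan, math.nan, len(lines), finite=False)
    xy = np.linalg.solve(m, rhs)
    resid = float(np.sum(w * (ab @ xy + abc[:, 2]) ** 2))
    return IntersectionEstimate(float(xy[0]), float(xy[1]), resid, len(lines))


def intersection_se(
    lines: list[SecondaryLine],
    rng: np.random.Generator,
    *,
    n_boot: int = 200,
) -> tuple[float, float]:
    """Parametric-bootstrap SE of the intersection abscissa and ordinate.

    Each line's (slope, intercept) is resampled from its OLS sampling
    distribution (bivariate normal with the fit covariance); the
    closest-neighbour intersection is recomputed per draw. Lines with an
    undefined covariance (zero residual dof) contribute their point
    estimate unchanged.
    """
    base = np.array([[ln.slope, ln.intercept] for ln in lines])
    covs = []
    for ln in lines:
        if math.isfinite(ln.se_slope) and math.isfinite(ln.se_intercept):
            covs.append(
                np.array(
                    [
                        [ln.se_slope**2, ln.cov_slope_intercept],
                        [ln.cov_slope_intercept, ln.se_intercept**2],
                    ]
                )
            )
        else:
            covs.append(np.zeros((2, 2)))
    xs, ys = [], []
    for _ in range(n_boot):
        draw = np.array(
            [rng.multivariate_normal(base[j], covs[j], method="cholesky")
             if covs[j][0, 0] > 0 else base[j]
             for j in range(len(lines))]
        )
        a = draw[:, 0]
        c = draw[:, 1]
        w = 1.0 / (a**2 + 1.0)
        m00 = float(np.sum(w * a * a))
        m01 = float(np.sum(w * a * -1.0))
        m11 = float(np.sum(w))
        r0 = -float(np.sum(w * a * c))
        r1 = float(np.sum(w * c))
        det = m00 * m11 - m01 * m01
        if abs(det) <= 1e-14 * max(m00 * m11, 1e-300):
            continue
        xs.append((r0 * m11 - m01 * r1) / det)
        ys.append((m00 * r1 - m01 * r0) / det)
    if len(xs) < 2:
        return math.nan, math.nan
    return float(np.std(xs, ddof=1)), float(np.std(ys, ddof=1))


def _ols_lines_matrix(i_arr: np.ndarray, y_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise OLS of y against the shared abscissa: (slopes, intercepts)."""
    xc = i_arr - i_arr.mean()
    sxx = float(np.sum(xc**2))
    slopes = (y_mat * xc).sum(axis=1) / sxx
    intercepts = y_mat.mean(axis=1) - slopes * i_arr.mean()
    return slopes, intercepts


def _intersect_xy(slopes: np.ndarray, intercepts: np.ndarray) -> tuple[float, float] | None:
    w = 1.0 / (slopes**2 + 1.0)
    m00 = float(np.sum(w * slopes * slopes))
    m01 = float(np.sum(w * slopes * -1.0))
    m11 = float(np.sum(w))
    r0 = -float(np.sum(w * slopes * intercepts))
    r1 = float(np.sum(w * intercepts))
    det = m00 * m11 - m01 * m01
    if not math.isfinite(det) or abs(det) <= 1e-14 * max(m00 * m11, 1e-300):
        return None
    return (r0 * m11 - m01 * r1) / det, (m00 * r1 - m01 * r0) / det


def crossing_difference_se(
    dixon: list[SecondaryLine],
    rng: np.random.Generator,
    *,
    n_boot: int = 300,
) -> float:
    """Bootstrap SE of (Dixon crossing x) - (S/v crossing x).

    Both secondary plots are deterministic transforms of the same velocity
    table (the S/v ordinate at a substrate level is just S_nM times the
    Dixon ordinate), so their crossing abscissae are strongly correlated;
    the SE of the difference is estimated by a wild bootstrap on the Dixon
    residuals. Each point's residual, inflated by its leverage
    (HC2-style, residuals understate noise by sqrt(1 - h)), is multiplied
    by an independent standard normal and added back to the fitted line;
    the perturbed ordinates rebuild both line families and both crossings
    per draw. Using per-point residual magnitudes keeps the SE honest
    under heteroscedastic velocity errors. Returns NaN when the lines do
    not share an inhibitor grid.
    """
    i_arr = dixon[0].i_values
    if not all(
        ln.i_values.size == i_arr.size and np.allclose(ln.i_values, i_arr)
        for ln in dixon
    ):
        return math.nan
    if i_arr.size * len(dixon) - 2 * len(dixon) < 1:
        return math.nan
    y = np.vstack([ln.y_values for ln in dixon])
    s_levels = np.array([ln.s for ln in dixon])
    fitted = np.array([ln.slope for ln in dixon])[:, None] * i_arr[None, :] + np.array(
        [ln.intercept for ln in dixon]
    )[:, None]
    n = i_arr.size
    sxx = float(np.sum((i_arr - i_arr.mean()) ** 2))
    leverage = 1.0 / n + (i_arr - i_arr.mean()) ** 2 / sxx
    r_adj = (y - fitted) / np.sqrt(1.0 - leverage)[None, :]
    if not np.any(r_adj):
        return 0.0
    dof = y.size - 2 * len(dixon)
    diffs = []
    for _ in range(n_boot):
        # residual magnitudes are themselves estimates: chi-square scale
        # uncertainty keeps the SE from being anti-conservative
        scale_b = math.sqrt(dof / rng.chisquare(dof))
        y_d = fitted + scale_b * r_adj * rng.standard_normal(y.shape)
        if np.any(y_d <= 0):
            continue
        y_s = (s_levels[:, None] * 1e3) * y_d  # S/v = S_nM * (1/v)
        xd = _intersect_xy(*_ols_lines_matrix(i_arr, y_d))
        xs = _intersect_xy(*_ols_lines_matrix(i_arr, y_s))
        if xd is None or xs is None:
            continue
        diffs.append(xd[0] - xs[0])
    if len(diffs) < 10:
        return math.nan
    return float(np.std(diffs, ddof=1))


def parallelism_test(
    lines: list[SecondaryLine],
    *,
    alpha: float = 0.05,
    spread_guard: float = SLOPE_SPREAD_GUARD,
) -> ParallelismResult:
    """Extra-sum-of-squares F-test of a shared slope across the lines.

    Reduced model: one common slope, per-line intercepts. Full model: free
    slope and intercept per line. Both are fitted by weighted least squares
    with variance-stabilising weights 1/y^2: the secondary-plot ordinates
    (1/v and S/v) inherit near-proportional errors from the velocities, so
    relative residuals restore the homoscedasticity the F reference
    distribution assumes. Lines are declared parallel when the F-test fails
    to reject at ``alpha`` AND the relative spread of the (OLS) slopes
    stays below ``spread_guard``. Degenerate noise-free families are
    decided by the spread alone.
    """
    k = len(lines)
    if k < 2:
        raise ValueError("need >= 2 lines")
    n_total = sum(ln.i_values.size for ln in lines)
    df_full = n_total - 2 * k
    if df_full < 1:
        raise ValueError("not enough points for the free-slope model")
    slopes = np.array([ln.slope for ln in lines])
    spread = _slope_spread(slopes)

    rss_full = 0.0
    sxx_w_sum = sxy_w_sum = 0.0
    per_line = []
    for ln in lines:
        x, y = ln.i_values, ln.y_values
        w = 1.0 / y**2
        xw = float(np.sum(w * x) / np.sum(w))
        yw = float(np.sum(w * y) / np.sum(w))
        sxx_w = float(np.sum(w * (x - xw) ** 2))
        sxy_w = float(np.sum(w * (x - xw) * (y - yw)))
        b_i = sxy_w / sxx_w
        a_i = yw - b_i * xw
        rss_full += float(np.sum(w * (y - b_i * x - a_i) ** 2))
        sxx_w_sum += sxx_w
        sxy_w_sum += sxy_w
        per_line.append((x, y, w, xw, yw))
    b_common = sxy_w_sum / sxx_w_sum
    rss_red = 0.0
    for x, y, w, xw, yw in per_line:
        a_i = yw - b_common * xw
        rss_red += float(np.sum(w * (y - b_common * x - a_i) ** 2))

    if rss_full <= 1e-20 * n_total:  # noise-free family (weighted scale ~ N)
        parallel = spread < EXACT_PARALLEL_TOL
        f_stat = 0.0 if parallel else math.inf
        p = 1.0 if parallel else 0.0
        return ParallelismResult(parallel, f_stat, p, spread, alpha)

    f_stat = ((rss_red - rss_full) / (k - 1)) / (rss_full / df_full)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, k - 1, df_full))
    parallel = spread < EXACT_PARALLEL_TOL or ((p > alpha) and (spread < spread_guard))
    return ParallelismResult(parallel, float(f_stat), p, spread, alpha)


def consistency_check(y_star: float, zero_i_fit: MMFitResult) -> float:
    """Percent difference between the S/v crossing ordinate and KM/Vmax.

    ``r = KM_nM / Vmax`` from the uninhibited Michaelis–Menten fit is the
    ordinate the uncompetitive model predicts for the crossing; returns
    ``100 * |y_star - r| / mean(y_star, r)``.
    """
    r = zero_i_fit.km_app * 1e3 / zero_i_fit.vmax_app
    if r <= 0:
        raise ValueError("non-positive KM/Vmax ratio")
    return 100.0 * abs(y_star - r) / ((y_star + r) / 2.0)


def classify_mechanism(
    dixon: list[SecondaryLine],
    sv: list[SecondaryLine],
    *,
    alpha: float = 0.05,
    zero_i_fit: MMFitResult | None = None,
    rng: np.random.Generator | None = None,
) -> MechanismCall:
    """Rule-table mechanism verdict from the two secondary-plot families.

    * Dixon parallel and S/v crossing at x < 0  ->  uncompetitive,
      Ki' = -x*;
    * S/v parallel and Dixon crossing at x < 0  ->  competitive, Ki = -x*;
    * both families crossing at x < 0 with statistically compatible
      abscissae  ->  noncompetitive (Ki = Ki' = -x*, pooled), otherwise
      mixed (Ki from Dixon, Ki' from S/v);
    * anything else (positive-x crossings, both families parallel, no
      finite intersection)  ->  indeterminate.

    ``rng`` drives the bootstrap SEs used by the compatibility test; the
    consistency percentage is attached whenever the uninhibited fit and an
    S/v crossing are available.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    try:
        d_par = parallelism_test(dixon, alpha=alpha)
        s_par = parallelism_test(sv, alpha=alpha)
    except ValueError as exc:
        warnings.warn(f"parallelism test unavailable ({exc}); verdict indeterminate")
        inter_s_only = closest_neighbor_intersection(sv)
        consistency = math.nan
        if zero_i_fit is not None and inter_s_only.finite:
            consistency = consistency_check(inter_s_only.y, zero_i_fit)
        return MechanismCall(
            verdict=Mechanism.INDETERMINATE,
            ki=math.inf,
            ki_prime=math.inf,
            dixon_parallel=None,
            sv_parallel=None,
            intersection_dixon=None,
            intersection_sv=inter_s_only if inter_s_only.finite else None,
            consistency_pct=consistency,
        )
    inter_d = closest_neighbor_intersection(dixon)
    inter_s = closest_neighbor_intersection(sv)
    i_scale = float(np.max(np.abs(np.concatenate([ln.i_values for ln in dixon]))))

    verdict, ki, kip = Mechanism.INDETERMINATE, math.inf, math.inf
    if d_par.parallel and not s_par.parallel:
        if inter_s.finite and inter_s.x < 0:
            verdict, kip = Mechanism.UNCOMPETITIVE, -inter_s.x
    elif s_par.parallel and not d_par.parallel:
        if inter_d.finite and inter_d.x < 0:
            verdict, ki = Mechanism.COMPETITIVE, -inter_d.x
    elif not d_par.parallel and not s_par.parallel:
        if inter_d.finite and inter_s.finite and inter_d.x < 0 and inter_s.x < 0:
            se_delta = crossing_difference_se(dixon, rng)
            dof = sum(ln.i_values.size for ln in dixon) - 2 * len(dixon)
            crit = float(stats.t.ppf(0.975, dof)) if dof >= 1 else COMPAT_Z
            if not math.isfinite(se_delta):  # no shared I grid: independent SEs
                se_d, _ = intersection_se(dixon, rng)
                se_s, _ = intersection_se(sv, rng)
                se_delta = math.hypot(
                    se_d if math.isfinite(se_d) else 0.0,
                    se_s if math.isfinite(se_s) else 0.0,
                )
            if abs(inter_d.x - inter_s.x) <= crit * se_delta + 1e-6 * max(i_scale, 1.0):
                pooled = -(inter_d.x + inter_s.x) / 2.0
                verdict, ki, kip = Mechanism.NONCOMPETITIVE, pooled, pooled
            else:
                verdict, ki, kip = Mechanism.MIXED, -inter_d.x, -inter_s.x

    consistency = math.nan
    if zero_i_fit is not None and inter_s.finite:
        consistency = consistency_check(inter_s.y, zero_i_fit)
    return MechanismCall(
        verdict=verdict,
        ki=ki,
        ki_prime=kip,
        dixon_parallel=d_par,
        sv_parallel=s_par,
        intersection_dixon=inter_d if inter_d.finite else None,
        intersection_sv=inter_s if inter_s.finite else None,
        consistency_pct=consistency,
    )
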