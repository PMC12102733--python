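"""Nonlinear least-squares fits of the kinetic models.

Two fitting surfaces:

* per inhibitor level — Michaelis–Menten fit of v(S) at each I, yielding
  the apparent constants (KM_app, Vmax_app) with covariance-based SEs,
  the table a kinetics paper prints;
* global — the general inhibitor model fitted across all (S, I)
  simultaneously under a fixed mechanism hypothesis, with only the
  inhibition constants that mechanism allows as free parameters
  (an infinite constant is structurally absent, never fitted to a bound).

Start values come from the Hanes linearisation (S/v vs S is a line with
slope 1/Vmax and intercept KM/Vmax), a deterministic, derivative-free
initialisation. Fits are unweighted by default; 1/SEM^2 weighting is
optional. Mechanisms are compared by small-sample-corrected AIC, reported
as a diagnostic only — the mechanism verdict belongs to the graphical
method in :mod:`inhibkin.graphical`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .core import KineticParameters, Mechanism, mm_velocity
from .rates import RateTable

__all__ = [
    "MMFitResult",
    "GlobalFitResult",
    "hanes_start",
    "fit_michaelis_menten",
    "fit_per_inhibitor_series",
    "fit_global_inhibition",
]

#: relative standard error above which a constant is flagged unidentifiable
UNIDENTIFIABLE_REL_SE = 1e3


@dataclass(frozen=True)
class MMFitResult:
    """Apparent Michaelis–Menten constants at one inhibitor level."""

    i: float  # uM
    km_app: float  # uM
    km_se: float
    vmax_app: float  # pmol min^-1 ug^-1
    vmax_se: float
    residual_ss: float
    n_points: int
    converged: bool

    def as_row(self) -> dict:
        return {
            "I_uM": self.i,
            "KM_app_uM": self.km_app,
            "KM_se": self.km_se,
            "Vmax_app": self.vmax_app,
            "Vmax_se": self.vmax_se,
            "residual_ss": self.residual_ss,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class GlobalFitResult:
    """General inhibitor model fitted under one mechanism hypothesis."""

    mechanism: Mechanism
    params: KineticParameters
    ses: dict  # parameter name -> SE (free parameters only)
    residual_ss: float
    aic_c: float
    n_points: int
    converged: bool
    unidentifiable: tuple[str, ...] = ()


def hanes_start(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """(KM, Vmax) start values from the Hanes line S/v = S/Vmax + KM/Vmax.

    Falls back to (median S, 1.2 * max v) when the linearisation yields
    non-positive estimates (heavy noise or degenerate data).
    """
    pos = v > 0
    fallback = (float(np.median(s)), 1.2 * float(np.max(v)))
    if pos.sum() < 2:
        return fallback
    slope, intercept = np.polyfit(s[pos], s[pos] / v[pos], 1)
    if slope <= 0 or intercept <= 0:
        return fallback
    return float(intercept / slope), float(1.0 / slope)


def _aicc(n: int, k: int, ss: float) -> float:
    """Small-sample-corrected AIC for Gaussian residuals with SS ``ss``."""
    if n <= k + 1:
        return math.inf
    ss = max(ss, 1e-300)
    return n * math.log(ss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_michaelis_menten(
    s: np.ndarray,
    v: np.ndarray,
    *,
    i: float = 0.0,
    weights: np.ndarray | None = None,
) -> MMFitResult:
    """Nonlinear least squares of v = Vmax*S/(KM+S).

    Requires >= 3 distinct S > 0 levels; raises on all-zero velocities or
    non-convergence.
    """
    s = np.asarray(s, float)
    v = np.asarray(v, float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite rate data")
    if len(np.unique(s[s > 0])) < 3:
        raise ValueError("need >= 3 distinct substrate levels with S > 0")
    if np.allclose(v, 0):
        raise ValueError("all velocities are zero; nothing to fit")
    km0, vmax0 = hanes_start(s, v)
    model = lmfit.Model(mm_velocity, independent_vars=["s"])
    pars = model.make_params(km=dict(value=km0, min=1e-12), vmax=dict(value=vmax0, min=1e-12))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(v, pars, s=s, weights=weights)
    if not fit.success:
        raise RuntimeError(
            f"Michaelis-Menten fit failed (start KM={km0:.4g}, Vmax={vmax0:.4g}): "
            f"{fit.message}"
        )
    km, vmax = fit.params["km"], fit.params["vmax"]
    return MMFitResult(
        i=float(i),
        km_app=float(km.value),
        km_se=float(km.stderr) if km.stderr is not None else math.nan,
        vmax_app=float(vmax.value),
        vmax_se=float(vmax.stderr) if vmax.stderr is not None else math.nan,
        residual_ss=float(np.sum(fit.residual**2)),
        n_points=int(s.size),
        converged=bool(fit.success),
    )


def fit_per_inhibitor_series(
    table: RateTable, *, weighted: bool = False
) -> list[MMFitResult]:
    """One Michaelis–Menten fit per inhibitor level, ordered by I."""
    out = []
    for i in table.i_levels:
        sub = table.at_inhibitor(i)
        w = None
        if weighted:
            sem = sub["sem"].to_numpy(float)
            w = np.where(sem > 0, 1.0 / np.maximum(sem, 1e-300), 0.0)
            if not np.any(w > 0):
                w = None
        out.append(
            fit_michaelis_menten(
                sub["S_uM"].to_numpy(float),
                sub["v_pmol_min_ug"].to_numpy(float),
                i=float(i),
                weights=w,
            )
        )
    return out


def _hc3_ses(predict, values: np.ndarray, v: np.ndarray) -> np.ndarray | None:
    """HC3 sandwich standard errors for an unweighted nonlinear LS fit.

    Velocity errors in these assays are typically closer to proportional
    than homoscedastic, which makes the classical covariance of an
    unweighted fit anti-conservative; the leverage-adjusted sandwich
    (residual^2 / (1-h)^2 on the meat diagonal) restores near-nominal
    Wald-interval coverage without assuming a variance model.
    """
    n, p = v.size, values.size
    if n <= p:
        return None
    jac = np.empty((n, p))
    for j in range(p):
        dp = np.zeros(p)
        dp[j] = 1e-6 * max(abs(values[j]), 1.0)
        jac[:, j] = (predict(values + dp) - predict(values - dp)) / (2 * dp[j])
    resid = v - predict(values)
    try:
        bread = np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return None
    leverage = np.clip(np.einsum("ij,jk,ik->i", jac, bread, jac), 0.0, 1.0 - 1e-8)
    meat = (jac.T * (resid**2 / (1.0 - leverage) ** 2)) @ jac
    cov = bread @ meat @ bread
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


_FREE_CONSTANTS = {
    Mechanism.NONE: (),
    Mechanism.COMPETITIVE: ("ki",),
    Mechanism.UNCOMPETITIVE: ("ki_prime",),
    Mechanism.NONCOMPETITIVE: ("ki",),  # ki' tied equal to ki
    Mechanism.MIXED: ("ki", "ki_prime"),
}


def fit_global_inhibition(
    table: RateTable,
    mechanism: Mechanism,
    *,
    weighted: bool = False,
) -> GlobalFitResult:
    """Fit the general inhibitor model across all (S, I) at once.

    The mechanism hypothesis fixes the free parameters: KM and Vmax always;
    Ki for competitive, Ki' for uncompetitive, a single shared constant for
    noncompetitive, both for mixed, neither for none. Terms belonging to an
    infinite constant are removed from the model expression. Requires at
    least two inhibitor levels including I = 0 whenever an inhibition
    constant is free.
    """
    free = _FREE_CONSTANTS[mechanism]
    i_levels = table.i_levels
    if free:
        if len(i_levels) < 2 or not np.any(np.isclose(i_levels, 0.0)):
            raise ValueError(
                "global inhibitor fit needs >= 2 inhibitor levels including I = 0"
            )
    df = table.data
    s = df["S_uM"].to_numpy(float)
    i_arr = df["I_uM"].to_numpy(float)
    v = df["v_pmol_min_ug"].to_numpy(float)
    weights = None
    if weighted:
        sem = df["sem"].to_numpy(float)
        weights = np.where(sem > 0, 1.0 / np.maximum(sem, 1e-300), 0.0)
        if not np.any(weights > 0):
            weights = None

    shared = mechanism is Mechanism.NONCOMPETITIVE

    def model_fn(s, i, km, vmax, ki=math.inf, ki_prime=math.inf):
        kp = ki if shared else ki_prime
        fe = 1.0 + i / ki if "ki" in free else 1.0
        fs = 1.0 + i / kp if (shared or "ki_prime" in free) else 1.0
        return vmax * s / (km * fe + s * fs)

    km0, vmax0 = hanes_start(s[np.isclose(i_arr, 0)], v[np.isclose(i_arr, 0)])
    model = lmfit.Model(model_fn, independent_vars=["s", "i"])
    pars = model.make_params(km=dict(value=km0, min=1e-12), vmax=dict(value=vmax0, min=1e-12))
    i_scale = float(np.max(i_arr)) or 1.0
    for name in ("ki", "ki_prime"):
        if name in free:
            pars.add(name, value=2 * i_scale, min=1e-9)
        else:
            pars.add(name, value=math.inf, vary=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(v, pars, s=s, i=i_arr, weights=weights)
    if not fit.success:
        raise RuntimeError(f"global {mechanism.value} fit failed: {fit.message}")

    free_names = ["km", "vmax", *free]
    robust = None
    if weights is None:
        robust = _hc3_ses(
            lambda vals: model_fn(s, i_arr, **dict(zip(free_names, vals))),
            np.array([fit.params[n].value for n in free_names]),
            v,
        )
    ses, flagged = {}, []
    for j, name in enumerate(free_names):
        par = fit.params[name]
        if robust is not None and math.isfinite(robust[j]):
            se = float(robust[j])
        else:
            se = float(par.stderr) if par.stderr is not None else math.nan
        ses[name] = se
        if math.isfinite(se) and par.value != 0 and se / abs(par.value) > UNIDENTIFIABLE_REL_SE:
            flagged.append(name)
    ki_val = float(fit.params["ki"].value) if "ki" in free else math.inf
    kp_val = (
        ki_val
        if shared
        else (float(fit.params["ki_prime"].value) if "ki_prime" in free else math.inf)
    )
    ss = float(np.sum(fit.residual**2))
    n_free = 2 + len(free)
    return GlobalFitResult(
        mechanism=mechanism,
        params=KineticParameters(
            km=float(fit.params["km"].value),
            vmax=float(fit.params["vmax"].value),
            ki=ki_val,
            ki_prime=kp_val,
        ),
        ses=ses,
        residual_ss=ss,
        aic_c=_aicc(int(v.size), n_free, ss),
        n_points=int(v.size),
        converged=True,
        unidentifiable=tuple(flagged),
    )
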