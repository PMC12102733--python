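"""Initial-rate extraction: progress curves -> specific-activity table.

Reaction rates are taken as ordinary least-squares slopes of fluorescence
versus time (the whole trace by default, since the assay consumes well
under 1% of the substrate over the run; a sub-window and an R^2 curvature
guard are available for less gentle regimes). Slopes are blank-corrected
using the S = 0 wells at the same inhibitor level, converted to specific
activity

    v [pmol min^-1 ug^-1] = slope [AU s^-1] * 60 / (gain * enzyme_mass)

and aggregated over replicates as mean +/- SEM, the exchange object for
all downstream fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assay import PlateRead

__all__ = [
    "LinearFit",
    "RateTable",
    "fit_initial_rate",
    "to_specific_activity",
    "build_rate_table",
    "write_rate_csv",
    "read_rate_csv",
]

RATE_COLUMNS = ["S_uM", "I_uM", "v_pmol_min_ug", "sem", "n"]


@dataclass(frozen=True)
class LinearFit:
    """OLS line through a progress curve: slope in AU s^-1."""

    slope: float
    intercept: float
    stderr: float  # standard error of the slope
    r_squared: float
    n_points: int


@dataclass
class RateTable:
    """Aggregated initial velocities v(S, I) with replicate SEMs.

    ``data`` columns: S_uM, I_uM, v_pmol_min_ug, sem, n, r2_min (worst
    replicate R^2, NaN when the table was read from a pre-computed CSV).
    At most one row per (S, I).
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.data.duplicated(subset=["S_uM", "I_uM"]).any():
            raise ValueError("duplicate (S, I) cells in rate table")

    @property
    def s_levels(self) -> np.ndarray:
        return np.sort(self.data["S_uM"].unique())

    @property
    def i_levels(self) -> np.ndarray:
        return np.sort(self.data["I_uM"].unique())

    def at_inhibitor(self, i: float) -> pd.DataFrame:
        return self.data[np.isclose(self.data["I_uM"], i)].sort_values("S_uM")


def fit_initial_rate(
    curve: PlateRead, window: tuple[float, float] | None = None
) -> LinearFit:
    """OLS slope of fluorescence vs time over ``window`` (s), default all reads.

    Raises ``ValueError`` with fewer than 3 reads in the window or zero
    time variance.
    """
    t, f = curve.times, curve.fluorescence
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, f = t[mask], f[mask]
    if t.size < 3:
        raise ValueError(
            f"well {curve.well_id}: {t.size} reads in window, need >= 3"
        )
    if np.ptp(t) == 0:
        raise ValueError(f"well {curve.well_id}: zero time variance")
    res = stats.linregress(t, f)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=int(t.size),
    )


def to_specific_activity(slope: float, gain: float, enzyme_mass: float) -> float:
    """AU s^-1 -> pmol min^-1 ug^-1 via the detector gain and enzyme load."""
    if gain <= 0 or enzyme_mass <= 0:
        raise ValueError("gain and enzyme_mass must be positive")
    return slope * 60.0 / (gain * enzyme_mass)


def build_rate_table(
    plate: list[PlateRead],
    gain: float,
    enzyme_mass: float,
    *,
    window: tuple[float, float] | None = None,
    r2_threshold: float = 0.98,
    provenance: str = "",
) -> RateTable:
    """Extract the blank-corrected rate table from a plate.

    S = 0 wells are consumed as blanks: at each inhibitor level the mean
    blank slope is subtracted from every signal slope before conversion to
    specific activity (slope-level correction — only slopes matter
    downstream, and it is insensitive to baseline offsets). Missing blanks
    produce a warning and no correction. Replicates aggregate as
    mean +/- SEM (SEM = 0 for a single replicate). A replicate R^2 below
    ``r2_threshold`` triggers a curvature warning but keeps the well.
    """
    if not plate:
        raise ValueError("empty plate")
    fits = {
        (w.s_nominal, w.i_nominal, w.replicate): fit_initial_rate(w, window)
        for w in plate
    }
    blank_slope: dict[float, float] = {}
    for i in sorted({w.i_nominal for w in plate}):
        blanks = [f.slope for (s, wi, _), f in fits.items() if wi == i and s == 0]
        if blanks:
            blank_slope[i] = float(np.mean(blanks))

    rows = []
    signal_cells = sorted(
        {(w.s_nominal, w.i_nominal) for w in plate if w.s_nominal > 0}
    )
    if not signal_cells:
        warnings.warn("plate contains only blanks; rate table is empty")
    n_per_cell = set()
    for s, i in signal_cells:
        cell = [f for (ws, wi, _), f in fits.items() if ws == s and wi == i]
        if i not in blank_slope:
            warnings.warn(f"no S=0 blanks at I={i:g} uM; slopes not blank-corrected")
        corr = blank_slope.get(i, 0.0)
        v = np.array([to_specific_activity(f.slope - corr, gain, enzyme_mass) for f in cell])
        r2_min = min(f.r_squared for f in cell)
        if r2_min < r2_threshold:
            warnings.warn(
                f"curvature: worst replicate R^2 {r2_min:.4f} < {r2_threshold} "
                f"at S={s:g}, I={i:g}"
            )
        sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        n_per_cell.add(v.size)
        rows.append(
            {
                "S_uM": s,
                "I_uM": i,
                "v_pmol_min_ug": float(np.mean(v)),
                "sem": sem,
                "n": v.size,
                "r2_min": r2_min,
            }
        )
    if len(n_per_cell) > 1:
        warnings.warn(f"inconsistent replicate counts across cells: {sorted(n_per_cell)}")
    return RateTable(data=pd.DataFrame(rows), provenance=provenance)


def write_rate_csv(table: RateTable, path) -> None:
    table.data[["S_uM", "I_uM", "v_pmol_min_ug", "sem", "n"]].to_csv(
        path, index=False, float_format="%.10g"
    )


def read_rate_csv(path) -> RateTable:
    """Entry point for user-supplied pre-computed rates."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty rate CSV: {path}") from exc
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate CSV {path} missing columns: {missing}")
    df = df.copy()
    df["r2_min"] = np.nan
    return RateTable(data=df[RATE_COLUMNS + ["r2_min"]], provenance=str(path))
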