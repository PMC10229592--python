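"""Plate-reader analysis for whole-cell fluorescent reporter strains.

Raw plate-reader channels are a fluorescence signal (arbitrary units) and
optical density (OD600) per well over time.  Dividing fluorescence by OD
gives the average per-cell signal; ratios between treated and untreated
wells give reporter fold changes.  Dose-response (transfer) curves are
characterized by the four-parameter Hill equation

    y(c) = y_min + (y_max - y_min) * c^n / (K_M^n + c^n),

where K_M (half-maximal/Michaelis constant, in analyte concentration
units) sets sensitivity and n (Hill coefficient, dimensionless) sets
steepness; repressed reporters are fit with y_max < y_min.  Its closed-form
inverse turns an observed signal back into an analyte concentration
estimate, valid strictly between the two asymptotes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PlateTimeSeries",
    "HillFit",
    "per_cell_signal",
    "reporter_fold_change",
    "max_fold_change_timepoint",
    "hill",
    "fit_hill",
    "invert_hill",
    "growth_stats",
    "compound_correlation",
]


@dataclass
class PlateTimeSeries:
    """Fluorescence and OD600 time courses for a set of wells."""

    gfp: np.ndarray  # wells x timepoints, arbitrary fluorescence units
    od600: np.ndarray  # wells x timepoints, positive
    time_h: np.ndarray
    well_meta: pd.DataFrame  # columns: well, strain, compound, concentration_uM, replicate

    def __post_init__(self) -> None:
        self.gfp = np.asarray(self.gfp, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.time_h = np.asarray(self.time_h, dtype=float)
        if self.gfp.shape != self.od600.shape:
            raise ValueError("gfp and od600 shapes differ")
        if self.gfp.shape[1] != self.time_h.size:
            raise ValueError("time axis length mismatch")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @classmethod
    def from_long_csv(cls, plate_path, map_path) -> "PlateTimeSeries":
        """Build from a long-format plate CSV (well, time_h, od600, gfp)
        and a well map CSV (well, strain, compound, concentration_uM,
        replicate)."""
        plate = pd.read_csv(plate_path)
        well_map = pd.read_csv(map_path)
        gfp = plate.pivot(index="well", columns="time_h", values="gfp")
        od = plate.pivot(index="well", columns="time_h", values="od600")
        od = od.loc[gfp.index, gfp.columns]
        meta = well_map.set_index("well").loc[gfp.index].reset_index()
        return cls(
            gfp=gfp.to_numpy(),
            od600=od.to_numpy(),
            time_h=gfp.columns.to_numpy(dtype=float),
            well_meta=meta,
        )


@dataclass
class HillFit:
    """Fitted 4-parameter Hill transfer curve for one reporter."""

    y_min: float
    y_max: float
    K_M: float
    n: float
    residual_sse: float
    converged: bool = True
    boundary_flag: bool = False


def per_cell_signal(
    plate: PlateTimeSeries, od_min: float | None = None
) -> np.ndarray:
    """Average per-cell fluorescence: gfp / od600, elementwise.

    Points where the culture has died or evaporated (OD below ``od_min``)
    are masked to NaN so they do not enter downstream statistics.
    """
    if np.any(plate.od600 <= 0):
        raise ValueError("od600 must be positive wherever per-cell signal is computed")
    out = plate.gfp / plate.od600
    if od_min is not None:
        out = np.where(plate.od600 >= od_min, out, np.nan)
    return out


def reporter_fold_change(
    treated: np.ndarray,
    control: np.ndarray,
    treated_sd: np.ndarray | None = None,
    control_sd: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Elementwise treated/control per-cell signal ratio at matched times.

    If per-series standard deviations are supplied (replicate spread), the
    ratio's uncertainty is propagated to first order (delta method):

        sd(f)^2 ~ f^2 * [(sd_t / t)^2 + (sd_c / c)^2].
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValueError("treated/control shape mismatch")
    fc = treated / control
    sd = None
    if treated_sd is not None and control_sd is not None:
        sd = np.abs(fc) * np.sqrt(
            (np.asarray(treated_sd) / treated) ** 2
            + (np.asarray(control_sd) / control) ** 2
        )
    return fc, sd


def max_fold_change_timepoint(fc: np.ndarray) -> int:
    """Index of maximal fold change; ties resolve to the earliest time."""
    fc = np.asarray(fc, dtype=float)
    return int(np.nanargmax(fc))


def hill(c, y_min: float, y_max: float, K_M: float, n: float):
    """Four-parameter Hill transfer curve."""
    c = np.asarray(c, dtype=float)
    cn = np.power(c, n, where=c > 0, out=np.zeros_like(c, dtype=float))
    return y_min + (y_max - y_min) * cn / (K_M**n + cn)


def fit_hill(
    concentrations: np.ndarray,
    responses: np.ndarray,
    weights: np.ndarray | None = None,
    n_bounds: tuple[float, float] = (0.05, 20.0),
    multistarts: int = 16,
) -> HillFit:
    """Bounded nonlinear least-squares Hill fit with multi-start.

    Hill fits are multi-modal in (K_M, n); 16 starts over log-spaced K_M
    within the measured concentration range and n in [0.5, 10] are refined
    and the lowest-SSE solution returned.  The response direction is free:
    repressed reporters converge to y_max < y_min.  A fit whose K_M lands
    on the search boundary is flagged as poorly constrained.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations (4 parameters)")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    pos = c[c > 0]
    k_lo, k_hi = pos.min() / 10.0, pos.max() * 10.0
    span = y.max() - y.min()
    lb = [y.min() - 10 * span - 1, y.min() - 10 * span - 1, k_lo, n_bounds[0]]
    ub = [y.max() + 10 * span + 1, y.max() + 10 * span + 1, k_hi, n_bounds[1]]

    def residuals(theta):
        return w * (hill(c, *theta) - y)

    n_k = max(multistarts // 4, 1)
    k_grid = np.geomspace(pos.min(), pos.max(), n_k)
    n_grid = np.geomspace(0.5, 10.0, max(multistarts // n_k, 1))
    best = None
    for k0 in k_grid:
        for n0 in n_grid:
            x0 = np.clip([y.min(), y.max(), k0, n0], lb, ub)
            try:
                sol = optimize.least_squares(residuals, x0, bounds=(lb, ub))
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("Hill fit failed from every start")
    y_min_f, y_max_f, km, nn = best.x
    boundary = bool(km <= k_lo * 1.001 or km >= k_hi * 0.999)
    return HillFit(
        y_min=float(y_min_f),
        y_max=float(y_max_f),
        K_M=float(km),
        n=float(nn),
        residual_sse=float(2 * best.cost),
        converged=bool(best.success),
        boundary_flag=boundary,
    )


def invert_hill(fit: HillFit, y_observed: float) -> float:
    """Closed-form Hill inverse: the concentration reproducing a signal.

    c = K_M * ((y - y_min) / (y_max - y))^(1/n).  ``y_observed`` must lie
    strictly between the asymptotes; outside that range the signal is
    saturated and the concentration is not identifiable (raises).
    """
    lo, hi = sorted((fit.y_min, fit.y_max))
    if not lo < y_observed < hi:
        raise ValueError(
            f"signal {y_observed} outside the responsive range ({lo}, {hi}); "
            "reporter saturated"
        )
    ratio = (y_observed - fit.y_min) / (fit.y_max - y_observed)
    return float(fit.K_M * ratio ** (1.0 / fit.n))


def growth_stats(
    od_series: np.ndarray,
    time_h: np.ndarray,
    min_points: int = 3,
    r2_threshold: float = 0.99,
) -> dict:
    """Growth rate and doubling time from an OD600 time course.

    The exponential phase is detected as the longest contiguous window
    whose log-OD linear regression reaches R^2 >= ``r2_threshold``; the
    growth rate is that regression's slope (positive during growth), and
    the doubling time is ln(2)/rate.  The endpoint formula
    ln(OD_final/OD_initial)/(t_final - t_initial) over the same window is
    reported alongside for comparison.  A flat culture returns rate 0 with
    an undefined doubling time flag.
    """
    od = np.asarray(od_series, dtype=float)
    t = np.asarray(time_h, dtype=float)
    if np.any(od <= 0):
        raise ValueError("OD must be positive to take logarithms")
    log_od = np.log(od)
    best = None  # (length, start, stop, slope)
    n = od.size
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            res = stats.linregress(t[i:j], log_od[i:j])
            if res.rvalue**2 >= r2_threshold:
                if best is None or (j - i) > best[0]:
                    best = (j - i, i, j, res.slope)
    if best is None or abs(best[3]) < 1e-12:
        return {
            "growth_rate_per_h": 0.0,
            "doubling_time_h": np.nan,
            "endpoint_rate_per_h": 0.0,
            "exponential_window": None,
            "doubling_defined": False,
        }
    _, i, j, slope = best
    endpoint = (log_od[j - 1] - log_od[i]) / (t[j - 1] - t[i])
    return {
        "growth_rate_per_h": float(slope),
        "doubling_time_h": float(np.log(2) / slope),
        "endpoint_rate_per_h": float(endpoint),
        "exponential_window": (int(i), int(j - 1)),
        "doubling_defined": True,
    }


def compound_correlation(
    fc_reference: np.ndarray, fc_other: np.ndarray
) -> np.ndarray:
    """Per-reporter Pearson correlation between two fold-change responses.

    Row i of each matrix is one reporter's fold-change time course; the
    result is the vector of row-wise correlations (specificity: how closely
    the response to another compound tracks the reference response).
    """
    A = np.asarray(fc_reference, dtype=float)
    B = np.asarray(fc_other, dtype=float)
    if A.shape != B.shape:
        raise ValueError("response matrices must have matched shapes")
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = np.sum(A * B, axis=1)
    den = np.sqrt(np.sum(A**2, axis=1) * np.sum(B**2, axis=1))
    return num / den


def transfer_curve(
    plate: PlateTimeSeries,
    strain: str,
    compound: str,
    timepoint: int | None = None,
    od_min: float | None = None,
) -> pd.DataFrame:
    """Replicate-mean dose-response table (concentration, mean, sd) for one
    strain/compound, evaluated at ``timepoint`` (default: the time of
    maximal fold change of the highest dose relative to zero dose)."""
    sig = per_cell_signal(plate, od_min=od_min)
    meta = plate.well_meta
    mask = (meta["strain"] == strain) & (meta["compound"] == compound)
    sub = meta[mask]
    concs = np.sort(sub["concentration_uM"].unique())
    if timepoint is None:
        hi, lo = concs.max(), concs.min()
        hi_mean = sig[sub.index[sub["concentration_uM"] == hi]].mean(axis=0)
        lo_mean = sig[sub.index[sub["concentration_uM"] == lo]].mean(axis=0)
        fc, _ = reporter_fold_change(hi_mean, lo_mean)
        timepoint = max_fold_change_timepoint(fc)
    rows = []
    for conc in concs:
        vals = sig[sub.index[sub["concentration_uM"] == conc], timepoint]
        rows.append(
            {
                "concentration_uM": conc,
                "mean": float(np.nanmean(vals)),
                "sd": float(np.nanstd(vals, ddof=1)) if vals.size > 1 else 0.0,
                "timepoint": timepoint,
            }
        )
    return pd.DataFrame(rows)
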