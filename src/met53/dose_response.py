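"""Crystal-violet viability normalization, four-parameter-logistic (4PL)
IC50 estimation, and caliper tumor-volume growth analysis.

The dose-response model is

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

fit by least squares on log10 concentration.  ``ic50`` is the curve's
inflection concentration (the relative IC50, as in standard 4PL usage); the
concentration at which the curve crosses absolute 50% viability is exposed as
a derived quantity.  Vehicle (concentration 0) wells anchor the viability
normalization (vehicle mean = 100%) and are excluded from the fit.

Caliper tumor volumes use V = A * B^2 / 2 with A the largest and B the
smallest diameter (mm), giving mm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError
from .stratification_survival import compare_scores

__all__ = [
    "DoseResponseTable",
    "DoseResponseFit",
    "normalize_viability",
    "four_pl",
    "fit_4pl",
    "tumor_volume",
    "growth_endpoint_test",
]


@dataclass
class DoseResponseTable:
    """Well-level OD readings: columns concentration (uM, 0 = vehicle), od,
    and optional cell_line / drug labels."""

    table: pd.DataFrame

    REQUIRED = ("concentration", "od")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"dose-response table missing columns: {missing}")
        if (self.table["concentration"] < 0).any():
            raise ValidationError("negative concentrations")


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    rss: float
    converged: bool
    degenerate: bool = False
    n_points: int = 0

    @property
    def absolute_ic50(self) -> float:
        """Concentration where the fitted curve crosses 50% viability,
        NaN if 50% lies outside (bottom, top)."""
        if not (min(self.bottom, self.top) < 50.0 < max(self.bottom, self.top)):
            return float("nan")
        frac = (self.top - self.bottom) / (50.0 - self.bottom) - 1.0
        return float(self.ic50 * frac ** (1.0 / self.hill))


def normalize_viability(table: DoseResponseTable) -> pd.DataFrame:
    """Percent viability per well: 100 * OD / mean(vehicle OD).

    Requires at least one vehicle (concentration 0) well with positive mean
    OD; vehicle wells average to 100 by construction.
    """
    df = table.table
    vehicle = df.loc[df["concentration"] == 0, "od"]
    if vehicle.empty:
        raise ValidationError("no vehicle (concentration 0) wells")
    ref = float(vehicle.mean())
    if ref == 0:
        raise ValidationError("vehicle mean OD is zero")
    out = df.copy()
    out["viability"] = 100.0 * out["od"] / ref
    return out


def four_pl(c: np.ndarray, bottom: float, top: float, hill: float, ic50: float) -> np.ndarray:
    """4PL response at concentrations ``c`` (decreasing for hill > 0)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def _4pl_logc(logc, bottom, top, hill, log_ic50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_4pl(
    concentrations: Sequence[float],
    viability: Sequence[float],
    init: tuple[float, float, float, float] | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 concentration.

    Initialization is deterministic: top = max(v), bottom = min(v), hill = 1,
    ic50 = geometric median of the positive concentrations; a small fixed grid
    of restarts over hill and ic50 guards against local minima.  Zero
    concentrations are rejected (vehicle wells belong to normalization, not
    the fit).  Non-convergence or an unidentifiable flat response yields a
    flagged result, not an exception.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability, dtype=float)
    if c.shape != v.shape:
        raise ValidationError("concentration and viability lengths differ")
    if (c <= 0).any():
        raise ValidationError(
            "fit_4pl expects positive concentrations only; drop vehicle wells"
        )
    if len(np.unique(c)) < 4:
        raise ValidationError("at least 4 distinct positive concentrations required")

    logc = np.log10(c)
    span = float(v.max() - v.min())
    if span < 1e-9:
        return DoseResponseFit(
            bottom=float(v.min()), top=float(v.max()), hill=float("nan"),
            ic50=float("nan"), rss=0.0, converged=False, degenerate=True,
            n_points=c.size,
        )

    if init is not None:
        starts = [(init[0], init[1], init[2], np.log10(init[3]))]
    else:
        mid = float(np.median(logc))
        starts = [(float(v.min()), float(v.max()), 1.0, mid)]
        for h0 in (0.5, 2.0):
            starts.append((float(v.min()), float(v.max()), h0, mid))
        for q in (0.25, 0.75):
            starts.append(
                (float(v.min()), float(v.max()), 1.0, float(np.quantile(logc, q)))
            )

    best = None
    for b0, t0, h0, lx0 in starts:
        try:
            popt, _ = curve_fit(
                _4pl_logc, logc, v,
                p0=[b0, t0, h0, lx0],
                bounds=([-np.inf, -np.inf, 1e-3, logc.min() - 6],
                        [np.inf, np.inf, 50.0, logc.max() + 6]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = v - _4pl_logc(logc, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best[1]:
            best = (popt, rss)
        if rss <= 1e-16 * max(1.0, float(v @ v)):
            break

    if best is None:
        return DoseResponseFit(
            bottom=float("nan"), top=float("nan"), hill=float("nan"),
            ic50=float("nan"), rss=float("nan"), converged=False,
            n_points=c.size,
        )
    (bottom, top, hill, log_ic50), rss = best
    if bottom > top:  # canonical orientation: report bottom <= top
        bottom, top, hill = top, bottom, -hill
    degenerate = bool(abs(top - bottom) < 1e-6 * max(1.0, abs(top)))
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), hill=float(hill),
        ic50=float(10.0 ** log_ic50), rss=rss, converged=True,
        degenerate=degenerate, n_points=int(c.size),
    )


def tumor_volume(a: float, b: float) -> float:
    """Caliper volume V = A * B^2 / 2 (mm^3), A = largest diameter.

    Inputs with A < B are swapped with a warning; non-positive diameters are
    errors.
    """
    if a <= 0 or b <= 0:
        raise ValidationError("diameters must be positive")
    if a < b:
        warnings.warn(
            f"largest diameter A={a} < smallest B={b}; swapping", stacklevel=2
        )
        a, b = b, a
    return a * b * b / 2.0


def growth_endpoint_test(
    measurements: pd.DataFrame,
    day: float,
    method: str = "student",
    value: str = "volume",
) -> dict:
    """Compare tumor burden between groups at one measurement day.

    ``measurements`` needs columns ``group``, ``day`` and ``value`` (volume in
    mm^3 by default).  Returns per-group n/mean/sd and two-sided pairwise
    tests delegated to :func:`met53.stratification_survival.compare_scores`.
    """
    for col in ("group", "day", value):
        if col not in measurements.columns:
            raise ValidationError(f"measurements missing column {col!r}")
    at_day = measurements[measurements["day"] == day]
    if at_day.empty:
        available = sorted(measurements["day"].unique().tolist())
        raise ValidationError(f"no measurements at day {day}; available days: {available}")
    groups = {g: sub[value].to_numpy(dtype=float) for g, sub in at_day.groupby("group")}
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups at the endpoint day")
    summary = {
        g: {"n": int(vals.size), "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan")}
        for g, vals in groups.items()
    }
    names = sorted(groups)
    tests = {}
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            stat, p = compare_scores(groups[g1], groups[g2], method=method)
            tests[f"{g1}_vs_{g2}"] = {"statistic": stat, "p_value": p, "method": method}
    return {"day": day, "groups": summary, "tests": tests}
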