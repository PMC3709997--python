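"""Standardized swimming activity, the Pearson correlation battery, and patchiness.

Standardized swimming activity of a stage is its swimmer density
(ind·m^-3) divided by the density of the same stage in the mud
(ind·m^-2), a measurement of swimming relative to availability.  Each
activity series is correlated (Pearson, untransformed, two-sided) against
the resident density of a covariate stage across site x round cells; each
pair tests a distinct null hypothesis, so no family-wise correction is
applied.  Patchiness — the variance-to-mean ratio of a variable over
replicates, >1 indicating aggregation — accompanies the battery as a
descriptive statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "standardized_activity",
    "propensity_correlation",
    "patchiness",
    "DEFAULT_BATTERY",
    "PropensityBattery",
]

#: (swimming stage, resident covariate) pairs: juvenile classes against
#: resident adults; male stages against female stages; female stages
#: against male stages.
DEFAULT_BATTERY: tuple[tuple[str, str], ...] = tuple(
    [(juv, "adult") for juv in ("<1.5", "1.5-2.5", "2.5-4")]
    + [(m, f) for m in ("male", "small male", "large male")
       for f in ("female", "non-ovigerous female",
                 "small non-ovigerous female", "large non-ovigerous female",
                 "ovigerous female")]
    + [(f, m) for f in ("female", "small non-ovigerous female",
                        "large non-ovigerous female")
       for m in ("male", "small male", "large male")]
)


def standardized_activity(swim_density: pd.Series, mud_density: pd.Series
                          ) -> pd.Series:
    """Elementwise swimmer density / resident density per cell.

    Cells with a zero (or missing) resident denominator are excluded
    (returned as NaN) — the activity is undefined there.
    """
    swim = pd.Series(swim_density, dtype=float)
    mud = pd.Series(mud_density, dtype=float).reindex(swim.index)
    out = swim / mud.where(mud > 0)
    out.name = "standardized_activity"
    return out


def propensity_correlation(activity: pd.Series, covariate: pd.Series
                           ) -> tuple[float, int, float, int]:
    """Pearson r, df (= n-2), two-sided p and n over complete cells.

    Computed on untransformed values.  Constant input yields an undefined
    correlation (NaN r and p).
    """
    a = pd.Series(activity, dtype=float)
    c = pd.Series(covariate, dtype=float).reindex(a.index)
    ok = a.notna() & c.notna()
    a, c = a[ok].to_numpy(), c[ok].to_numpy()
    n = len(a)
    if n < 3:
        raise ValueError(f"need >= 3 complete cells, got {n}")
    if np.std(a) == 0 or np.std(c) == 0:
        return float("nan"), n - 2, float("nan"), n
    r = float(np.corrcoef(a, c)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return r, df, 0.0, n
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return r, df, float(2 * stats.t.sf(t, df)), n


def patchiness(values) -> float:
    """Variance-to-mean ratio (unbiased sample variance; mean must be > 0)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 2:
        raise ValueError("patchiness needs >= 2 values")
    mean = arr.mean()
    if not mean > 0:
        return float("nan")
    return float(arr.var(ddof=1) / mean)


@dataclass(frozen=True)
class PropensityResults:
    """Long-format battery report: one row per stage pair."""

    table: pd.DataFrame

    def summary(self) -> str:
        with pd.option_context("display.float_format", lambda v: f"{v:8.4f}"):
            return ("Standardized swimming activity correlations\n"
                    + self.table.to_string(index=False))


class PropensityBattery:
    """Correlation battery over a per-cell stage-density table.

    ``cells`` is indexed by (site, round) with columns ``swim_<stage>``
    (ind·m^-3, mean over nets) and ``mud_<stage>`` (ind·m^-2, mean over
    cores) for every stage group appearing in the battery.
    """

    def __init__(self, cells: pd.DataFrame,
                 battery: tuple[tuple[str, str], ...] = DEFAULT_BATTERY):
        self.cells = cells
        self.battery = battery

    def fit(self) -> PropensityResults:
        rows = []
        for swim_stage, covariate in self.battery:
            swim = self.cells[f"swim_{swim_stage}"]
            mud = self.cells[f"mud_{swim_stage}"]
            cov = self.cells[f"mud_{covariate}"]
            activity = standardized_activity(swim, mud)
            n_def = int(activity.notna().sum())
            if n_def < 3:
                rows.append((swim_stage, covariate, np.nan, np.nan, np.nan,
                             n_def, "too few cells"))
                continue
            r, df, p, n = propensity_correlation(activity, cov)
            rows.append((swim_stage, covariate, r, df, p, n, ""))
        table = pd.DataFrame(rows, columns=[
            "swimming_stage", "resident_covariate", "r", "df", "p",
            "n_cells", "note"])
        return PropensityResults(table=table)
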