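"""Fully random three-factor ANOVA with quasi-F ratios and variance components.

The survey design crosses Site (a levels) with Round (b levels), with Night
(c per round) nested in Round and replicate nets within each
site x round x night cell.  All factors are random, so no single mean
square is a valid denominator for the Round effect and a quasi-F is formed
from sums of mean squares:

====================  =============================  =========================
Source                F or quasi-F                   Variance component
====================  =============================  =========================
Round (R)             (MS_R + MS_SN(R)) /            (MS_R + MS_SN(R) - MS_RS
                      (MS_N(R) + MS_RS)               - MS_N(R)) / (a c n)
Site (S)              MS_S / MS_RS                   (MS_S - MS_RS) / (b c n)
R x S                 MS_RS / MS_SN(R)               (MS_RS - MS_SN(R)) / (c n)
Night(Round) (N(R))   MS_N(R) / MS_SN(R)             (MS_N(R) - MS_SN(R)) / (a n)
S x N(R)              MS_SN(R) / MS_e                (MS_SN(R) - MS_e) / n
Error (e)                                            MS_e
====================  =============================  =========================

where ``n`` is the harmonic mean of replicate counts per cell (exact
replicate count when balanced).  Unbalanced replication is handled by the
unweighted-means analysis: sums of squares among cells are computed from
unweighted cell means and scaled by the harmonic-mean cell size, which
reduces exactly to the textbook decomposition on balanced data.

p-values for the plain ratios use the F distribution with the df of the
numerator and denominator mean squares; the quasi-F uses
Satterthwaite-synthesised df on both composites (an approximation — the
synthesised df are exposed in the results for audit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SOURCES",
    "DesignConstants",
    "mean_squares",
    "f_ratios",
    "variance_components",
    "satterthwaite_df",
    "quasi_f_p",
    "RandomEffectsAnova",
    "RandomEffectsAnovaResults",
]

#: Canonical source order.
SOURCES = ("round", "site", "round_x_site", "night", "site_x_night", "error")

_PRETTY = {
    "round": "Round",
    "site": "Site",
    "round_x_site": "Round x Site",
    "night": "Night(Round)",
    "site_x_night": "Night(Round) x Site",
    "error": "Error",
}


class DesignError(ValueError):
    """Raised for layouts the random model cannot accommodate."""


@dataclass(frozen=True)
class DesignConstants:
    """Constants entering the variance-component divisors.

    a: number of sites; b: number of rounds; c: nights per round;
    n: harmonic mean of replicate samples per site x round x night cell
    (may be non-integer under unbalanced replication).
    """

    a: int
    b: int
    c: int
    n: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 2:
            raise DesignError("a, b and c must each be at least 2")
        if not self.n > 0:
            raise DesignError("harmonic-mean replicate count n must be positive")


def _cell_frame(data: pd.DataFrame, response: str,
                site: str, round_: str, night: str) -> pd.DataFrame:
    df = data[[site, round_, night, response]].dropna()
    if df.empty:
        raise DesignError("no complete observations")
    return df.rename(columns={site: "site", round_: "round",
                              night: "night", response: "y"})


def mean_squares(data: pd.DataFrame, response: str = "y", *,
                 site: str = "site", round_: str = "round",
                 night: str = "night") -> tuple[pd.Series, pd.Series, DesignConstants]:
    """Per-source degrees of freedom and mean squares.

    ``data`` holds one row per replicate sample with site, round and
    within-round night identifiers plus the (already transformed) response.
    Every site x round x night cell must contain at least one replicate and
    every round must contain the same number of nights.

    Returns ``(df, ms, constants)`` as Series indexed by source plus the
    design constants used for variance components.
    """
    df = _cell_frame(data, response, site, round_, night)

    rounds = sorted(df["round"].unique())
    sites = sorted(df["site"].unique())
    a, b = len(sites), len(rounds)
    nights_per_round = {r: sorted(df.loc[df["round"] == r, "night"].unique())
                        for r in rounds}
    counts = {r: len(v) for r, v in nights_per_round.items()}
    if len(set(counts.values())) != 1:
        raise DesignError(f"unequal nights per round: {counts}")
    c = next(iter(counts.values()))

    grouped = df.groupby(["site", "round", "night"], sort=True)["y"]
    cell_sizes = grouped.size()
    expected_cells = a * b * c
    if len(cell_sizes) != expected_cells:
        have = set(cell_sizes.index)
        missing = [
            (s, r, nt) for s in sites for r in rounds
            for nt in nights_per_round[r] if (s, r, nt) not in have
        ]
        raise DesignError(f"empty site x round x night cell(s): {missing[:5]}")

    n_harm = len(cell_sizes) / float((1.0 / cell_sizes).sum())
    constants = DesignConstants(a=a, b=b, c=c, n=n_harm)

    # Unweighted cell means arranged as an (a, b, c) array.
    means = grouped.mean()
    cube = np.empty((a, b, c))
    site_idx = {s: i for i, s in enumerate(sites)}
    round_idx = {r: j for j, r in enumerate(rounds)}
    night_idx = {r: {nt: k for k, nt in enumerate(nights_per_round[r])}
                 for r in rounds}
    for (s, r, nt), m in means.items():
        cube[site_idx[s], round_idx[r], night_idx[r][nt]] = m

    grand = cube.mean()
    m_site = cube.mean(axis=(1, 2))            # (a,)
    m_round = cube.mean(axis=(0, 2))           # (b,)
    m_sr = cube.mean(axis=2)                   # (a, b)
    m_rn = cube.mean(axis=0)                   # (b, c)

    nh = n_harm
    ss = {
        "round": nh * a * c * np.sum((m_round - grand) ** 2),
        "site": nh * b * c * np.sum((m_site - grand) ** 2),
        "round_x_site": nh * c * np.sum(
            (m_sr - m_site[:, None] - m_round[None, :] + grand) ** 2),
        "night": nh * a * np.sum((m_rn - m_round[:, None]) ** 2),
        "site_x_night": nh * np.sum(
            (cube - m_sr[:, :, None] - m_rn[None, :, :] + m_round[None, :, None]) ** 2),
    }
    # Pooled within-cell SS.
    cell_mean_per_obs = grouped.transform("mean")
    ss["error"] = float(((df["y"] - cell_mean_per_obs) ** 2).sum())

    dof = {
        "round": b - 1,
        "site": a - 1,
        "round_x_site": (a - 1) * (b - 1),
        "night": b * (c - 1),
        "site_x_night": (a - 1) * b * (c - 1),
        "error": int(len(df) - expected_cells),
    }
    if dof["error"] < 1:
        raise DesignError("error df < 1: at least some cells need replicates")

    df_series = pd.Series(dof, name="df").reindex(list(SOURCES))
    ms_series = pd.Series({k: ss[k] / dof[k] for k in SOURCES},
                          name="MS").reindex(list(SOURCES))
    return df_series, ms_series, constants


def f_ratios(ms: Mapping[str, float]) -> pd.Series:
    """F or quasi-F value per testable source.

    The Round source has no single valid error term under the fully random
    model; its quasi-F is ``(MS_R + MS_SN(R)) / (MS_N(R) + MS_RS)``.  A zero
    denominator yields ``nan`` (undefined ratio) rather than an exception.
    """
    ms = {k: float(ms[k]) for k in SOURCES}
    if any(v < 0 for v in ms.values()):
        raise ValueError("mean squares must be non-negative")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    return pd.Series({
        "round": ratio(ms["round"] + ms["site_x_night"],
                       ms["night"] + ms["round_x_site"]),
        "site": ratio(ms["site"], ms["round_x_site"]),
        "round_x_site": ratio(ms["round_x_site"], ms["site_x_night"]),
        "night": ratio(ms["night"], ms["site_x_night"]),
        "site_x_night": ratio(ms["site_x_night"], ms["error"]),
        "error": float("nan"),
    }, name="F").reindex(list(SOURCES))


def variance_components(ms: Mapping[str, float], constants: DesignConstants,
                        *, truncate: bool = True) -> tuple[pd.Series, pd.Series]:
    """Variance component and percent of total variation per source.

    Negative estimates are truncated to zero before percentages (classical
    convention) unless ``truncate=False``, in which case the raw unbiased
    estimates are returned (useful for simulation studies of the estimator).
    """
    m = {k: float(ms[k]) for k in SOURCES}
    a, b, c, n = constants.a, constants.b, constants.c, constants.n
    comp = pd.Series({
        "round": (m["round"] + m["site_x_night"] - m["round_x_site"]
                  - m["night"]) / (a * c * n),
        "site": (m["site"] - m["round_x_site"]) / (b * c * n),
        "round_x_site": (m["round_x_site"] - m["site_x_night"]) / (c * n),
        "night": (m["night"] - m["site_x_night"]) / (a * n),
        "site_x_night": (m["site_x_night"] - m["error"]) / n,
        "error": m["error"],
    }, name="variance_component").reindex(list(SOURCES))
    if truncate:
        comp = comp.clip(lower=0.0)
    total = comp.sum()
    pct = (100.0 * comp / total if total > 0
           else pd.Series(np.nan, index=comp.index))
    pct.name = "pct_variation"
    return comp, pct


def satterthwaite_df(terms: Sequence[tuple[float, float]]) -> float:
    """Effective df of a sum of mean squares: ``(sum MS)^2 / sum(MS^2/df)``."""
    num = sum(msq for msq, _ in terms) ** 2
    den = sum(msq**2 / dof for msq, dof in terms)
    return num / den if den > 0 else float("nan")


def quasi_f_p(value: float, numerator: Sequence[tuple[float, float]],
              denominator: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """p-value for a (quasi-)F with Satterthwaite df on both composites.

    ``numerator``/``denominator`` are sequences of ``(MS, df)`` pairs making
    up each composite mean square.  Returns ``(p, df_num, df_den)``.
    """
    df_num = satterthwaite_df(numerator)
    df_den = satterthwaite_df(denominator)
    if not np.isfinite(value) or not np.isfinite(df_num) or not np.isfinite(df_den):
        return float("nan"), df_num, df_den
    return float(stats.f.sf(value, df_num, df_den)), df_num, df_den


class RandomEffectsAnova:
    """Fully random Site x Round with Night nested in Round, fitted to
    replicate-level data.

    Parameters
    ----------
    data : DataFrame
        One row per replicate sample.
    response : str
        Column holding the (already transformed) response.
    site, round_, night : str
        Factor columns; nights are identified within round (1..c).

    Examples
    --------
    >>> res = RandomEffectsAnova(df, response="log_density").fit()
    >>> res.anova_table  # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, response: str = "y", *,
                 site: str = "site", round_: str = "round", night: str = "night"):
        self.data = data
        self.response = response
        self._cols = dict(site=site, round_=round_, night=night)

    def fit(self, *, truncate_components: bool = True) -> "RandomEffectsAnovaResults":
        dof, ms, constants = mean_squares(
            self.data, self.response, **self._cols)
        return RandomEffectsAnovaResults(dof, ms, constants,
                                         response=self.response,
                                         truncate=truncate_components)


class RandomEffectsAnovaResults:
    """ANOVA table, quasi-F details and variance components."""

    def __init__(self, dof: pd.Series, ms: pd.Series, constants: DesignConstants,
                 *, response: str = "y", truncate: bool = True):
        self.df = dof
        self.ms = ms
        self.constants = constants
        self.response = response
        self.fvalues = f_ratios(ms)
        self.components, self.pct_variation = variance_components(
            ms, constants, truncate=truncate)
        self.pvalues, self.quasi_df = self._pvalues()

    def _pvalues(self) -> tuple[pd.Series, tuple[float, float]]:
        dof, ms, f = self.df, self.ms, self.fvalues
        p = {}
        pairs = {"site": "round_x_site", "round_x_site": "site_x_night",
                 "night": "site_x_night", "site_x_night": "error"}
        for src, den in pairs.items():
            p[src] = (float(stats.f.sf(f[src], dof[src], dof[den]))
                      if np.isfinite(f[src]) else float("nan"))
        p["round"], qdf_num, qdf_den = quasi_f_p(
            f["round"],
            [(ms["round"], dof["round"]), (ms["site_x_night"], dof["site_x_night"])],
            [(ms["night"], dof["night"]), (ms["round_x_site"], dof["round_x_site"])],
        )
        p["error"] = float("nan")
        return pd.Series(p, name="p").reindex(list(SOURCES)), (qdf_num, qdf_den)

    @property
    def anova_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "source": [_PRETTY[s] for s in SOURCES],
            "df": self.df.values,
            "MS": self.ms.values,
            "F": self.fvalues.values,
            "p": self.pvalues.values,
            "variance_component": self.components.values,
            "pct_variation": self.pct_variation.values,
        }, index=list(SOURCES))
        return tab

    def summary(self) -> str:
        lines = [
            f"Random-model ANOVA — response: {self.response}",
            f"Design: a={self.constants.a} sites, b={self.constants.b} rounds, "
            f"c={self.constants.c} nights/round, harmonic n={self.constants.n:.3f}",
            f"Round quasi-F df (Satterthwaite): "
            f"{self.quasi_df[0]:.2f}, {self.quasi_df[1]:.2f}",
            "",
        ]
        tab = self.anova_table.copy()
        with pd.option_context("display.float_format", lambda v: f"{v:10.4f}"):
            lines.append(tab.to_string(index=False))
        return "\n".join(lines)
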