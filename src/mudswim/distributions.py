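"""Swimmer-vs-resident distribution comparisons.

Two complementary analyses identify which stages are overrepresented among
swimmers relative to the resident population:

* a bootstrap comparison of 0.5-mm size distributions — the null is that
  swimmers are a random subsample of the mud residents, so resident
  lengths are resampled (with replacement) to the number of swimmers
  actually measured, 1000 times, and a trimmed 95% percentile band per
  size class is compared against the observed mean-over-nets swimmer
  proportion;
* a likelihood-ratio G-test of the five-stage adult structure (small/large
  males, small/large non-ovigerous females, ovigerous females), with
  category pooling when a stage is absent from the residents: large males
  pool into small males, large non-ovigerous females pool into ovigerous
  females (reduced df).

Both analyses apply only where enough animals were measured: at least 100
swimmers and 100 residents for the bootstrap, strictly more than 100 of
each for the G-test.  Below threshold the analysis reports a
``not analysed`` status rather than running silently.
"""

from __future__ import annotations
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .individuals import ADULT_STAGES, DEFAULT_SCHEME, Individual, StageScheme
from .samples import NetSample

__all__ = [
    "BootstrapComparison",
    "StageGTest",
    "bootstrap_size_comparison",
    "observed_swimmer_proportions",
    "g_test_stages",
    "adult_stage_counts",
    "SizeDistributionComparison",
]

MIN_BOOTSTRAP_COUNT = 100   # "at least 100" — inclusive
MIN_GTEST_COUNT = 100       # "> 100" — exclusive

_POOL_PARTNERS = {
    # printed rules first, then their within-group reversals for
    # degenerate tables the printed rules never faced
    "large male": ("small male",),
    "large non-ovigerous female": ("ovigerous female",),
    "small male": ("large male",),
    "small non-ovigerous female": ("large non-ovigerous female",
                                   "ovigerous female"),
    "ovigerous female": ("large non-ovigerous female",
                         "small non-ovigerous female"),
}


@dataclass(frozen=True)
class BootstrapComparison:
    """Per-size-class expected proportion, trimmed CI and over/under flags."""

    table: pd.DataFrame | None  # class, expected, lower, upper, observed, flag
    B: int
    m: int
    n_residents: int
    n_nets: int
    status: str = "analysed"    # or "not analysed: <reason>"

    @property
    def analysed(self) -> bool:
        return self.status == "analysed"

    def summary(self) -> str:
        head = (f"Bootstrap size-distribution comparison — B={self.B}, "
                f"m={self.m} swimmers, {self.n_residents} residents, "
                f"{self.n_nets} nets [{self.status}]")
        if self.table is None:
            return head
        with pd.option_context("display.float_format", lambda v: f"{v:8.4f}"):
            return head + "\n" + self.table.to_string(index=False)


def _lengths(items) -> np.ndarray:
    if isinstance(items, NetSample):
        items = items.individuals
    items = list(items)
    if items and isinstance(items[0], Individual):
        return np.array([ind.length_mm for ind in items], dtype=float)
    return np.asarray(items, dtype=float)


def observed_swimmer_proportions(net_samples,
                                 scheme: StageScheme = DEFAULT_SCHEME
                                 ) -> tuple[np.ndarray, int, int]:
    """Mean-over-nets size-class proportions of measured swimmers.

    Proportions are computed per net and then averaged unweighted across
    nets (nets with no measured individuals are not usable); this differs
    from pooling counts when nets are unequal.  ``net_samples`` may hold
    :class:`NetSample` objects or plain per-net length sequences.  Returns
    ``(proportions, n_swimmers_measured, n_usable_nets)``.
    """
    k = len(scheme.histogram_edges) - 1
    per_net = []
    total = 0
    for net in net_samples:
        lengths = _lengths(net)
        if lengths.size == 0:
            continue
        bins = scheme.histogram_bins(lengths)
        counts = np.bincount(bins, minlength=k).astype(float)
        per_net.append(counts / counts.sum())
        total += lengths.size
    if not per_net:
        raise ValueError("no net has any measured swimmer")
    return np.mean(per_net, axis=0), total, len(per_net)


def bootstrap_size_comparison(residents, swimmer_nets,
                              *, B: int = 1000,
                              rng: np.random.Generator | None = None,
                              seed: int | None = None,
                              scheme: StageScheme = DEFAULT_SCHEME,
                              trim: int | None = None) -> BootstrapComparison:
    """Compare the swimmer size distribution against resident resampling.

    ``residents`` is the pooled resident collection (Individuals or
    lengths).  Each of the ``B`` iterations draws, with replacement, as
    many lengths from the residents as swimmers were actually measured,
    bins them into the 0.5-mm classes and records the class proportions;
    per class, the ``trim`` smallest and largest bootstrap values are
    removed (25 each side at B=1000) and the extremes of what remains are
    the 95% confidence limits.  Classes whose observed mean-over-nets
    proportion falls outside the limits are flagged ``over`` or ``under``.
    """
    if B < 100:
        raise ValueError(f"B must be at least 100, got {B}")
    if trim is None:
        trim = int(round(0.025 * B))
    if not 0 < trim < B // 2:
        raise ValueError(f"trim {trim} incompatible with B={B}")
    if rng is None:
        rng = np.random.default_rng(seed)

    res_lengths = _lengths(residents)
    n_res = len(res_lengths)
    usable = [net for net in swimmer_nets if _lengths(net).size]
    m = sum(_lengths(net).size for net in usable)
    if n_res < MIN_BOOTSTRAP_COUNT or m < MIN_BOOTSTRAP_COUNT:
        return BootstrapComparison(
            table=None, B=B, m=m, n_residents=n_res, n_nets=len(usable),
            status=(f"not analysed: requires >= {MIN_BOOTSTRAP_COUNT} swimmers "
                    f"and residents (have {m} swimmers, {n_res} residents)"))

    observed, m, n_nets = observed_swimmer_proportions(usable, scheme)
    k = len(scheme.histogram_edges) - 1
    res_bins = scheme.histogram_bins(res_lengths)
    expected = np.bincount(res_bins, minlength=k).astype(float) / n_res

    # Resample bin indices directly (equivalent to resampling lengths).
    draws = rng.choice(res_bins, size=(B, m), replace=True)
    boot = np.zeros((B, k))
    for i in range(B):
        boot[i] = np.bincount(draws[i], minlength=k)
    boot /= m
    boot.sort(axis=0)
    lower = boot[trim]
    upper = boot[B - trim - 1]

    flag = np.where(observed > upper, "over",
                    np.where(observed < lower, "under", "ns"))
    table = pd.DataFrame({
        "size_class": scheme.histogram_labels,
        "expected": expected, "lower": lower, "upper": upper,
        "observed": observed, "flag": flag,
    })
    return BootstrapComparison(table=table, B=B, m=m, n_residents=n_res,
                               n_nets=n_nets)


class SizeDistributionComparison:
    """Model-style wrapper: residents + swimmer nets, ``fit`` runs the
    bootstrap comparison."""

    def __init__(self, residents, swimmer_nets: list[NetSample],
                 scheme: StageScheme = DEFAULT_SCHEME):
        self.residents = residents
        self.swimmer_nets = swimmer_nets
        self.scheme = scheme

    def fit(self, *, B: int = 1000, seed: int | None = None,
            rng: np.random.Generator | None = None) -> BootstrapComparison:
        return bootstrap_size_comparison(self.residents, self.swimmer_nets,
                                         B=B, seed=seed, rng=rng,
                                         scheme=self.scheme)


# ---------------------------------------------------------------------------
# G-test of adult stage structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageGTest:
    """G statistic with pooling bookkeeping for the adult stage structure."""

    g: float | None
    df: int | None
    p: float | None
    expected_pct: pd.Series | None
    observed_pct: pd.Series | None
    pooled: tuple[str, ...] = field(default_factory=tuple)
    status: str = "analysed"

    @property
    def analysed(self) -> bool:
        return self.status == "analysed"

    def summary(self) -> str:
        if not self.analysed:
            return f"Adult stage G-test [{self.status}]"
        pool = f"; pooled: {', '.join(self.pooled)}" if self.pooled else ""
        return (f"Adult stage G-test: G_{self.df} = {self.g:.3f}, "
                f"p = {self.p:.4g}{pool}")


def adult_stage_counts(individuals, scheme: StageScheme = DEFAULT_SCHEME,
                       *, weights=None) -> pd.Series:
    """Counts of the five adult stages among ``individuals``.

    ``weights`` (e.g. reciprocal subsample fractions) scale each
    individual's contribution; the result is rounded to whole animals.
    """
    counts = pd.Series(0.0, index=list(ADULT_STAGES))
    if weights is None:
        weights = np.ones(len(individuals))
    for ind, w in zip(individuals, weights):
        stage = scheme.adult_stage(ind)
        if stage is not None:
            counts[stage] += w
    return counts.round().astype(int)


def swimmer_adult_stage_counts(net_samples: list[NetSample],
                               scheme: StageScheme = DEFAULT_SCHEME) -> pd.Series:
    """Subsample-expanded adult stage counts pooled over nets (rounded)."""
    total = pd.Series(0.0, index=list(ADULT_STAGES))
    for net in net_samples:
        w = 1.0 / net.subsample_fraction
        for ind in net.individuals:
            stage = scheme.adult_stage(ind)
            if stage is not None:
                total[stage] += w
    return total.round().astype(int)


def g_test_stages(expected_counts, observed_counts, *,
                  enforce_threshold: bool = True) -> StageGTest:
    """G-test of observed (swimming) vs expected (resident) adult stages.

    Expected counts are scaled to the observed total.  Stages with zero
    expected count are pooled into their designated partner (large males
    into small males; large non-ovigerous females into ovigerous females)
    and the df drop accordingly; a stage empty on both margins is dropped.
    Zero observed cells contribute nothing to G (the ``O ln O`` limit).
    """
    exp = pd.Series(expected_counts, dtype=float).reindex(list(ADULT_STAGES)).fillna(0.0)
    obs = pd.Series(observed_counts, dtype=float).reindex(list(ADULT_STAGES)).fillna(0.0)
    if (exp < 0).any() or (obs < 0).any():
        raise ValueError("stage counts must be non-negative")
    n_exp, n_obs = exp.sum(), obs.sum()
    if enforce_threshold and (n_exp <= MIN_GTEST_COUNT or n_obs <= MIN_GTEST_COUNT):
        return StageGTest(
            g=None, df=None, p=None, expected_pct=None, observed_pct=None,
            status=(f"not analysed: requires > {MIN_GTEST_COUNT} resident and "
                    f"swimming adults (have {n_exp:.0f}, {n_obs:.0f})"))
    if n_exp == 0 or n_obs == 0:
        return StageGTest(g=None, df=None, p=None, expected_pct=None,
                          observed_pct=None, status="not analysed: no adults")

    pooled: list[str] = []
    work_exp, work_obs = exp.copy(), obs.copy()
    changed = True
    while changed:
        changed = False
        for stage in list(work_exp.index):
            if work_exp[stage] > 0:
                continue
            if work_obs[stage] == 0:
                continue  # empty on both margins -> dropped below
            for partner in _POOL_PARTNERS.get(stage, ()):
                if partner in work_exp.index and work_exp[partner] > 0:
                    work_exp[partner] += work_exp[stage]
                    work_obs[partner] += work_obs[stage]
                    work_exp = work_exp.drop(stage)
                    work_obs = work_obs.drop(stage)
                    pooled.append(f"{stage} -> {partner}")
                    changed = True
                    break
            if changed:
                break
    keep = (work_exp > 0) | (work_obs > 0)
    work_exp, work_obs = work_exp[keep], work_obs[keep]
    if (work_exp == 0).any():
        return StageGTest(g=None, df=None, p=None, expected_pct=None,
                          observed_pct=None,
                          status="not analysed: observed stage absent from residents")

    scaled_exp = work_exp / work_exp.sum() * work_obs.sum()
    nz = work_obs > 0
    g = 2.0 * float((work_obs[nz] * np.log(work_obs[nz] / scaled_exp[nz])).sum())
    df = int(len(work_exp) - 1)
    p = float(stats.chi2.sf(g, df)) if df > 0 else float("nan")
    return StageGTest(
        g=g, df=df, p=p,
        expected_pct=100 * exp / n_exp, observed_pct=100 * obs / n_obs,
        pooled=tuple(pooled))
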