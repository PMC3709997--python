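"""Cell-level (site x round) aggregation of samples into analysis tables.

All regression and propensity analyses run on site x round cell means:
swimmer densities averaged over the 7-9 nets of a cell and resident
densities (or biomass) averaged over its 12 cores.
"""

from __future__ import annotations

import pandas as pd

from .individuals import DEFAULT_SCHEME, StageScheme, stage_predicate
from .samples import (AllometryParams, CoreSample, NetSample, biomass_per_m2,
                      core_density, net_density)
from .transforms import log10_plus1

__all__ = ["net_density_records", "cell_stage_table", "anova_input"]

#: Stage groups aggregated into the per-cell table.
DEFAULT_GROUPS = ("total", "<1.5", "1.5-2.5", "2.5-4", "4-6", ">6", "adult",
                  "male", "small male", "large male", "female",
                  "non-ovigerous female", "small non-ovigerous female",
                  "large non-ovigerous female", "ovigerous female")


def net_density_records(net_samples: list[NetSample],
                        groups=DEFAULT_GROUPS,
                        scheme: StageScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """One row per net with the density of every stage group (ind·m^-3)."""
    preds = {g: stage_predicate(g, scheme) for g in groups}
    rows = []
    for net in net_samples:
        rec = {"site": net.site, "round": net.round, "night": net.night,
               "net": net.net_id}
        for g, pred in preds.items():
            rec[g] = net_density(net, pred)
        rows.append(rec)
    return pd.DataFrame(rows)


def cell_stage_table(net_samples: list[NetSample],
                     core_samples: list[CoreSample],
                     groups=DEFAULT_GROUPS,
                     scheme: StageScheme = DEFAULT_SCHEME,
                     allometry: AllometryParams | None = None) -> pd.DataFrame:
    """Site x round table of mean swimmer and resident densities per group.

    Columns are ``swim_<group>`` (mean over nets, ind·m^-3) and
    ``mud_<group>`` (mean over cores, ind·m^-2); with ``allometry`` a
    ``mud_biomass`` column (mg·m^-2) is added.
    """
    preds = {g: stage_predicate(g, scheme) for g in groups}

    nets = net_density_records(net_samples, groups, scheme)
    swim = (nets.groupby(["site", "round"])[list(groups)].mean()
            .rename(columns={g: f"swim_{g}" for g in groups}))

    rows = []
    for core in core_samples:
        rec = {"site": core.site, "round": core.round}
        for g, pred in preds.items():
            rec[f"mud_{g}"] = core_density(core, pred)
        if allometry is not None:
            rec["mud_biomass"] = biomass_per_m2(core, allometry)
        rows.append(rec)
    mud = pd.DataFrame(rows).groupby(["site", "round"]).mean()

    return swim.join(mud, how="outer")


def anova_input(net_samples: list[NetSample], group: str = "total",
                scheme: StageScheme = DEFAULT_SCHEME,
                transform: bool = True) -> pd.DataFrame:
    """Replicate-level ANOVA frame: site, round, night, (transformed) density."""
    pred = stage_predicate(group, scheme)
    rows = [{"site": n.site, "round": n.round, "night": n.night,
             "y": net_density(n, pred)} for n in net_samples]
    df = pd.DataFrame(rows)
    if transform:
        df["y"] = log10_plus1(df["y"].to_numpy())
    return df
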