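"""Shared helpers for simulation-based tests: cell-level aggregation of the
vectorised count tables produced by ``simulate_counts``."""

import numpy as np

from mudswim.simulate import STAGES

ADULT = list(STAGES[3:])


def net_log_cell_means(sim, stages=STAGES):
    """log10 site x round mean swimmer density (ind/m3) over nets."""
    nt = sim.net_table
    dens = (nt[[f"obs_{s}" for s in stages]].sum(axis=1)
            / nt["fraction"] / nt["volume_m3"])
    cell = dens.groupby([nt["site"], nt["round"]]).mean()
    return np.log10(cell.where(cell > 0))


def core_log_cell_means(sim, stages=STAGES):
    """log10 site x round mean resident density (ind/m2) over cores."""
    ct = sim.core_table
    area = sim.truth.config.core_area_m2
    dens = ct[[f"count_{s}" for s in stages]].sum(axis=1) / area
    cell = dens.groupby([ct["site"], ct["round"]]).mean()
    return np.log10(cell.where(cell > 0))


def cell_density(sim, stage_cols, table):
    """Site x round mean density for arbitrary stage column sums."""
    if table == "net":
        nt = sim.net_table
        dens = (nt[stage_cols].sum(axis=1) / nt["fraction"] / nt["volume_m3"])
        return dens.groupby([nt["site"], nt["round"]]).mean()
    ct = sim.core_table
    dens = ct[stage_cols].sum(axis=1) / sim.truth.config.core_area_m2
    return dens.groupby([ct["site"], ct["round"]]).mean()
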