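"""Delimited-text I/O for surveys and YAML configuration.

A survey is stored as two UTF-8 tab-separated tables with one-line
headers: ``samples.tsv`` (per-sample metadata keyed by sample id) and
``individuals.tsv`` (one row per measured individual, keyed back to its
sample).  This is the simplest round-trippable representation of the
two-level data; all analysis modules consume only the typed objects.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .individuals import Individual, StageScheme
from .samples import AllometryParams, CoreSample, NetSample

__all__ = ["write_survey", "read_survey", "load_config", "dump_config"]

SAMPLE_COLUMNS = ["sample_id", "kind", "site", "round", "night", "unit_id",
                  "subsample_fraction", "filtered_volume_m3", "core_area_m2"]
INDIVIDUAL_COLUMNS = ["sample_id", "length_mm", "sex", "ovigerous"]


def write_survey(net_samples: list[NetSample], core_samples: list[CoreSample],
                 outdir: str | Path) -> tuple[Path, Path]:
    """Write ``samples.tsv`` and ``individuals.tsv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    srows, irows = [], []
    for net in net_samples:
        srows.append([net.sample_id, "net", net.site, net.round, net.night,
                      net.net_id, net.subsample_fraction,
                      net.filtered_volume_m3, ""])
        irows += [[net.sample_id, ind.length_mm, ind.sex, int(ind.ovigerous)]
                  for ind in net.individuals]
    for core in core_samples:
        srows.append([core.sample_id, "core", core.site, core.round, "",
                      core.core_id, 1.0, "", core.core_area_m2])
        irows += [[core.sample_id, ind.length_mm, ind.sex, int(ind.ovigerous)]
                  for ind in core.individuals]
    spath = outdir / "samples.tsv"
    ipath = outdir / "individuals.tsv"
    pd.DataFrame(srows, columns=SAMPLE_COLUMNS).to_csv(spath, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(irows, columns=INDIVIDUAL_COLUMNS).to_csv(ipath, sep="\t", index=False, float_format="%.17g")
    return spath, ipath


def read_survey(indir: str | Path) -> tuple[list[NetSample], list[CoreSample]]:
    """Read a survey written by :func:`write_survey`.

    Schema violations abort with the offending row identified.
    """
    indir = Path(indir)
    samples = pd.read_csv(indir / "samples.tsv", sep="\t",
                          float_precision="round_trip",
                          dtype={"site": str, "round": str, "night": str,
                                 "unit_id": str})
    individuals = pd.read_csv(indir / "individuals.tsv", sep="\t",
                              float_precision="round_trip")

    by_sample: dict[str, list[Individual]] = {}
    for pos, row in enumerate(individuals.itertuples(index=False)):
        try:
            ind = Individual(length_mm=float(row.length_mm), sex=str(row.sex),
                             ovigerous=bool(int(row.ovigerous)))
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"individuals.tsv row {pos + 2}: {exc}") from exc
        by_sample.setdefault(row.sample_id, []).append(ind)

    nets, cores = [], []
    for pos, row in enumerate(samples.itertuples(index=False)):
        inds = tuple(by_sample.get(row.sample_id, []))
        try:
            if row.kind == "net":
                nets.append(NetSample(
                    site=row.site, round=row.round, night=row.night,
                    net_id=row.unit_id,
                    subsample_fraction=float(row.subsample_fraction),
                    filtered_volume_m3=float(row.filtered_volume_m3),
                    individuals=inds))
            elif row.kind == "core":
                cores.append(CoreSample(
                    site=row.site, round=row.round, core_id=row.unit_id,
                    core_area_m2=float(row.core_area_m2), individuals=inds))
            else:
                raise ValueError(f"unknown sample kind {row.kind!r}")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"samples.tsv row {pos + 2}: {exc}") from exc
    return nets, cores


def load_config(path: str | Path) -> dict:
    """Load analysis configuration (stage scheme, allometry, thresholds,
    seeds) from YAML into typed objects where applicable."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(raw)
    if "stage_scheme" in raw:
        ss = raw["stage_scheme"]
        out["stage_scheme"] = StageScheme(
            size_class_edges=tuple(ss.get("size_class_edges", (1.5, 2.5, 4.0, 6.0))),
            **({"histogram_edges": tuple(ss["histogram_edges"])}
               if "histogram_edges" in ss else {}),
        )
    if "allometry" in raw and raw["allometry"] is not None:
        out["allometry"] = AllometryParams(**raw["allometry"])
    return out


def dump_config(config: dict, path: str | Path) -> None:
    serializable = {}
    for key, val in config.items():
        if isinstance(val, StageScheme):
            serializable[key] = {
                "size_class_edges": list(val.size_class_edges),
                "histogram_edges": list(val.histogram_edges)}
        elif isinstance(val, AllometryParams):
            serializable[key] = asdict(val)
        else:
            serializable[key] = val
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(serializable, fh, sort_keys=False)
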