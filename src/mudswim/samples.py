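"""Sample containers and normalisation: subsample expansion, density, biomass.

Two kinds of sample exist.  A :class:`NetSample` is the catch of one
stationary plankton net over one night of tidal immersion; large catches
were split with a Folsom plankton splitter, so the processed individuals
represent a known fraction (1, 1/2, ... 1/512) of the original sample, and
counts are expanded by the reciprocal of that fraction before being divided
by the volume of water filtered (ind·m^-3).  A :class:`CoreSample` is one
sediment core (7 cm diameter by default) and is never subsampled; counts
are divided by the core area (ind·m^-2).

Biomass uses a length-weight allometry ``mass_mg = coefficient *
length_mm ** exponent``; the scientific coefficients are not built in and
must be supplied via configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

from .individuals import Individual

__all__ = [
    "NetSample",
    "CoreSample",
    "AllometryParams",
    "CORE_AREA_7CM_M2",
    "net_density",
    "core_density",
    "biomass_per_m2",
    "count_matching",
]

#: Area of the default 7-cm-diameter sediment corer, m^2.
CORE_AREA_7CM_M2 = math.pi * 0.035**2


class ValidationError(ValueError):
    """Raised when a sample violates its invariants."""


class ConfigurationError(ValueError):
    """Raised when required configuration (e.g. allometry) is missing."""


@dataclass(frozen=True)
class AllometryParams:
    """Length-weight relationship ``mass_mg = coefficient * length_mm**exponent``.

    No scientific default is shipped; tests and examples use synthetic
    values and field use requires a literature-derived pair.
    """

    coefficient: float
    exponent: float

    def __post_init__(self) -> None:
        if not (self.coefficient > 0 and self.exponent > 0):
            raise ConfigurationError(
                "allometry coefficient and exponent must both be positive; "
                f"got {self.coefficient}, {self.exponent}"
            )

    def mass_mg(self, length_mm: float) -> float:
        return self.coefficient * length_mm**self.exponent


#: Placeholder allometry for demonstrations only — NOT a literature value.
SYNTHETIC_ALLOMETRY = AllometryParams(coefficient=0.02, exponent=3.0)


@dataclass(frozen=True)
class NetSample:
    """One plankton-net catch: identifiers, Folsom fraction, filtered volume."""

    site: str
    round: str
    night: str
    net_id: str
    subsample_fraction: float
    filtered_volume_m3: float
    individuals: tuple[Individual, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValidationError(
                f"subsample_fraction must be in (0, 1], got {self.subsample_fraction}"
            )
        if not self.filtered_volume_m3 > 0:
            raise ValidationError(
                f"filtered_volume_m3 must be > 0, got {self.filtered_volume_m3}"
            )
        object.__setattr__(self, "individuals", tuple(self.individuals))

    @property
    def sample_id(self) -> str:
        return f"net:{self.site}:{self.round}:{self.night}:{self.net_id}"


@dataclass(frozen=True)
class CoreSample:
    """One sediment core; never subsampled (implicit fraction of 1)."""

    site: str
    round: str
    core_id: str
    core_area_m2: float = CORE_AREA_7CM_M2
    individuals: tuple[Individual, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.core_area_m2 > 0:
            raise ValidationError(f"core_area_m2 must be > 0, got {self.core_area_m2}")
        object.__setattr__(self, "individuals", tuple(self.individuals))

    @property
    def sample_id(self) -> str:
        return f"core:{self.site}:{self.round}:{self.core_id}"


def count_matching(individuals: Iterable[Individual],
                   predicate: Callable[[Individual], bool] | None = None) -> int:
    if predicate is None:
        return sum(1 for _ in individuals)
    return sum(1 for ind in individuals if predicate(ind))


def net_density(sample: NetSample,
                predicate: Callable[[Individual], bool] | None = None) -> float:
    """Density (ind·m^-3) of individuals matching ``predicate``.

    The processed count is expanded by the reciprocal of the Folsom
    subsample fraction, then divided by the filtered water volume.
    """
    count = count_matching(sample.individuals, predicate)
    return (count / sample.subsample_fraction) / sample.filtered_volume_m3


def core_density(sample: CoreSample,
                 predicate: Callable[[Individual], bool] | None = None) -> float:
    """Density (ind·m^-2) of individuals matching ``predicate``."""
    return count_matching(sample.individuals, predicate) / sample.core_area_m2


def biomass_per_m2(sample: CoreSample, params: AllometryParams | None) -> float:
    """Total biomass (mg·m^-2) of a core under a length-weight allometry."""
    if params is None:
        raise ConfigurationError(
            "biomass requires AllometryParams; no scientific default is shipped"
        )
    total = sum(params.mass_mg(ind.length_mm) for ind in sample.individuals)
    return total / sample.core_area_m2
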