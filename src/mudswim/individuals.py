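"""Domain model for measured amphipods and the staging scheme.

The study organism is the burrow-dwelling intertidal amphipod
*Corophium volutator*.  Each processed individual carries a body length
(tip of rostrum to end of telson, mm), a sex category, and — for females —
an ovigery flag.  Individuals are classified into size classes used for
density analyses and, when adult, into one of five adult stages used for
stage-structure comparisons.

Conventions
-----------
* Adults are strictly longer than 4 mm; an individual of exactly 4.0 mm is
  treated as a juvenile (sexing is only feasible above 4 mm).
* Size bins are half-open, closed on the left: ``[1.5, 2.5)`` etc.; the
  final class ``>6`` is ``[6, inf)``.  The 0.5-mm histogram runs from 1 to
  11 mm with the last bin closed on both sides.
* Intersex individuals are functional males and are pooled with males for
  every staging purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "JUVENILE",
    "MALE",
    "FEMALE",
    "INTERSEX",
    "SEXES",
    "ADULT_STAGES",
    "Individual",
    "StageScheme",
    "classify",
    "stage_predicate",
    "STAGE_GROUPS",
]

JUVENILE = "juvenile"
MALE = "male"
FEMALE = "female"
INTERSEX = "intersex"
SEXES = (JUVENILE, MALE, FEMALE, INTERSEX)

#: The five adult stages used in stage-structure comparisons.
ADULT_STAGES = (
    "small male",
    "large male",
    "small non-ovigerous female",
    "large non-ovigerous female",
    "ovigerous female",
)

ADULT_LENGTH_MM = 4.0  # adults are strictly longer than this


class StagingError(ValueError):
    """Raised when an individual cannot be classified under a scheme."""


@dataclass(frozen=True, slots=True)
class Individual:
    """One measured amphipod.

    Parameters
    ----------
    length_mm : float
        Body length from tip of rostrum to end of telson, in mm.
    sex : str
        One of ``juvenile``, ``male``, ``female``, ``intersex``.
    ovigerous : bool
        Whether the individual carries eggs; females only.
    """

    length_mm: float
    sex: str = JUVENILE
    ovigerous: bool = False

    def __post_init__(self) -> None:
        if not self.length_mm > 0:
            raise ValueError(f"length_mm must be > 0, got {self.length_mm!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.ovigerous and self.sex != FEMALE:
            raise ValueError("only females can be ovigerous")
        if self.sex != JUVENILE and not self.length_mm > ADULT_LENGTH_MM:
            raise ValueError(
                f"adults must exceed {ADULT_LENGTH_MM} mm; got sex={self.sex!r} "
                f"at {self.length_mm} mm"
            )

    @property
    def is_adult(self) -> bool:
        return self.sex != JUVENILE and self.length_mm > ADULT_LENGTH_MM

    @property
    def functional_sex(self) -> str:
        """Sex with intersex pooled into males."""
        return MALE if self.sex == INTERSEX else self.sex


def _default_histogram_edges() -> tuple[float, ...]:
    return tuple(np.round(np.arange(1.0, 11.0 + 1e-9, 0.5), 3))


@dataclass(frozen=True)
class StageScheme:
    """Breakpoints defining size classes, the length histogram and adult stages.

    ``size_class_edges`` are the interior breakpoints of the juvenile/size
    classes; the defaults give the classes <1.5, 1.5-2.5, 2.5-4, 4-6 and >6
    mm.  ``histogram_edges`` define the 0.5-mm classes (1 to 11 mm) used in
    size-distribution comparisons.  ``adult_split_mm`` separates small from
    large adults (4-6 vs >6 mm).
    """

    size_class_edges: tuple[float, ...] = (1.5, 2.5, 4.0, 6.0)
    histogram_edges: tuple[float, ...] = field(default_factory=_default_histogram_edges)
    adult_split_mm: float = 6.0

    def __post_init__(self) -> None:
        for name in ("size_class_edges", "histogram_edges"):
            edges = np.asarray(getattr(self, name), dtype=float)
            if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
                raise ValueError(f"{name} must be strictly increasing, got {edges}")

    @property
    def size_class_labels(self) -> tuple[str, ...]:
        e = self.size_class_edges
        labels = [f"<{e[0]:g}"]
        labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(e[:-1], e[1:])]
        labels.append(f">{e[-1]:g}")
        return tuple(labels)

    @property
    def histogram_labels(self) -> tuple[str, ...]:
        e = self.histogram_edges
        return tuple(f"{lo:g}-{hi:g}" for lo, hi in zip(e[:-1], e[1:]))

    @property
    def max_length_mm(self) -> float:
        return float(self.histogram_edges[-1])

    def size_class(self, length_mm: float) -> str:
        """Half-open bins closed on the left; final class is unbounded above."""
        idx = int(np.searchsorted(self.size_class_edges, length_mm, side="right"))
        return self.size_class_labels[idx]

    def histogram_bin(self, length_mm: float) -> int:
        """Index of the 0.5-mm class; lengths below the first edge fall in
        bin 0 and the top edge is included in the last bin."""
        e = self.histogram_edges
        idx = int(np.searchsorted(e, length_mm, side="right")) - 1
        return int(np.clip(idx, 0, len(e) - 2))

    def histogram_bins(self, lengths: Sequence[float]) -> np.ndarray:
        e = np.asarray(self.histogram_edges)
        idx = np.searchsorted(e, np.asarray(lengths, dtype=float), side="right") - 1
        return np.clip(idx, 0, len(e) - 2)

    def adult_stage(self, individual: Individual) -> str | None:
        """Adult stage label, or None for juveniles (including length == 4)."""
        if not individual.is_adult:
            return None
        sex = individual.functional_sex
        large = individual.length_mm >= self.adult_split_mm
        if sex == MALE:
            return "large male" if large else "small male"
        if individual.ovigerous:
            return "ovigerous female"
        return ("large non-ovigerous female" if large
                else "small non-ovigerous female")


DEFAULT_SCHEME = StageScheme()


def classify(individual: Individual, scheme: StageScheme = DEFAULT_SCHEME
             ) -> tuple[str, str | None]:
    """Classify one individual into (size class, adult stage or ``None``).

    Raises
    ------
    StagingError
        If the length falls outside ``(0, scheme.max_length_mm]``.
    """
    if not 0 < individual.length_mm <= scheme.max_length_mm:
        raise StagingError(
            f"length {individual.length_mm} mm outside supported range "
            f"(0, {scheme.max_length_mm}] for {individual!r}"
        )
    return scheme.size_class(individual.length_mm), scheme.adult_stage(individual)


# ---------------------------------------------------------------------------
# Stage groups (filters) used throughout the analyses.  Each predicate takes
# an Individual and a StageScheme and answers membership; the names are the
# groupings used in the density, regression and propensity analyses.
# ---------------------------------------------------------------------------

def _size_in(lo: float | None, hi: float | None) -> Callable[[Individual, StageScheme], bool]:
    def pred(ind: Individual, scheme: StageScheme) -> bool:
        ok = True
        if lo is not None:
            ok = ok and ind.length_mm >= lo
        if hi is not None:
            ok = ok and ind.length_mm < hi
        return ok
    return pred


def _is_male(ind: Individual, scheme: StageScheme) -> bool:
    return ind.is_adult and ind.functional_sex == MALE


def _is_female(ind: Individual, scheme: StageScheme) -> bool:
    return ind.is_adult and ind.functional_sex == FEMALE


def _is_nof(ind: Individual, scheme: StageScheme) -> bool:
    return _is_female(ind, scheme) and not ind.ovigerous


STAGE_GROUPS: dict[str, Callable[[Individual, StageScheme], bool]] = {
    "total": lambda ind, s: True,
    "<1.5": _size_in(None, 1.5),
    "1.5-2.5": _size_in(1.5, 2.5),
    "2.5-4": _size_in(2.5, 4.0),
    "4-6": _size_in(4.0, 6.0),
    ">6": _size_in(6.0, None),
    "adult": lambda ind, s: ind.is_adult,
    "male": _is_male,
    "small male": lambda ind, s: _is_male(ind, s) and ind.length_mm < s.adult_split_mm,
    "large male": lambda ind, s: _is_male(ind, s) and ind.length_mm >= s.adult_split_mm,
    "female": _is_female,
    "non-ovigerous female": _is_nof,
    "small non-ovigerous female":
        lambda ind, s: _is_nof(ind, s) and ind.length_mm < s.adult_split_mm,
    "large non-ovigerous female":
        lambda ind, s: _is_nof(ind, s) and ind.length_mm >= s.adult_split_mm,
    "ovigerous female": lambda ind, s: _is_female(ind, s) and ind.ovigerous,
}


def stage_predicate(name: str, scheme: StageScheme = DEFAULT_SCHEME
                    ) -> Callable[[Individual], bool]:
    """A unary predicate over individuals for a named stage group."""
    try:
        pred = STAGE_GROUPS[name]
    except KeyError:
        raise KeyError(
            f"unknown stage group {name!r}; known: {sorted(STAGE_GROUPS)}"
        ) from None
    return lambda ind: pred(ind, scheme)
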