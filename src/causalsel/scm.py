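"""Deterministic two-cause structural systems.

Two binary candidate causes (``focal``, the event whose causal status is
rated, and ``alternate``) combine either conjunctively (AND) or
disjunctively (OR) to produce a binary outcome.  Each cause occurs
independently with a prior probability drawn from the 10x10 design grid
{0.1, ..., 1.0}^2; zero is excluded because the rated outcome is only ever
observed when both draws were possible.

This module enumerates the four cause assignments ("worlds") of a system
and derives the outcome probabilities that the causal-strength predictors
are defined over.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "ATOL",
    "Structure",
    "PriorSetting",
    "World",
    "DesignGrid",
    "OutcomeProbabilities",
    "evaluate_outcome",
    "world_probability",
    "outcome_probabilities",
    "enumerate_grid",
    "grid_index",
]

#: Absolute tolerance for probability comparisons (grid membership, the
#: p = 1 boundary).  Grid values are exact decimals, so anything well below
#: 0.05 works; 1e-12 keeps float noise from round-tripped CSVs harmless.
ATOL = 1e-12


class Structure(str, enum.Enum):
    """How the two causes combine to produce the outcome."""

    CONJUNCTIVE = "conjunctive"  # outcome = focal AND alternate
    DISJUNCTIVE = "disjunctive"  # outcome = focal OR alternate

    @classmethod
    def coerce(cls, value: "Structure | str") -> "Structure":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown causal structure {value!r}; "
                f"expected 'conjunctive' or 'disjunctive'"
            ) from None


def _check_binary(name: str, value: int) -> int:
    if value not in (0, 1):
        raise ValueError(f"{name} must be binary (0 or 1), got {value!r}")
    return int(value)


def evaluate_outcome(structure: Structure | str, focal: int, alternate: int) -> int:
    """Deterministic outcome of the system given the two cause values."""
    structure = Structure.coerce(structure)
    focal = _check_binary("focal", focal)
    alternate = _check_binary("alternate", alternate)
    if structure is Structure.CONJUNCTIVE:
        return focal & alternate
    return focal | alternate


@dataclass(frozen=True)
class PriorSetting:
    """Independent prior probabilities of the two candidate causes.

    Both lie in (0, 1]: zero is excluded from the design because the
    observed outcome requires each draw to have been possible.
    """

    p_focal: float
    p_alternate: float

    def __post_init__(self) -> None:
        for name, p in (("p_focal", self.p_focal), ("p_alternate", self.p_alternate)):
            if not (0.0 < p <= 1.0 + ATOL):
                raise ValueError(f"{name} must lie in (0, 1], got {p}")

    @property
    def focal_certain(self) -> bool:
        return self.p_focal >= 1.0 - ATOL

    @property
    def alternate_certain(self) -> bool:
        return self.p_alternate >= 1.0 - ATOL


def grid_index(p: float) -> int:
    """Map a grid probability to its 1..10 design index (g/10 = p)."""
    g = round(10.0 * p)
    if not 1 <= g <= 10 or abs(p - g / 10.0) > 1e-9:
        raise ValueError(f"{p} is not a design-grid probability (multiples of 0.1)")
    return int(g)


@dataclass(frozen=True)
class World:
    """A joint assignment of the two causes plus the implied outcome.

    Consistency of ``outcome`` with the structure's function of the causes
    is checked on construction.
    """

    structure: Structure
    focal: int
    alternate: int
    outcome: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", Structure.coerce(self.structure))
        _check_binary("focal", self.focal)
        _check_binary("alternate", self.alternate)
        _check_binary("outcome", self.outcome)
        expected = evaluate_outcome(self.structure, self.focal, self.alternate)
        if self.outcome != expected:
            raise ValueError(
                f"inconsistent world: {self.structure.value} outcome of "
                f"(focal={self.focal}, alternate={self.alternate}) is {expected}, "
                f"got {self.outcome}"
            )

    @classmethod
    def from_causes(cls, structure: Structure | str, focal: int, alternate: int) -> "World":
        structure = Structure.coerce(structure)
        return cls(structure, focal, alternate, evaluate_outcome(structure, focal, alternate))


def world_probability(world: World, priors: PriorSetting) -> float:
    """Probability of a world under independent cause priors.

    The outcome is deterministic given the causes, so this is just the
    product of the two marginal probabilities of the cause values.
    """
    p_f = priors.p_focal if world.focal else 1.0 - priors.p_focal
    p_a = priors.p_alternate if world.alternate else 1.0 - priors.p_alternate
    return p_f * p_a


def enumerate_worlds(structure: Structure | str) -> Iterator[World]:
    """The four possible worlds of a system, in (focal, alternate) binary order."""
    structure = Structure.coerce(structure)
    for focal in (0, 1):
        for alternate in (0, 1):
            yield World.from_causes(structure, focal, alternate)


@dataclass(frozen=True)
class OutcomeProbabilities:
    """Outcome probabilities with the focal cause playing the role of C.

    When the focal prior is 1 the event C = 0 has probability zero and the
    conditionals on ¬C are undefined; they are then reported as NaN with
    ``undefined_conditional`` set, rather than raising, so callers can fall
    back on a closed-form limit at the grid edge.
    """

    p_E: float
    p_E_given_C: float
    p_E_given_notC: float
    p_notE_given_notC: float
    undefined_conditional: bool = False


def outcome_probabilities(
    structure: Structure | str, priors: PriorSetting
) -> OutcomeProbabilities:
    """Outcome probabilities by exhaustive world enumeration (C = focal)."""
    structure = Structure.coerce(structure)
    p_E = 0.0
    p_C = 0.0
    p_E_and_C = 0.0
    p_E_and_notC = 0.0
    for world in enumerate_worlds(structure):
        p = world_probability(world, priors)
        if world.outcome:
            p_E += p
            if world.focal:
                p_E_and_C += p
            else:
                p_E_and_notC += p
        if world.focal:
            p_C += p
    p_notC = 1.0 - p_C
    p_E_given_C = p_E_and_C / p_C  # p_C > 0 always (priors exclude zero)
    if p_notC <= ATOL:
        return OutcomeProbabilities(
            p_E=p_E,
            p_E_given_C=p_E_given_C,
            p_E_given_notC=math.nan,
            p_notE_given_notC=math.nan,
            undefined_conditional=True,
        )
    p_E_given_notC = p_E_and_notC / p_notC
    return OutcomeProbabilities(
        p_E=p_E,
        p_E_given_C=p_E_given_C,
        p_E_given_notC=p_E_given_notC,
        p_notE_given_notC=1.0 - p_E_given_notC,
    )


@dataclass(frozen=True)
class DesignGrid:
    """The 100 prior settings used in the experiments, focal-major ascending."""

    settings: tuple[PriorSetting, ...]

    def __post_init__(self) -> None:
        if len(self.settings) != 100 or len(set(self.settings)) != 100:
            raise ValueError("design grid must hold 100 distinct settings")

    def __iter__(self) -> Iterator[PriorSetting]:
        return iter(self.settings)

    def __len__(self) -> int:
        return len(self.settings)

    def __getitem__(self, i: int) -> PriorSetting:
        return self.settings[i]


def enumerate_grid() -> DesignGrid:
    """All 100 parameterizations: 10 focal x 10 alternate values, each g/10.

    Ordering is focal-major ascending: (0.1, 0.1), (0.1, 0.2), ...,
    (1.0, 1.0).  The index g in 1..10 is the regression coding used
    downstream (one unit = a 0.1 probability step).
    """
    settings = tuple(
        PriorSetting(gf / 10.0, ga / 10.0)
        for gf in range(1, 11)
        for ga in range(1, 11)
    )
    return DesignGrid(settings)
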