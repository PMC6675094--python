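"""Monte-Carlo counterfactual sampling and witness-world machinery.

The sampling account holds that people evaluate token causation by
sampling a counterfactual world in proportion to its probability: a
focal-absent world prompts a necessity check (holding the rest of the
actual world fixed), a focal-present world prompts a sufficiency check
(letting the alternate cause vary from its prior).  This module implements
that process literally, as a seeded simulation whose mean score converges
to the closed form in :func:`causalsel.predictors.predict_icard`, and the
witness-world/normality machinery from which the HH1/HH2 piecewise
profiles can be reconstructed mechanistically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .scm import (
    ATOL,
    PriorSetting,
    Structure,
    World,
    evaluate_outcome,
    world_probability,
)
from .predictors import HHConfig

__all__ = [
    "SamplerConfig",
    "SampleEstimate",
    "NormalityOrder",
    "is_necessary",
    "sufficiency_probability",
    "sample_icard_rating",
    "sample_icard_grid",
    "hh_witness",
    "normality_compare",
    "predict_hh_disjunctive_mechanistic",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Monte-Carlo settings.

    ``plug_in`` replaces the per-draw Bernoulli sufficiency outcome with
    its expectation (a variance-reduction device; the estimator stays
    unbiased either way).
    """

    n_samples: int = 100_000
    seed: int = 0
    plug_in: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")


@dataclass(frozen=True)
class SampleEstimate:
    estimate: float
    std_error: float
    n_samples: int


def is_necessary(structure: Structure | str, actual: World) -> bool:
    """Was the focal cause necessary for the outcome in the actual world?

    Flips focal to 0 with the alternate held fixed and asks whether the
    outcome flips to 0.  Requires an actual world in which focal occurred
    and the outcome obtained.
    """
    structure = Structure.coerce(structure)
    if actual.focal != 1 or actual.outcome != 1:
        raise ValueError(
            "necessity is evaluated in an actual world with focal = 1 and outcome = 1"
        )
    return evaluate_outcome(structure, 0, actual.alternate) == 0


def sufficiency_probability(structure: Structure | str, priors: PriorSetting) -> float:
    """Probability that focal = 1 yields the outcome with the alternate redrawn.

    Conjunctively, sufficiency requires the alternate to be present
    (probability p_alternate); disjunctively focal alone suffices.
    """
    structure = Structure.coerce(structure)
    if structure is Structure.CONJUNCTIVE:
        return priors.p_alternate
    return 1.0


def sample_icard_rating(
    structure: Structure | str,
    priors: PriorSetting,
    cfg: SamplerConfig | None = None,
) -> SampleEstimate:
    """Monte-Carlo estimate of the counterfactual-sampling rating.

    Each draw samples a focal-present world with probability p_focal
    (taking the sampling probability directly from the prior).  A
    focal-absent draw scores the necessity indicator for the actual
    both-present world; a focal-present draw scores a Bernoulli
    sufficiency outcome with the alternate redrawn from its prior.  The
    estimate is the mean score; ``std_error`` is the sample standard error
    of that mean.  Reproducible given the seed; no global RNG state.
    """
    structure = Structure.coerce(structure)
    cfg = cfg or SamplerConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    focal_present = rng.random(n) < priors.p_focal
    actual = World.from_causes(structure, 1, 1)
    necessity = 1.0 if is_necessary(structure, actual) else 0.0
    scores = np.full(n, necessity)
    n_present = int(focal_present.sum())
    if cfg.plug_in:
        scores[focal_present] = sufficiency_probability(structure, priors)
    else:
        alternate = rng.random(n_present) < priors.p_alternate
        sufficient = np.where(
            structure is Structure.CONJUNCTIVE, alternate, True
        ).astype(float)
        scores[focal_present] = sufficient

    estimate = float(scores.mean())
    if n > 1:
        std_error = float(scores.std(ddof=1) / np.sqrt(n))
    else:
        std_error = float("nan")
    return SampleEstimate(estimate=estimate, std_error=std_error, n_samples=n)


def sample_icard_grid(
    structure: Structure | str, cfg: SamplerConfig | None = None
):
    """Monte-Carlo sampling estimates over the full design grid.

    Returns a :class:`causalsel.predictors.PredictionGrid` labelled
    ``Icard-MC`` (one independent seeded run per setting), exportable
    through the same CSV shape as the closed-form profiles.
    """
    from .predictors import PredictionGrid
    from .scm import enumerate_grid

    structure = Structure.coerce(structure)
    cfg = cfg or SamplerConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(100)
    grid = enumerate_grid()
    values = np.array(
        [
            sample_icard_rating(
                structure,
                s,
                SamplerConfig(cfg.n_samples, int(seed) % 2**31, cfg.plug_in),
            ).estimate
            for s, seed in zip(grid, seeds)
        ]
    )
    return PredictionGrid(model="Icard-MC", structure=structure, grid=grid, values=values)


def hh_witness(structure: Structure | str, actual: World) -> World:
    """The witness world consulted to judge the focal cause's necessity.

    From the both-present actual world: conjunctively, flipping focal
    alone already removes the outcome; disjunctively the outcome is
    overdetermined, so the witness world must have both causes absent.
    Either way the witness outcome is 0.
    """
    structure = Structure.coerce(structure)
    if actual.focal != 1 or actual.alternate != 1 or actual.outcome != 1:
        raise ValueError("the witness is taken from the both-present actual world")
    if structure is Structure.CONJUNCTIVE:
        return World.from_causes(structure, 0, 1)
    return World.from_causes(structure, 0, 0)


class NormalityOrder(str, enum.Enum):
    MORE_NORMAL = "more_normal"
    LESS_NORMAL = "less_normal"
    EQUAL = "equal"
    INCOMPARABLE = "incomparable"


def _typicality(value: int, p: float) -> float:
    return p if value else 1.0 - p


def normality_compare(
    w1: World,
    w2: World,
    priors: PriorSetting,
    mode: str = "per_variable",
) -> NormalityOrder:
    """Rank two worlds of the same system by normality.

    ``total_probability`` compares total world probabilities.
    ``per_variable`` compares each cause variable's marginal typicality
    and orders worlds by strict dominance: w1 is more normal only when
    every variable is strictly more typical in it.  Conflicting directions
    — and partial ties short of full equality — are incomparable.
    """
    if w1.structure is not w2.structure:
        raise ValueError("worlds must belong to the same structure")
    if mode == "total_probability":
        p1 = world_probability(w1, priors)
        p2 = world_probability(w2, priors)
        if abs(p1 - p2) <= ATOL:
            return NormalityOrder.EQUAL
        return NormalityOrder.MORE_NORMAL if p1 > p2 else NormalityOrder.LESS_NORMAL
    if mode != "per_variable":
        raise ValueError(f"unknown normality mode {mode!r}")

    diffs = []
    for v1, v2, p in (
        (w1.focal, w2.focal, priors.p_focal),
        (w1.alternate, w2.alternate, priors.p_alternate),
    ):
        d = _typicality(v1, p) - _typicality(v2, p)
        diffs.append(0.0 if abs(d) <= ATOL else d)
    if all(d == 0.0 for d in diffs):
        return NormalityOrder.EQUAL
    if all(d > 0.0 for d in diffs):
        return NormalityOrder.MORE_NORMAL
    if all(d < 0.0 for d in diffs):
        return NormalityOrder.LESS_NORMAL
    return NormalityOrder.INCOMPARABLE


def predict_hh_disjunctive_mechanistic(
    priors: PriorSetting,
    mode: str = "per_variable",
    cfg: HHConfig | None = None,
) -> float:
    """HH disjunctive rating rebuilt from the witness/normality machinery.

    The focal cause is judged causal iff its witness world is strictly
    more normal than the actual world under the requested normality order.
    Reproduces the HH1 (per-variable) and HH2 (total-probability) piecewise
    closed forms exactly on the design grid.
    """
    cfg = cfg or HHConfig()
    actual = World.from_causes(Structure.DISJUNCTIVE, 1, 1)
    witness = hh_witness(Structure.DISJUNCTIVE, actual)
    order = normality_compare(witness, actual, priors, mode=mode)
    return cfg.x_high if order is NormalityOrder.MORE_NORMAL else 0.0
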