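"""Closed-form predicted causal ratings for five token-causation models.

All predictors map a prior setting of the two-cause system to a predicted
causal rating of the focal event in [0, 1]:

* ``HH`` — a witness-world/normality account (conjunctive structure), with
  two disjunctive variants ``HH1`` (per-variable normality) and ``HH2``
  (total-world-probability normality).
* ``Icard`` — a counterfactual-sampling account mixing necessity and
  sufficiency in proportion to the focal prior.
* ``SP`` — probability raising over the prior: P(E|C) − P(E).
* ``DeltaP`` — probability raising over the cause-absent state:
  P(E|C) − P(E|¬C).
* ``PowerPC`` — ΔP normalized by P(¬E|¬C).

SP/ΔP/Power-PC are evaluated from the general conditional-probability
definitions via world enumeration; at the p_focal = 1 grid edge, where the
conditional on ¬C is undefined, the closed-form limit is used so the full
grid is covered (the closed forms are finite everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .scm import (
    ATOL,
    DesignGrid,
    PriorSetting,
    Structure,
    enumerate_grid,
    outcome_probabilities,
)

__all__ = [
    "MODEL_NAMES",
    "HHConfig",
    "PredictionGrid",
    "predict_hh_conjunctive",
    "predict_hh_disjunctive",
    "predict_icard",
    "predict_sp",
    "predict_deltap",
    "predict_powerpc",
    "predict",
    "predict_grid",
    "models_for_structure",
]

#: Predictor labels accepted by :func:`predict_grid`.
MODEL_NAMES = ("HH", "HH1", "HH2", "Icard", "SP", "DeltaP", "PowerPC")


@dataclass(frozen=True)
class HHConfig:
    """Free parameters of the witness-world/normality predictor.

    The account is ordinal; following the convention adopted throughout, a
    maximally causal verdict scores ``x_high`` (default 1) and a demoted
    but still causal verdict scores ``x_mid`` (default 1/2), with
    0 < x_mid < x_high <= 1.  ``conjunctive_tie`` fixes the rating when the
    two priors are equal and both at most 0.5, a case the piecewise
    definition leaves open: ``"high"`` (default) treats the two equally
    normal witness worlds as no reason to demote the focal cause.
    """

    x_high: float = 1.0
    x_mid: float = 0.5
    conjunctive_tie: Literal["high", "mid"] = "high"

    def __post_init__(self) -> None:
        if not (0.0 < self.x_mid < self.x_high <= 1.0):
            raise ValueError(
                f"require 0 < x_mid < x_high <= 1, got "
                f"x_mid={self.x_mid}, x_high={self.x_high}"
            )
        if self.conjunctive_tie not in ("high", "mid"):
            raise ValueError("conjunctive_tie must be 'high' or 'mid'")


def predict_hh_conjunctive(priors: PriorSetting, cfg: HHConfig | None = None) -> float:
    """Witness-normality rating of the focal cause, conjunctive structure.

    A focal prior above 0.5 makes the focal witness world (focal absent)
    less normal than the actual world, so focal is never a cause.
    Otherwise focal is causal, demoted to ``x_mid`` only when the alternate
    cause has the more normal witness world (p_alternate < p_focal <= 0.5).
    When p_focal <= 0.5 < p_alternate the alternate is not an admissible
    cause at all, so focal scores ``x_high``.
    """
    cfg = cfg or HHConfig()
    p_f, p_a = priors.p_focal, priors.p_alternate
    if p_f > 0.5 + ATOL:
        return 0.0
    if p_a < p_f - ATOL:  # alternate's witness world is more normal
        return cfg.x_mid
    if abs(p_a - p_f) <= ATOL and cfg.conjunctive_tie == "mid":
        return cfg.x_mid
    return cfg.x_high


def predict_hh_disjunctive(
    priors: PriorSetting,
    mode: Literal["per_variable", "total_probability"] = "per_variable",
    cfg: HHConfig | None = None,
) -> float:
    """Witness-normality rating, disjunctive structure (variants HH1/HH2).

    The sole witness world has both causes absent.  In per-variable mode
    (HH1) it counts as more normal than the actual world only when every
    variable is strictly more typical there, i.e. both priors < 0.5; mixed
    cases are incomparable and score 0.  In total-probability mode (HH2)
    worlds are ranked by their total probability, and the witness world
    wins iff p_focal + p_alternate < 1.
    """
    cfg = cfg or HHConfig()
    p_f, p_a = priors.p_focal, priors.p_alternate
    if mode == "per_variable":
        causal = p_f < 0.5 - ATOL and p_a < 0.5 - ATOL
    elif mode == "total_probability":
        causal = p_f + p_a < 1.0 - ATOL
    else:
        raise ValueError(f"unknown normality mode {mode!r}")
    return cfg.x_high if causal else 0.0


def predict_icard(structure: Structure | str, priors: PriorSetting) -> float:
    """Counterfactual-sampling rating of the focal cause.

    A focal-absent world is sampled with probability 1 − p_focal and scores
    the necessity of focal (1 in the conjunctive structure, 0 in the
    disjunctive one, where the alternate draw overdetermines the outcome);
    a focal-present world is sampled with probability p_focal and scores
    the probability that focal would be sufficient with the alternate
    redrawn from its prior (p_alternate conjunctively, 1 disjunctively).
    """
    structure = Structure.coerce(structure)
    p_f, p_a = priors.p_focal, priors.p_alternate
    if structure is Structure.CONJUNCTIVE:
        # (1 - p_f)·1 + p_f·p_a  ==  1 - p_f·(1 - p_a)
        return 1.0 - p_f * (1.0 - p_a)
    return p_f


def predict_sp(structure: Structure | str, priors: PriorSetting) -> float:
    """Probability raising over the prior: P(E|C) − P(E), C = focal."""
    probs = outcome_probabilities(structure, priors)
    return probs.p_E_given_C - probs.p_E


def predict_deltap(structure: Structure | str, priors: PriorSetting) -> float:
    """Probability raising over the cause-absent state: P(E|C) − P(E|¬C).

    At p_focal = 1 the conditional on ¬C is undefined by enumeration; the
    closed-form limit (p_alternate conjunctively, 1 − p_alternate
    disjunctively) is returned instead so the grid edge is covered.
    """
    structure = Structure.coerce(structure)
    probs = outcome_probabilities(structure, priors)
    if probs.undefined_conditional:
        if structure is Structure.CONJUNCTIVE:
            return priors.p_alternate
        return 1.0 - priors.p_alternate
    return probs.p_E_given_C - probs.p_E_given_notC


def predict_powerpc(structure: Structure | str, priors: PriorSetting) -> float:
    """ΔP normalized by the outcome's absence rate when the cause is absent.

    The disjunctive 0/0 case (alternate certain) resolves to the constant-1
    closed form, which is also the limit from below.
    """
    structure = Structure.coerce(structure)
    probs = outcome_probabilities(structure, priors)
    if probs.undefined_conditional or probs.p_notE_given_notC <= ATOL:
        # Closed-form limits: conjunctive → p_alternate; disjunctive → 1.
        if structure is Structure.CONJUNCTIVE:
            return priors.p_alternate
        return 1.0
    return (probs.p_E_given_C - probs.p_E_given_notC) / probs.p_notE_given_notC


def models_for_structure(structure: Structure | str) -> tuple[str, ...]:
    """Predictor labels defined for a structure (HH is conjunctive-only,
    HH1/HH2 disjunctive-only)."""
    structure = Structure.coerce(structure)
    if structure is Structure.CONJUNCTIVE:
        return ("HH", "Icard", "SP", "DeltaP", "PowerPC")
    return ("HH1", "HH2", "Icard", "SP", "DeltaP", "PowerPC")


def predict(
    model: str,
    structure: Structure | str,
    priors: PriorSetting,
    cfg: HHConfig | None = None,
) -> float:
    """Evaluate one predictor at one prior setting."""
    structure = Structure.coerce(structure)
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    if model == "HH":
        if structure is not Structure.CONJUNCTIVE:
            raise ValueError("model 'HH' is defined for the conjunctive structure only")
        return predict_hh_conjunctive(priors, cfg)
    if model in ("HH1", "HH2"):
        if structure is not Structure.DISJUNCTIVE:
            raise ValueError(f"model {model!r} is defined for the disjunctive structure only")
        mode = "per_variable" if model == "HH1" else "total_probability"
        return predict_hh_disjunctive(priors, mode, cfg)
    if model == "Icard":
        return predict_icard(structure, priors)
    if model == "SP":
        return predict_sp(structure, priors)
    if model == "DeltaP":
        return predict_deltap(structure, priors)
    return predict_powerpc(structure, priors)


@dataclass(frozen=True)
class PredictionGrid:
    """A predictor's ratings over the full 100-setting design grid."""

    model: str
    structure: Structure
    grid: DesignGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.grid),):
            raise ValueError("one value per grid setting required")
        if np.any(values < -ATOL) or np.any(values > 1.0 + ATOL):
            raise ValueError("predicted ratings must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    def value_at(self, priors: PriorSetting) -> float:
        for setting, value in zip(self.grid, self.values):
            if (
                abs(setting.p_focal - priors.p_focal) <= ATOL
                and abs(setting.p_alternate - priors.p_alternate) <= ATOL
            ):
                return float(value)
        raise KeyError(f"{priors} is not a grid setting")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model,
                "structure": self.structure.value,
                "p_focal": [s.p_focal for s in self.grid],
                "p_alternate": [s.p_alternate for s in self.grid],
                "prediction": self.values,
            }
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame["p_focal"] = frame["p_focal"].map("{:.1f}".format)
        frame["p_alternate"] = frame["p_alternate"].map("{:.1f}".format)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionGrid":
        """Read a grid written by :meth:`to_csv` (order-insensitive)."""
        frame = pd.read_csv(path)
        missing = [c for c in ("model", "structure", "p_focal", "p_alternate", "prediction")
                   if c not in frame.columns]
        if missing:
            raise ValueError(f"prediction CSV is missing columns {missing}")
        models = frame["model"].unique()
        structures = frame["structure"].unique()
        if len(models) != 1 or len(structures) != 1:
            raise ValueError("prediction CSV must hold a single model and structure")
        grid = enumerate_grid()
        lookup = {
            (round(f, 1), round(a, 1)): v
            for f, a, v in zip(frame["p_focal"], frame["p_alternate"], frame["prediction"])
        }
        try:
            values = np.array(
                [lookup[(round(s.p_focal, 1), round(s.p_alternate, 1))] for s in grid]
            )
        except KeyError as exc:
            raise ValueError(f"prediction CSV is missing grid setting {exc}") from None
        return cls(
            model=str(models[0]),
            structure=Structure.coerce(structures[0]),
            grid=grid,
            values=values,
        )


def predict_grid(
    model: str,
    structure: Structure | str,
    cfg: HHConfig | None = None,
) -> PredictionGrid:
    """Materialize a predictor's full response profile over the design grid."""
    structure = Structure.coerce(structure)
    grid = enumerate_grid()
    values = np.array([predict(model, structure, s, cfg) for s in grid])
    return PredictionGrid(model=model, structure=structure, grid=grid, values=values)
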