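"""Synthetic participant-rating generator.

Emulates the statistical structure of the two rating experiments: ~1000
subjects each rate 5 distinct prior settings drawn uniformly without
replacement from the 10x10 design grid, answering on a 1-9 agreement
scale.  A subject's latent rating is a linear function of the two grid
indices (one unit = a 0.1 probability step) with subject-level random
intercepts and slopes, plus two certainty nonlinearities observed
empirically:

* a *jump* — an additive offset applied when a prior equals 1, over and
  above the linear trend;
* *suppression* — the other prior's slope flattens toward its grid-mean
  level when a prior equals 1 (multiplier 0 removes the effect entirely
  while leaving the condition's average level unchanged).

The latent value is clamped to [0, 1] and discretized to the 1-9 scale by
affine rounding; the scaled rating is (raw - 1)/8.  Clamping slightly
attenuates recovered slopes near the scale ends, which downstream
recovery tolerances account for.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .scm import Structure, enumerate_grid

__all__ = [
    "GeneratorConfig",
    "RATINGS_COLUMNS",
    "default_config",
    "generate_design",
    "generate_ratings",
    "condition_means",
    "load_ratings_csv",
    "write_ratings_csv",
]

#: Canonical CSV schema of a ratings table.
RATINGS_COLUMNS = ("subject", "trial", "structure", "p_focal", "p_alternate", "rating")

#: Mean grid index; the suppression anchor (slopes flatten to this level).
GRID_MEAN_INDEX = 5.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Generative parameters of a synthetic rating experiment.

    Slopes are in scaled-rating units per 0.1 probability step (i.e. per
    grid-index unit); jumps are scaled-rating offsets at the certain
    (p = 1) conditions; suppression multipliers scale the other
    variable's slope when a prior equals 1 (0 = fully suppressed,
    1 = untouched).
    """

    structure: Structure = Structure.CONJUNCTIVE
    n_subjects: int = 999
    trials_per_subject: int = 5
    intercept: float = 0.5
    slope_focal: float = 0.0
    slope_alternate: float = 0.0
    jump_focal_certain: float = 0.0
    jump_alternate_certain: float = 0.0
    suppress_focal_when_alt_certain: float = 1.0
    suppress_alt_when_focal_certain: float = 1.0
    sd_intercept: float = 0.1
    sd_slope_focal: float = 0.02
    sd_slope_alternate: float = 0.02
    sd_residual: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", Structure.coerce(self.structure))
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("n_subjects and trials_per_subject must be positive")
        if self.trials_per_subject > 100:
            raise ValueError("at most 100 distinct settings exist per subject")
        for name in ("sd_intercept", "sd_slope_focal", "sd_slope_alternate", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("suppress_focal_when_alt_certain", "suppress_alt_when_focal_certain"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["structure"] = self.structure.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown generator config keys: {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(name: str, **overrides) -> GeneratorConfig:
    """Load a shipped experiment config (``exp1_conjunctive`` or
    ``exp2_disjunctive``), optionally overriding fields (e.g. ``seed``)."""
    resource = importlib.resources.files("causalsel.configs").joinpath(f"{name}.yaml")
    if not resource.is_file():
        raise ValueError(
            f"unknown default config {name!r}; "
            "expected 'exp1_conjunctive' or 'exp2_disjunctive'"
        )
    cfg = GeneratorConfig.from_dict(yaml.safe_load(resource.read_text()))
    return cfg.replace(**overrides) if overrides else cfg


def generate_design(n_subjects: int, trials: int, seed: int) -> pd.DataFrame:
    """Assign prior settings to subject-trials.

    Each subject receives ``trials`` distinct settings drawn uniformly
    without replacement from the 100-setting design grid.  Returns a long
    frame with columns subject, trial, p_focal, p_alternate.
    """
    if trials > 100:
        raise ValueError("trials per subject cannot exceed the 100 grid settings")
    if n_subjects < 1 or trials < 1:
        raise ValueError("n_subjects and trials must be positive")
    grid = enumerate_grid()
    rng = np.random.default_rng(seed)
    # Row-wise uniform sample without replacement: first `trials` ranks of a
    # random permutation per subject.
    order = np.argsort(rng.random((n_subjects, 100)), axis=1)[:, :trials]
    p_f = np.array([s.p_focal for s in grid])[order.ravel()]
    p_a = np.array([s.p_alternate for s in grid])[order.ravel()]
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(1, n_subjects + 1), trials),
            "trial": np.tile(np.arange(1, trials + 1), n_subjects),
            "p_focal": p_f,
            "p_alternate": p_a,
        }
    )


def generate_ratings(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate a full ratings table under the generative model.

    Deterministic given ``config.seed``.  Columns: subject, trial,
    structure, p_focal, p_alternate, rating (integer 1-9), rating_scaled.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    design = generate_design(
        config.n_subjects,
        config.trials_per_subject,
        seed=seeds[0],
    )
    rng = np.random.default_rng(seeds[1])

    g_f = np.rint(10.0 * design["p_focal"].to_numpy()).astype(int)
    g_a = np.rint(10.0 * design["p_alternate"].to_numpy()).astype(int)
    d_f = (g_f == 10).astype(float)
    d_a = (g_a == 10).astype(float)

    # Suppression flattens a slope toward its grid-mean level when the
    # other prior is certain, leaving the condition's average level alone.
    m_f = np.where(d_a == 1.0, config.suppress_focal_when_alt_certain, 1.0)
    m_a = np.where(d_f == 1.0, config.suppress_alt_when_focal_certain, 1.0)
    phi_f = m_f * g_f + (1.0 - m_f) * GRID_MEAN_INDEX
    phi_a = m_a * g_a + (1.0 - m_a) * GRID_MEAN_INDEX

    mu = (
        config.intercept
        + config.slope_focal * phi_f
        + config.slope_alternate * phi_a
        + config.jump_focal_certain * d_f
        + config.jump_alternate_certain * d_a
    )

    n = config.n_subjects
    b0 = rng.normal(0.0, config.sd_intercept, size=n)
    b1 = rng.normal(0.0, config.sd_slope_focal, size=n)
    b2 = rng.normal(0.0, config.sd_slope_alternate, size=n)
    subj = design["subject"].to_numpy() - 1
    latent = (
        mu
        + b0[subj]
        + b1[subj] * g_f
        + b2[subj] * g_a
        + rng.normal(0.0, config.sd_residual, size=len(design))
    )

    clipped = np.clip(latent, 0.0, 1.0)
    rating = np.rint(1.0 + 8.0 * clipped).astype(int)

    out = design.copy()
    out.insert(2, "structure", config.structure.value)
    out["rating"] = rating
    out["rating_scaled"] = (rating - 1) / 8.0
    return out


def condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-setting mean scaled rating and count.

    Returns a frame indexed by (p_focal, p_alternate) with columns
    ``mean`` and ``count``; grid settings never rated are omitted with a
    warning.  Raises on an empty table.
    """
    if len(table) == 0:
        raise ValueError("cannot compute condition means of an empty ratings table")
    table = _with_scaled(table)
    means = (
        table.groupby(["p_focal", "p_alternate"])["rating_scaled"]
        .agg(["mean", "count"])
        .sort_index()
    )
    if len(means) < 100:
        warnings.warn(
            f"only {len(means)} of 100 grid settings have ratings; "
            "uncovered settings omitted",
            stacklevel=2,
        )
    return means


def _with_scaled(table: pd.DataFrame) -> pd.DataFrame:
    if "rating_scaled" not in table.columns:
        table = table.copy()
        table["rating_scaled"] = (table["rating"] - 1) / 8.0
    return table


def load_ratings_csv(path) -> pd.DataFrame:
    """Read a ratings CSV in the canonical schema, deriving rating_scaled.

    Raises ``ValueError`` naming the first missing column or first bad row
    on schema violations.
    """
    table = pd.read_csv(path)
    for col in RATINGS_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"ratings CSV is missing required column {col!r}")
    ratings = table["rating"]
    bad = ~ratings.between(1, 9) | (ratings != ratings.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"ratings CSV row {row}: rating {ratings.iloc[row]!r} "
            "is not an integer in 1..9"
        )
    table["rating"] = ratings.astype(int)
    return _with_scaled(table)


def write_ratings_csv(table: pd.DataFrame, path) -> None:
    """Write the canonical 6-column CSV (probabilities to one decimal)."""
    out = table.loc[:, list(RATINGS_COLUMNS)].copy()
    out["p_focal"] = out["p_focal"].map("{:.1f}".format)
    out["p_alternate"] = out["p_alternate"].map("{:.1f}".format)
    out.to_csv(path, index=False)
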