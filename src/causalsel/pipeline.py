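"""End-to-end analysis report: everything computed from one ratings table.

Produces a JSON-serializable report mirroring the full analysis battery:
main effects, the four certainty analyses (two jump tests, two conditional
tests, two interactions), order-effect checks, and item-level model
comparison with Williams's tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Iterable

import pandas as pd

from . import __version__
from .predictors import predict_grid, models_for_structure
from .scm import Structure
from .simulate import condition_means, _with_scaled
from .stats import (
    certainty_jump_test,
    compare_models,
    conditional_effect_test,
    fit_main_effects,
    interaction_test,
    order_effect_checks,
)

__all__ = ["run_analysis", "summarize"]


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, Structure):
        return obj.value
    return obj


def run_analysis(
    table: pd.DataFrame,
    structure: Structure | str | None = None,
    models: Iterable[str] | None = None,
    estimator: str = "mixedlm",
    config_meta: dict | None = None,
) -> dict:
    """Run the full analysis battery on a ratings table.

    ``structure`` defaults to the table's structure column (which must be
    constant); ``models`` defaults to every predictor defined for that
    structure.  Returns a plain dict ready for ``json.dump``.
    """
    table = _with_scaled(table)
    if structure is None:
        values = table["structure"].unique()
        if len(values) != 1:
            raise ValueError(f"ratings table mixes structures: {sorted(values)}")
        structure = values[0]
    structure = Structure.coerce(structure)
    models = tuple(models) if models is not None else models_for_structure(structure)

    effects = fit_main_effects(table, estimator=estimator)
    jumps = {v: certainty_jump_test(table, v) for v in ("focal", "alternate")}
    conditional = {
        "focal_when_alternate_certain": conditional_effect_test(table, "focal", "alternate"),
        "alternate_when_focal_certain": conditional_effect_test(table, "alternate", "focal"),
    }
    interactions = {
        "focal_by_alternate_certain": interaction_test(table, "focal", "alternate"),
        "alternate_by_focal_certain": interaction_test(table, "alternate", "focal"),
    }
    order = order_effect_checks(table)

    means = condition_means(table)
    grids = {name: predict_grid(name, structure) for name in models}
    comparison = compare_models(grids, means)

    report = {
        "package_version": __version__,
        "structure": structure.value,
        "n_subjects": int(table["subject"].nunique()),
        "n_ratings": int(len(table)),
        "main_effects": _asdict(effects),
        "certainty_jumps": _asdict(jumps),
        "conditional_effects": _asdict(conditional),
        "interactions": _asdict(interactions),
        "order_checks": _asdict(order),
        "model_comparison": {
            "n_conditions": comparison.n_conditions,
            "correlations": _asdict(list(comparison.correlations)),
            "williams_pairs": [
                {"model_a": a, "model_b": b, **_asdict(w)}
                for a, b, w in comparison.pairwise
            ],
        },
    }
    if config_meta:
        blob = json.dumps(config_meta, sort_keys=True).encode()
        report["config"] = config_meta
        report["config_sha1"] = hashlib.sha1(blob).hexdigest()
    return report


def summarize(report: dict) -> str:
    """Plain-text digest of an analysis report."""
    eff = report["main_effects"]
    lines = [
        f"causalsel {report['package_version']} — {report['structure']} structure",
        f"{report['n_subjects']} subjects, {report['n_ratings']} ratings",
        "",
        "Main effects (scaled rating per 0.1 probability step):",
        f"  focal:     b = {eff['slope_focal']:+.4f}  SE = {eff['se_focal']:.4f}"
        f"  t = {eff['t_focal']:.1f}  p = {eff['p_focal']:.3g}",
        f"  alternate: b = {eff['slope_alternate']:+.4f}  SE = {eff['se_alternate']:.4f}"
        f"  t = {eff['t_alternate']:.1f}  p = {eff['p_alternate']:.3g}",
        "",
        "Certainty jumps (observed mean vs 95% extrapolation interval):",
    ]
    for var, jump in report["certainty_jumps"].items():
        lo, hi = jump["interval"]
        flag = "OUTSIDE" if jump["outside_flag"] else "inside"
        lines.append(
            f"  {var}: observed {jump['observed_mean']:.2f} vs "
            f"[{lo:.2f}, {hi:.2f}] — {flag}"
        )
    lines.append("")
    lines.append("Conditional effects (other prior certain):")
    for name, res in report["conditional_effects"].items():
        lines.append(
            f"  {name}: b = {res['slope']:+.4f}  p = {res['p']:.2f}"
            f"  BF_null = {res['bf_null']:.1f}"
        )
    lines.append("")
    lines.append("Item-level model comparison (Pearson r over conditions):")
    for corr in sorted(
        report["model_comparison"]["correlations"],
        key=lambda c: -1.0 if c["r"] is None else c["r"],
        reverse=True,
    ):
        if corr["not_applicable"]:
            lines.append(f"  {corr['model']:8s} r = n/a (constant profile)")
        else:
            lo, hi = corr["ci_95"]
            lines.append(
                f"  {corr['model']:8s} r = {corr['r']:.2f}  [{lo:.2f}, {hi:.2f}]"
            )
    return "\n".join(lines)
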