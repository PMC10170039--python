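"""Best-case / worst-case counterfactual panels and efficiency impact ratios.

To quantify how much a quality or access variable drives the overall
efficiency score, the panel is re-solved with that one column replaced by a
hypothetical bound and the per-DMU ratio (scenario score / baseline score)
is reported.  A ratio above 1 means the counterfactual improves efficiency;
below 1, that the real data already outperform it.

Rules are expressions over existing columns or the near-zero constant
``epsilon``: e.g. the best case for pressure-ulcer counts is "epsilon"
(no ulcers) and the worst case is "E7" (every inpatient has one).  Only the
Q4 pair of bounds is prescribed by the study design; the rest of the default
table below is a documented reconstruction and fully overridable — runs
record the rule used in the output metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import VRS, ModelRun, SolverError, run_model
from .network import NetworkSpec
from .panel import PanelDataset, ValidationError

#: absolute stand-in for "zero" cells in counterfactual columns; matches the
#: positivity floor of the synthetic generator, and is idempotent (re-applying
#: a best-case rule changes nothing)
SCENARIO_EPSILON = 1e-6

_MAX_RULE = re.compile(r"^\s*([0-9.eE+-]+)\s*\*\s*max\(\s*(\w+)\s*\)\s*$")


@dataclass(frozen=True)
class ScenarioSpec:
    """One counterfactual: set ``variable_id`` to ``rule`` under ``mode``.

    ``rule`` is ``"epsilon"``, a column name (cellwise copy), or
    ``"<factor>*max(<column>)"`` (constant multiple of an observed maximum).
    """

    variable_id: str
    mode: str  # "best" | "worst"
    rule: str

    def __post_init__(self) -> None:
        if self.mode not in ("best", "worst"):
            raise ValueError(f"mode must be 'best' or 'worst', got {self.mode!r}")

    @property
    def scenario_id(self) -> str:
        return f"{self.variable_id}:{self.mode}"


@dataclass(frozen=True)
class ScenarioImpact:
    """Per-DMU score ratios of one scenario against the baseline."""

    variable_id: str
    mode: str
    rule: str
    per_dmu_ratio: dict[str, float]
    max_impact: float  # max over DMUs of (ratio - 1)
    mean_impact: float  # mean over DMUs of (ratio - 1)
    group_mean_abs: dict[str, float]  # group -> mean |ratio - 1|


#: default bound table for the ten quality/access variables.  Best/worst
#: bounds other than Q4's are reconstructions: desirable counts are bounded
#: by their volume column (E7 inpatients, E8 outpatient visits, E9
#: surgeries), undesirable counts by the same volumes, waiting days by a
#: multiple of the observed maximum.
DEFAULT_RULES: dict[str, dict[str, str]] = {
    "Q1": {"best": "E7", "worst": "epsilon"},
    "Q2": {"best": "E7", "worst": "epsilon"},
    "Q3": {"best": "E9", "worst": "epsilon"},
    "Q4": {"best": "epsilon", "worst": "E7"},
    "Q5": {"best": "epsilon", "worst": "E7"},
    "Q6": {"best": "epsilon", "worst": "E9"},
    "Q7": {"best": "epsilon", "worst": "E9"},
    "A1": {"best": "E9", "worst": "epsilon"},
    "A2": {"best": "epsilon", "worst": "E8"},
    "A3": {"best": "epsilon", "worst": "2*max(A3)"},
}


def default_scenarios(variables=None) -> list[ScenarioSpec]:
    """Both modes of the default rule table, optionally restricted."""
    out = []
    for var, rules in DEFAULT_RULES.items():
        if variables is not None and var not in variables:
            continue
        for mode in ("best", "worst"):
            out.append(ScenarioSpec(var, mode, rules[mode]))
    return out


def _evaluate_rule(panel: PanelDataset, rule: str, shape) -> np.ndarray:
    if rule == "epsilon":
        return np.full(shape, SCENARIO_EPSILON)
    m = _MAX_RULE.match(rule)
    if m:
        factor, col = float(m.group(1)), m.group(2)
        return np.full(shape, factor * float(panel.column(col).max()))
    if rule in panel.variable_ids:
        return panel.column(rule)
    raise ValidationError(f"scenario rule {rule!r} references no panel column")


def apply_scenario(panel: PanelDataset, spec: ScenarioSpec) -> PanelDataset:
    """Return a panel with exactly one column replaced per the rule."""
    if spec.variable_id not in panel.variable_ids:
        raise KeyError(f"scenario variable {spec.variable_id!r} not in panel")
    new_col = _evaluate_rule(panel, spec.rule, (panel.n_dmus, panel.n_periods))
    if np.any(new_col <= 0):
        raise ValidationError(
            f"scenario {spec.scenario_id} produced non-positive values"
        )
    return panel.with_column(spec.variable_id, new_col)


def impact_analysis(
    panel: PanelDataset,
    spec: NetworkSpec,
    scenarios: list[ScenarioSpec],
    rts: str = VRS,
    *,
    baseline: ModelRun | None = None,
    **solve_kwargs,
) -> list[ScenarioImpact]:
    """Recompute the model under each counterfactual and report ratios.

    Ratios are taken on the cross-period average overall scores.  One
    variable is changed at a time; correlated columns are deliberately left
    untouched (joint edits are a different study design).
    """
    if baseline is None:
        baseline = run_model(panel, spec, rts, **solve_kwargs)
    base = baseline.summary
    impacts = []
    for sc in scenarios:
        try:
            counterfactual = apply_scenario(panel, sc)
            run = run_model(counterfactual, spec, rts, **solve_kwargs)
        except (SolverError, ValidationError, KeyError) as exc:
            raise type(exc)(f"[scenario {sc.scenario_id}] {exc}") from exc
        ratio = run.summary / base
        impact = ratio - 1.0
        groups = pd.Series({d: panel.groups[d] for d in ratio.index})
        group_mean_abs = impact.abs().groupby(groups).mean()
        impacts.append(
            ScenarioImpact(
                variable_id=sc.variable_id,
                mode=sc.mode,
                rule=sc.rule,
                per_dmu_ratio={d: float(r) for d, r in ratio.items()},
                max_impact=float(impact.max()),
                mean_impact=float(impact.mean()),
                group_mean_abs={g: float(v) for g, v in group_mean_abs.items()},
            )
        )
    return impacts


def impacts_frame(impacts: list[ScenarioImpact]) -> pd.DataFrame:
    """Long table ``variable,mode,rule,dmu,ratio,impact``."""
    rows = []
    for imp in impacts:
        for dmu, ratio in imp.per_dmu_ratio.items():
            rows.append(
                {
                    "variable": imp.variable_id,
                    "mode": imp.mode,
                    "rule": imp.rule,
                    "dmu": dmu,
                    "ratio": ratio,
                    "impact": ratio - 1.0,
                }
            )
    return pd.DataFrame(rows)


def impacts_summary(impacts: list[ScenarioImpact]) -> pd.DataFrame:
    """Summary table ``variable,mode,rule,max_impact,mean_impact,group,group_mean_abs``."""
    rows = []
    for imp in impacts:
        for group, val in sorted(imp.group_mean_abs.items()):
            rows.append(
                {
                    "variable": imp.variable_id,
                    "mode": imp.mode,
                    "rule": imp.rule,
                    "max_impact": imp.max_impact,
                    "mean_impact": imp.mean_impact,
                    "group": group,
                    "group_mean_abs": val,
                }
            )
    return pd.DataFrame(rows)
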