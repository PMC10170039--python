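"""Sensitivity of scores to the choice of representative within a cluster.

When screening finds a cluster of near-collinear variables, any single
member can stand in for the group.  This module enumerates every model
variant obtained by picking one representative per cluster (Cartesian
product across clusters) and measures, per DMU, how much the cross-period
average overall score moves across variants.  Small ranges mean the
conclusions do not hinge on which collinear variable was kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .core import VRS, run_model
from .network import NetworkSpec
from .panel import PanelDataset
from .screening import CorrelationCluster

#: per-DMU score ranges above this are flagged as sensitive (5 percentage points)
SENSITIVITY_THRESHOLD = 0.05


@dataclass(frozen=True)
class VariantReport:
    """Per-DMU spread of overall scores across model variants."""

    model_id: str
    variants: tuple[NetworkSpec, ...]
    per_dmu_range: pd.Series  # dmu -> max pairwise |score difference|
    flagged: tuple[str, ...]  # DMUs whose range exceeds the threshold
    summaries: pd.DataFrame  # dmu x variant matrix of overall scores
    threshold: float


def enumerate_variants(
    spec: NetworkSpec, clusters: list[CorrelationCluster]
) -> list[NetworkSpec]:
    """One spec per combination of single-representative cluster choices.

    Clusters with no member in the spec are skipped (the variant count is
    the product of the remaining cluster sizes); a cluster only partially
    present is an error, because its members would no longer be
    exchangeable within the model.
    """
    applicable = []
    spec_vars = set(spec.variables())
    for cl in clusters:
        members = list(cl.variable_ids)
        present = [v for v in members if v in spec_vars]
        if not present:
            continue
        if len(present) != len(members):
            raise KeyError(
                f"cluster {members} only partially present in spec "
                f"{spec.name!r}: missing {sorted(set(members) - spec_vars)}"
            )
        applicable.append(members)

    variants = []
    for picks in itertools.product(*applicable) if applicable else [()]:
        mapping: dict[str, str | None] = {}
        for members, keep in zip(applicable, picks):
            for v in members:
                if v != keep:
                    mapping[v] = None
        suffix = "+".join(picks) if picks else "base"
        variants.append(
            spec.replace_variables(mapping, name=f"{spec.name}[{suffix}]")
        )
    return variants


def compare_variants(
    panel: PanelDataset,
    variants: list[NetworkSpec],
    rts: str = VRS,
    threshold: float = SENSITIVITY_THRESHOLD,
    **solve_kwargs,
) -> VariantReport:
    """Run every variant and report the per-DMU max pairwise score spread.

    The difference metric is the max absolute pairwise difference of the
    per-DMU cross-period average overall scores (equivalently max - min),
    which is symmetric in the variant order.
    """
    if not variants:
        raise ValueError("need at least one variant")
    summaries = pd.DataFrame(
        {v.name: run_model(panel, v, rts, **solve_kwargs).summary for v in variants}
    )
    per_dmu_range = summaries.max(axis=1) - summaries.min(axis=1)
    per_dmu_range.name = "range"
    flagged = tuple(per_dmu_range.index[per_dmu_range > threshold])
    base = variants[0].name.split("[")[0]
    return VariantReport(
        model_id=base,
        variants=tuple(variants),
        per_dmu_range=per_dmu_range,
        flagged=flagged,
        summaries=summaries,
        threshold=threshold,
    )
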