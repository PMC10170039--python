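"""Pearson-correlation screening and merging of near-collinear variables.

Too many variables relative to the number of DMUs inflates the efficient
set, and near-collinear variables carry the same information into the LP.
Screening computes the Pearson product-moment correlation over the pooled
(dmu, period) observations, clusters variables whose correlation reaches a
threshold (default 0.95) *within the same (division, role) context* — only
variables with the same classification in the model are exchangeable — and
optionally merges a cluster into a single summed variable (e.g. doctor hours
+ nurse hours -> clinical staff hours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkSpec
from .panel import PanelDataset, ValidationError


@dataclass(frozen=True)
class CorrelationCluster:
    """>= 2 variables, pairwise correlated above threshold, sharing a role."""

    variable_ids: tuple[str, ...]
    role_context: tuple[str, str]  # (division or "src->dst", role)
    pairwise_r: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable_ids", tuple(self.variable_ids))

    def __len__(self) -> int:
        return len(self.variable_ids)


def pearson_matrix(panel: PanelDataset, variables=None) -> pd.DataFrame:
    """Pearson correlations over pooled (dmu, period) observations.

    Zero-variance columns get NaN rows/columns (undefined correlation) and
    are therefore never clustered.  Requires at least 3 pooled observations.
    """
    variables = list(variables) if variables is not None else list(panel.variable_ids)
    n_obs = panel.n_dmus * panel.n_periods
    if n_obs < 3:
        raise ValidationError(
            f"need >= 3 pooled (dmu, period) observations, got {n_obs}"
        )
    pooled = pd.DataFrame(
        {v: panel.column(v).ravel() for v in variables}
    )
    corr = pooled.corr(method="pearson")  # constant columns -> NaN
    np.fill_diagonal(corr.values, [1.0 if pooled[v].std() > 0 else np.nan for v in variables])
    return corr


def find_clusters(
    matrix: pd.DataFrame, spec: NetworkSpec, threshold: float = 0.95
) -> list[CorrelationCluster]:
    """Connected components of the thresholded same-role correlation graph.

    Edges join pairs of variables that share a (division, role) context in
    ``spec`` and have r >= ``threshold``; components of size >= 2 are
    returned.  Components may chain overlapping pairs into one cluster.
    """
    contexts = spec.role_contexts()
    by_context: dict[tuple[str, str], list[str]] = {}
    for var, ctx in contexts.items():
        if var in matrix.index:
            by_context.setdefault(ctx, []).append(var)

    clusters: list[CorrelationCluster] = []
    for ctx, vars_ in sorted(by_context.items()):
        # union-find over the thresholded graph within this context
        parent = {v: v for v in vars_}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        edges: dict[tuple[str, str], float] = {}
        for i, a in enumerate(vars_):
            for b in vars_[i + 1 :]:
                r = matrix.loc[a, b]
                if np.isfinite(r) and r >= threshold:
                    edges[(a, b)] = float(r)
                    parent[find(a)] = find(b)
        comps: dict[str, list[str]] = {}
        for v in vars_:
            comps.setdefault(find(v), []).append(v)
        for members in comps.values():
            if len(members) < 2:
                continue
            member_set = set(members)
            clusters.append(
                CorrelationCluster(
                    variable_ids=tuple(sorted(members)),
                    role_context=ctx,
                    pairwise_r={
                        pair: r
                        for pair, r in edges.items()
                        if pair[0] in member_set and pair[1] in member_set
                    },
                )
            )
    return clusters


def merge_variables(
    panel: PanelDataset, cluster, new_id: str, method: str = "sum"
) -> PanelDataset:
    """Replace the cluster members by their per-cell sum under ``new_id``.

    Summation is the only merge supported: it is unit-safe for like-for-like
    quantities (hours + hours) and conserves the cellwise total exactly.
    The input panel is not modified.
    """
    if method != "sum":
        raise ValueError(f"unsupported merge method {method!r}; only 'sum'")
    members = list(
        cluster.variable_ids if isinstance(cluster, CorrelationCluster) else cluster
    )
    if not members:
        raise ValueError("empty cluster")
    for v in members:
        if v not in panel.variable_ids:
            raise KeyError(f"cluster member {v!r} not in panel")
    if new_id in panel.variable_ids and new_id not in members:
        raise ValidationError(
            f"merged name {new_id!r} collides with an existing variable"
        )
    total = np.sum([panel.column(v) for v in members], axis=0)
    # insert the merged column at the first member's position
    first = min(panel.var_index(v) for v in members)
    values = np.array(panel.values)
    keep = [j for j, v in enumerate(panel.variable_ids) if v not in members]
    var_ids = [v for v in panel.variable_ids if v not in members]
    insert_at = sum(1 for j in keep if j < first)
    values = values[:, :, keep]
    values = np.insert(values, insert_at, total, axis=2)
    var_ids.insert(insert_at, new_id)
    return PanelDataset(
        dmu_ids=panel.dmu_ids,
        periods=panel.periods,
        variable_ids=tuple(var_ids),
        values=values,
        groups=dict(panel.groups),
    )
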