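"""Network model specification and the binding of panel columns to it.

A network model partitions a DMU into ``K`` divisions (subunits).  Every
variable plays exactly one role inside a division: external input, desirable
output, undesirable output, or link.  A link is produced by one division and
consumed by another within the same DMU, so it appears in two divisions but
carries a single role ("link") tied to its (source, target) pair.

Binding a panel to a spec for one period yields, per division, the matrices
of the linear program: inputs ``X`` (n x m_k), desirable outputs ``V``
(n x r_k), undesirable outputs ``U`` (n x w_k), and link matrices
``Z[(k, h)]`` (n x t_{k,h}).  Exact zeros are replaced at bind time by a
small positive value (1e-6 of the within-period column mean) because
slack-based scores divide by the evaluated DMU's own observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .panel import PanelDataset

INPUT_ORIENTED = "input_oriented"
OUTPUT_ORIENTED = "output_oriented"

#: relative zero-replacement factor applied at bind time
ZERO_EPS_FACTOR = 1e-6

BUILTIN_MODELS = ("modelA", "modelB", "modelC", "modelD")


class ConfigError(ValueError):
    """Malformed or inconsistent network specification."""


@dataclass(frozen=True)
class NetworkSpec:
    """Division/variable/link wiring of one network DEA model."""

    divisions: tuple[str, ...]
    inputs: dict[str, tuple[str, ...]]
    desirable_outputs: dict[str, tuple[str, ...]]
    undesirable_outputs: dict[str, tuple[str, ...]]
    links: tuple[tuple[str, str, str], ...] = ()
    orientation: dict[str, str] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "divisions", tuple(self.divisions))
        if len(self.divisions) < 1:
            raise ConfigError("a model needs at least one division")
        if len(set(self.divisions)) != len(self.divisions):
            raise ConfigError("duplicate division ids")

        def norm(mapping) -> dict[str, tuple[str, ...]]:
            out = {}
            for div, vars_ in dict(mapping).items():
                if div not in self.divisions:
                    raise ConfigError(f"unknown division {div!r}")
                out[div] = tuple(vars_)
            return {d: out.get(d, ()) for d in self.divisions}

        object.__setattr__(self, "inputs", norm(self.inputs))
        object.__setattr__(self, "desirable_outputs", norm(self.desirable_outputs))
        object.__setattr__(self, "undesirable_outputs", norm(self.undesirable_outputs))
        links = tuple((str(a), str(b), str(v)) for a, b, v in self.links)
        for src, dst, var in links:
            if src not in self.divisions or dst not in self.divisions:
                raise ConfigError(f"link {var!r} references unknown division")
            if src == dst:
                raise ConfigError(f"link {var!r} must connect two distinct divisions")
        if len({v for _, _, v in links}) != len(links):
            raise ConfigError("a variable may appear in at most one link")
        object.__setattr__(self, "links", links)

        # default orientation: first division input-oriented, rest output-oriented
        orient = {str(k): str(v) for k, v in self.orientation.items()}
        for div, o in orient.items():
            if div not in self.divisions:
                raise ConfigError(f"orientation for unknown division {div!r}")
            if o not in (INPUT_ORIENTED, OUTPUT_ORIENTED):
                raise ConfigError(f"invalid orientation {o!r} for division {div!r}")
        full = {
            d: orient.get(d, INPUT_ORIENTED if i == 0 else OUTPUT_ORIENTED)
            for i, d in enumerate(self.divisions)
        }
        object.__setattr__(self, "orientation", full)

        # role uniqueness within each division
        for d in self.divisions:
            roles = (
                list(self.inputs[d])
                + list(self.desirable_outputs[d])
                + list(self.undesirable_outputs[d])
                + [v for s, t, v in links if d in (s, t)]
            )
            seen: set[str] = set()
            for v in roles:
                if v in seen:
                    raise ConfigError(
                        f"variable {v!r} has more than one role in division {d!r}"
                    )
                seen.add(v)

    # -- introspection ----------------------------------------------------
    @property
    def n_divisions(self) -> int:
        return len(self.divisions)

    def variables(self) -> tuple[str, ...]:
        """All variables referenced by the spec, in first-appearance order."""
        out: list[str] = []
        for d in self.divisions:
            out += list(self.inputs[d]) + list(self.desirable_outputs[d]) + list(
                self.undesirable_outputs[d]
            )
        out += [v for _, _, v in self.links]
        return tuple(dict.fromkeys(out))

    def role_contexts(self) -> dict[str, tuple[str, str]]:
        """Map variable -> (division-or-linkpair, role) context."""
        ctx: dict[str, tuple[str, str]] = {}
        for d in self.divisions:
            for v in self.inputs[d]:
                ctx[v] = (d, "input")
            for v in self.desirable_outputs[d]:
                ctx[v] = (d, "desirable_output")
            for v in self.undesirable_outputs[d]:
                ctx[v] = (d, "undesirable_output")
        for s, t, v in self.links:
            ctx[v] = (f"{s}->{t}", "link")
        return ctx

    def validate_against(self, panel: PanelDataset) -> None:
        missing = [v for v in self.variables() if v not in panel.variable_ids]
        if missing:
            raise ConfigError(f"spec variable(s) not present in panel: {missing}")

    # -- variable substitution (used by the sensitivity module) -----------
    def replace_variables(self, mapping: dict[str, str | None], name=None) -> "NetworkSpec":
        """Return a spec with variables renamed (value) or removed (None)."""

        def sub(vars_: tuple[str, ...]) -> tuple[str, ...]:
            out = []
            for v in vars_:
                if v in mapping:
                    if mapping[v] is not None:
                        out.append(mapping[v])
                else:
                    out.append(v)
            return tuple(dict.fromkeys(out))

        return NetworkSpec(
            divisions=self.divisions,
            inputs={d: sub(v) for d, v in self.inputs.items()},
            desirable_outputs={d: sub(v) for d, v in self.desirable_outputs.items()},
            undesirable_outputs={d: sub(v) for d, v in self.undesirable_outputs.items()},
            links=tuple(
                (s, t, mapping.get(v, v))
                for s, t, v in self.links
                if mapping.get(v, v) is not None
            ),
            orientation=dict(self.orientation),
            name=name or self.name,
        )


@dataclass(frozen=True)
class DivisionData:
    """Bound matrices of one division for one period (rows = DMUs)."""

    division: str
    X: np.ndarray  # (n, m_k) external inputs
    V: np.ndarray  # (n, r_k) desirable outputs
    U: np.ndarray  # (n, w_k) undesirable outputs
    Z: dict[tuple[str, str], np.ndarray]  # link matrices the division touches
    input_ids: tuple[str, ...] = ()
    desirable_ids: tuple[str, ...] = ()
    undesirable_ids: tuple[str, ...] = ()


def _spec_from_dict(raw: dict, name: str) -> NetworkSpec:
    if not isinstance(raw, dict) or "divisions" not in raw:
        raise ConfigError("model spec must be a mapping with a 'divisions' key")
    return NetworkSpec(
        divisions=tuple(raw["divisions"]),
        inputs=raw.get("inputs", {}),
        desirable_outputs=raw.get("desirable_outputs", {}),
        undesirable_outputs=raw.get("undesirable_outputs", {}),
        links=tuple(tuple(l) for l in raw.get("links", [])),
        orientation=raw.get("orientation", {}),
        name=raw.get("name", name),
    )


def read_model_spec(path_or_name) -> NetworkSpec:
    """Read a network spec from YAML/JSON, or load a shipped model by name.

    The shipped configs ``modelA`` .. ``modelD`` are documented
    reconstructions of the four hospital network layouts (the published
    diagrams are schematic); override them with your own file as needed.
    """
    name = str(path_or_name)
    if name in BUILTIN_MODELS:
        text = (
            resources.files("netdea").joinpath(f"configs/{name}.yaml").read_text()
        )
        return _spec_from_dict(yaml.safe_load(text), name)
    with open(path_or_name, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _spec_from_dict(raw, name)


def zero_replaced(matrix: np.ndarray) -> np.ndarray:
    """Replace exact zeros by ``1e-6 x column mean`` (columnwise).

    Strictly positive cells are never modified.  An all-zero column falls
    back to the absolute constant 1e-6.
    """
    out = np.array(matrix, dtype=float)
    if out.size == 0:
        return out
    means = out.mean(axis=0)
    eps = np.where(means > 0, ZERO_EPS_FACTOR * means, ZERO_EPS_FACTOR)
    mask = out == 0.0
    out[mask] = np.broadcast_to(eps, out.shape)[mask]
    return out


def bind(
    panel: PanelDataset, spec: NetworkSpec, period: str
) -> dict[str, DivisionData]:
    """Extract per-division matrices for one period, with zero replacement.

    Rows follow ``panel.dmu_ids`` order.  Link matrices are shared: the same
    (source, target) array object appears in both endpoint divisions.
    """
    spec.validate_against(panel)
    t = panel.period_index(period)

    def mat(var_ids) -> np.ndarray:
        if not var_ids:
            return np.empty((panel.n_dmus, 0))
        cols = [panel.values[:, t, panel.var_index(v)] for v in var_ids]
        return zero_replaced(np.stack(cols, axis=1))

    link_vars: dict[tuple[str, str], list[str]] = {}
    for s, d, v in spec.links:
        link_vars.setdefault((s, d), []).append(v)
    link_mats = {pair: mat(vs) for pair, vs in link_vars.items()}

    bound = {}
    for div in spec.divisions:
        bound[div] = DivisionData(
            division=div,
            X=mat(spec.inputs[div]),
            V=mat(spec.desirable_outputs[div]),
            U=mat(spec.undesirable_outputs[div]),
            Z={pair: m for pair, m in link_mats.items() if div in pair},
            input_ids=spec.inputs[div],
            desirable_ids=spec.desirable_outputs[div],
            undesirable_ids=spec.undesirable_outputs[div],
        )
    return bound
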