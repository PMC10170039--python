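"""Weakly-disposable network slack-based efficiency measure.

For a DMU *o* in a network of K divisions, every divisional score comes from
one linear program over the full coupled system.  The benchmark intensity
vector of each division k is split, lambda^k = mu^k + phi^k, so that the
per-peer abatement factor theta_j = phi_j / (phi_j + mu_j) in [0, 1] scales
desirable and undesirable outputs jointly (weak disposability) while keeping
the program linear:

    x_o^k = X^k (mu^k + phi^k) + s^{k-}          external inputs
    v_o^k = V^k phi^k - s^{k+}                   desirable outputs
    u_o^k = U^k phi^k                            undesirable outputs
    Z^{(k,h)} (mu^h + phi^h) = Z^{(k,h)} (mu^k + phi^k)   for every link pair
    sum_j (mu_j^k + phi_j^k) = 1   per division  (VRS only; dropped for CRS)
    mu, phi, s^-, s^+ >= 0

The objective focuses on one division at a time.  Input-oriented divisions
maximise the mean relative input slack and score 1 - optimum; output-oriented
divisions maximise the mean relative desirable-output slack and score
1 / (1 + optimum).  (The printed slack-based objectives have a trivial
zero-slack maximum when read literally; maximising the slack ratio is the
standard slack-based-measure convention and makes best-practice DMUs score
exactly 1.)  The overall score of a DMU is the arithmetic mean of its K
divisional scores.

Setting mu^k = 0 and phi^k = e_o satisfies every constraint with zero
slacks, so the program is feasible for any observed DMU and every score lies
in (0, 1].  All LPs are solved with the HiGHS dual simplex via
``scipy.optimize.linprog``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import INPUT_ORIENTED, DivisionData, NetworkSpec, bind
from .panel import PanelDataset

logger = logging.getLogger("netdea")

#: DMUs with overall score >= 1 - FRONTIER_TOL are classified as efficient
FRONTIER_TOL = 1e-6

VRS = "vrs"
CRS = "crs"


class SolverError(RuntimeError):
    """The LP solver failed (infeasible / unbounded / numerical)."""


@dataclass(frozen=True)
class DivisionSolution:
    """Outcome of the LP focused on one division."""

    division: str
    score: float
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    mu: np.ndarray
    phi: np.ndarray
    theta: np.ndarray  # per-peer abatement, NaN where mu_j + phi_j == 0
    status: str
    objective: float

    @property
    def lam(self) -> np.ndarray:
        """Combined intensity vector lambda = mu + phi."""
        return self.mu + self.phi


@dataclass(frozen=True)
class DMUResult:
    """All divisional scores of one DMU plus their arithmetic mean."""

    dmu_id: str
    rts: str
    divisional: dict[str, DivisionSolution]
    overall: float

    def divisional_scores(self) -> dict[str, float]:
        return {d: s.score for d, s in self.divisional.items()}


@dataclass(frozen=True)
class ModelRun:
    """run_model output: per-period results plus the cross-period summary."""

    spec_name: str
    rts: str
    period_results: dict[str, list[DMUResult]]
    summary: pd.Series  # dmu -> mean overall score across periods

    def scores_frame(self) -> pd.DataFrame:
        """Long table ``dmu,period,rts,division,score,overall``."""
        rows = []
        for period, results in self.period_results.items():
            for res in results:
                for div, sol in res.divisional.items():
                    rows.append(
                        {
                            "dmu": res.dmu_id,
                            "period": period,
                            "rts": res.rts,
                            "division": div,
                            "score": sol.score,
                            "overall": res.overall,
                        }
                    )
        return pd.DataFrame(rows)


def _check_rts(rts: str) -> str:
    rts = str(rts).lower()
    if rts not in (VRS, CRS):
        raise ValueError(f"rts must be 'vrs' or 'crs', got {rts!r}")
    return rts


class _Program:
    """Constraint system of Eq-style coupled LPs for one bound period.

    The equality matrix does not depend on the evaluated DMU (only the
    right-hand side does), so it is assembled once per (period, rts) and
    reused across DMUs and focus divisions.
    """

    def __init__(
        self,
        data: dict[str, DivisionData],
        spec: NetworkSpec,
        rts: str,
        *,
        free_links: bool = False,
        strong_disposability: bool = False,
    ):
        self.spec = spec
        self.data = data
        self.rts = _check_rts(rts)
        self.strong = strong_disposability
        divs = spec.divisions
        self.n = next(iter(data.values())).X.shape[0] if data else 0
        n, K = self.n, len(divs)

        # variable layout: [mu^1..mu^K | phi^1..phi^K | s^-/s^+ per division]
        self.mu_off = {d: i * n for i, d in enumerate(divs)}
        self.phi_off = {d: K * n + i * n for i, d in enumerate(divs)}
        off = 2 * K * n
        self.sin_off, self.sout_off = {}, {}
        for d in divs:
            self.sin_off[d] = off
            off += data[d].X.shape[1]
            self.sout_off[d] = off
            off += data[d].V.shape[1]
        self.n_vars = off

        rows: list[np.ndarray] = []
        self.rhs_builders: list[tuple[str, str, int]] = []  # (kind, div, col)
        for d in divs:
            dd = data[d]
            for i in range(dd.X.shape[1]):
                row = np.zeros(self.n_vars)
                row[self.mu_off[d] : self.mu_off[d] + n] = dd.X[:, i]
                row[self.phi_off[d] : self.phi_off[d] + n] = dd.X[:, i]
                row[self.sin_off[d] + i] = 1.0
                rows.append(row)
                self.rhs_builders.append(("x", d, i))
            for r in range(dd.V.shape[1]):
                row = np.zeros(self.n_vars)
                row[self.phi_off[d] : self.phi_off[d] + n] = dd.V[:, r]
                row[self.sout_off[d] + r] = -1.0
                rows.append(row)
                self.rhs_builders.append(("v", d, r))
            for w in range(dd.U.shape[1]):
                row = np.zeros(self.n_vars)
                row[self.phi_off[d] : self.phi_off[d] + n] = dd.U[:, w]
                rows.append(row)
                self.rhs_builders.append(("u", d, w))
        if not free_links:
            link_mats: dict[tuple[str, str], np.ndarray] = {}
            for d in divs:
                link_mats.update(data[d].Z)
            for (src, dst), Z in sorted(link_mats.items()):
                for t in range(Z.shape[1]):
                    row = np.zeros(self.n_vars)
                    row[self.mu_off[dst] : self.mu_off[dst] + n] += Z[:, t]
                    row[self.phi_off[dst] : self.phi_off[dst] + n] += Z[:, t]
                    row[self.mu_off[src] : self.mu_off[src] + n] -= Z[:, t]
                    row[self.phi_off[src] : self.phi_off[src] + n] -= Z[:, t]
                    rows.append(row)
                    self.rhs_builders.append(("link", src, t))
        if self.rts == VRS:
            for d in divs:
                row = np.zeros(self.n_vars)
                row[self.mu_off[d] : self.mu_off[d] + n] = 1.0
                row[self.phi_off[d] : self.phi_off[d] + n] = 1.0
                rows.append(row)
                self.rhs_builders.append(("vrs", d, 0))
        self.A_eq = np.vstack(rows) if rows else np.empty((0, self.n_vars))

        self.bounds = [(0.0, None)] * self.n_vars
        if strong_disposability:  # force mu = 0, i.e. abatement theta = 1
            for d in divs:
                for j in range(self.mu_off[d], self.mu_off[d] + n):
                    self.bounds[j] = (0.0, 0.0)

    def rhs(self, o: int) -> np.ndarray:
        b = np.zeros(self.A_eq.shape[0])
        for idx, (kind, d, col) in enumerate(self.rhs_builders):
            if kind == "x":
                b[idx] = self.data[d].X[o, col]
            elif kind == "v":
                b[idx] = self.data[d].V[o, col]
            elif kind == "u":
                b[idx] = self.data[d].U[o, col]
            elif kind == "vrs":
                b[idx] = 1.0
            # link rows stay 0
        return b

    def solve(self, o: int, division: str) -> DivisionSolution:
        spec, data, n = self.spec, self.data, self.n
        dd = data[division]
        oriented_in = spec.orientation[division] == INPUT_ORIENTED
        m_k, r_k = dd.X.shape[1], dd.V.shape[1]

        if (oriented_in and m_k == 0) or (not oriented_in and r_k == 0):
            logger.warning(
                "division %r has an empty %s-side objective; score defined as 1",
                division,
                "input" if oriented_in else "output",
            )
            phi = np.zeros(n)
            phi[o] = 1.0
            return DivisionSolution(
                division=division,
                score=1.0,
                input_slacks=np.zeros(m_k),
                output_slacks=np.zeros(r_k),
                mu=np.zeros(n),
                phi=phi,
                theta=np.where(phi > 0, 1.0, np.nan),
                status="degenerate-objective",
                objective=0.0,
            )

        c = np.zeros(self.n_vars)  # linprog minimises; we maximise slack ratios
        if oriented_in:
            x_o = dd.X[o]
            c[self.sin_off[division] : self.sin_off[division] + m_k] = -1.0 / (m_k * x_o)
        else:
            v_o = dd.V[o]
            c[self.sout_off[division] : self.sout_off[division] + r_k] = -1.0 / (
                r_k * v_o
            )

        res = linprog(
            c, A_eq=self.A_eq, b_eq=self.rhs(o), bounds=self.bounds, method="highs"
        )
        if res.status == 2:
            raise SolverError(
                f"LP infeasible for dmu index {o}, division {division!r} "
                f"(rts={self.rts}); observed data always admits mu=0, phi=e_o, "
                "so check for edited/non-positive inputs"
            )
        if res.status == 3:
            raise SolverError(
                f"LP unbounded for dmu index {o}, division {division!r} "
                f"(rts={self.rts}); degenerate data under CRS"
            )
        if not res.success:
            raise SolverError(
                f"solver failure for dmu index {o}, division {division!r}: {res.message}"
            )

        opt = max(0.0, -res.fun)
        score = (1.0 - opt) if oriented_in else 1.0 / (1.0 + opt)
        score = min(1.0, max(score, 1e-12))
        z = res.x
        mu = z[self.mu_off[division] : self.mu_off[division] + n].copy()
        phi = z[self.phi_off[division] : self.phi_off[division] + n].copy()
        lam = mu + phi
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(lam > 1e-12, phi / np.where(lam > 0, lam, 1.0), np.nan)
        return DivisionSolution(
            division=division,
            score=float(score),
            input_slacks=z[self.sin_off[division] : self.sin_off[division] + m_k].copy(),
            output_slacks=z[
                self.sout_off[division] : self.sout_off[division] + r_k
            ].copy(),
            mu=mu,
            phi=phi,
            theta=theta,
            status="optimal",
            objective=float(opt),
        )


def solve_division(
    data: dict[str, DivisionData],
    spec: NetworkSpec,
    dmu: int,
    division: str,
    rts: str = VRS,
    *,
    free_links: bool = False,
    strong_disposability: bool = False,
) -> DivisionSolution:
    """Solve the coupled LP with the objective focused on one division.

    ``data`` is the output of :func:`netdea.network.bind` for one period;
    ``dmu`` is the row index of the evaluated DMU.
    """
    prog = _Program(
        data, spec, rts, free_links=free_links, strong_disposability=strong_disposability
    )
    return prog.solve(dmu, division)


def solve_dmu(
    data: dict[str, DivisionData],
    spec: NetworkSpec,
    dmu: int,
    rts: str = VRS,
    dmu_id: str | None = None,
    *,
    free_links: bool = False,
    strong_disposability: bool = False,
) -> DMUResult:
    """Solve all K divisional LPs of one DMU; overall = mean of the scores."""
    prog = _Program(
        data, spec, rts, free_links=free_links, strong_disposability=strong_disposability
    )
    divisional = {}
    for div in spec.divisions:
        try:
            divisional[div] = prog.solve(dmu, div)
        except SolverError as exc:
            raise SolverError(f"[division {div!r}] {exc}") from exc
    overall = float(np.mean([s.score for s in divisional.values()]))
    return DMUResult(
        dmu_id=dmu_id if dmu_id is not None else str(dmu),
        rts=_check_rts(rts),
        divisional=divisional,
        overall=overall,
    )


def run_model(
    panel: PanelDataset,
    spec: NetworkSpec,
    rts: str = VRS,
    *,
    free_links: bool = False,
    strong_disposability: bool = False,
) -> ModelRun:
    """Score every DMU in every period; each period is solved independently.

    The summary is the per-DMU arithmetic mean of overall scores across
    periods (multi-year reports use exactly this average).
    """
    rts = _check_rts(rts)
    period_results: dict[str, list[DMUResult]] = {}
    for period in panel.periods:
        data = bind(panel, spec, period)
        prog = _Program(
            data,
            spec,
            rts,
            free_links=free_links,
            strong_disposability=strong_disposability,
        )
        results = []
        for o, dmu_id in enumerate(panel.dmu_ids):
            divisional = {}
            for div in spec.divisions:
                try:
                    divisional[div] = prog.solve(o, div)
                except SolverError as exc:
                    raise SolverError(
                        f"[dmu {dmu_id!r}, period {period!r}, division {div!r}] {exc}"
                    ) from exc
            results.append(
                DMUResult(
                    dmu_id=dmu_id,
                    rts=rts,
                    divisional=divisional,
                    overall=float(np.mean([s.score for s in divisional.values()])),
                )
            )
        period_results[period] = results
    summary = pd.Series(
        {
            dmu: float(
                np.mean([period_results[p][i].overall for p in panel.periods])
            )
            for i, dmu in enumerate(panel.dmu_ids)
        },
        name="overall",
    )
    return ModelRun(spec.name, rts, period_results, summary)


def scale_efficiency(vrs: DMUResult, crs: DMUResult) -> float:
    """rho_CRS / rho_VRS on overall scores; lies in (0, 1] up to LP tolerance."""
    if vrs.dmu_id != crs.dmu_id:
        raise ValueError(
            f"mismatched dmu ids: {vrs.dmu_id!r} (vrs) vs {crs.dmu_id!r} (crs)"
        )
    if vrs.rts != VRS or crs.rts != CRS:
        raise ValueError("arguments must be a (VRS, CRS) result pair")
    return crs.overall / vrs.overall


def scale_efficiency_table(vrs_run: ModelRun, crs_run: ModelRun) -> pd.Series:
    """Per-DMU scale efficiency on cross-period average overall scores."""
    if list(vrs_run.summary.index) != list(crs_run.summary.index):
        raise ValueError("mismatched dmu ids between the two runs")
    if vrs_run.rts != VRS or crs_run.rts != CRS:
        raise ValueError("arguments must be a (VRS, CRS) run pair")
    out = crs_run.summary / vrs_run.summary
    out.name = "scale_efficiency"
    return out


def classify_frontier(results, tol: float = FRONTIER_TOL) -> set[str]:
    """DMU ids whose overall score is within ``tol`` of 1.

    ``results`` is a list of :class:`DMUResult` or a per-DMU score Series
    (e.g. ``ModelRun.summary``).
    """
    if isinstance(results, pd.Series):
        return set(results.index[results >= 1.0 - tol])
    return {r.dmu_id for r in results if r.overall >= 1.0 - tol}
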