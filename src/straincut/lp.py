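"""Linear-programming services: FBA, FVA and a parsimonious optimum.

All solves go through one backend contract (:meth:`LinearSystem.solve`)
implemented on scipy's HiGHS interior-point/simplex driver, so results do
not depend on a commercial solver. The steady-state system S·v = 0 is built
over internal metabolites only; ratio constraints contribute extra equality
(or inequality, in ``min`` mode) rows.

Single-flux reports (e.g. oxygen-uptake columns) must use
:func:`parsimonious_fluxes`, never a raw FBA witness: among alternate
optima it deterministically returns the one minimizing Σ|v_i| (two-stage
LP), making such columns reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import GEMModel


@dataclass(frozen=True)
class SolverOptions:
    """LP tolerances. ``supp_tol`` must exceed solver noise for flux
    supports supp(v) = {i : |v_i| > supp_tol} to be stable."""

    feas_tol: float = 1e-9
    opt_tol: float = 1e-6
    supp_tol: float = 1e-6


DEFAULT_OPTIONS = SolverOptions()


@dataclass
class FluxState:
    """A network mode: flux vector, objective value and solver status."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def support(self, supp_tol: float = DEFAULT_OPTIONS.supp_tol) -> frozenset:
        return frozenset(r for r, v in self.fluxes.items() if abs(v) > supp_tol)


@dataclass
class FluxRange:
    """Per-reaction achievable (min, max) flux under the current constraints."""

    ranges: Dict[str, Tuple[float, float]]
    status: str = "optimal"

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.ranges[rid]


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class LinearSystem:
    """Pre-built LP matrices for one model; bounds can be overridden per solve.

    Rebuilding only bounds (not the matrix) is what makes knockout screens
    cheap: a gene deletion merely pins blocked reactions to zero.
    """

    def __init__(self, model: GEMModel, options: SolverOptions = DEFAULT_OPTIONS):
        self.model = model
        self.options = options
        self.rxn_ids: List[str] = list(model.reactions)
        self._col = {r: j for j, r in enumerate(self.rxn_ids)}
        n = len(self.rxn_ids)
        internal = model.internal_metabolite_ids
        rows = []
        for mid in internal:
            row = np.zeros(n)
            for j, rid in enumerate(self.rxn_ids):
                coef = model.reactions[rid].stoich.get(mid)
                if coef:
                    row[j] = float(coef)
            rows.append(row)
        ratio_rows = []
        for rc in model.ratio_constraints:
            row = np.zeros(n)
            for rid, coef in rc.row().items():
                row[self._col[rid]] = float(coef)
            ratio_rows.append(row)
        if getattr(model, "ratio_mode", "equality") == "min" and ratio_rows:
            # |v_a| >= r|v_b| with uptakes negative: q_b v_a - q_a v_b <= 0
            self.A_eq = np.array(rows) if rows else np.zeros((0, n))
            self._ratio_ub = np.array(ratio_rows)
        else:
            self.A_eq = np.array(rows + ratio_rows) if rows or ratio_rows else np.zeros((0, n))
            self._ratio_ub = np.zeros((0, n))
        self.base_bounds: List[Tuple[float, float]] = [
            (model.reactions[r].lb, model.reactions[r].ub) for r in self.rxn_ids
        ]

    # -- core contract --------------------------------------------------
    def solve(
        self,
        objective: Mapping[str, float],
        sense: str = "max",
        bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
        extra_leq: Sequence[Tuple[Mapping[str, float], float]] = (),
        extra_eq: Sequence[Tuple[Mapping[str, float], float]] = (),
    ) -> FluxState:
        """Optimize a linear objective over the flux cone.

        ``extra_leq`` / ``extra_eq`` are (coefficient-dict, rhs) rows added
        for this solve only.
        """
        n = len(self.rxn_ids)
        c = np.zeros(n)
        for rid, coef in objective.items():
            c[self._col[rid]] = coef
        sign = -1.0 if sense == "max" else 1.0
        bounds = list(self.base_bounds)
        if bound_overrides:
            for rid, b in bound_overrides.items():
                bounds[self._col[rid]] = b
        A_ub_rows, b_ub = [], []
        for row in self._ratio_ub:
            A_ub_rows.append(row)
            b_ub.append(0.0)
        for coefs, rhs in extra_leq:
            row = np.zeros(n)
            for rid, coef in coefs.items():
                row[self._col[rid]] = coef
            A_ub_rows.append(row)
            b_ub.append(rhs)
        A_eq = self.A_eq
        b_eq = np.zeros(A_eq.shape[0])
        if extra_eq:
            extra_rows, extra_rhs = [], []
            for coefs, rhs in extra_eq:
                row = np.zeros(n)
                for rid, coef in coefs.items():
                    row[self._col[rid]] = coef
                extra_rows.append(row)
                extra_rhs.append(rhs)
            A_eq = np.vstack([A_eq, extra_rows])
            b_eq = np.concatenate([b_eq, extra_rhs])
        res = linprog(
            sign * c,
            A_ub=np.array(A_ub_rows) if A_ub_rows else None,
            b_ub=np.array(b_ub) if b_ub else None,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=bounds,
            method="highs",
        )
        status = _STATUS.get(res.status, "error")
        if status != "optimal":
            return FluxState({}, float("nan"), status)
        fluxes = {rid: float(res.x[j]) for rid, j in self._col.items()}
        value = -res.fun if sense == "max" else res.fun
        return FluxState(fluxes, float(value), "optimal")

    # -- parsimonious tie-break -----------------------------------------
    def solve_parsimonious(
        self,
        objective: str,
        sense: str = "max",
        bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
        extra_leq: Sequence[Tuple[Mapping[str, float], float]] = (),
    ) -> FluxState:
        """Two-stage LP: optimize ``objective``, then minimize Σ|v| at that
        optimum (within opt_tol). Deterministic across runs."""
        stage1 = self.solve({objective: 1.0}, sense, bound_overrides, extra_leq)
        if not stage1.optimal:
            return stage1
        z = stage1.objective_value
        slack = self.options.opt_tol * max(1.0, abs(z))
        n = len(self.rxn_ids)
        bounds = list(self.base_bounds)
        if bound_overrides:
            for rid, b in bound_overrides.items():
                bounds[self._col[rid]] = b
        # v = p - q with p, q >= 0; min sum(p + q) drives one side to zero
        pb = [(max(lb, 0.0), max(ub, 0.0)) for lb, ub in bounds]
        qb = [(max(-ub, 0.0), max(-lb, 0.0)) for lb, ub in bounds]
        A_eq = np.hstack([self.A_eq, -self.A_eq])
        b_eq = np.zeros(A_eq.shape[0])
        A_ub_rows, b_ub = [], []
        for row in self._ratio_ub:
            A_ub_rows.append(np.concatenate([row, -row]))
            b_ub.append(0.0)
        for coefs, rhs in extra_leq:
            row = np.zeros(n)
            for rid, coef in coefs.items():
                row[self._col[rid]] = coef
            A_ub_rows.append(np.concatenate([row, -row]))
            b_ub.append(rhs)
        j = self._col[objective]
        row = np.zeros(2 * n)
        row[j], row[n + j] = (-1.0, 1.0) if sense == "max" else (1.0, -1.0)
        A_ub_rows.append(row)
        b_ub.append(-(z - slack) if sense == "max" else (z + slack))
        res = linprog(
            np.ones(2 * n),
            A_ub=np.array(A_ub_rows),
            b_ub=np.array(b_ub),
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=pb + qb,
            method="highs",
        )
        if res.status != 0:
            return stage1  # fall back to the raw witness
        v = res.x[:n] - res.x[n:]
        fluxes = {rid: float(v[jj]) for rid, jj in self._col.items()}
        return FluxState(fluxes, z, "optimal")


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def fba_max(
    model: GEMModel, objective: str, options: SolverOptions = DEFAULT_OPTIONS
) -> FluxState:
    """Maximize the flux of ``objective`` over the cone; returns a witness."""
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    return LinearSystem(model, options).solve({objective: 1.0}, "max")


def fva_range(
    model: GEMModel,
    reactions: Iterable[str],
    fix_objective: Optional[Tuple[str, float]] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
    system: Optional[LinearSystem] = None,
    bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FluxRange:
    """Per-reaction (min, max) flux, optionally at a fixed objective level.

    With ``fix_objective=(biomass, 1.0)`` the ranges are taken over
    optimal-growth states; without it, over the whole cone.
    """
    sys_ = system or LinearSystem(model, options)
    extra_leq: List[Tuple[Mapping[str, float], float]] = []
    if fix_objective is not None:
        obj, gamma = fix_objective
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        stage = sys_.solve({obj: 1.0}, "max", bound_overrides)
        if not stage.optimal:
            return FluxRange({}, status=stage.status)
        z = stage.objective_value
        slack = options.opt_tol * max(1.0, abs(z))
        extra_leq.append(({obj: -1.0}, -(gamma * z - slack)))
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in reactions:
        lo = sys_.solve({rid: 1.0}, "min", bound_overrides, extra_leq)
        hi = sys_.solve({rid: 1.0}, "max", bound_overrides, extra_leq)
        if not (lo.optimal and hi.optimal):
            return FluxRange({}, status=lo.status if not lo.optimal else hi.status)
        ranges[rid] = (lo.objective_value, hi.objective_value)
    return FluxRange(ranges)


def parsimonious_fluxes(
    model: GEMModel, objective: str, options: SolverOptions = DEFAULT_OPTIONS
) -> FluxState:
    """FBA optimum with the minimum-Σ|v| tie-break (deterministic)."""
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    return LinearSystem(model, options).solve_parsimonious(objective, "max")
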