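"""Amplification (overexpression) target discovery by flux scanning.

The scan is FSEOF-shaped: production of the target compound is enforced at
a grid of fractions of its maximum, growth is re-maximized at each level,
and the parsimonious flux vector is recorded. Reactions whose absolute
flux rises monotonically with enforced production are candidate
amplification targets; their GPR genes are reported with the supporting
reactions. Exchange reactions are excluded — secreting more product is not
an overexpression lead. This scan is a documented stand-in for supplement-
only amplification algorithms and is labelled as such in all outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .coupling import CouplingSpec
from .lp import DEFAULT_OPTIONS, LinearSystem, SolverOptions
from .model import GEMModel

logger = logging.getLogger("straincut")

DEFAULT_LEVELS: Tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(1, 10))


@dataclass
class FseofProfile:
    """Per-reaction flux trajectories under enforced production."""

    levels: Tuple[float, ...]          # enforcement fractions actually solved
    fluxes: Dict[str, List[float]]     # reaction id -> |flux| trajectory
    verdicts: Dict[str, str]           # increasing | decreasing | flat | non-monotone
    product_max: float

    def increasing_reactions(self) -> List[str]:
        return sorted(r for r, v in self.verdicts.items() if v == "increasing")


def _verdict(traj: Sequence[float], tol: float) -> str:
    if len(traj) < 2:
        return "flat"
    diffs = np.diff(traj)
    if np.all(np.abs(diffs) <= tol):
        return "flat"
    if np.all(diffs >= -tol) and np.any(diffs > tol):
        return "increasing"
    if np.all(diffs <= tol) and np.any(diffs < -tol):
        return "decreasing"
    return "non-monotone"


def fseof_scan(
    model: GEMModel,
    spec: CouplingSpec,
    levels: Optional[Sequence[float]] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> FseofProfile:
    """Scan fluxes while the product exchange is forced to f·max, f in levels."""
    levels = tuple(levels) if levels is not None else DEFAULT_LEVELS
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("enforcement levels must be strictly increasing")
    system = LinearSystem(model, options)
    pmax_state = system.solve({spec.product_exchange_id: 1.0}, "max")
    if not pmax_state.optimal or pmax_state.objective_value <= options.supp_tol:
        raise ValueError("product max flux is zero in the scanned strain; nothing to scan")
    pmax = pmax_state.objective_value
    product = spec.product_exchange_id
    trajectories: Dict[str, List[float]] = {rid: [] for rid in model.reactions}
    solved_levels: List[float] = []
    for f in levels:
        lb = f * pmax
        rxn = model.reactions[product]
        state = system.solve_parsimonious(
            spec.biomass_id,
            "max",
            bound_overrides={product: (lb, rxn.ub)},
        )
        if not state.optimal:
            logger.warning("enforcement level %.3g infeasible; dropped", f)
            continue
        solved_levels.append(f)
        for rid in model.reactions:
            trajectories[rid].append(abs(state.fluxes[rid]))
    if not solved_levels:
        raise ValueError("all enforcement levels infeasible")
    verdicts = {rid: _verdict(traj, options.supp_tol) for rid, traj in trajectories.items()}
    return FseofProfile(
        levels=tuple(solved_levels),
        fluxes=trajectories,
        verdicts=verdicts,
        product_max=pmax,
    )


@dataclass
class AmplificationTarget:
    gene: str
    supporting_reactions: List[str]
    mean_slope: float


def amplification_genes(
    profile: FseofProfile, model: GEMModel
) -> List[AmplificationTarget]:
    """Genes behind monotonically increasing, non-exchange reactions.

    Genes of blocked reactions (bounds pinned to zero in the scanned
    strain) can never appear: a blocked reaction's flux is identically
    zero, hence flat.
    """
    support: Dict[str, List[str]] = {}
    slopes: Dict[str, List[float]] = {}
    for rid in profile.increasing_reactions():
        rxn = model.reactions[rid]
        if rxn.is_exchange:
            continue
        traj = profile.fluxes[rid]
        span = profile.levels[-1] - profile.levels[0]
        slope = (traj[-1] - traj[0]) / span if span > 0 else 0.0
        for gene in sorted(rxn.gpr.genes()):
            support.setdefault(gene, []).append(rid)
            slopes.setdefault(gene, []).append(slope)
    return [
        AmplificationTarget(g, support[g], float(np.mean(slopes[g])))
        for g in sorted(support)
    ]


def targets_to_tsv(targets: Sequence[AmplificationTarget]) -> str:
    lines = ["gene\tn_supporting_reactions\tmean_abs_flux_slope"]
    for t in targets:
        lines.append(f"{t.gene}\t{len(t.supporting_reactions)}\t{t.mean_slope:.6g}")
    return "\n".join(lines) + "\n"
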