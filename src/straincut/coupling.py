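"""Genetic minimal cut sets (gMCS) for growth-coupled production.

A gene set is a *cut* when, in the mutant it induces, no feasible state
grows at rate ≥ eps_growth while producing ≤ delta_product of the target
compound (the undesired "growth without production" region is empty), yet
the mutant can still grow at ≥ eps_growth (the desired region survives).
Under a forced maintenance flux (NGAM) the zero vector is excluded from
the cone, so every cut additionally yields a strictly positive minimum
product flux over the whole cone — strong coupling.

Two enumeration engines are provided: an exhaustive brute-force oracle and
a level-wise engine with pruning that returns identical results wherever
both run. The pruning rules rest on knockout monotonicity: deleting more
genes blocks more reactions and can only shrink the feasible cone.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .gpr import blocked_reactions, gene_equivalence_classes
from .lp import DEFAULT_OPTIONS, LinearSystem, SolverOptions
from .model import ConfigurationError, GEMModel

logger = logging.getLogger("straincut")


@dataclass(frozen=True)
class CouplingSpec:
    """Names the coupling problem: what grows, what is produced, from what.

    ``eps_growth`` is the minimum growth demanded in the desired region;
    ``delta_product`` the production level below which a state counts as
    "no production"; ``max_interventions`` the knockout budget k.
    """

    biomass_id: str
    product_exchange_id: str
    substrate_exchange_ids: Tuple[str, ...]
    eps_growth: float = 1e-3
    delta_product: float = 1e-6
    max_interventions: int = 4
    oxygen_exchange_id: Optional[str] = None

    def __post_init__(self):
        if self.eps_growth <= 0:
            raise ConfigurationError("eps_growth must be > 0")
        if self.delta_product < 0:
            raise ConfigurationError("delta_product must be >= 0")
        if self.max_interventions < 1:
            raise ConfigurationError("max_interventions must be >= 1")

    def validate_against(self, model: GEMModel) -> None:
        ids = [self.biomass_id, self.product_exchange_id, *self.substrate_exchange_ids]
        if self.oxygen_exchange_id:
            ids.append(self.oxygen_exchange_id)
        for rid in ids:
            if rid not in model.reactions:
                raise ConfigurationError(f"coupling spec references unknown reaction {rid}")


def default_spec(
    model: GEMModel,
    product_exchange_id: str,
    substrate_exchange_ids: Sequence[str],
    max_interventions: int = 4,
    oxygen_exchange_id: Optional[str] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> CouplingSpec:
    """Spec with eps_growth = 1e-3 · wild-type max growth, delta = 1e-6."""
    from .lp import fba_max

    wt = fba_max(model, model.biomass_id, options)
    if not wt.optimal or wt.objective_value <= 0:
        raise ConfigurationError("wild-type model cannot grow; cannot derive eps_growth")
    return CouplingSpec(
        biomass_id=model.biomass_id,
        product_exchange_id=product_exchange_id,
        substrate_exchange_ids=tuple(substrate_exchange_ids),
        eps_growth=1e-3 * wt.objective_value,
        delta_product=1e-6,
        max_interventions=max_interventions,
        oxygen_exchange_id=oxygen_exchange_id,
    )


@dataclass(frozen=True)
class InterventionStrategy:
    """A candidate gene-deletion set with its coupling verdict."""

    genes: FrozenSet[str]
    is_cut: bool
    is_minimal: bool
    mutant_max_growth: float
    strong_min_product: float

    def sort_key(self) -> Tuple[int, Tuple[str, ...]]:
        return (len(self.genes), tuple(sorted(self.genes)))


class CouplingEvaluator:
    """Shared LP system + memo for repeated cut checks on one model."""

    def __init__(
        self,
        model: GEMModel,
        spec: CouplingSpec,
        options: SolverOptions = DEFAULT_OPTIONS,
    ):
        spec.validate_against(model)
        self.model = model
        self.spec = spec
        self.options = options
        self.system = LinearSystem(model, options)
        self._memo: Dict[FrozenSet[str], InterventionStrategy] = {}
        self.lp_calls = 0

    def _overrides(self, genes: FrozenSet[str]) -> Dict[str, Tuple[float, float]]:
        return {rid: (0.0, 0.0) for rid in blocked_reactions(self.model, genes)}

    def evaluate(self, genes: Iterable[str], want_strong: bool = True) -> InterventionStrategy:
        genes = frozenset(genes)
        cached = self._memo.get(genes)
        if cached is not None:
            if not want_strong or not math.isnan(cached.strong_min_product):
                return cached
            if cached.mutant_max_growth < self.spec.eps_growth:
                return cached  # cone dead or growth-infeasible; strong stays nan
        spec = self.spec
        ov = self._overrides(genes)
        self.lp_calls += 1
        growth = self.system.solve({spec.biomass_id: 1.0}, "max", ov)
        g_max = growth.objective_value if growth.optimal else 0.0
        if not growth.optimal or g_max < spec.eps_growth:
            # desired region empty: cannot be (part of) a valid strategy
            strat = InterventionStrategy(genes, False, False, g_max, float("nan"))
            self._memo[genes] = strat
            return strat
        self.lp_calls += 1
        target = self.system.solve(
            {spec.biomass_id: 1.0},
            "max",
            ov,
            extra_leq=[({spec.product_exchange_id: 1.0}, spec.delta_product)],
        )
        is_cut = (not target.optimal) or target.objective_value < spec.eps_growth
        strong = float("nan")
        if want_strong:
            self.lp_calls += 1
            s = self.system.solve({spec.product_exchange_id: 1.0}, "min", ov)
            strong = s.objective_value if s.optimal else float("nan")
        strat = InterventionStrategy(genes, is_cut, False, g_max, strong)
        self._memo[genes] = strat
        return strat

    def growth_alive(self, genes: FrozenSet[str]) -> bool:
        strat = self._memo.get(genes)
        if strat is None:
            strat = self.evaluate(genes, want_strong=False)
        return strat.mutant_max_growth >= self.spec.eps_growth


def check_coupling(
    model: GEMModel,
    spec: CouplingSpec,
    genes: Iterable[str],
    options: SolverOptions = DEFAULT_OPTIONS,
    evaluator: Optional[CouplingEvaluator] = None,
) -> InterventionStrategy:
    """Classify one gene set: cut / not, mutant growth, strong minimum."""
    ev = evaluator or CouplingEvaluator(model, spec, options)
    return ev.evaluate(genes, want_strong=True)


def _cuttable_genes(model: GEMModel) -> List[str]:
    occurring: Set[str] = set()
    for rxn in model.reactions.values():
        occurring |= rxn.gpr.genes()
    return sorted(occurring & model.genes)


def _mark_minimal(
    cuts: List[InterventionStrategy], ev: CouplingEvaluator
) -> List[InterventionStrategy]:
    """Retain cuts none of whose proper subsets is a cut (re-checked by LP)."""
    out = []
    cut_sets = {c.genes for c in cuts}
    for c in sorted(cuts, key=InterventionStrategy.sort_key):
        minimal = True
        for size in range(1, len(c.genes)):
            for sub in itertools.combinations(sorted(c.genes), size):
                fs = frozenset(sub)
                if fs in cut_sets or ev.evaluate(fs, want_strong=False).is_cut:
                    minimal = False
                    break
            if not minimal:
                break
        if minimal:
            strong = c.strong_min_product
            if math.isnan(strong):
                strong = ev.evaluate(c.genes, want_strong=True).strong_min_product
            out.append(replace(c, is_minimal=True, strong_min_product=strong))
    return out


def filter_minimal(
    strategies: Sequence[InterventionStrategy],
    model: GEMModel,
    spec: CouplingSpec,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> List[InterventionStrategy]:
    """Keep exactly the strategies whose every proper subset fails to cut."""
    for s in strategies:
        if not s.is_cut:
            raise ValueError(f"filter_minimal expects cuts only; {sorted(s.genes)} is not")
    ev = CouplingEvaluator(model, spec, options)
    return _mark_minimal(list(strategies), ev)


def enumerate_gmcs_bruteforce(
    model: GEMModel,
    spec: CouplingSpec,
    options: SolverOptions = DEFAULT_OPTIONS,
    budget: int = 50_000,
) -> List[InterventionStrategy]:
    """Exhaustive oracle: test every gene subset of size ≤ k, keep minimal cuts.

    Guarded by ``budget`` on the number of subsets; refuse above it and
    direct callers to the pruned engine.
    """
    spec.validate_against(model)
    if spec.product_exchange_id == spec.biomass_id:
        logger.warning("product equals biomass: growth is production, already coupled")
        return []
    genes = _cuttable_genes(model)
    k = spec.max_interventions
    n_subsets = sum(math.comb(len(genes), s) for s in range(1, k + 1))
    if n_subsets > budget:
        raise ValueError(
            f"{n_subsets} subsets exceed the brute-force budget {budget}; "
            "use enumerate_gmcs_pruned"
        )
    ev = CouplingEvaluator(model, spec, options)
    if ev.evaluate(frozenset(), want_strong=False).is_cut:
        logger.warning("wild type is already growth-coupled; nothing to cut")
        return []
    cuts = []
    for size in range(1, k + 1):
        for combo in itertools.combinations(genes, size):
            strat = ev.evaluate(frozenset(combo), want_strong=False)
            if strat.is_cut:
                cuts.append(strat)
    out = _mark_minimal(cuts, ev)
    out.sort(key=InterventionStrategy.sort_key)
    return out


def enumerate_gmcs_pruned(
    model: GEMModel,
    spec: CouplingSpec,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> List[InterventionStrategy]:
    """Level-wise search with pruning; equals brute force wherever both run.

    Pruning rules: (i) never extend a set already proven a cut (supersets
    cannot be minimal); (ii) skip genes occurring in no GPR (deleting them
    never changes any rule); (iii) drop any set whose mutant cannot reach
    eps_growth — by knockout monotonicity no superset can revive growth;
    (iv) sets containing an already-found cut are skipped before solving.
    """
    spec.validate_against(model)
    if spec.product_exchange_id == spec.biomass_id:
        logger.warning("product equals biomass: growth is production, already coupled")
        return []
    genes = _cuttable_genes(model)
    order = {g: i for i, g in enumerate(genes)}
    ev = CouplingEvaluator(model, spec, options)
    if ev.evaluate(frozenset(), want_strong=False).is_cut:
        logger.warning("wild type is already growth-coupled; nothing to cut")
        return []
    cuts: List[InterventionStrategy] = []
    cut_sets: List[FrozenSet[str]] = []
    survivors: List[Tuple[str, ...]] = [()]
    for size in range(1, spec.max_interventions + 1):
        next_survivors: List[Tuple[str, ...]] = []
        for base in survivors:
            start = order[base[-1]] + 1 if base else 0
            for g in genes[start:]:
                cand = base + (g,)
                fs = frozenset(cand)
                if any(cs <= fs for cs in cut_sets):
                    continue  # contains a known cut: not minimal
                strat = ev.evaluate(fs, want_strong=False)
                if strat.is_cut:
                    cuts.append(strat)
                    cut_sets.append(fs)
                elif strat.mutant_max_growth >= spec.eps_growth:
                    next_survivors.append(cand)
                # else: desired region dead, prune the whole branch
        survivors = next_survivors
    out = _mark_minimal(cuts, ev)
    out.sort(key=InterventionStrategy.sort_key)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def strategies_to_tsv(strategies: Sequence[InterventionStrategy]) -> str:
    """TSV skeleton of a knockout-strategy table."""
    lines = ["strategy_id\tgenes\tsize\tmutant_max_growth\tstrong_min_product"]
    for i, s in enumerate(sorted(strategies, key=InterventionStrategy.sort_key), 1):
        lines.append(
            "gMCS%d\t%s\t%d\t%.6g\t%.6g"
            % (i, ";".join(sorted(s.genes)), len(s.genes), s.mutant_max_growth, s.strong_min_product)
        )
    return "\n".join(lines) + "\n"
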