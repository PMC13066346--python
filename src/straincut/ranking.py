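"""Six-criteria characterization and scoring of knockout strategies.

Each mutant strain is summarized by the criteria used to screen
growth-coupled designs:

1. number of interventions (``int``, fewer is better),
2. biomass yield Y_x/s = max growth / total substrate uptake (higher),
3. minimum product yield at maximum growth, min Y_p/s|max x (higher),
4. minimum product yield under sub-optimal growth, min Y_p/s (higher),
5. %O2 — percent change of oxygen uptake versus wild type at the
   parsimonious optimum (more negative, i.e. less oxygen, is better),
6. number of accessible metabolites (fewer is better: interrupting a
   pathway at its branch point limits unwanted intermediate buildup).

Scores are equal-weight min–max normalized sums over the candidate set
being ranked; weights are configurable. min Y_p/s is computed with total
substrate uptake pinned at the medium maximum and growth left free, which
keeps the yield ratio linear (the pointwise minimum of a flux ratio over a
cone is not an LP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence

from .coupling import CouplingSpec
from .gpr import knockout_propagate
from .lp import DEFAULT_OPTIONS, FluxRange, LinearSystem, SolverOptions, fva_range
from .model import GEMModel

CRITERIA_DIRECTIONS: Dict[str, int] = {
    # +1: higher is better; -1: lower is better
    "int": -1,
    "Y_xs": +1,
    "minYps_maxx": +1,
    "minYps": +1,
    "pctO2": -1,
    "n_accessible": -1,
}


@dataclass
class StrainCharacterization:
    """One row of a knockout-characterization table."""

    label: str
    genes: FrozenSet[str]
    n_interventions: int
    Y_xs: float
    Y_px: float
    minYps_maxx: float
    maxYps_maxx: float
    minYps: float
    pctO2: Optional[float]
    n_accessible: int
    max_growth: float = float("nan")

    def criteria(self) -> Dict[str, float]:
        return {
            "int": float(self.n_interventions),
            "Y_xs": self.Y_xs,
            "minYps_maxx": self.minYps_maxx,
            "minYps": self.minYps,
            "pctO2": self.pctO2 if self.pctO2 is not None else 0.0,
            "n_accessible": float(self.n_accessible),
        }


def _total_uptake(fluxes: Mapping[str, float], substrate_ids: Sequence[str]) -> float:
    return sum(max(0.0, -fluxes.get(s, 0.0)) for s in substrate_ids)


def count_accessible_metabolites(
    model: GEMModel,
    genes: Iterable[str] = (),
    options: SolverOptions = DEFAULT_OPTIONS,
) -> int:
    """Internal metabolites incident to at least one reaction that can carry
    flux anywhere in the mutant's cone (whole-cone FVA, no growth fix)."""
    _, mutant = knockout_propagate(model, genes)
    rng = fva_range(mutant, list(mutant.reactions), options=options)
    if rng.status != "optimal":
        return 0
    active = {
        rid
        for rid, (lo, hi) in rng.ranges.items()
        if abs(lo) > options.supp_tol or abs(hi) > options.supp_tol
    }
    accessible = set()
    for rid in active:
        for mid in mutant.reactions[rid].stoich:
            if not mutant.metabolites[mid].external:
                accessible.add(mid)
    return len(accessible)


def characterize_strain(
    model: GEMModel,
    spec: CouplingSpec,
    genes: Iterable[str] = (),
    label: Optional[str] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> StrainCharacterization:
    """Compute the six criteria for one strategy (empty set = wild type).

    All single-flux quantities come from the parsimonious optimum so that
    alternate optima cannot make report columns irreproducible.
    """
    genes = frozenset(genes)
    spec.validate_against(model)
    _, mutant = knockout_propagate(model, genes)
    sysm = LinearSystem(mutant, options)
    ps = sysm.solve_parsimonious(spec.biomass_id, "max")
    if not ps.optimal:
        raise ValueError(f"mutant {sorted(genes)} is infeasible; cannot characterize")
    growth = ps.objective_value
    uptake = _total_uptake(ps.fluxes, spec.substrate_exchange_ids)
    Y_xs = growth / uptake if uptake > options.supp_tol else float("nan")

    prange = fva_range(
        mutant,
        [spec.product_exchange_id],
        fix_objective=(spec.biomass_id, 1.0),
        options=options,
        system=sysm,
    )
    pmin, pmax = prange[spec.product_exchange_id]
    minYps_maxx = pmin / uptake if uptake > options.supp_tol else 0.0
    maxYps_maxx = pmax / uptake if uptake > options.supp_tol else 0.0
    Y_px = pmin / growth if growth > options.supp_tol else 0.0

    # min Y_p/s: pin total substrate uptake at the medium maximum, growth free
    upt_obj = {s: -1.0 for s in spec.substrate_exchange_ids}
    umax_state = sysm.solve(upt_obj, "max")
    minYps = 0.0
    if umax_state.optimal and umax_state.objective_value > options.supp_tol:
        umax = umax_state.objective_value
        slack = options.opt_tol * max(1.0, umax)
        pin = [({s: 1.0 for s in spec.substrate_exchange_ids}, -(umax - slack))]
        pmin_free = sysm.solve({spec.product_exchange_id: 1.0}, "min", extra_leq=pin)
        if pmin_free.optimal:
            minYps = pmin_free.objective_value / umax

    pctO2: Optional[float] = None
    if spec.oxygen_exchange_id is not None:
        wt_ps = LinearSystem(model, options).solve_parsimonious(spec.biomass_id, "max")
        o2_wt = abs(wt_ps.fluxes.get(spec.oxygen_exchange_id, 0.0)) if wt_ps.optimal else 0.0
        if o2_wt > options.supp_tol:
            o2_mut = abs(ps.fluxes.get(spec.oxygen_exchange_id, 0.0))
            pctO2 = 100.0 * (o2_mut - o2_wt) / o2_wt
        # WT oxygen uptake 0: percent change undefined, reported as N/A

    n_acc = count_accessible_metabolites(model, genes, options)
    if label is None:
        label = "WT" if not genes else "Δ" + "Δ".join(sorted(genes))
    return StrainCharacterization(
        label=label,
        genes=genes,
        n_interventions=len(genes),
        Y_xs=Y_xs,
        Y_px=Y_px,
        minYps_maxx=minYps_maxx,
        maxYps_maxx=maxYps_maxx,
        minYps=minYps,
        pctO2=pctO2,
        n_accessible=n_acc,
        max_growth=growth,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoreRow:
    label: str
    normalized: Dict[str, float]
    score: float
    rank: int
    excluded: bool = False


def score_and_rank(
    rows: Sequence[object],
    weights: Optional[Mapping[str, float]] = None,
) -> List[ScoreRow]:
    """Min–max normalize each criterion over the candidate set and rank.

    ``rows`` may be :class:`StrainCharacterization` objects or plain dicts
    with a ``label`` key and criterion keys. A row with a non-finite value
    on a weighted criterion is flagged and excluded from normalization.
    Ties are broken lexicographically by label; a single candidate (or a
    criterion with zero span) normalizes to 1.
    """
    if not rows:
        raise ValueError("need at least one candidate row")
    w = {c: 1.0 for c in CRITERIA_DIRECTIONS}
    if weights:
        w.update(weights)
    records: List[Dict[str, float]] = []
    labels: List[str] = []
    for r in rows:
        if isinstance(r, StrainCharacterization):
            records.append(r.criteria())
            labels.append(r.label)
        else:
            records.append({c: r.get(c, float("nan")) for c in CRITERIA_DIRECTIONS})
            labels.append(str(r["label"]))

    def finite(rec) -> bool:
        return all(
            math.isfinite(rec[c]) for c in CRITERIA_DIRECTIONS if w.get(c, 0.0) != 0.0
        )

    usable = [i for i, rec in enumerate(records) if finite(rec)]
    spans: Dict[str, tuple] = {}
    for c in CRITERIA_DIRECTIONS:
        vals = [records[i][c] for i in usable if math.isfinite(records[i][c])]
        spans[c] = (min(vals), max(vals)) if vals else (0.0, 0.0)

    out: List[ScoreRow] = []
    for i, rec in enumerate(records):
        if i not in usable:
            out.append(ScoreRow(labels[i], {}, float("nan"), rank=-1, excluded=True))
            continue
        normalized = {}
        score = 0.0
        for c, direction in CRITERIA_DIRECTIONS.items():
            lo, hi = spans[c]
            if not math.isfinite(rec[c]):
                normalized[c] = 0.0
                continue
            if hi - lo <= 0:
                norm = 1.0
            else:
                norm = (rec[c] - lo) / (hi - lo)
                if direction < 0:
                    norm = 1.0 - norm
            normalized[c] = norm
            score += w.get(c, 0.0) * norm
        out.append(ScoreRow(labels[i], normalized, score, rank=0))
    ranked = sorted(
        [r for r in out if not r.excluded], key=lambda r: (-r.score, r.label)
    )
    for pos, r in enumerate(ranked, 1):
        r.rank = pos
    return sorted(out, key=lambda r: (r.excluded, r.rank if r.rank > 0 else 10**9))


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "Name",
    "Strain",
    "Y_x/s",
    "Y_p/x",
    "Min Y_p/s max x",
    "Max Y_p/s max x",
    "Min Y_p/s",
    "%O2",
    "Score",
    "n_accessible",
]


def render_report_table(
    characterizations: Sequence[StrainCharacterization],
    scores: Optional[Sequence[ScoreRow]] = None,
) -> str:
    """Knockout-characterization table, 3-decimal columns, Δ-prefixed strains."""
    score_by_label = {s.label: s for s in scores or []}
    lines = ["\t".join(TABLE_COLUMNS)]
    counter = 0
    for ch in characterizations:
        if ch.genes:
            counter += 1
            name = f"gMCS{counter}"
        else:
            name = "WT"
        sc = score_by_label.get(ch.label)
        row = [
            name,
            ch.label,
            f"{ch.Y_xs:.3f}",
            f"{ch.Y_px:.3f}",
            f"{ch.minYps_maxx:.3f}",
            f"{ch.maxYps_maxx:.3f}",
            f"{ch.minYps:.3f}",
            "" if (ch.pctO2 is None or not ch.genes) else f"{ch.pctO2:.3f}",
            "" if sc is None else f"{sc.score:.3f}",
            str(ch.n_accessible),
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
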