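"""Synthetic fixture models with known analytic answers.

The fixtures emulate the structural features the analysis assumes on a real
aromatic-degrading bacterium: a forced non-growth maintenance flux (NGAM)
that excludes the zero flux vector, a linear aromatic-degradation pathway
feeding central metabolism, a co-substrate tied by a fixed molar uptake
ratio, an oxygen-consuming respiration lump, and GPR rules including
isozyme/complex cases.

``build_mini_lignin`` is a fixed 16-reaction miniature of the vanillate →
protocatechuate → PDC route with a TCA lump, built so that the three
qualitative knockout mechanisms of interest are all present: a cut at the
pathway branch point (gLigI), cuts mid-pathway via dead-end accumulation
(gLigJ, gLigK), and a cut by removal of the TCA sink (gTCA). Its key
numbers are exact by construction:

* wild-type max growth = 157/15 = 10.46667 (vanillate 10 and glucose 20/3
  through the respiration and glycolysis lumps, minus NGAM 1, divided by
  5 precursor units per biomass);
* ΔgLigI max growth = 67/15 = 4.46667 with the product exchange pinned at
  10, hence a minimum product yield at max growth of 10/(50/3) = 0.600 —
  the value forced by the 3:2 aromatic:glucose uptake ratio;
* the size-1 product cut sets are exactly {gLigI}, {gLigJ}, {gLigK}, {gTCA}.

``random_coupled_network`` generates seeded planted-answer networks for
oracle testing: a linear product-catabolism segment with bypass routes,
whose reaction-level minimal cut sets follow from path enumeration on the
route graph and are lifted to gene sets through the sprinkled GPRs. Every
planted set is re-verified with the LP-based cut check at generation time.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np

from .coupling import CouplingEvaluator, CouplingSpec
from .model import GEMModel, Medium, Metabolite, RatioConstraint, Reaction
from .gpr import parse_gpr

logger = logging.getLogger("straincut")

F = Fraction


def _rxn(rid, stoich, lb=0.0, ub=1000.0, gpr="", exchange=False):
    return Reaction(
        id=rid,
        stoich={k: F(v) for k, v in stoich.items()},
        lb=lb,
        ub=ub,
        gpr=parse_gpr(gpr),
        is_exchange=exchange,
    )


def build_mini_lignin() -> Tuple[GEMModel, Medium, CouplingSpec]:
    """The fixed mini-lignin fixture, medium applied, byte-stable across runs."""
    mets = [
        Metabolite(mid)
        for mid in (
            "VAN", "GLC", "O2", "PCA", "FOR", "CHMS", "PDC",
            "OMA", "KCH", "PYR", "OAA", "E", "BIO",
        )
    ]
    reactions = [
        _rxn("EX_van", {"VAN": -1}, lb=-10.0, ub=0.0, exchange=True),
        _rxn("EX_glc", {"GLC": -1}, lb=-1000.0, ub=0.0, exchange=True),
        _rxn("EX_o2", {"O2": -1}, lb=-1000.0, ub=0.0, exchange=True),
        _rxn("EX_pdc", {"PDC": -1}, lb=0.0, ub=1000.0, exchange=True),
        _rxn("EX_bio", {"BIO": -1}, lb=0.0, ub=1000.0, exchange=True),
        _rxn("VANDM", {"VAN": -1, "PCA": 1, "FOR": 1}, gpr="gLigM"),
        _rxn("PCAD", {"PCA": -1, "CHMS": 1}, gpr="gLigAB"),
        _rxn("CHMSD", {"CHMS": -1, "PDC": 1}, gpr="gLigC"),
        _rxn("PDCH", {"PDC": -1, "OMA": 1}, gpr="gLigI"),
        _rxn("OMAH", {"OMA": -1, "KCH": 1}, gpr="gLigJ"),
        _rxn("KCHA", {"KCH": -1, "PYR": 1, "OAA": 1}, gpr="gLigK"),
        _rxn("TCA", {"PYR": -1, "OAA": -1, "O2": -2, "E": 3}, gpr="gTCA"),
        _rxn("FDH", {"FOR": -1, "O2": F(-1, 2), "E": 1}, gpr="gFdh"),
        _rxn("GLYC", {"GLC": -1, "E": 2}, gpr="gGlyc"),
        _rxn("BIOMASS", {"E": -5, "BIO": 1}),
        _rxn("NGAM", {"E": -1}, lb=1.0),
    ]
    genes = {"gLigM", "gLigAB", "gLigC", "gLigI", "gLigJ", "gLigK", "gTCA", "gFdh", "gGlyc"}
    ratio = RatioConstraint("EX_van", "EX_glc", F(3, 2))
    model = GEMModel(
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        biomass_id="BIOMASS",
        ngam_id="NGAM",
        ratio_constraints=[ratio],
        id="mini_lignin",
    )
    medium = Medium(
        exchange_bounds={
            "EX_van": (-10.0, 0.0),
            "EX_glc": (-1000.0, 0.0),
            "EX_o2": (-1000.0, 0.0),
            "EX_pdc": (0.0, 1000.0),
            "EX_bio": (0.0, 1000.0),
        },
        ratio_constraints=[ratio],
    )
    spec = CouplingSpec(
        biomass_id="BIOMASS",
        product_exchange_id="EX_pdc",
        substrate_exchange_ids=("EX_van", "EX_glc"),
        eps_growth=0.01,
        delta_product=1e-4,
        max_interventions=4,
        oxygen_exchange_id="EX_o2",
    )
    return model, medium, spec


def build_precursor_demo() -> Tuple[GEMModel, Medium, CouplingSpec]:
    """Small fixture for amplification-target scans.

    The product P is made from a dedicated precursor PRE whose synthesis
    (gene gPre) competes with catabolism of the common intermediate A.
    Enforcing product formation therefore pulls flux into the
    precursor-synthesis step, which a flux scan must classify as
    increasing; the conversion PRE → P is spontaneous (empty GPR) so the
    only amplification gene is gPre. This mirrors how glycerol enforcement
    highlights sn-glycerol-3-phosphate synthesis in the real network.
    """
    mets = [Metabolite(m) for m in ("SUB", "A", "PRE", "P", "E", "BIO")]
    reactions = [
        _rxn("EX_sub", {"SUB": -1}, lb=-10.0, ub=0.0, exchange=True),
        _rxn("EX_p", {"P": -1}, lb=0.0, ub=1000.0, exchange=True),
        _rxn("EX_bio", {"BIO": -1}, lb=0.0, ub=1000.0, exchange=True),
        _rxn("UPT", {"SUB": -1, "A": 1}, gpr="gUp"),
        _rxn("PRESYN", {"A": -1, "PRE": 1}, gpr="gPre"),
        _rxn("PSYN", {"PRE": -1, "P": 1}),
        _rxn("CAT", {"A": -1, "E": 2}, gpr="gCat"),
        _rxn("BIOMASS", {"E": -5, "BIO": 1}),
        _rxn("NGAM", {"E": -1}, lb=1.0),
    ]
    model = GEMModel(
        metabolites=mets,
        reactions=reactions,
        genes={"gUp", "gPre", "gCat"},
        biomass_id="BIOMASS",
        ngam_id="NGAM",
        id="precursor_demo",
    )
    medium = Medium(exchange_bounds={"EX_sub": (-10.0, 0.0), "EX_p": (0.0, 1000.0), "EX_bio": (0.0, 1000.0)})
    spec = CouplingSpec(
        biomass_id="BIOMASS",
        product_exchange_id="EX_p",
        substrate_exchange_ids=("EX_sub",),
        eps_growth=0.01,
        delta_product=1e-6,
    )
    return model, medium, spec


# ---------------------------------------------------------------------------
# Planted random networks
# ---------------------------------------------------------------------------


@dataclass
class PlantedNetwork:
    """A seeded random network together with its planted minimal cut sets."""

    seed: int
    model: GEMModel
    spec: CouplingSpec
    planted: List[FrozenSet[str]]


def _route_min_cuts(edges: Dict[str, Tuple[str, str]], source: str, sink: str,
                    max_size: int) -> List[FrozenSet[str]]:
    """Minimal edge-cut sets disconnecting source from sink (enumerated)."""
    import networkx as nx

    def disconnects(removed: FrozenSet[str]) -> bool:
        g = nx.DiGraph()
        for eid, (u, v) in edges.items():
            if eid not in removed:
                g.add_edge(u, v)
        g.add_node(source)
        g.add_node(sink)
        return not nx.has_path(g, source, sink)

    cuts: List[FrozenSet[str]] = []
    ids = sorted(edges)
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(ids, size):
            fs = frozenset(combo)
            if any(c <= fs for c in cuts):
                continue
            if disconnects(fs):
                cuts.append(fs)
    return cuts


def _gene_alternatives(gpr_text: str) -> List[FrozenSet[str]]:
    """Minimal gene sets whose deletion falsifies a (depth ≤ 2) GPR."""
    expr = parse_gpr(gpr_text)
    genes = sorted(expr.genes())
    alts: List[FrozenSet[str]] = []
    for size in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, size):
            fs = frozenset(combo)
            if any(a <= fs for a in alts):
                continue
            if not expr.evaluate(fs):
                alts.append(fs)
    return alts


def random_coupled_network(
    seed: int,
    n_genes: int = 10,
    depth: int = 4,
    n_bypass: int = 1,
    isozyme_rate: float = 0.15,
    complex_rate: float = 0.15,
    max_cut_size: int = 3,
    _attempt: int = 0,
) -> PlantedNetwork:
    """Generate a deterministic planted-answer network.

    The product-catabolism segment P → D1 → … → D_depth → (TCA lump) → E
    carries ``n_bypass`` shortcut reactions D_i → E. Its reaction-level
    minimal cut sets are computed by path enumeration and lifted to gene
    sets through the GPRs (isozymes force pairs, complexes fork variants).
    Substrate entry and glycolysis genes are never cuts: blocking them
    kills the ratio-tied uptake and with it the forced maintenance flux.
    All planted sets are verified by the LP cut check before returning.
    """
    rng = np.random.default_rng(seed + 1_000_003 * _attempt)
    mets = [Metabolite(m) for m in ("SUB", "GLC", "O2", "U1", "P", "E", "BIO")]
    mets += [Metabolite(f"D{i}") for i in range(1, depth + 1)]
    ratio = RatioConstraint("EX_sub", "EX_glc", F(int(rng.choice([2, 3, 4])), 2))

    reactions = [
        _rxn("EX_sub", {"SUB": -1}, lb=-10.0, ub=0.0, exchange=True),
        _rxn("EX_glc", {"GLC": -1}, lb=-1000.0, ub=0.0, exchange=True),
        _rxn("EX_o2", {"O2": -1}, lb=-1000.0, ub=0.0, exchange=True),
        _rxn("EX_p", {"P": -1}, lb=0.0, ub=1000.0, exchange=True),
        _rxn("EX_bio", {"BIO": -1}, lb=0.0, ub=1000.0, exchange=True),
        _rxn("BIOMASS", {"E": -5, "BIO": 1}),
        _rxn("NGAM", {"E": -1}, lb=1.0),
    ]
    genes: List[str] = []

    def new_gene(stem: str) -> str:
        g = f"g{stem}"
        genes.append(g)
        return g

    # substrate entry chain (never cuttable in effect) and glycolysis lump
    reactions.append(_rxn("UP1", {"SUB": -1, "U1": 1}, gpr=new_gene("Up1")))
    reactions.append(_rxn("UP2", {"U1": -1, "P": 1}, gpr=new_gene("Up2")))
    reactions.append(_rxn("GLYC", {"GLC": -1, "E": 2}, gpr=new_gene("Glc")))

    # product catabolism segment: P -> D1 -> ... -> Ddepth -> E (TCA lump)
    route_edges: Dict[str, Tuple[str, str]] = {}
    prev = "P"
    for i in range(1, depth + 1):
        rid = f"DEG{i}"
        reactions.append(_rxn(rid, {prev: -1, f"D{i}": 1}, gpr=new_gene(f"D{i}")))
        route_edges[rid] = (prev, f"D{i}")
        prev = f"D{i}"
    reactions.append(_rxn("TCA", {prev: -1, "O2": -2, "E": 3}, gpr=new_gene("Tca")))
    route_edges["TCA"] = (prev, "E")

    # bypasses from interior pathway nodes straight to the energy pool
    interior = [f"D{i}" for i in range(1, depth)]
    n_bypass = min(n_bypass, len(interior))
    origins = sorted(rng.choice(len(interior), size=n_bypass, replace=False)) if n_bypass else []
    for b, oi in enumerate(origins, 1):
        rid = f"BYP{b}"
        reactions.append(_rxn(rid, {interior[oi]: -1, "E": 1}, gpr=new_gene(f"Byp{b}")))
        route_edges[rid] = (interior[oi], "E")

    # sprinkle isozyme / complex GPRs on route reactions within gene budget
    for rxn in reactions:
        if rxn.id in route_edges and len(genes) < n_genes:
            u = rng.random()
            base = rxn.gpr.serialize()
            if u < isozyme_rate:
                rxn.gpr = parse_gpr(f"{base} or {new_gene(base[1:] + 'b')}")
            elif u < isozyme_rate + complex_rate:
                rxn.gpr = parse_gpr(f"{base} and {new_gene(base[1:] + 'b')}")

    model = GEMModel(
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        biomass_id="BIOMASS",
        ngam_id="NGAM",
        ratio_constraints=[ratio],
        id=f"planted_{seed}",
    )
    spec = CouplingSpec(
        biomass_id="BIOMASS",
        product_exchange_id="EX_p",
        substrate_exchange_ids=("EX_sub", "EX_glc"),
        eps_growth=0.01,
        delta_product=1e-6,
        max_interventions=max_cut_size,
        oxygen_exchange_id="EX_o2",
    )

    # analytic planted answer: route edge cuts lifted through the GPRs
    edge_cuts = _route_min_cuts(route_edges, "P", "E", max_cut_size)
    planted: List[FrozenSet[str]] = []
    for ec in edge_cuts:
        alt_lists = [_gene_alternatives(model.reactions[rid].gpr.serialize()) for rid in sorted(ec)]
        for choice in itertools.product(*alt_lists):
            gs = frozenset().union(*choice)
            planted.append(gs)
    # minimality filter across lifted sets, size budget
    planted = [g for g in planted if len(g) <= max_cut_size]
    planted = sorted(set(planted), key=lambda s: (len(s), tuple(sorted(s))))
    planted = [
        g for g in planted if not any(o < g for o in planted if o != g)
    ]

    ev = CouplingEvaluator(model, spec)
    wt = ev.evaluate(frozenset(), want_strong=False)
    if wt.mutant_max_growth < spec.eps_growth:
        logger.warning("seed %d produced an ungrowable WT; regenerating", seed)
        return random_coupled_network(
            seed, n_genes, depth, n_bypass, isozyme_rate, complex_rate,
            max_cut_size, _attempt + 1,
        )
    for gs in planted:
        strat = ev.evaluate(gs, want_strong=True)
        assert strat.is_cut, f"planted set {sorted(gs)} failed the cut check (seed {seed})"
        for sub in itertools.combinations(sorted(gs), len(gs) - 1):
            assert not ev.evaluate(frozenset(sub), want_strong=False).is_cut, (
                f"planted set {sorted(gs)} not minimal (seed {seed})"
            )
    return PlantedNetwork(seed=seed, model=model, spec=spec, planted=planted)
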