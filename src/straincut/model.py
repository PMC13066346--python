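"""Constraint-based metabolic model container and I/O.

A :class:`GEMModel` holds metabolites, bounded reactions with GPR rules, a
designated biomass reaction and (optionally) a forced non-growth ATP
maintenance reaction (NGAM). Internal metabolites are balanced at steady
state (S·v = 0); boundary species flagged ``external`` are excluded from
the balance. Flux signs follow the COBRA convention: exchange uptake is
negative, secretion positive.

Two dialects are read: SBML Level 3 + FBC v2 (via python-libsbml) and a
flat JSON dialect designed for fixture generation and diffing. Only the
JSON dialect is written.

Stoichiometric coefficients are stored as exact rationals
(:class:`fractions.Fraction`); LP matrices are built in floating point at
solve time, so minimality proofs on toy models do not hinge on float noise.

A medium is a set of exchange bounds plus optional fixed molar uptake-ratio
constraints between two exchanges (e.g. a 3:2 aromatic-to-glucose ratio),
each materialized as one extra equality row appended to S.
"""

from __future__ import annotations

import copy
import json
import logging
import sys
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .gpr import GprExpr, parse_gpr

logger = logging.getLogger("straincut")


class ModelIntegrityError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    external: bool = False


@dataclass
class Reaction:
    """A bounded reaction. Bounds are mmol·gDW⁻¹·h⁻¹ (biomass in h⁻¹)."""

    id: str
    stoich: Dict[str, Fraction]
    lb: float = 0.0
    ub: float = 1000.0
    gpr: GprExpr = field(default_factory=GprExpr.true)
    name: str = ""
    is_exchange: bool = False

    def __post_init__(self):
        if self.lb > self.ub:
            raise ModelIntegrityError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        if not self.stoich:
            raise ModelIntegrityError(f"reaction {self.id}: empty stoichiometry")


@dataclass(frozen=True)
class RatioConstraint:
    """Fixed molar ratio |v_a| = r·|v_b| between two exchange fluxes.

    Encoded as the equality q_b·v_a − q_a·v_b = 0 with q_a/q_b = r, which
    under simultaneous uptake (both fluxes negative) enforces the stated
    magnitude ratio. If one operand is forced to zero the other follows.
    """

    rxn_a: str
    rxn_b: str
    a_per_b: Fraction

    def __post_init__(self):
        if self.a_per_b <= 0:
            raise ConfigurationError("ratio must be positive")

    def row(self) -> Dict[str, Fraction]:
        r = Fraction(self.a_per_b)
        return {self.rxn_a: Fraction(r.denominator), self.rxn_b: -Fraction(r.numerator)}


@dataclass
class Medium:
    """Exchange bounds (uptake as negative lb) plus ratio constraints."""

    exchange_bounds: Dict[str, Tuple[float, float]]
    ratio_constraints: List[RatioConstraint] = field(default_factory=list)


class GEMModel:
    """Genome-scale metabolic model.

    Attributes
    ----------
    metabolites, reactions : insertion-ordered dicts keyed by id.
    genes : set of gene ids (the GPR universe G).
    biomass_id : id of the growth objective reaction.
    ngam_id : id of the forced maintenance reaction, if any; its lb > 0
        excludes the zero flux vector from the feasible cone.
    ratio_constraints : extra equality rows appended to S.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        genes: Iterable[str],
        biomass_id: str,
        ngam_id: Optional[str] = None,
        ratio_constraints: Optional[List[RatioConstraint]] = None,
        id: str = "model",
    ):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise ModelIntegrityError(f"duplicate metabolite id {m.id}")
            self.metabolites[m.id] = m
        self.reactions: Dict[str, Reaction] = {}
        for r in reactions:
            if r.id in self.reactions:
                raise ModelIntegrityError(f"duplicate reaction id {r.id}")
            self.reactions[r.id] = r
        self.genes = set(genes)
        self.biomass_id = biomass_id
        self.ngam_id = ngam_id
        self.ratio_constraints = list(ratio_constraints or [])
        self.ratio_mode = "equality"
        self._check()

    # -- integrity ------------------------------------------------------
    def _check(self) -> None:
        for r in self.reactions.values():
            for mid in r.stoich:
                if mid not in self.metabolites:
                    raise ModelIntegrityError(
                        f"reaction {r.id} references unknown metabolite {mid}"
                    )
            missing = r.gpr.genes() - self.genes
            if missing:
                raise ModelIntegrityError(
                    f"reaction {r.id} GPR cites gene(s) absent from G: {sorted(missing)}"
                )
            if r.is_exchange:
                internal = [m for m in r.stoich if not self.metabolites[m].external]
                if len(internal) != 1:
                    raise ModelIntegrityError(
                        f"exchange {r.id} must touch exactly one internal metabolite"
                    )
        if self.biomass_id not in self.reactions:
            raise ConfigurationError(
                f"biomass reaction {self.biomass_id!r} not in model; pass it explicitly"
            )
        if self.ngam_id is not None:
            ngam = self.reactions.get(self.ngam_id)
            if ngam is None:
                raise ConfigurationError(f"NGAM reaction {self.ngam_id!r} not in model")
            if ngam.lb <= 0:
                raise ModelIntegrityError(
                    f"NGAM reaction {self.ngam_id} must be forced (lb > 0), got lb={ngam.lb}"
                )
        for rc in self.ratio_constraints:
            for rid in (rc.rxn_a, rc.rxn_b):
                if rid not in self.reactions:
                    raise ConfigurationError(f"ratio references unknown reaction {rid}")
                if not self.reactions[rid].is_exchange:
                    raise ConfigurationError(
                        f"ratio constraint references non-exchange reaction {rid}"
                    )

    # -- views ----------------------------------------------------------
    @property
    def internal_metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites.values() if not m.external]

    @property
    def exchange_ids(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "GEMModel":
        return copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<GEMModel {self.id}: {len(self.genes)} genes, "
            f"{len(self.reactions)} reactions, {len(self.metabolites)} metabolites>"
        )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _frac_to_json(x: Fraction) -> Union[int, str]:
    return int(x) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"


def _frac_from_json(x) -> Fraction:
    return Fraction(x)


def model_to_dict(model: GEMModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "external": m.external,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: _frac_to_json(v) for k, v in r.stoich.items()},
                "lb": r.lb,
                "ub": r.ub,
                "gpr": r.gpr.serialize(),
                "exchange": r.is_exchange,
            }
            for r in model.reactions.values()
        ],
        "genes": sorted(model.genes),
        "biomass": model.biomass_id,
        "ngam": model.ngam_id,
        "ratio_constraints": [
            {"rxn_a": rc.rxn_a, "rxn_b": rc.rxn_b, "a_per_b": _frac_to_json(rc.a_per_b)}
            for rc in model.ratio_constraints
        ],
    }


def model_from_dict(data: dict) -> GEMModel:
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            external=bool(m.get("external", False)),
        )
        for m in data["metabolites"]
    ]
    rxns = []
    for r in data["reactions"]:
        try:
            gpr = parse_gpr(r.get("gpr", ""))
        except ValueError as e:
            raise ModelIntegrityError(f"reaction {r['id']}: malformed GPR: {e}") from e
        rxns.append(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoich={k: _frac_from_json(v) for k, v in r["stoich"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                gpr=gpr,
                is_exchange=bool(r.get("exchange", r["id"].startswith("EX_"))),
            )
        )
    ratios = [
        RatioConstraint(rc["rxn_a"], rc["rxn_b"], Fraction(rc["a_per_b"]))
        for rc in data.get("ratio_constraints", [])
    ]
    if "biomass" not in data or data["biomass"] is None:
        raise ConfigurationError(
            "no biomass designation in model file; pass it explicitly"
        )
    return GEMModel(
        metabolites=mets,
        reactions=rxns,
        genes=data.get("genes", []),
        biomass_id=data["biomass"],
        ngam_id=data.get("ngam"),
        ratio_constraints=ratios,
        id=data.get("id", "model"),
    )


def write_model(model: GEMModel, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------


def _gpa_to_string(assoc) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_gpa_to_string(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_gpa_to_string(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ModelIntegrityError(f"unsupported GPR association node {type(assoc)}")


def _load_sbml(text_or_path: Union[str, Path]) -> GEMModel:
    import libsbml

    src = str(text_or_path)
    if Path(src).exists():
        doc = libsbml.readSBMLFromFile(src)
    else:
        doc = libsbml.readSBMLFromString(src)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIntegrityError(f"SBML parse error: {err.getMessage() if err else 'unknown'}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIntegrityError("SBML document contains no model")
    fbc = sbml_model.getPlugin("fbc")

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                external=sp.getBoundaryCondition(),
            )
        )

    genes = set()
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            genes.add(fbc.getGeneProduct(i).getId())

    def param_value(pid, default):
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else default

    rxns = []
    objective_rxn = None
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: Dict[str, Fraction] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), Fraction(0)) - Fraction(
                sr.getStoichiometry()
            ).limit_denominator(10**6)
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), Fraction(0)) + Fraction(
                sr.getStoichiometry()
            ).limit_denominator(10**6)
        stoich = {k: v for k, v in stoich.items() if v != 0} or stoich
        rfbc = rx.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        gpr_text = ""
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = param_value(rfbc.getLowerFluxBound(), lb)
            if rfbc.isSetUpperFluxBound():
                ub = param_value(rfbc.getUpperFluxBound(), ub)
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                gpr_text = _gpa_to_string(gpa.getAssociation())
        try:
            gpr = parse_gpr(gpr_text)
        except ValueError as e:
            raise ModelIntegrityError(f"reaction {rx.getId()}: malformed GPR: {e}") from e
        met_index = {m.id: m for m in mets}
        internal_touched = [m for m in stoich if not met_index[m].external]
        is_ex = len(stoich) == 1 or (len(internal_touched) == 1 and len(stoich) > len(internal_touched))
        rxns.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName(),
                stoich=stoich,
                lb=float(lb),
                ub=float(ub),
                gpr=gpr,
                is_exchange=is_ex,
            )
        )

    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_rxn = obj.getFluxObjective(0).getReaction()
    if objective_rxn is None:
        raise ConfigurationError(
            "SBML model declares no active objective; pass the biomass reaction explicitly"
        )
    return GEMModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        biomass_id=objective_rxn,
        ngam_id=None,
        id=sbml_model.getId() or "model",
    )


def load_model(
    source: Union[str, Path],
    dialect: str = "json",
    biomass_id: Optional[str] = None,
    ngam_id: Optional[str] = None,
) -> GEMModel:
    """Load a model from SBML-FBC (``dialect='sbml-fbc'``) or the JSON dialect.

    ``biomass_id`` / ``ngam_id`` override or supply the designations when the
    file does not carry them.
    """
    if dialect == "json":
        src = str(source)
        text = Path(src).read_text() if Path(src).exists() else src
        data = json.loads(text)
        if biomass_id is not None:
            data["biomass"] = biomass_id
        if ngam_id is not None:
            data["ngam"] = ngam_id
        model = model_from_dict(data)
    elif dialect == "sbml-fbc":
        model = _load_sbml(source)
        if biomass_id is not None:
            model.biomass_id = biomass_id
        if ngam_id is not None:
            model.ngam_id = ngam_id
        model._check()
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    logger.info(
        "loaded model %s: %d genes, %d reactions, %d metabolites",
        model.id,
        len(model.genes),
        len(model.reactions),
        len(model.metabolites),
    )
    return model


# ---------------------------------------------------------------------------
# Medium application
# ---------------------------------------------------------------------------


def apply_medium(model: GEMModel, medium: Medium, ratio_mode: str = "equality") -> GEMModel:
    """Return a copy of ``model`` with the medium applied.

    Exchange bounds listed in the medium overwrite the model's; every other
    exchange is closed to uptake (lb raised to 0, secretion untouched).
    Ratio constraints are attached to the model and materialized as extra
    equality rows at LP-build time. ``ratio_mode='min'`` relaxes each ratio
    to a lower bound on the first operand's share (|v_a| ≥ r·|v_b|).
    """
    if ratio_mode not in ("equality", "min"):
        raise ConfigurationError(f"unknown ratio_mode {ratio_mode!r}")
    out = model.copy()
    for rid, (lb, ub) in medium.exchange_bounds.items():
        rxn = out.reactions.get(rid)
        if rxn is None:
            raise ConfigurationError(f"medium references unknown reaction {rid}")
        if not rxn.is_exchange:
            raise ConfigurationError(f"medium bound on non-exchange reaction {rid}")
        rxn.lb, rxn.ub = float(lb), float(ub)
    for rxn in out.reactions.values():
        if rxn.is_exchange and rxn.id not in medium.exchange_bounds:
            rxn.lb = max(rxn.lb, 0.0)
    for rc in medium.ratio_constraints:
        for rid in (rc.rxn_a, rc.rxn_b):
            if rid not in out.reactions or not out.reactions[rid].is_exchange:
                raise ConfigurationError(
                    f"ratio constraint between non-exchange reactions: {rid}"
                )
    out.ratio_constraints = list(medium.ratio_constraints)
    out.ratio_mode = ratio_mode
    return out


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def validate_model(model: GEMModel) -> dict:
    """Report-only structural diagnostics; never mutates the model."""
    report: dict = {"warnings": []}
    produced: Dict[str, bool] = {m: False for m in model.internal_metabolite_ids}
    consumed: Dict[str, bool] = {m: False for m in model.internal_metabolite_ids}
    for r in model.reactions.values():
        for mid, coef in r.stoich.items():
            if mid not in produced:
                continue
            if (coef > 0 and r.ub > 0) or (coef < 0 and r.lb < 0):
                produced[mid] = True
            if (coef < 0 and r.ub > 0) or (coef > 0 and r.lb < 0):
                consumed[mid] = True
    dead_ends = sorted(m for m in produced if not (produced[m] and consumed[m]))
    report["dead_end_metabolites"] = dead_ends
    report["reactions_without_gpr"] = sorted(
        r.id for r in model.reactions.values() if r.gpr.kind == "true" and not r.is_exchange
    )
    ngam = model.reactions.get(model.ngam_id) if model.ngam_id else None
    report["ngam_present"] = ngam is not None
    report["ngam_forced_lb"] = ngam.lb if ngam is not None else None
    if ngam is None or ngam.lb <= 0:
        report["warnings"].append(
            "no forced NGAM: the zero flux vector is feasible, so strong-coupling "
            "minima may be trivially 0"
        )
    if dead_ends:
        report["warnings"].append(f"dead-end metabolites: {dead_ends}")
    bad_exchange = [
        r.id
        for r in model.reactions.values()
        if r.is_exchange
        and len([m for m in r.stoich if not model.metabolites[m].external]) != 1
    ]
    report["malformed_exchanges"] = bad_exchange
    return report
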