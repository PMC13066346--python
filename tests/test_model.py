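"""Model container, JSON/SBML I/O, medium application and diagnostics."""

import json
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from straincut import (
    GEMModel,
    Medium,
    Metabolite,
    RatioConstraint,
    Reaction,
    apply_medium,
    fba_max,
    load_model,
    parse_gpr,
    validate_model,
    write_model,
)
from straincut.lp import LinearSystem
from straincut.model import ConfigurationError, ModelIntegrityError, model_to_dict


def test_json_round_trip_is_identity(mini_model, tmp_path):
    path = tmp_path / "mini.json"
    write_model(mini_model, path)
    again = load_model(path, dialect="json")
    assert model_to_dict(again) == model_to_dict(mini_model)
    # exact rationals survive (FDH consumes half an O2 per formate)
    assert again.reactions["FDH"].stoich["O2"] == Fraction(-1, 2)


def test_unknown_metabolite_is_integrity_error():
    with pytest.raises(ModelIntegrityError, match="unknown metabolite"):
        GEMModel(
            [Metabolite("A")],
            [Reaction("R", {"A": Fraction(-1), "GHOST": Fraction(1)})],
            set(),
            biomass_id="R",
        )


def test_gpr_gene_absent_from_gene_set_is_integrity_error(tmp_path):
    data = {
        "metabolites": [{"id": "A"}],
        "reactions": [
            {"id": "EX_a", "stoich": {"A": -1}, "lb": -1, "ub": 1, "gpr": "gMissing"}
        ],
        "genes": [],
        "biomass": "EX_a",
    }
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(data))
    with pytest.raises(ModelIntegrityError, match="gMissing"):
        load_model(path)


def test_missing_biomass_designation_instructs_explicit_pass(tmp_path):
    data = {
        "metabolites": [{"id": "A"}],
        "reactions": [{"id": "EX_a", "stoich": {"A": -1}, "lb": -1, "ub": 1}],
        "genes": [],
    }
    path = tmp_path / "nobm.json"
    path.write_text(json.dumps(data))
    with pytest.raises(ConfigurationError, match="explicitly"):
        load_model(path)
    # supplying it explicitly fixes the load
    model = load_model(path, biomass_id="EX_a")
    assert model.biomass_id == "EX_a"


def test_malformed_gpr_names_the_reaction(tmp_path):
    data = {
        "metabolites": [{"id": "A"}],
        "reactions": [
            {"id": "EX_a", "stoich": {"A": -1}, "lb": -1, "ub": 1, "gpr": "gA and ("}
        ],
        "genes": ["gA"],
        "biomass": "EX_a",
    }
    path = tmp_path / "badgpr.json"
    path.write_text(json.dumps(data))
    with pytest.raises(ModelIntegrityError, match="EX_a"):
        load_model(path)


def test_forced_ngam_excludes_zero_vector(mini_model):
    # the zero vector violates the NGAM lower bound, so closing every
    # uptake leaves nothing to satisfy maintenance: the model is infeasible
    closed = mini_model.copy()
    for rid in ("EX_van", "EX_glc", "EX_o2"):
        closed.reactions[rid].lb = 0.0
    assert fba_max(closed, "BIOMASS").status == "infeasible"


def test_ngam_must_be_forced(mini_model):
    broken = mini_model.copy()
    broken.reactions["NGAM"].lb = 0.0
    with pytest.raises(ModelIntegrityError, match="forced"):
        GEMModel(
            broken.metabolites.values(),
            broken.reactions.values(),
            broken.genes,
            biomass_id="BIOMASS",
            ngam_id="NGAM",
        )


# ---------------------------------------------------------------------------
# Medium and ratio constraint
# ---------------------------------------------------------------------------


def _mini_without_medium(mini_model):
    raw = mini_model.copy()
    raw.ratio_constraints = []
    return raw


def test_apply_medium_sets_bounds_and_closes_others(mini_model):
    raw = _mini_without_medium(mini_model)
    medium = Medium(
        exchange_bounds={"EX_van": (-10, 0), "EX_glc": (-1000, 0), "EX_o2": (-1000, 0)},
        ratio_constraints=[RatioConstraint("EX_van", "EX_glc", Fraction(3, 2))],
    )
    prepared = apply_medium(raw, medium)
    assert prepared.reactions["EX_van"].lb == -10
    # unlisted exchanges are closed to uptake but can still secrete
    assert prepared.reactions["EX_pdc"].lb == 0.0
    assert prepared.reactions["EX_pdc"].ub > 0
    # any feasible state obeys |v_van| = 1.5 |v_glc|
    state = fba_max(prepared, "BIOMASS")
    assert state.optimal
    assert abs(state.fluxes["EX_van"]) == pytest.approx(
        1.5 * abs(state.fluxes["EX_glc"]), abs=1e-6
    )


def test_ratio_with_zero_operand_forces_zero(mini_model):
    pinned = mini_model.copy()
    pinned.reactions["EX_glc"].lb = 0.0  # no glucose uptake possible
    state = fba_max(pinned, "EX_van")  # also try to *secrete* vanillate
    sys_ = LinearSystem(pinned)
    lo = sys_.solve({"EX_van": 1.0}, "min")
    # vanillate flux is pinned to zero in every feasible state... but with
    # no uptake at all the forced NGAM makes the cone empty outright
    assert state.status == "infeasible" or abs(state.fluxes["EX_van"]) < 1e-9
    assert lo.status == "infeasible" or abs(lo.objective_value) < 1e-9


def test_vanillate_only_medium_is_ngam_infeasible(mini_model):
    # vanillate alone cannot satisfy the ratio row: glucose uptake 0 forces
    # vanillate uptake 0, and with no carbon the NGAM cannot run
    raw = _mini_without_medium(mini_model)
    medium = Medium(
        exchange_bounds={"EX_van": (-10, 0), "EX_o2": (-1000, 0)},
        ratio_constraints=[RatioConstraint("EX_van", "EX_glc", Fraction(3, 2))],
    )
    prepared = apply_medium(raw, medium)
    assert prepared.reactions["EX_glc"].lb == 0.0
    assert fba_max(prepared, "BIOMASS").status == "infeasible"


def test_ratio_between_non_exchanges_is_configuration_error(mini_model):
    raw = _mini_without_medium(mini_model)
    medium = Medium(
        exchange_bounds={"EX_van": (-10, 0)},
        ratio_constraints=[RatioConstraint("EX_van", "VANDM", Fraction(1))],
    )
    with pytest.raises(ConfigurationError, match="non-exchange"):
        apply_medium(raw, medium)


@given(st.lists(st.sampled_from(
    ["BIOMASS", "EX_pdc", "EX_van", "GLYC", "FDH", "TCA"]), min_size=1, max_size=2, unique=True))
def test_ratio_never_enlarges_feasible_set(mini_model, objectives):
    """Every state feasible with the ratio row is feasible without it, so
    any linear maximum can only drop when the row is appended."""
    free = mini_model.copy()
    free.ratio_constraints = []
    for rid in objectives:
        with_ratio = fba_max(mini_model, rid)
        without = fba_max(free, rid)
        assert without.optimal
        if with_ratio.optimal:
            assert with_ratio.objective_value <= without.objective_value + 1e-6


def test_ratio_min_mode_is_a_relaxation(mini_model):
    eq = fba_max(mini_model, "BIOMASS").objective_value
    relaxed = mini_model.copy()
    relaxed.ratio_mode = "min"
    ge = fba_max(relaxed, "BIOMASS").objective_value
    assert ge >= eq - 1e-6  # the inequality mode can only enlarge the cone


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def test_validate_reports_forced_ngam(mini_model):
    report = validate_model(mini_model)
    assert report["ngam_present"] and report["ngam_forced_lb"] == 1.0
    assert report["dead_end_metabolites"] == []
    assert not report["warnings"]


def test_validate_warns_on_unforced_ngam(mini_model):
    loose = mini_model.copy()
    loose.reactions["NGAM"].lb = 0.0
    loose.ngam_id = None
    report = validate_model(loose)
    assert any("zero flux vector" in w or "strong-coupling" in w for w in report["warnings"])


def test_validate_lists_dead_ends(mini_model):
    broken = mini_model.copy()
    broken.metabolites["ORPHAN"] = Metabolite("ORPHAN")
    broken.reactions["MAKE_ORPHAN"] = Reaction(
        "MAKE_ORPHAN", {"E": Fraction(-1), "ORPHAN": Fraction(1)}
    )
    report = validate_model(broken)
    assert "ORPHAN" in report["dead_end_metabolites"]


# ---------------------------------------------------------------------------
# SBML-FBC cross-check against cobrapy
# ---------------------------------------------------------------------------


def _cobra_mini(mini_model):
    cobra = pytest.importorskip("cobra")
    m = cobra.Model("mini")
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in mini_model.metabolites}
    for rxn in mini_model.reactions.values():
        r = cobra.Reaction(rxn.id)
        r.lower_bound, r.upper_bound = rxn.lb, rxn.ub
        m.add_reactions([r])
        r.add_metabolites({mets[k]: float(v) for k, v in rxn.stoich.items()})
        gpr = rxn.gpr.serialize()
        if gpr:
            r.gene_reaction_rule = gpr
    m.objective = "BIOMASS"
    return m


def test_sbml_fbc_loader_agrees_with_cobra(mini_model, tmp_path):
    """Write the fixture through cobrapy's SBML writer and read it back with
    the libsbml-based loader: structure and FBA optimum must agree."""
    cobra = pytest.importorskip("cobra")
    cm = _cobra_mini(mini_model)
    path = tmp_path / "mini.xml"
    cobra.io.write_sbml_model(cm, str(path))
    loaded = load_model(path, dialect="sbml-fbc", ngam_id=None)
    assert len(loaded.reactions) == len(mini_model.reactions)
    assert len(loaded.metabolites) == len(mini_model.metabolites)
    assert len(loaded.genes) == len(mini_model.genes)
    # GPRs survive the trip (ids may gain an SBML-legal prefix; compare sizes)
    complex_r = [r for r in loaded.reactions.values() if len(r.gpr.genes()) > 0]
    assert len(complex_r) == 9
    # FBA on the loaded model equals cobrapy's own optimum (no ratio row here)
    ours = fba_max(loaded, loaded.biomass_id)
    theirs = cm.optimize()
    assert ours.objective_value == pytest.approx(theirs.objective_value, rel=1e-6)
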