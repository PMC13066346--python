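"""Six-criteria characterization, scoring and report rendering."""

import math

import pytest

from straincut import (
    characterize_strain,
    count_accessible_metabolites,
    render_report_table,
    score_and_rank,
)
from straincut.reference_data import (
    PDC_KNOCKOUT_TABLE,
    propionate_candidates,
)


@pytest.fixture(scope="module")
def dligi(mini):
    model, _, spec = mini
    return characterize_strain(model, spec, {"gLigI"})


@pytest.fixture(scope="module")
def wt_row(mini):
    model, _, spec = mini
    return characterize_strain(model, spec, ())


def test_branch_knockout_yield_forced_by_ratio(dligi):
    # full vanillate conversion at the 3:2 ratio: 10 / (10 + 20/3) = 0.600
    assert dligi.minYps_maxx == pytest.approx(0.600, abs=1e-4)
    assert dligi.maxYps_maxx == pytest.approx(0.600, abs=1e-4)


def test_branch_knockout_oxygen_drop(dligi):
    # 5 vs 25 O2 at the parsimonious optima
    assert dligi.pctO2 == pytest.approx(-80.0, abs=1e-2)


def test_wild_type_produces_nothing(wt_row):
    assert wt_row.Y_px == pytest.approx(0.0, abs=1e-6)
    assert wt_row.minYps_maxx == pytest.approx(0.0, abs=1e-5)
    assert wt_row.maxYps_maxx == pytest.approx(0.0, abs=1e-5)
    assert wt_row.minYps == pytest.approx(0.0, abs=1e-6)
    assert wt_row.n_interventions == 0


def test_yield_identity(dligi, wt_row):
    # min Y_p/s at max growth factors exactly into Y_p/x · Y_x/s
    for row in (dligi, wt_row):
        assert round(row.Y_px, 3) * round(row.Y_xs, 3) == pytest.approx(
            round(row.minYps_maxx, 3), abs=0.02
        )
    assert dligi.minYps <= dligi.minYps_maxx + 1e-6


def test_accessible_metabolites(mini, wt_row, dligi):
    model, _, _ = mini
    n_internal = len(model.internal_metabolite_ids)
    # every internal metabolite is reachable in the wild type
    assert wt_row.n_accessible == n_internal
    # the branch-point knockout strands the four downstream metabolites
    # (OMA, KCH, PYR, OAA): their only producing chain is blocked
    assert wt_row.n_accessible - dligi.n_accessible == 4


def test_fully_blocked_model_has_no_accessible_metabolites(mini):
    model, _, _ = mini
    dead = model.copy()
    for rxn in dead.reactions.values():
        if rxn.id != "NGAM":
            rxn.lb = rxn.ub = 0.0
    assert count_accessible_metabolites(dead) == 0


def test_infeasible_mutant_cannot_be_characterized(mini):
    model, _, spec = mini
    with pytest.raises(ValueError, match="infeasible"):
        characterize_strain(model, spec, {"gLigM"})


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def test_mini_strategies_rank_reproducibly(mini):
    model, _, spec = mini
    rows = [characterize_strain(model, spec, {g}) for g in
            ("gLigI", "gLigJ", "gLigK", "gTCA")]
    first = score_and_rank(rows)
    second = score_and_rank(rows)
    assert [(r.rank, r.label) for r in first] == [(r.rank, r.label) for r in second]
    # all four are criterion-identical here, so ties break lexicographically
    assert [r.label for r in first] == ["ΔgLigI", "ΔgLigJ", "ΔgLigK", "ΔgTCA"]


def test_single_candidate_scores_sum_of_weights():
    row = {"label": "only", "int": 2, "Y_xs": 1.0, "minYps_maxx": 0.5,
           "minYps": 0.1, "pctO2": -10.0, "n_accessible": 5}
    scored = score_and_rank([row])
    assert scored[0].score == pytest.approx(6.0)
    scored_w = score_and_rank([row], weights={"int": 2.0, "pctO2": 0.0})
    assert scored_w[0].score == pytest.approx(2.0 + 4.0)


def test_score_invariant_under_column_rescaling():
    rows = [
        {"label": "a", "int": 1, "Y_xs": 10.0, "minYps_maxx": 0.2, "minYps": 0.1,
         "pctO2": -5.0, "n_accessible": 8},
        {"label": "b", "int": 2, "Y_xs": 30.0, "minYps_maxx": 0.6, "minYps": 0.3,
         "pctO2": -1.0, "n_accessible": 4},
    ]
    base = {r.label: r.score for r in score_and_rank(rows)}
    scaled = [dict(r, Y_xs=r["Y_xs"] * 100.0) for r in rows]
    again = {r.label: r.score for r in score_and_rank(scaled)}
    assert base == pytest.approx(again)


def test_dominated_candidate_preserves_relative_order():
    rows = [
        {"label": "a", "int": 1, "Y_xs": 10.0, "minYps_maxx": 0.6, "minYps": 0.2,
         "pctO2": -9.0, "n_accessible": 5},
        {"label": "b", "int": 2, "Y_xs": 8.0, "minYps_maxx": 0.4, "minYps": 0.1,
         "pctO2": -4.0, "n_accessible": 7},
    ]
    # strictly worse than both on every criterion
    dominated = {"label": "z", "int": 4, "Y_xs": 1.0, "minYps_maxx": 0.05,
                 "minYps": 0.0, "pctO2": 3.0, "n_accessible": 12}
    order = [r.label for r in score_and_rank(rows)]
    with_dom = [r.label for r in score_and_rank(rows + [dominated])]
    assert [l for l in with_dom if l != "z"] == order
    assert with_dom[-1] == "z"


def test_non_finite_row_is_flagged_and_excluded():
    rows = [
        {"label": "ok", "int": 1, "Y_xs": 10.0, "minYps_maxx": 0.6, "minYps": 0.2,
         "pctO2": -9.0, "n_accessible": 5},
        {"label": "broken", "int": 1, "Y_xs": float("nan"), "minYps_maxx": 0.4,
         "minYps": 0.1, "pctO2": -4.0, "n_accessible": 7},
    ]
    scored = score_and_rank(rows)
    flags = {r.label: r.excluded for r in scored}
    assert flags == {"ok": False, "broken": True}


def test_published_pdc_table_ranks_mid_pathway_cuts_first():
    """On the printed PDC knockout criteria (accessible-metabolite counts
    are not printed, weight 0) the mid-pathway single-gene cuts ligJ/ligK
    outscore the classic branch-point ligI deletion."""
    scored = score_and_rank(PDC_KNOCKOUT_TABLE, weights={"n_accessible": 0.0})
    by_rank = [r.label for r in scored]
    assert set(by_rank[:2]) == {"ΔligJ", "ΔligK"}
    assert by_rank[2] == "ΔligI"
    assert by_rank[-1] == "ΔpckA"


def test_propionate_candidates_rank_pcka_first():
    scored = score_and_rank(propionate_candidates())
    assert scored[0].label == "ΔpckA"
    assert scored[0].rank == 1


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def test_report_table_layout(mini, wt_row, dligi):
    scored = score_and_rank([dligi])
    text = render_report_table([wt_row, dligi], scored)
    lines = text.strip().split("\n")
    header = lines[0].split("\t")
    assert header[:8] == [
        "Name", "Strain", "Y_x/s", "Y_p/x", "Min Y_p/s max x",
        "Max Y_p/s max x", "Min Y_p/s", "%O2",
    ]
    wt_cells = lines[1].split("\t")
    assert wt_cells[0] == "WT"
    assert wt_cells[4] == "0.000" and wt_cells[7] == ""  # %O2 blank for WT
    mut_cells = lines[2].split("\t")
    assert mut_cells[1] == "ΔgLigI"
    assert mut_cells[4] == "0.600"


def test_empty_report_is_header_only():
    assert render_report_table([]) .strip().count("\n") == 0
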