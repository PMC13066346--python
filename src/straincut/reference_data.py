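"""Published characterization values for iNovo479 knockout strains.

The iNovo479 genome-scale model of *Novosphingobium aromaticivorans*
DSM12444 (479 genes, 645 reactions, 604 metabolites) is the full-scale
target of this package. Its published knockout screens provide two small
printed tables that are useful as ranking inputs without the model file:

* ``PDC_KNOCKOUT_TABLE`` — the seven knockout strategies coupling growth
  to 2-pyrone-4,6-dicarboxylate (PDC) on a 3:2 vanillate:glucose medium,
  with five of the six ranking criteria as printed (the accessible-
  metabolite counts are not printed; rank that table with the
  ``n_accessible`` weight set to 0).

* ``propionate_candidates()`` — a propionate candidate set in which only
  the ΔpckA row carries printed values; the competitor rows are SYNTHETIC
  stand-ins constrained by the published qualitative facts (ΔpckA has the
  higher biomass yield and considerably higher product yields than every
  other candidate; Δadk is the only other single-gene candidate, the rest
  delete four genes). Only rank-level conclusions should be drawn from the
  synthetic rows, never score values.

Yields are mgDW/mmol (Y_x/s), mmol/mgDW (Y_p/x) and mmol/mmol (Y_p/s);
%O2 is the percent change in oxygen uptake versus the wild type.
"""

from __future__ import annotations

from typing import Dict, List

# PDC on vanillate:glucose 3:2 — printed characterization rows.
# Criteria keys match ranking.CRITERIA_DIRECTIONS; n_accessible is not
# printed and must be weighted 0 when ranking this table.
PDC_KNOCKOUT_TABLE: List[Dict] = [
    {"label": "ΔligI", "int": 1, "Y_xs": 58.264, "Y_px": 0.010,
     "minYps_maxx": 0.600, "maxYps_maxx": 0.600, "minYps": 0.043, "pctO2": -19.417},
    {"label": "ΔligK", "int": 1, "Y_xs": 71.056, "Y_px": 0.008,
     "minYps_maxx": 0.522, "maxYps_maxx": 0.600, "minYps": 0.043, "pctO2": -19.449},
    {"label": "ΔligJ", "int": 1, "Y_xs": 71.056, "Y_px": 0.008,
     "minYps_maxx": 0.522, "maxYps_maxx": 0.600, "minYps": 0.043, "pctO2": -19.449},
    {"label": "ΔpckA", "int": 1, "Y_xs": 89.229, "Y_px": 0.004,
     "minYps_maxx": 0.362, "maxYps_maxx": 0.464, "minYps": 0.043, "pctO2": -14.817},
    {"label": "ΔsucCΔsucDΔgcvTΔcysE", "int": 4, "Y_xs": 75.693, "Y_px": 0.006,
     "minYps_maxx": 0.448, "maxYps_maxx": 0.573, "minYps": 0.272, "pctO2": -19.574},
    {"label": "ΔsucCΔsucDΔgcvPBΔcysE", "int": 4, "Y_xs": 75.909, "Y_px": 0.006,
     "minYps_maxx": 0.420, "maxYps_maxx": 0.579, "minYps": 0.271, "pctO2": -19.519},
    {"label": "ΔsucCΔsucDΔgcvPAΔcysE", "int": 4, "Y_xs": 75.909, "Y_px": 0.006,
     "minYps_maxx": 0.420, "maxYps_maxx": 0.579, "minYps": 0.271, "pctO2": -19.519},
]

# Printed wild-type row for the same medium (all product yields zero).
PDC_WILDTYPE_ROW: Dict = {
    "label": "WT", "int": 0, "Y_xs": 121.190, "Y_px": 0.0,
    "minYps_maxx": 0.0, "maxYps_maxx": 0.0, "minYps": 0.0, "pctO2": 0.0,
}


def propionate_candidates() -> List[Dict]:
    """Propionate candidate rows for rank-agreement checks.

    The ΔpckA row is the printed one (vanillate sole carbon source). The
    other rows are synthetic: their magnitudes are placeholders chosen to
    respect the published dominance facts (strictly lower biomass yield
    and product yields than ΔpckA; Δadk is single-gene, the others
    four-gene). They exist so the scoring scheme can be exercised at the
    rank level; the numbers themselves carry no information.
    """
    rows = [
        {"label": "ΔpckA", "int": 1, "Y_xs": 99.931, "Y_px": 0.005,
         "minYps_maxx": 0.751, "maxYps_maxx": 0.751, "minYps": 0.606,
         "pctO2": -5.719, "n_accessible": 540},
        # synthetic competitor rows (see docstring)
        {"label": "Δadk", "int": 1, "Y_xs": 82.0, "Y_px": 0.004,
         "minYps_maxx": 0.41, "maxYps_maxx": 0.52, "minYps": 0.30,
         "pctO2": -7.5, "n_accessible": 560},
        {"label": "ΔSaro_2568ΔpykΔSaro_0559ΔSaro_2259", "int": 4, "Y_xs": 74.0,
         "Y_px": 0.004, "minYps_maxx": 0.45, "maxYps_maxx": 0.55, "minYps": 0.34,
         "pctO2": -8.8, "n_accessible": 520},
        {"label": "ΔeddΔpykΔSaro_RS09250ΔSaro_RS13605", "int": 4, "Y_xs": 71.5,
         "Y_px": 0.004, "minYps_maxx": 0.43, "maxYps_maxx": 0.54, "minYps": 0.33,
         "pctO2": -8.2, "n_accessible": 525},
        {"label": "ΔzwfΔpykΔSaro_2679ΔSaro_0559", "int": 4, "Y_xs": 70.0,
         "Y_px": 0.003, "minYps_maxx": 0.40, "maxYps_maxx": 0.50, "minYps": 0.31,
         "pctO2": -7.9, "n_accessible": 530},
    ]
    return rows
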