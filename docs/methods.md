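# Methods

## Problem and model

`straincut` searches a constraint-based metabolic model for gene-knockout
strategies that *force* production of a target compound whenever the cell
grows — the design goal behind growth-coupled bioproduction, here motivated
by lignin valorization in aromatic-degrading bacteria such as
*Novosphingobium aromaticivorans* (iNovo479).

A model is the usual steady-state LP object: stoichiometric matrix **S**
over internal metabolites, flux vector **v** with bounds *lb ≤ v ≤ ub*, and
the flux cone C = {v : S·v = 0, lb ≤ v ≤ ub}. Each reaction carries a
gene-protein-reaction (GPR) boolean rule; deleting a gene set D blocks
exactly the reactions whose rule evaluates false with the genes of D off.
Three structural conventions matter throughout:

* **Forced maintenance (NGAM).** A non-growth ATP-maintenance reaction with
  lb > 0 excludes the zero vector from C. This is what turns "the mutant
  cannot grow without producing" into the stronger "every feasible state of
  the mutant produces" (strong coupling): the minimum of the product flux
  over the whole mutant cone is strictly positive.
* **Uptake-ratio row.** A fixed molar ratio |v_a| = r·|v_b| between two
  substrate exchanges (default r = 3/2 for the aromatic:glucose pair) is
  appended to S as one equality row q_b·v_a − q_a·v_b = 0 with
  q_a/q_b = r. The equality (rather than a ≥ bound) is the default because
  it is the regime at which the highest production rate is obtained and it
  makes the 0.600 yield arithmetic of the vanillate case exact; a `min`
  mode relaxing it to a lower bound on the aromatic share is available on
  `apply_medium`. Appending the row can only shrink the feasible set
  (property-tested).
* **Sign convention.** Exchange uptake is negative, secretion positive
  (COBRA convention); all yields are defined on absolute uptake magnitudes.

## Cut definition and enumeration

Given a coupling spec (biomass id, product exchange id, substrate ids,
eps_growth, delta_product, budget k), a gene set D is a **cut** when in the
mutant:

1. maximizing growth subject to v_product ≤ delta_product is infeasible or
   stays below eps_growth (no "growth without production" state), and
2. unconstrained maximum growth still reaches eps_growth (the desired
   region survives).

A genetic minimal cut set (gMCS) is a cut none of whose proper subsets is a
cut. Defaults: eps_growth = 10⁻³ × wild-type max growth, delta_product =
10⁻⁶, k = 4. The thresholds are LP-pragmatic choices; the fixture specs use
eps_growth = 0.01, delta_product = 10⁻⁴ on the same reasoning.

Two engines share one memoized LP evaluator (the matrix is built once;
knockouts only pin bounds):

* `enumerate_gmcs_bruteforce` — every subset of size ≤ k, then a subset-
  inclusion minimality filter with LP re-checks. Guarded by a subset-count
  budget; it is the oracle.
* `enumerate_gmcs_pruned` — canonical lexicographic level-wise extension
  with pruning: sets containing a known cut are skipped (minimality); sets
  whose mutant cannot reach eps_growth are dropped along with their whole
  branch (knockout monotonicity: more deletions can only shrink the cone);
  genes occurring in no GPR are never tried. The two engines return
  identical sets on every instance where both run — this is enforced by a
  100-network seeded sweep in the test suite.

The search runs over genes, not over single-deletion equivalence classes:
single-deletion equivalence does not imply interchangeability at higher
order (isozyme rules are a counterexample), and exactness against the
oracle was given priority over the constant-factor saving. Equivalence
classes are still computed (`gene_equivalence_classes`) for reporting, with
"non-cuttable" meaning "occurs in no GPR" — genes whose single deletion
blocks nothing but that sit inside OR-rules stay searchable, which is what
makes isozyme pairs reachable. A MILP dual reformulation of the search is a
possible extension; at genome scale the full k ≤ 4 sweep is cluster-scale
work and out of scope here.

## LP layer

All solves go through scipy's HiGHS via one `solve(c, A_eq, bounds, …)`
contract; no commercial solver is involved. Tolerances: feas_tol 10⁻⁹,
opt_tol 10⁻⁶, supp_tol 10⁻⁶ (support stability requires supp_tol above
solver noise). Every single-flux report (the %O2 column, FSEOF
trajectories) uses the parsimonious optimum — a second LP minimizing Σ|v|
(split variables) with the objective fixed to its optimum within opt_tol —
because a raw FBA witness is not unique and would make report columns
irreproducible. The opt_tol slack means reported fluxes can sit ~10⁻⁶
below their ideal values; tests compare at 10⁻⁴–10⁻⁵ accordingly. How the
original screens resolved alternate optima for their oxygen columns is not
stated anywhere; the parsimonious convention is this package's documented
choice.

## Characterization and ranking

Six criteria per strategy, computed at the parsimonious optimum of the
mutant (U = Σ|substrate uptake|):

| criterion | definition | better |
|---|---|---|
| int | number of deleted genes | lower |
| Y_x/s | max growth / U | higher |
| min Y_p/s \| max x | FVA minimum of product at γ = 1, / U | higher |
| min Y_p/s | min product with U pinned at the medium maximum, growth free, / U | higher |
| %O2 | 100·(\|O2_mut\| − \|O2_wt\|)/\|O2_wt\|, parsimonious optima | lower |
| n_accessible | internal metabolites incident to a reaction with nonzero whole-cone FVA range | lower |

min Y_p/s pins total substrate uptake rather than minimizing the ratio
pointwise because the pointwise yield minimum over a cone is not an LP;
the convention is stated in report headers. n_accessible is an
FVA-incidence stand-in for a supplement-only metric. Y_p/x is reported as
min-product-at-max-growth / growth; with the default biomass unit (1 gDW
per unit flux·h) the identity round(Y_p/x)·round(Y_x/s) ≈ round(min Y_p/s
| max x) holds to 0.02 after 3-decimal rounding, and is asserted on every
characterization. %O2 is undefined (reported blank) when the wild type
takes up no oxygen.

Scores are Σ w_c · norm_c with min–max normalization over the candidate set
and equal default weights; the published scoring constants are not
recoverable from the main text, so only rank-level agreement is asserted:
on the printed PDC table (five of six criteria printed; n_accessible weight
0) the mid-pathway cuts ΔligJ/ΔligK outrank ΔligI, and on the propionate
candidate set ΔpckA ranks first. Ties break lexicographically by strain
label. Rows with a non-finite weighted criterion are flagged and excluded
from normalization.

## Amplification targets

`fseof_scan` enforces the product exchange at fractions f of its maximum
(default 9 levels, 10–90 %, endpoints avoided for degeneracy), re-maximizes
growth, and records parsimonious |flux| trajectories. Verdicts use
supp_tol slack: all steps within ±tol → flat; monotone with at least one
real step → increasing/decreasing; otherwise non-monotone. Genes of
increasing non-exchange reactions are the amplification leads. This
FSEOF-shaped scan is a stand-in for an unavailable supplementary algorithm
and is labelled as such; it reproduces the one checkable qualitative
claim — enforcement highlights the dedicated precursor-synthesis step
(the `build_precursor_demo` fixture, modelled on the
sn-glycerol-3-phosphate case).

## Synthetic fixtures

`build_mini_lignin` is a fixed 16-reaction, 9-gene miniature of the
vanillate→PCA→CHMS→PDC→OMA→…→TCA route with formate oxidation, a glucose
lump, NGAM (lb 1) and the 3:2 ratio row. Its 13 internal metabolites and
integer/rational stoichiometry make every published-style quantity exact
by hand LP: WT growth 157/15, ΔgLigI growth 67/15 with product pinned at
10, min yield at max growth 0.600, O2 uptake 25 → 5 (−80 %), strong-
coupling minimum 3/7, and exactly four singleton gMCS
({gLigI},{gLigJ},{gLigK},{gTCA}) exhibiting branch-point, dead-end and
sink-removal cuts. Entry-pathway deletions (gLigM, gLigAB, gLigC, gFdh,
gGlyc) are lethal because the ratio row ties both uptakes together — which
is also why the generator's planted networks never contain them in cuts.

`random_coupled_network(seed, …)` plants the answer: a catabolic segment
of `depth` steps past the product with `n_bypass` shortcut routes; its
reaction-level minimal cut sets come from path enumeration on the route
graph and are lifted to gene sets through randomly sprinkled isozyme
("or", forces pairs) and complex ("and", forks variants) rules within the
`n_genes` budget. Defaults (depth 4, one bypass, rates 0.15, ratio drawn
from {1, 3/2, 2}, substrate lb −10, NGAM lb 1) mirror the fixture
conventions. Every planted set is verified as a minimal cut by the LP
check at generation time; an ungrowable draw regenerates from a derived
seed with a log line. All randomness flows from `numpy`'s seeded
Generator, so equal seeds give byte-identical models.

What the fixtures do **not** emulate: genome-scale redundancy (hundreds of
alternative pathways), cofactor/proton bookkeeping, realistic biomass
composition, thermodynamic constraints, and GPRs deeper than two levels.
Passing tests therefore demonstrate correctness of the algorithms under
the stated structural assumptions, not predictive accuracy on a real
organism; full-scale runs require the published SBML model via the CLI.

## Problem sizes and determinism

The bundled analyses run at desk scale: the oracle-equivalence suite uses
100 seeded networks of 9–12 genes with k ≤ 3 (≈1 minute), and
`scripts/acceptance.py` re-runs a 40-network sweep plus the fixture
analytics (≈20 s). Output ordering is by cardinality then lexicographic
gene ids; re-running an archived CLI config reproduces every TSV given the
same solver backend and tolerances.

## Known limitations

* Enumeration is exponential in k; genome-scale k = 4 sweeps need the MILP
  route or a cluster.
* The equality ratio row also couples secretion of the two substrates, not
  only uptake; with uptake-only exchange bounds (as in all bundled media)
  this has no effect.
* SBML support is read-only (Level 3 + FBC v2); models are written in the
  JSON dialect only.
* `n_accessible` and the FSEOF scan are documented stand-ins for
  supplement-only definitions and should not be over-interpreted.
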