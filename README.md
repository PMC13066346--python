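# straincut

Growth-coupled strain design on constraint-based metabolic models via
**genetic minimal cut sets (gMCS)**.

Lignin-derived aromatics (vanillate and friends) can be funneled by
bacteria such as *Novosphingobium aromaticivorans* into valuable compounds
— 2-pyrone-4,6-dicarboxylate (PDC), glutarate, glycerol, propionate… — but
a wild-type cell burns everything for growth. `straincut` finds the gene
deletions that make production unavoidable: given a genome-scale model
with gene-protein-reaction (GPR) rules, it enumerates all minimal gene
sets (up to k knockouts) whose deletion leaves no feasible state that
grows without producing, characterizes each mutant by six screening
criteria, ranks the strategies, and proposes overexpression targets by
flux scanning under enforced production. It is aimed at metabolic
engineers doing in-silico strain design before committing to wet-lab work.

## The model in brief

A metabolic network at steady state is the flux cone
C = {v : S·v = 0, lb ≤ v ≤ ub}. With a forced non-growth maintenance flux
(NGAM, lb > 0) the zero vector is infeasible, so a gene set D is a valid
strategy when, in the mutant it induces,

* max growth s.t. v_product ≤ δ is infeasible or < ε (no growth without
  production), and
* max growth ≥ ε (the strain still lives),

which under the NGAM implies **strong coupling**: min v_product over the
whole mutant cone is strictly positive. A gMCS is such a set none of whose
proper subsets qualifies. Substrate co-feeding is modelled by an uptake
ratio row |v_aromatic| = 3/2·|v_glucose| appended to S. Strategies are
scored by min–max-normalized criteria: knockout count, biomass yield
Y_x/s, minimum product yield at maximum growth min Y_p/s|max x, minimum
product yield min Y_p/s, oxygen change %O2, and accessible-metabolite
count. See `docs/methods.md` for the precise definitions and conventions.

## Worked example

The bundled 16-reaction mini-lignin fixture (vanillate → PCA → PDC → TCA
with a 3:2 vanillate:glucose ratio and a forced maintenance flux) has
exact hand-computable answers:

```python
import straincut as sc

model, medium, spec = sc.build_mini_lignin()
print(sc.fba_max(model, "BIOMASS").objective_value)   # 10.466666666666665

for s in sc.enumerate_gmcs_pruned(model, spec):
    print(sorted(s.genes), round(s.mutant_max_growth, 5),
          round(s.strong_min_product, 4))
# ['gLigI'] 4.46667 0.4286
# ['gLigJ'] 4.46667 0.4286
# ['gLigK'] 4.46667 0.4286
# ['gTCA'] 4.46667 0.4286

ch = sc.characterize_strain(model, spec, {"gLigI"})
print(round(ch.minYps_maxx, 3), round(ch.pctO2, 1))   # 0.6 -80.0
```

Reading: four single-gene deletions couple growth to PDC export — the
branch-point hydrolase knockout (gLigI), two mid-pathway dead-end cuts
(gLigJ, gLigK) and the TCA-sink removal (gTCA). Each mutant still grows at
4.467 (vs 10.467 wild type), is forced to secrete at least 0.429 product
even at zero growth, converts all vanillate to product at maximum growth
(yield 0.600, fixed by the 3:2 ratio) and takes up 80 % less oxygen.

The same run from the shell:

```bash
straincut fixtures --out fx
straincut design --model fx/mini_lignin.json --product EX_pdc \
    --substrates EX_van,EX_glc --oxygen EX_o2 --max-interventions 2 \
    --eps-growth 0.01 --delta-product 1e-4 --out run
cat run/characterization.tsv
```

`straincut characterize --genes ligI ...` reproduces published-style yield
tables for explicit knockout lists without re-running the search (useful
with a full SBML model such as iNovo479), and `straincut fseof` emits
amplification-target genes whose flux rises monotonically as production is
enforced.

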