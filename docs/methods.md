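# Methods

## Model and assumptions

The package works with constraint-based metabolic models: a set of
metabolites over two compartments — cytosol (`c`) and extracellular space
(`e`) — and reactions with signed stoichiometry and flux bounds. The core
assumption is quasi-steady state: internal metabolite pools neither
accumulate nor deplete, so every flux vector satisfies S·v = 0 with S the
metabolites × reactions stoichiometric matrix. Optimal behaviour is
modelled as linear programming over this polytope. The biomass reaction is
a pseudo-reaction consuming measured precursors in mmol per gram dry
weight and producing one unit of a biomass pseudo-metabolite drained by a
demand; its flux is read in gDW·h⁻¹ while all other fluxes are
mmol·gDW⁻¹·h⁻¹.

Reaction kinds follow compartment membership: all-cytosolic reactions are
metabolic, a single-species boundary reaction on an `e` metabolite is an
exchange, and anything spanning both compartments is a transport. Demand
and biomass flags are preserved through classification. Exchange flux is
negative on uptake; transfer pairs (transport + exchange) are written in
the outward direction so that a lower bound of zero uniformly means
"export only", which is how non-importable (synthesizable) nutrients are
encoded. Gene associations are flat gene lists per reaction; a reaction is
disabled only when all of its genes are deleted, so a single-gene deletion
screen silences exactly the single-gene reactions. Boolean AND/OR gene
rules are out of scope.

## Reconstruction pipeline

1. **Draft assembly.** Exact string matching on KEGG Orthology ids
   ("KO bridge"): a pool reaction enters the draft iff its KO set
   intersects the annotation table's KO set; its gene list is the set of
   unigenes mapping to any shared KO. Everything starts in the cytosol;
   compartments appear only when transfer reactions are added, late in
   refinement.
2. **Balance checking.** Net element and charge deltas from metabolite
   formulas. Species whose formula cannot be read as a plain element
   multiset — the `UNKNOWN` token, or polymers with indeterminate repeat
   counts such as `(C6H10O5)n` — make the verdict `unknown` rather than
   balanced: such reactions are exactly the ones that can couple into
   mass-creating cycles, so they are flagged, never certified. Repairing
   unbalanced stoichiometries is reported, not automated.
3. **Pruning.** Pool entries flagged general/incomplete are dropped; a
   reaction whose net stoichiometry equals the sum of two retained
   elementary steps is removed as a lumped duplicate (detection is
   deliberately limited to pairs — general subset-sum matching is
   combinatorial and two-step lumps are the practical case); exact
   stoichiometry duplicates keep the lexicographically smallest id.
   Chirality variants are merged through a user-supplied alias→canonical
   id map, followed by duplicate pruning.
4. **Gap filling.** Producibility of a metabolite is flux-based: add a
   temporary demand, maximise it under the medium bounds, call the
   metabolite producible when the optimum exceeds ε = 1e−6. The drain is
   always a fresh demand so the measurement never competes with an
   exchange that is simultaneously the supply route. Gap filling greedily
   searches candidate sets of size 1 then 2 (lexicographic tie-break) per
   target; at pathway scale candidates must share a pathway with a
   reaction already in the model. Since reactions are only ever added, the
   LP feasible set only grows, so previously producible metabolites stay
   producible and the weakly-connected-component count of the bipartite
   metabolite–reaction graph never increases. Breakpoint search walks
   breadth-first backwards over producing reactions from a blocked target,
   reporting non-producible upstream metabolites as `orphan` (no producer
   at all) or `blocked`.

## Flux balance analysis

LPs are solved with HiGHS via `scipy.optimize.linprog`, requesting
primal/dual feasibility of 1e−9; optimal solutions are asserted to satisfy
‖S·v‖∞ ≤ 1e−6. Solver status is propagated verbatim — infeasible or
unbounded problems never return silent zeros. Because FBA optima are
generally degenerate, any analysis that compares flux *distributions*
(rather than the optimum) uses a parsimonious solution: the objective flux
is pinned and Σ|v| minimised, splitting only genuinely sign-free variables
into positive/negative parts. This makes flux comparison between two
growth states well defined; the comparison lists reactions whose
parsimonious flux changes by more than a threshold (default 1e−6), sorted
by |Δ| descending.

Bound policy defaults (mmol·gDW⁻¹·h⁻¹): reversible (−1000, 1000),
irreversible (0, 1000), synthesizable-nutrient exchanges (0, 1000), feed
nutrients (−5, 1000), trace elements (−1, 1000), semi-essential amino
acids (−3, 1000); per-reaction overrides win over class bounds. These are
the conventions of the crab reconstruction this package grew from and can
be replaced wholesale.

## Biomass equation

Contents measured in g per 100 g fresh weight convert to coefficients by
`(content/100)/(1 − w)/M × 1000` — milligrams per gram dry weight divided
by milligrams per millimole. Defaults: water fraction w = 0.516 (the
measured hepatopancreas value), growth-associated maintenance 30 mmol ATP
per gDW entering with hydrolysis stoichiometry (ATP + H₂O → ADP + Pi);
the maintenance value is a conventional placeholder in the range used for
animal GEMs and is fully configurable, NADPH turnover is available but off
by default. Molar masses ship in a constants table of average atomic
weights for the measured forms: free amino acids, free fatty acids,
carrier salts where the literature quotes the salt (calcium carbonate
100.09, magnesium L-aspartate 288.50) and elemental masses where it quotes
the element (Zn 65.38, Se 78.97, Cu 63.55). EPA is recorded both as free
acid (302.45) and ethyl ester (330.50) because published feed values are
quoted in either form; the free acid is the default.

## Nutrition and growth

With the biomass flux pinned at 1 gDW·h⁻¹, each exchange flux is the
optimal absorption per gram dry weight deposited; uptake is reported
positive, net export negative with an accumulation flag (raw FBA is the
default to mirror standard practice; a pFBA flag exists for when a unique
flux pattern is required). Literature feed demands convert to
mmol·gDW⁻¹·h⁻¹ at one gram of feed per day: percent of feed → value×10
mg/g, g/kg → value mg/g, mg/kg → value/1000 mg/g, each divided by the
carrier molar mass. The deposition rate is simulated uptake divided by the
converted literature demand; it is undefined (reported as a dash) when the
literature value is missing or the simulated flux is an accumulation.
Isomer routes are always reported per metabolite id, never summed.

The specific growth rate converts a simulated biomass synthesis rate x
(gDW·d⁻¹) into %·d⁻¹ for an animal of initial fresh mass m₁ fed the
fraction f of body mass daily: SGR = [ln(m₁ + f·m₁·x/(1−w)) − ln(m₁)]×100,
evaluated at the ration bracket (defaults f = 0.03 and 0.05, m₁ = 8.41 g).
SGR is strictly increasing and concave in x and the lower bound never
exceeds the upper. Growth under a literature feed caps each named
exchange's uptake at the converted demand and maximises biomass, also
reporting offered vs absorbed amounts — the unabsorbed surplus is the
fraction of the feed excreted to the water.

## Synthetic data

The generator emulates the statistical structure of a real reconstruction
at toy scale: a feed-bounded substrate uptake driving a linear core,
essential nutrients with import-only routes, synthesizable nutrients with
internal sources and closed uptake, a biomass reaction over all
precursors, optional disconnected islands (extra weakly connected
components), an optional polymer-leak pair (two indeterminate-formula
species whose interconversion cycle nets free substrate — the classic
starch/amylose imbalance pattern), and optional ATP maintenance competing
for substrate. All randomness flows from a single seeded
`numpy.random.Generator`; no global state. Defaults: 3 core metabolites,
2 essential + 2 synthesizable nutrients, uptake bound 5 mmol·gDW⁻¹·h⁻¹
(the feed-class bound), biomass coefficients uniform on (0.05, 0.5)
rounded to 4 decimals — chosen so the optimum comfortably exceeds the
1 gDW·h⁻¹ rate used in requirement simulations.

Because each supply route is planted, the biomass optimum has the closed
form min(min_i u_i/c_i, U/(Σ_j c_j + m)), and per-nutrient requirements at
unit rate equal the biomass coefficients; tests compare the LP against
these values exactly. Gap planting removes biomass-essential reactions
(core steps, precursor syntheses, essential transports) into a companion
pool together with decoy entries that cannot restore anything; re-added
reactions return with generic pool bounds, which leaves the optimum
unchanged because exchange bounds still cap uptake.

What the toys do **not** emulate: cofactor coupling across pathways,
realistic KEGG-scale pools (pools are capped at the hundreds), boolean
gene rules, charge imbalances, and the thermodynamic infeasibilities of
real networks. Passing tests therefore demonstrate algorithmic
correctness on networks with known answers, not predictive accuracy on
real organisms.

## Sanity checks

Ten checks in fixed order, after the COBRA community's model-quality
tutorial: (1) closed-model leaks through exchanges; (2) leaks through
per-metabolite demands; (3) energy from water; (4) matter from a reversed
ATP demand; (5) flux through the cytosolic proton demand; (6) ATP yield
from glucose above a plausibility cap (default 40 mol/mol, configurable —
the theoretical aerobic maximum is ~32, so anything near 40 signals an
energy-generating cycle); (7) duplicated reactions; (8) empty
stoichiometry columns; (9) demand reactions with negative lower bounds;
(10) whether a single-gene-deletion screen runs to completion. Checks
whose prerequisites are missing (no ATP demand, no water exchange) are
reported as skipped, never silently passed. A fully elementally balanced
network whose only boundary reactions are exchanges cannot fail the leak
or energy checks — mass conservation over the flux cone — and this is
asserted as a property test on random balanced instances.

## Numerical choices and degenerate inputs

ε for producibility and leaks: 1e−6 mmol·gDW⁻¹·h⁻¹. LP feasibility
tolerances 1e−9, steady-state residual assertion 1e−6. Duplicate
detection rounds coefficients to 9 decimals. Empty models, empty drafts
(no KO intersection) and zero-content composition rows are all valid
degenerate inputs and round-trip through every dialect; unbounded
producibility LPs report infinite flux rather than erroring. Ties in gap
filling and pruning break lexicographically by reaction id, so all
reports are deterministic.

## Known limitations

- Gap filling is greedy per target with set size capped at 2 by default;
  it finds minimal sets for planted gaps but is not a MILP-optimal global
  gap filler, and offers no thermodynamic feasibility screening.
- Balance *repair* is manual: the toolkit detects and reports imbalances
  and can apply user patches, but never rebalances by optimisation.
- The SBML dialect is best-effort (level 3 + fbc, annotations carried in
  notes); the canonical dialects are the two-file TSV and JSON mirrors.
- Deposition rates inherit the degeneracy of raw FBA optima; when
  alternate optima matter, use the parsimonious flag and say so.
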