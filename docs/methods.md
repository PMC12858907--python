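# Methods

## Scope and model

`gemcom` implements steady-state constraint-based modeling of microbial
communities. Each strain is a stoichiometric network S^k with flux
bounds and one biomass pseudo-reaction; a community stacks K namespaced
strain blocks and couples them only through a shared extracellular
pool. For every shared metabolite m the pool balance

    Σ_k v[ex]^k_m + IP_m − EP_m = 0

introduces two non-negative community variables: import IP_m from the
medium (bounded by the available amount) and export EP_m out of the
system (unbounded; internally capped at 1e6 for the solver, far above
any attainable flux). Strain-level exchange bounds are kept as
declared, so a strain's intrinsic uptake capacity (e.g. a low-affinity
transporter) still binds inside a rich community.

All programs are linear and solved with HiGHS through
`scipy.optimize.linprog` — deterministic and single-threaded, so
identical inputs give bit-identical outputs.

### Sign and medium conventions

Exchange flux > 0 is secretion, < 0 uptake. A medium lists amounts in
mmol/gDW; for single-strain FBA an amount a sets the exchange lower
bound to max(LB, −a) — the tighter of what the strain can take up and
what the environment offers. Both readings are needed: a rich medium
must not loosen a strain's own transporter capacity, and a lean medium
must cap an eager importer. Metabolites absent from a medium receive
1000 mmol/gDW when their formula contains neither C nor N (inorganic
salts), otherwise 0; metabolites without a formula count as organic so
unknown compounds are never silently fed. Media may name bare compound
ids ("glc"); they match extracellular metabolites with or without the
`_e` compartment tag.

Amounts are finite stocks interpreted as flux bounds over a unit
horizon for single-shot solves; the temporal reading belongs to the
depletion simulation below.

### Community objectives

Four scenarios cover the common design questions:

* **no_limitation** — max Σ_k c^k v_biomass^k (default weights 1);
  any member may carry zero biomass. Superset monotonicity holds by
  construction: adding strains can never lower this optimum.
* **equal_abundance** — hard coupling v_biomass^k = μ for all k,
  maximize μ (the common per-strain biomass). This is a deliberate
  encoding choice: equalizing biomass is a constraint, not a weight
  vector, because the unconstrained weighted sum is already scenario 2.
* **target_strain** — maximize one member's biomass ("exclusive
  allocation of metabolic resources"); other members' biomass is
  unconstrained and reported as found.
* **defined_abundances** — v_biomass^k = a^k μ with Σ a^k = 1,
  maximize μ (the community total at fixed composition).

A coupled scenario whose coupling admits no positive μ returns the
all-zero solution with μ = 0 and status optimal — "this composition
cannot grow" is a result, not an error, so screens always complete.

### Parsimonious FBA

Two-stage lexicographic solve: stage 1 fixes the scenario optimum z*;
stage 2 re-solves with the constraint c·x ≥ z* − (1e-9 + 1e-9|z*|) and
minimizes total community import Σ_m IP_m. Minimizing *import* (rather
than the classical total |flux|) is the primary mode because nutrient
uptake is the community-level resource being economized; the classical
sum-of-absolute-fluxes mode is available as `mode="total_flux"` for
comparison. Cross-feeding is always computed on the pFBA point
estimate so degenerate alternate optima do not conjure arbitrary
exchange edges; edges below the 1e-6 flux threshold are discarded.

### Finite-pool depletion

`simulate_depletion` reconstructs growth time over a finite nutrient
stock: at each step of length dt every import rate is capped at
min(remaining/dt, vmax), the community is solved with pFBA, pools are
decremented by net consumption and credited with net secretion
(between steps, so donated metabolites accumulate for partners), and
biomass increments are accumulated. The run stops when a step's total
increment falls below 1e-6 — classified as `pool_exhausted` when no
organic pool remains, `no_growth` otherwise — or at `max_steps`.
Growth time is productive steps × dt. Defaults dt = 1 h, vmax =
10 mmol gDW⁻¹ h⁻¹, max_steps = 200: coarse enough to keep screens
fast, fine enough that halving dt changes cumulative biomass by at
most one step's worth on the test fixtures. This scheme is a
deliberately simple reconstruction — no biomass-weighted uptake
scaling (X(t)·v kinetics), no spatial structure — so absolute growth
times are comparative quantities, not predictions.

## Media series and screening

`build_media_series` splits a fixed carbon budget (default
100 mmol/gDW) evenly over the first C carbon sources for C = 1, 2, 4,
… up to the list length, adds ammonium at 100 mmol/gDW, and leaves
C/N-free inorganics to the 1000 mmol/gDW default — the single- versus
multi-carbon regime used to mimic single- and co-contamination. The
screen enumerates all subsets of sizes [min, max] in deterministic
(size, lexicographic) order; a six-strain pool gives 57 combinations
of two or more strains. Sensitivity analysis perturbs each single
carbon source by ±20% and reallocates budget pairwise (totals
preserved), reporting |Δbiomass|/biomass with a flagged, undivided
"undefined baseline" when the reference biomass is ≤ 1e-6.

`carbon_equivalence` converts (formula, mg/L) compound lists to total
mol C using IUPAC 2021 atomic weights and reports the glucose mass
delivering the same molar carbon; the culture volume must be supplied
by the caller.

## Cross-feeding networks

For each shared metabolite with a secreting and a consuming strain,
donor→recipient edges carry an allocated flux
d_i·u_j/(Σ donors + import): unique, order-independent, and
conservation-respecting (allocations plus the unattributed import-fed
share reproduce every recipient's uptake). Pool imports are never
attributed to a donor. Metabolite classes (amino acid, organic acid,
carbohydrate, vitamin, nucleotide, other) come from a user-overridable
TSV; a built-in table covers commonly exchanged compounds. Exchange
counts are tallied per (donor, recipient, class) — a metabolite type
is counted once per partner pair, the stricter of the two possible
conventions, and the one documented here. A strain that donates in
every examined condition and receives in none carries the potentiator
signature.

## Synthetic consortia

The generator emits minimal strain models (≤ 12 reactions) built
around one internal precursor: per carbon source an exchange,
transport, and catabolic route; optionally a cofactor-boosted route, an
auxotrophy, and biomass-coupled secretions. Stoichiometries are
abstract rather than mass-balanced so every optimum stays
hand-computable; formulas are attached only where elemental-balance
tests need them. The designed consortium encodes the
Degrader/Helper/Potentiator ecology:

* d1 grows alone on glucose (yield 1.0) and secretes 0.5 acetate per
  biomass; a vitamin-boosted route lifts its yield to 1.5 at 0.05
  vitamin per glucose;
* h1 is auxotrophic in effect — its only substrate is d1's acetate
  (yield 0.5, boosted 0.75);
* p1 runs on a citrate trickle (uptake cap 1), secreting 2 vitamin per
  biomass and consuming nothing the others make;
* the six-strain pool adds a citrate/fumarate degrader d2, a doubly
  dependent helper h2 (acetate plus an absolute vitamin requirement),
  and a bystander y1 whose glucose yield (0.5) is strictly dominated
  by d1's, so optimal communities never feed it.

The potentiator's carbon source is citrate deliberately: on the
single-carbon (glucose) medium, removing the degrader zeroes the whole
community, while from C = 2 on, p1 cross-feeds without ever receiving.
PCI is therefore evaluated on the C = 2 medium. Yields and caps are
fixed by design (the generator is deterministic; the seed is recorded
provenance), keeping analytic optima exact: the bystander-substituted
PCI is exactly 0, not merely small.

What the toys do not emulate: genome-scale network redundancy,
maintenance ATP demands, thermodynamic/loopless constraints,
elementally balanced biomass equations, and realistic uptake kinetics.
Passing tests demonstrate the correctness of the solver, the coupling
encodings, and the network extraction — not predictive accuracy for
any real consortium.

## Verification strategy

Two independent routes check every optimization path. A brute-force
vertex-enumeration reference solver (`gemcom.oracle`) enumerates all
basic solutions of the same LP arrays — exponential, pure numpy, and
entirely separate from the HiGHS path — and must agree within 1e-6 on
dozens of seeded random models and communities; fixture optima frozen
in `tests/data/oracle_baseline.tsv` were produced by this reference
solver. Independently, one test solves the same strain model
end-to-end through COBRApy/GLPK and compares objectives. Every
returned solution is additionally verified against its own constraints
(steady-state residual and pool balance ≤ 1e-6, bounds respected)
before it is handed back.

Numerical defaults: LP feasibility 1e-9 (HiGHS), flux-zero threshold
1e-6 everywhere a flux is compared to zero, pFBA stage-1 preservation
1e-9 relative. Problem sizes in the test suite and acceptance script —
100 random communities for conservation, 50 oracle comparisons, the
full 57-combination screen over three media — keep the whole suite in
the seconds range while exercising every code path at sizes where the
exhaustive oracle is exact.

## Known limitations

* No dynamic biomass-weighted FBA; depletion growth times are
  comparative, not calibrated to wall-clock culture time.
* Alternate-optimum degeneracy is resolved by the pFBA point estimate;
  an edge present in one optimum but not another is reported as the
  parsimonious solution has it. A flux-variability pass to tag fragile
  edges is a natural extension.
* SBML support targets Level 3 + FBC as written by COBRApy; exotic
  annotation schemes fall back to name-based biomass detection, which
  errors on ambiguity rather than guessing.
* The equal-abundance scenario is a hard coupling; communities where
  one member cannot grow return μ = 0 rather than a partial
  composition. Use defined_abundances to explore unequal compositions.
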