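# Methods

## The model

`germsoma` simulates the evolution of cell differentiation in a filament of
two metabolically complementary microbial cell types, inspired by
heterocystous cyanobacteria.  A constant-size population of `n_cells` cells
sits on a ring (or, after deaths in the broken topology, on a set of linear
chain fragments).  Each cell is **photosynthetic** (produces carbohydrate)
or **nitrogen-fixing** (converts received carbohydrate into fixed
nitrogen), and carries four heritable traits in [0, 1]:

| trait | meaning |
|---|---|
| `p_keep` | fraction of its carbohydrate a photosynthetic cell keeps |
| `p_diff` | probability a photosynthetic cell's newborn daughter differentiates |
| `n_keep` | fraction of received carbohydrate a nitrogen fixer keeps for growth |
| `n_diff` | probability a nitrogen fixer's newborn daughter differentiates |

Only two traits are expressed in any one cell; the other two ride along
neutrally and become visible when a descendant differentiates.

### Resource exchange

Each iteration has a production/exchange phase and a selection phase.  In
the exchange phase every photosynthetic cell j produces `w_produce = 1`
unit of carbohydrate, keeps `p_keep_j`, and splits the remainder equally
(uniform kernel) or in proportion to a gaussian weight
exp(−d²/2s²) (gaussian kernel, cut off at 3 s) over the nitrogen-fixing
cells within its interaction range.  The range spans K/2 chain neighbours
on each side, truncated at chain breaks.  A nitrogen fixer i thus receives
carbohydrate

  g_i = Σ_j (1 − p_keep_j) w_ij / W_j,

where W_j sums the donor's weights over its nitrogen-fixing neighbours.
It keeps `n_keep_i · g_i` for its own use and converts the rest into fixed
nitrogen at γ units of nitrogen per unit carbohydrate, splitting that
export over its photosynthetic neighbours the same way, which defines h_i.
A donor with no opposite-type neighbour in range loses its export: the
equations define transfers to existing partners only, and letting the
donor silently retain the share would change the meaning of the keep
traits.  With this convention both resources are conserved exactly
(kept + delivered + lost = produced), which `check_conservation` verifies
to 1e−12.

### Fitness

Cells need carbohydrate and fixed nitrogen in equal parts, so growth is
limited by the scarcer resource.  A photosynthetic cell's division
propensity is

  W_p = ε + σ · min(p_keep, h),

with σ the relative division rate of photosynthetic cells and ε a small
base fitness that exists only to keep selection weights positive.  A
nitrogen fixer splits its kept carbohydrate between growth carbon and
fueling nitrogen fixation for itself; the split s that maximises
min((n_keep − s) g, γ s g) is s* = n_keep/(1 + γ), giving

  W_n = ε + γ n_keep g / (1 + γ).

A freshly differentiated cell carries a pending differentiation cost:
fractional mode multiplies its fitness by (1 − c) until the first time it
is *chosen* to divide (not merely survives); constant mode subtracts a
fixed amount, floored at 0.1 ε so weights stay positive.

The **symmetric variant** removes the built-in asymmetry (nitrogen
fixation requiring imported carbohydrate): each type produces one unit of
its own resource unconditionally, keeps its keep-fraction, exports the
rest, and W_n mirrors W_p as ε + min(n_keep, g).  Note that the σ ↔ 1/σ
label-swap symmetry of this variant is exact only up to the additive ε
term, so the mirror is asserted exactly at σ = 1 and statistically (via
mirrored strategy calls) elsewhere.

### Birth-death loop

Each iteration: (1) recompute exchange and fitness for the whole filament;
(2) pick one reproducer with probability W_i/ΣW and clear its pending
cost; (3) insert a daughter carrying the parent's traits between the
parent and a uniformly chosen adjacent side; (4) the daughter
differentiates (phenotype flip, pending cost set) with the probability
given by the parent's phenotype-appropriate diff trait; (5) each of the
daughter's four traits independently mutates with probability μ by a
uniform step in [−δ, +δ], clipped to [0, 1]; (6) one cell chosen uniformly
at random — possibly the daughter — dies.  In the connected topology its
neighbours rejoin; in the broken topology the chain stays severed there
(fragments never rejoin, so fragment count is non-decreasing except when
an isolated cell dies).  One **generation** is `n_cells` iterations.

The loop is implemented as a numba kernel over flat arrays consuming a
pre-drawn matrix of 12 uniforms per event, which makes runs
bit-reproducible for a given root seed and lets a pure-Python reference
implementation replay the identical random stream; the test suite checks
state-for-state agreement between the two over hundreds of events in every
variant.  Root seeds are split via `numpy` `SeedSequence` into independent
initialization and evolution streams, and replicate seeds derive from
(root seed, grid indices, replicate index) so sweep results are invariant
to execution order.

### Strategy classification

After a run, population trait means (averaged over the final 10% of
generations, to tame the stationary fluctuation around the evolved state)
are mapped to a developmental strategy with an effective-zero threshold of
0.05: terminal differentiation with photosynthetic germline (I: p_keep,
p_diff > 0, n_keep ≈ 0), the same with dividing soma (II), reversible
differentiation (III: all four positive), symbiosis (IV: both keeps
positive, both diff rates ≈ 0), and the two mirror classes with a
nitrogen-fixing germline (V, VI).  Trait combinations in which a needed
type can never be produced are nonviable and return "unclassified".  The
classifier is total and exclusive (audited on a 21⁴ grid) and commutes
with the type-swap symmetry (I↔VI, II↔V).

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `n_cells` | 400 | reference population size for the headline conditions |
| `sigma` | 3.0 | reference asymmetric division-rate condition |
| `eps_base` ε | 0.01 | small vs. typical resource-limited fitness (≈0.25–1.5) |
| `gamma` γ | 1.0 | one nitrogen per carbohydrate; consistent with the 1–2 sugars per ammonia energetics and the only value for which the evolved photosynthetic keep-fraction equilibrates at 1/2 (the balance point is γ/(1+γ)) |
| `cost_frac` c | 0.0 | costs are switched on per experiment (0.1 is the package's canonical "with costs" value) |
| `k_range` K | 2 | nearest-neighbour exchange |
| `mu_mut` μ | 0.01 | one expected trait mutation per generation per trait across the population; changes convergence speed, not outcomes |
| `delta_mut` δ | 0.1 | mutation step of 10% of the trait range |
| `w_produce` | 1.0 | unit carbohydrate production per photosynthetic cell |

ε, γ, μ, δ, the homogeneous initial traits (0.5, 0.5, 0.5, 0.5) and the
"with costs" value are package choices; all are exposed in the run
configuration.

## What the simulations emulate — and what they do not

The generator *is* the study system: there is no external data.  The model
abstracts away everything about real cyanobacteria except resource
complementarity, local exchange along a filament, division-rate asymmetry
and costly differentiation — no regulatory patterning (heterocyst spacing),
no explicit metabolite kinetics, no cell size or age structure, no
environment.  Passing tests therefore demonstrate properties of this
idealised evolutionary process, not quantitative predictions for any
organism.

## Numerical and design choices

- K counts the *total* number of interacting neighbours (K/2 per side);
  odd K is rejected.  Gaussian-kernel weights are not renormalised before
  the proportional split (the split itself normalises).
- Donor shares go to opposite-type neighbours only; same-type neighbours
  receive nothing.
- The daughter, never the parent, is the differentiation candidate; the
  death draw includes the daughter (nothing in the process description
  excludes it).
- Fragment count is defined as the number of maximal chains, so the first
  break of the ring leaves one (now linear) fragment.
- Fitness is recomputed from scratch every event; at the array sizes used
  here the numba kernel makes incremental bookkeeping unnecessary.
- Modal-strategy ties in phase diagrams are reported as ties, never broken
  silently.
- Strategy calls use a final-window mean (default last 10% of recorded
  generations); the evolved state fluctuates, and a single-generation
  reading is noisy near the 0.05 threshold.

## Problem sizes used in the shipped analyses

The acceptance analysis reproduces the reference endpoint (broken chain,
σ = 3, c = 0, N = 400, 5000 generations, several seeds) at full scale,
plus a shortened-run check at the same population size (3500
generations).  Sweep reproductions are run at reduced scale as the
package's own choice of desk-scale design: the broken-chain direction
check (I at σ = 5, III at σ = 1, VI at σ = 0.2) uses N = 300 with 3000
generations (5000 at σ = 5, where the somatic keep-fraction relaxes to
its floor more slowly).  Small populations are *not* a neutral scale knob
here: at N ≲ 200, drift keeps the somatic keep-fraction's stationary mean
above the 0.05 classification threshold at σ = 5, so runs that are
terminal differentiation for all practical purposes get read as
reversible; N = 300 is the smallest size at which the call is decisive.
Frequencies and bootstrap intervals in the shipped tests use a handful of
replicates rather than hundreds.

## Known limitations

- **The symbiosis corner is only marginally reproduced.**  In this
  implementation the symbiotic strategy (IV: both lineages divide, neither
  differentiates) appears only as a rare excursion (roughly 5% of
  replicates at the most favourable condition found: connected topology,
  σ = 1.05, c = 0.7, K a third of the filament) and is never the modal
  call, even when a population is initialised exactly at the symbiotic
  trait state: a daughter that differentiates into the faster-dividing
  type gains individual fitness, so whichever differentiation rate points
  toward the faster type equilibrates at a mutation–selection floor of
  ~0.1–0.3, above the 0.05 effective-zero threshold, and the population is
  read as II/V (dividing soma) or III instead.  The II/V neighbourhood of the symbiosis niche (connected
  topology, high differentiation cost, interaction range a large fraction
  of the filament) does evolve as expected.  The discrepancy is robust to
  halving the mutation step and to costs up to 0.9, so it most likely
  reflects a difference in fine model detail (exchange divisors or cost
  mechanics) rather than a parameter choice; the acceptance suite reports
  the measured symbiosis frequency rather than hiding the disagreement.

- The broken topology equilibrates at many short fragments (mean length
  ≈ 2–3 at K = 2), so its evolved strategies are dominated by the survival
  of near-minimal complementary units.
- Near strategy boundaries (σ ≈ 1–3, or small N) several strategies evolve
  with appreciable frequency; single runs are not representative there,
  which is why all headline quantities are modal calls or frequencies over
  replicates.
- The unexpressed ("asterisk") traits drift and can sit anywhere in [0, 1]
  at the end of a run; only expressed traits are meaningful in trajectory
  plots.
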