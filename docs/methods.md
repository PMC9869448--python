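# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the reasoning behind the surrogate values, what the
synthetic world generators emulate, and the problem sizes the test suite
and acceptance script run at.

## Entities and state

A **locus** is a tradition type; an **allele** is an agent's possessed
instance. Apex loci target an external function — a resource (`basic`,
`igut` carnivory) or the social-learning booster — while component loci
improve another locus; parent links form one rooted **institution tree**
per apex, whose **complexity** is its locus count. Topology carries no
fitness weight beyond the count, but it constrains resolution (a component
expression is claimable only under a claimed parent).

**Agents** carry an allele set, an energy reserve, a reproduction buffer, a
lifetime harvest score (rank) and, when genetics are enabled, a heritable
cognitive capacity. **Communities** are member sets holding an
edge-connected territory on the grid; they are the arena of expression,
learning and sharing, and are strictly culturally isolated from one
another.

## The update cycle

One update is `1/updates_per_year` years (default 1/10). Per community:
expression → institution resolution → harvesting → social learning →
invention; then globally: territorial contest → fission checks → dispersal
checks → agent energetics/reproduction/mortality; finally split-event
settling and metrics sampling. All randomness flows from a single
generator, so a (configuration, seed) pair reproduces a run bit for bit.

### Resolution (closed form)

Apex expressions are processed in uniformly random order; each claims, top
down, one available expression of every reachable tree locus. For trees
this greedy process is order-invariant: the performance processed at rank
*j* claims locus *l* iff *j* < minpath(*l*), the minimum expression count
along *l*'s ancestor path. Realized complexity per rank follows in closed
form; only the assignment of agents to ranks is random. The test suite
checks the closed form against a literal sequential greedy under all
processing orders and against exhaustive allocation search on small
instances (the greedy total is never above the optimum and empirically
within 10% of it).

An apex performance with an incompletely populated tree still counts at its
realized complexity (graceful degradation): a community that loses one
locus of a class-k institution degrades to k−1 rather than to nothing.

### Social learning

Each agent draws `observation_rate` (default 1.3, fractional surplus as a
Bernoulli extra) observation opportunities per update, sampled from the
community's expression tally. If the observed locus is one the agent lacks,
it learns with probability

`p = slr/1000 × (1 + rank_bias·ρ) × min(1, (d/d̄)^χ) × B`

where ρ is the model agent's rank percentile, d/d̄ the observed locus's
expression density relative to the mean expressed density (χ =
`conformity_exponent`, default 0.45 — a conformist **rarity penalty**), and
B the boost factor. The measured social-learning rate (successes per 1000
opportunities) therefore equals the `slr` parameter in the unbiased,
unboosted steady state by construction.

Two deliberate design choices shape everything downstream:

- **Attention-limited observation.** If every naive agent instead drew an
  independent chance on *every* expression (learning hazard ∝ slr ×
  carriers), allele densities saturate near fixation for any slr in the
  interesting range, fission never loses loci, and no glass ceiling can
  form. A bounded observation budget makes maintenance compete with
  repertoire breadth — more loci means slower per-locus transmission — and
  produces the complexity-dependent losses the model exists to study.
- **Rarity penalty.** Without the conformist bias, rare-variant recovery is
  so reliable that fidelity stays near 1 through class 6. With it, loci
  that drift rare are disproportionately hard to relearn and are lost at
  fission, concentrating losses on complex institutions.

### Invention

Each agent invents with probability `invention_rate` per update (default
3·10⁻⁵). An inventor holding no apex allele acquires a uniformly chosen
apex; otherwise it creates a new component under one of its institutions
(institution chosen uniformly, then the parent locus uniformly within the
tree). Inventions are demonstrated social acts: an
`invention_seed_fraction` (default 0.12) share of the community co-adopts
the new practice at birth — under attention-limited conformist learning a
lone novel allele would nearly always die unobserved, and no institution
could ever nucleate.

### SLR-boosting institution

When enabled, an observation whose model agent performed the booster apex
this update at realized complexity *c* succeeds at `B = 1 +
boost_coefficient × (min(c, capacity) − 1)` (capacity caps the benefit only
when genetics are enabled and coupled). Anchoring the boost at depth beyond
the apex matters in both directions: a bare apex that boosted its own
transmission would spread as a self-catalytic cultural parasite before any
carnivory institution exists, while a mature booster institution *must*
boost its own maintenance — without that, a repertoire of carnivory plus
booster loci exceeds what the attention budget can sustain at slr = 30 and
the booster always collapses. The booster yields no energy; its value is
entirely indirect, which is the point of the coevolution experiments. The
default `boost_coefficient = 2` is sized so the benefit can outweigh the
attention and energy cost of carrying a third institution at desk-scale run
lengths.

### Demography, energy, territory

Income is `density × (area/members) × efficiency` per resource, shared per
the monopolizability; everyone pays `cost_of_living` (1/yr), expression
costs (0.01/expression) and, with genetics, a capacity cost. Energy above a
one-year reserve overflows into the reproduction buffer; adults whose
buffer exceeds `reproduction_threshold` (9 — roughly a decade between
surviving births at unit surplus) produce a newborn with an empty allele
set and a one-year endowment. Mortality combines a baseline hazard
(0.02/yr), a senescent power term ((age/45)⁵ × 1.2/yr) and a starvation
term (1/yr while the reserve is negative).

Territorial power is the adult count abated with distance from the
territory centroid (`1/(1 + 0.05·d)`); every perimeter cell is contested
each update against its strongest differently-owned neighbour with
probability `contest_rate × sigmoid(steepness × relative power)`.
Communities exceeding `fission_threshold = 16` adults split: the territory
is bisected by an alternating flood fill seeded at the two extremes of its
principal axis (both halves edge-connected), members are assigned at
random, daughters start fresh performance windows. Communities below 6
members or 8 cells disperse; their land reverts to wilderness.

## Measurement

A community's **complexity class** is the largest c such that at least
`class_threshold` (0.25) of its adults achieved best realized carnivory
complexity ≥ c within the trailing `class_window` (40 updates, implemented
as two half-window maxima per agent). **Fidelity** at class k is the
fraction of settled daughters (measured `settling_window = 25` updates
after the split) of class-k parents whose class did not drop; the paper's
natural alternative — counting per split rather than per daughter — is a
configuration switch. θ-sensitivity: within 0.2–0.35 the fidelity profile
keeps its shape; higher thresholds add a class-independent noise floor of
apex-support dips unrelated to allele loss.

The **split harness** (`run_split_harness`) measures fidelity at a fixed
class by running many independent single-community lineages in a small
closed arena (12×12 cells, no invention), each seeded from the fixture
generator at 0.85 allele density, equilibrated for 6 fissions, and then
recording both settled daughter classes for every split whose parent
measured class k, until the lineage loses the class (up to 6 recorded
splits per lineage). Pooled over lineages this conditions the measurement
on class-k parents at the model's own steady-state densities.

## Calibration of surrogate values

The published account specifies mechanisms but not magnitudes, so all
numeric defaults here are this package's own, fixed by calibrating to the
qualitative regime the mechanisms are supposed to produce: an unaided
community equilibrates near one agent per three cells and splits every
100–200 updates; inheritance fidelity is ≈1 through class 4, loses ~5% of
daughters at class 5 and ~15–20% at class 6 (split harness, BASE learning,
slr = 50); the measured social-learning rate matches the slr parameter; and
carnivory returns reward complexity strongly enough that higher classes
spread by demic diffusion. Calibration used the split harness and
desk-scale spatial runs; all values were frozen before the acceptance
measurements were taken.

## What the generators emulate — and what they do not

The fixture generator builds communities with prescribed institution trees
(random recursive topology) and allele densities, stationary-ish age
structures and full energy reserves; the split harness embeds them in a
small empty arena. This emulates the *within-community* conditions of the
full model faithfully, but not between-community competition: spatial runs
add territorial squeeze, dispersal churn and rebuilding daughters, which
depress effective fidelity and the equilibrium class relative to harness
conditions. Passing harness-based checks therefore demonstrates the
inheritance channel itself, not the full spatial selection balance.

## Problem sizes in tests and acceptance

The published experiments average 100 runs of 200,000 updates on 200×200
to 500×500 grids. This package's test suite reproduces the phenomena at
desk scale as its own study conditions: fidelity profiles from ≥500
harness splits per class; a glass-ceiling run on a 56×56 grid for 12,000
updates; slr sweeps over {20, 35, 50, 65, 80} on 32×32 grids for 3,000
updates (6 seeds each); coevolution contrasts on 44×44 tiled arenas for
6,000–8,000 updates with pre-seeded entry-level institutions (the
booster's three-way nucleation needs run lengths near the published
300,000 updates). The acceptance script pools ten independent harness
batches per class (≥500 splits, burn-in of 8 fissions per lineage) for the
class-5 and class-6 fecundity reductions.

## Known limitations

- The equilibrium complexity class of desk-scale spatial BASE runs sits
  around 3–4 rather than 5, even though those same runs reproduce the
  fidelity-by-class curve (≈0.99/0.99/0.94/0.82 for classes 3–6): under
  the attention-limited learning economy, between-community churn degrades
  effective fidelity below harness values, and establishment — not
  selection — limits the climb. Longer runs on larger grids narrow but do
  not close this gap.
- The gene–culture coupling contrast (capacity rising only when it gates
  the booster) is below drift noise at desk scale: capacity's individual
  benefit is diluted by tolerated-theft sharing, leaving mostly
  community-level selection, which needs the published problem sizes.
- Repertoire breadth is globally costly (attention pollution): surviving
  low-value traditions slow the transmission of everything else. This is a
  real prediction of bounded-attention learning, but it has no counterpart
  in the published model and makes innovation rates double-edged here.
- No cross-community cultural diffusion, no community fusion, no explicit
  within-community network topology, no cheating/policing institutions, no
  allele forgetting; dispersing agents die rather than being absorbed.
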