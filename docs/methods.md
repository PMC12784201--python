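# Methods

## The model

`traitnet` generates undirected social networks in which the chance (and
strength) of a social tie between two individuals is set by their *social
attraction*, built from trait-based social preferences. Two preference
types are modelled:

* **Similarity preference** — an individual prefers partners whose value
  of a trait is close to its own (homophily). The trait-specific pair
  attraction is a kernel of trait distance that equals 1 at zero distance
  and decreases with distance.
* **Popularity preference** — higher trait values are preferred by
  everyone, independent of the chooser's own value. Each individual gets a
  popularity score in [0, 1] and a pair's attraction is the arithmetic
  mean of the two scores.

Each preference–trait combination carries an importance weight ω ∈ [0, 1].
For a pair (i, j) the overall attraction is

    A_ij = max(ε, Π_k [(1 − ω_k) + ω_k · a_k(i, j)]),    ε = 10⁻⁶,

the product running over all preferences, with a_k the trait-specific
attraction. At ω = 0 a preference drops out of the product entirely, so a
model with all importances zero produces uniform attraction and hence
uniform random structure; at ω = 1 a single preference can veto a tie
outright. The multiplicative blended-factor form was chosen over an
additive mixture because it (a) reproduces the exact random-graph limit
at zero importance, (b) lets each trait scale attraction independently,
and (c) allows a maximal preference to dominate — the behaviour one wants
from "maximal importance". The floor ε keeps the edge draw well defined
when a kernel returns exactly 0 at full importance.

Popularity pair attraction uses the arithmetic mean of the two scores
rather than their product: a product would assign ~0 attraction to every
pair involving a minimum-score individual, disconnecting the whole
low-score class at full importance, whereas the mean yields the
core–periphery gradient that popularity preferences are expected to
produce (low-score individuals still attach to high-score ones).

## Traits and kernels

Three trait distributions stand in for trait classes known to structure
animal social networks:

| kind | stands for | distribution | similarity kernel |
|---|---|---|---|
| categorical | sex | k equiprobable categories (default k = 2) | 1 if same category, else κ (default 0) |
| continuous normal | body size | Normal(μ, σ), default (0, 1) | exp(−Δx²/(2λ²)), λ = realised population sd |
| continuous circular | relatedness | uniform on a circle of circumference C (default 1) | 1 − d/(C/2), d = min(\|Δx\|, C−\|Δx\|) |

Popularity scores are min–max normalised within the realised population
(the maximum scores 1), which makes them rank-consistent and scale-free;
for categorical traits the non-preferred end can be lifted to a baseline
κ. A circular trait is only admitted with a similarity preference: a
circle has no "higher" end to be popular. A constant trait vector leaves
popularity undefined and raises an error rather than silently scoring.
Normal-trait location and scale are immaterial because the kernel
bandwidth defaults to the realised population sd; equiprobable categories
mirror a balanced sex ratio, and uniformity on the circle makes pairwise
circular distances exchangeable — the natural null for a relatedness
ring.

## Network construction

A network on n nodes with target mean degree d̄ receives exactly
m = round(n·d̄/2) edges (half-integers round up), drawn sequentially
without replacement with probability proportional to A_ij among the
remaining pairs. The draw is implemented with exponential race keys
(draw Exp(1)/A_ij per pair and keep the m smallest), which is
distributionally identical to the sequential draw and O(n²); the test
suite verifies this against exact enumeration of the sequential
probabilities. In weighted mode the edge weight is the attraction
rescaled so the mean edge weight is 1, making weighted and unweighted
measures scale-comparable.

Only single-component networks are used (each network is one unfragmented
population). Connectivity is enforced by rejection: disconnected draws are
discarded and redrawn in full with the same traits and attraction, which
preserves the conditional edge-set law (repair would bias it). The retry
cap defaults to 100,000: at full categorical-similarity importance with
κ = 0, cross-category attraction sits at the ε floor and a connected draw
is a rare event (order 10⁻³–10⁻⁴ per attempt), so a cap of a few thousand
attempts is routinely needed there; elsewhere rejections are rare. The
rejection count is recorded in the network's metadata and summed per
ensemble. Traits are *not* redrawn on rejection — resampling them would
confound the trait-pattern statistics.

Study defaults: n = 100 nodes, mean degree 10, ensembles of 100 networks
per importance point (acceptance-scale runs use ensembles of 25; the full
size is one config change).

## Structure measures

Six global measures, each averaged per ensemble; the first four also have
weighted variants (weighted degree = summed edge weights; weighted paths
travel edges at length 1/weight; weighted clustering is the Onnela
triangle-intensity coefficient):

* **degree variation** — coefficient of variation (sample sd / mean) of
  the degree sequence; scale-free, hence comparable across mean degrees;
* **degree assortativity** — Pearson correlation of degrees over edge
  endpoints (both orientations; edge-weight-weighted in the weighted
  variant);
* **clustering** — mean local clustering coefficient, degree-<2 nodes
  contributing 0;
* **mean distance** — mean shortest-path length over unordered pairs;
* **popularity-trait–degree correlation** — Pearson correlation of trait
  value with unweighted degree; the signature of a popularity preference;
* **similarity-trait assortativity** — Newman's discrete coefficient for
  categorical traits, endpoint Pearson for normal traits, and for
  circular traits the mean edge circular proximity 1 − d/(C/2)
  standardised by the all-pairs proximity mean and sd (a Mantel-style
  contrast: 0 under no assortment, positive when neighbours sit closer on
  the circle than random pairs — linear Pearson assortativity is
  meaningless on a circle).

Degenerate cases (constant degrees, a single category present, a constant
trait) yield NaN, the tagged undefined value; ensemble aggregation
averages over defined samples only and reports the defined count, never
coercing undefined to 0. A relevant finite-size fact: the connected
G(n, m) baseline itself has slightly *negative* expected degree
assortativity (≈ −0.02 at n = 100, m = 500), so baseline comparisons in
the tests use an independently generated G(n, m) ensemble as reference
rather than literal zero.

## Transmission

Discrete-time simulations start from one uniformly random infected node
and update all susceptibles synchronously per timestep until everyone is
infected; infected individuals stay infected. Synchronous updating keeps
"timestep" well defined for the efficiency statistic. Per step a
susceptible i is infected with probability

* simple, unweighted: min(1, β·m_i), m_i = infected neighbours;
* simple, weighted: min(1, β·s_i^inf), s_i^inf = summed weight to
  infected neighbours;
* complex, unweighted: β·(m_i/k_i), k_i = degree;
* complex, weighted: β·(s_i^inf/s_i), s_i = weighted degree.

The linear-capped form is the plainest reading of "probability grows with
the number/proportion"; an independent-exposure alternative
1 − (1−β)^m is available behind `prob_form="geometric"`. β defaults to
0.1 — all reported comparisons are within-β, so conclusions are
β-relative. At β = 1 the simple process reduces exactly to a
breadth-first front (t100 = seed eccentricity), which the tests exploit
as an oracle. Saturation is guaranteed on a connected network because any
susceptible with an infected neighbour has positive probability.

Each network runs 10 replicates per transmission subtype (a 100-network
ensemble therefore contributes 1,000 simulations per subtype). The
recorded outcomes are the timesteps t25–t100 at which 25/50/75/100% of
individuals have been infected; *transmission efficiency* is the inverse
of the mean time, 1/mean(t), not the mean of inverses.

## Robustness

Nodes are removed one at a time until two remain, in one of four orders:
random, highest (weighted) degree first, lowest degree first, or highest
(weighted) betweenness first. Robustness is the *component break time* —
the number of removals before the remaining induced graph first has more
than one component (isolated nodes count), capped at n − 2. Rankings are
static by default (computed once on the intact network) for exact
reproducibility and cost; dynamic recomputation is behind a flag and the
choice is recorded in sweep output via the strategy label. Ties are
broken uniformly at random with the run's seeded generator. The full
largest-component trajectory is returned alongside the break time so
alternative robustness summaries (e.g. area under the curve) can be
computed downstream.

## Sweeps, seeding and problem sizes

`run_sweep` drives the whole design: per importance grid point it redraws
traits per network, builds attraction, draws the ensemble, computes all
measures and runs the configured transmission subtypes and removal
strategies, then aggregates mean/sd/defined-count per column. Separate-
effect sweeps use 11 evenly spaced ω values in [0, 1] with the other
preference at 0; the joint sweep trades relative importance along
(t, 1 − t). Per-network generators derive from
`SeedSequence([master_seed, grid_index, replicate_index])`, so any subset
of a sweep reruns bit-identically.

The acceptance suite and `scripts/acceptance.py` use ensembles of 25
networks (and 10 transmission replicates per network) — chosen as the
smallest scale at which the ensemble standard errors cleanly resolve the
directional effects under study; the full study scale (ensembles of 100)
is a single configuration change.

## What the synthetic data does and does not emulate

The generator reproduces the *mechanism* under study — trait preferences
shaping tie probabilities — under idealised conditions: i.i.d. trait
draws, a fixed edge budget, no space, no time, no observation error.
Passing tests therefore show that the implementation realises the model
faithfully and that the claimed structural/functional consequences follow
from the mechanism; they do not show that any particular empirical
network was produced this way. Real animal social data add sampling
noise, temporal turnover, spatial constraints and non-stationary group
composition, none of which are modelled here.

## Known limitations

* Attraction is symmetric; directed or one-sided preferences are out of
  scope (heterophily is available only as a kernel sign flip).
* The rejection rule conditions the ensemble on connectivity; at extreme
  parameter corners (full-importance categorical homophily with κ = 0)
  the accepted networks are conditioned on rare bridging edges, and
  generation cost grows accordingly.
* Parameter inference from observed networks is not implemented; the
  model here runs forward only (a user-supplied trait CSV can replace the
  sampled traits).
* Break time is a first-fragmentation statistic; it says nothing about
  the sizes of the fragments beyond the recorded trajectory.
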