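# Methods

This note records the models implemented in `hawkdove`, the parameters that
matter, the synthetic data the tests run on, and the design choices made
where the underlying theory leaves the implementation open.

## Interaction descriptors and the reward matrix

A dyad is an ordered pair of positive trait values x > y (body sizes, any
fixed unit). The four descriptors are

    z_mu = x*y/(x-y)      mutualism
    z_an = 1/(x*y*(x-y))  antagonism
    z_ag = x/y            aggression
    z_al = (x-y)/x        altruism

Mutualism uses the size product (for a fixed sum, the product is largest
when the two sizes are similar — a similarity proxy), antagonism its
inverse; both are scale-adjusted by the size gap. Aggression and altruism
are pure ratios and therefore scale-free; z_mu scales linearly with the
unit and z_an as its inverse cube, so analyses that pool dyads should keep
one trait unit throughout (the network retention step only ranks values, so
it is unit-safe).

Dividing every descriptor by z_an yields the relativized reward matrix
(e_dd, e_dh; e_hd, e_hh) = (x²y², y(x−y)²; x²(x−y), 1). The antagonism
form 1/(x·y·(x−y)) is the unique descriptor consistent with this matrix
and with the break-even equations: dividing each descriptor by it
reproduces every entry exactly (an identity the tests assert to 1e-12).

**Degeneracy.** All descriptors divide by x − y, so equal sizes are a true
singularity of the theory. A dyad is rejected when (x − y)/x < eps
(default 1e-9, configurable). Ties are *never* jittered silently: a
perturbation of 1 part in 10⁹ would be invisible in the traits but moves
z_mu and z_an by orders of magnitude.

## Break-even thresholds and strategy prediction

The four role/opponent combinations compare two matrix entries each; the
thresholds are the ratios at which the entries tie (at normalized size
x = 1, since the break-evens are not scale-invariant and decisions should
depend only on relative size ρ = y/x):

| focal vs opponent | equation | threshold |
|---|---|---|
| larger vs dove | y² + y − x = 0 | φ = (√5−1)/2 ≈ 0.618 |
| larger vs hawk | y(x−y)² = 1 | ≈ 1.7549 (outside (0,1): aggress always) |
| smaller vs dove | y² − (x²+2x)y + x² = 0 | 1 − φ ≈ 0.382 |
| smaller vs hawk | x²(x−y) = 1 | 0 (resist always) |

The quadratics are solved in closed form (the smaller-vs-dove quadratic has
an extraneous root above x; the root in (0, x) is returned). The cubic is
solved by bracketed Brent iteration with a sign-change bracket grown
deterministically from y = x; no randomness enters any solver.

`predict_strategy` always returns the argmax of the two relevant entries.
One mapping deserves note: for a smaller player facing a larger dove, the
comparison is e_dd = x²y² versus e_dh = y(x−y)². Below the 1 − φ mark the
altruism-column entry e_dh dominates and the decision is labelled
*cooperate* (the smaller player accepts the benefactor relationship); above
it e_dd dominates and the decision is labelled *cheat* (the smaller player
extracts mutualism-level benefit from a partner it no longer needs to
defer to). The labels follow the theory's narrative for hypothesis 3; the
payoffs follow the matrix; the two agree on where the switch happens.

Exact ties at a threshold resolve to the cooperative / non-aggressive
branch — the theory is silent, and a documented deterministic rule beats
platform-dependent float comparison.

"Golden ratio" follows the reciprocal convention φ ≈ 0.618 throughout
(the conventional constant is 1/φ ≈ 1.618); only the naming, not the
mathematics, is affected.

## Growth curves and phases

Abundance series are fitted with the Zwietering re-parameterizations of the
Gompertz, logistic and Richards equations, chosen because their parameters
are the quantities the phase partition needs directly: asymptote A
(abundance units), maximum slope mu_m (abundance/hour), lag time lam
(hours), and for Richards a shape nu (Richards with nu = 1 is exactly the
logistic; verified pointwise in the tests). Fitting is bounded least
squares on the raw scale (log-scale optional) with a heuristic start
(A₀ = max value; mu₀ = max finite-difference slope; lam₀ = tangent
intercept) plus five seeded jittered restarts — deterministic and robust to
the shallow local minima these curves have. A constant series raises a
degeneracy error rather than returning an unidentifiable mu → 0 fit.

Model selection: the two 3-parameter models are ranked by small-sample AICc
(they are not nested in each other); the winner is tested against Richards
with a one-extra-parameter extra-sum-of-squares F-test at α = 0.05.
Identical RSS always resolves to fewer parameters. Both criteria are
recorded on the result so either can be audited.

Phases: lag = [t_min, lam], linear = (lam, t95], asymptotic = (t95, t_max],
with t95 the fitted time of reaching 95 % of A (configurable cutoff; no
canonical value exists, 95 % is the common convention for "effectively at
asymptote"). t95 is found by bracketed root-finding on the fitted curve; if
it falls beyond the window the asymptotic phase is empty and a warning is
issued rather than an error — slow growers are data, not mistakes.

## Empirical strengths and validation

With x(t), y(t) the co-culture abundances of the larger (X) and smaller (Y)
strain and x0(t), y0(t) their monoculture abundances:

    Mu = (x/x0 + y/y0)/2      Ag = (x/y)/(x0/y0)      Al = (y/y0)/(x/x0)

Al·Ag ≡ 1 algebraically, and Mu is bounded by the two fold changes (both
are property-tested). Mu > 1 marks the cooperation region, Mu < 1
competition. Which strain is "X" is re-decided at each time point by
co-culture abundance (default), with a per-pair fixed ordering by mean
abundance as an option — the definition says only that X is the more
abundant strain in co-culture, leaving re-ordering over time ambiguous.

Validation pools all pairs × time points within a phase (as the scatter
figures do) and computes Pearson r (Spearman optional) between each
descriptor evaluated on the co-culture abundances and its matching
strength. Phase labels come from the leading (more abundant) strain's
co-culture fit; p-values are per phase. Any smoothing in plots is cosmetic
and never enters the statistics. The antagonism side has no published
empirical-strength formula and is deliberately not invented; only Mu, Ag,
Al are computed.

## Networks, roles, and tier ratios

All n(n−1)/2 dyads receive one descriptor value per type; the top fraction
q of values become edges; the rest are culled. The retained
count is round(q·n(n−1)/2); rank ties break lexicographically by dyad id so
retention is fully deterministic. No culling fraction is published, so the
default q = 0.1 is exposed in config and recorded in output metadata.
Aggression and altruism edges are directed from the larger member (actor:
hawk, altruist) to the smaller (recipient: dove, egoist); mutualism,
antagonism and relatedness are undirected.

Mutualism hierarchy: hubs are nodes whose connectivity is well above the
cohort average, operationalized as
degree > mean + k·sd (k = 1 default — the simplest parametric reading);
they are primary leaders. Non-hub neighbours of hubs are secondary leaders.
Tertiary leaders are the layer directly behind the secondaries: nodes
adjacent to a secondary (but no primary) whose every shortest path to each
reachable primary passes through a secondary. Followers are the remaining
nodes adjacent to a tertiary but not to a secondary. Everything else is
unassigned, and a degree-regular network (the hub rule unsatisfiable)
yields no primaries with a warning. Directed-network roles are purely
local: out-edges only → hawk/altruist, in-edges only → dove/egoist, both →
mixed, none → isolated. The relatedness network reuses the hub rule for
core vs periphery.

Tier-ratio tests take every connected cross-tier dyad (lower-tier trait /
upper-tier trait), average over dyads (not tier means), and run a
one-sample one-sided t-test against the supplied threshold (φ for the
leader and hawk/dove comparisons, 1 − φ for the altruist tiers). Dyads
sharing an individual are not independence-corrected — matching the
original analysis — but a seeded node-label permutation p-value is
available alongside the naive one.

Genetic similarity is the allele-sharing IBS fraction, mean over
non-missing SNPs of (2 − |g_i − g_j|)/2: assumption-light and
well-defined inside a single full-sib family, where allele-frequency-based
relatedness estimators are not meaningful. Between-network correlations
are computed on the *pre-culling* all-dyads vectors so the five networks
align over the same dyad index regardless of retention.

## Synthetic data

The generators define the study conditions for every test; they are pure
functions of spec + seed.

**Cohort** (`CohortSpec`): n = 71 individuals by default, log-normal body
masses (median 600 g, log-sd 0.30 — an adult carp-like spread). Optional
planted tiers: tier sizes plus target bands for the mean cross-tier size
ratio; lower-tier draws are anchored on the harmonic mean of the upper tier
so the realized all-pairs mean ratio lands in the band (rejection-checked).

**Co-culture** (`CocultureSpec`): coupled logistic (gLV-style) dynamics

    dN_x/dt = r_x s_x(t) N_x (1 − N_x/A_x + a_xy N_y/A_y)

and symmetrically for y, with r = 4·mu_m/A, a smooth lag switch s(t), and
monoculture as the zero-coupling limit. Default: 40 pairs, asymptotes
A_x ∈ (0.9, 1.2) and A_y ∈ (0.5, 0.75) in arbitrary qPCR units, maximum
slopes mu_m ∈ (0.08, 0.14) per hour, lags 2–5 h, symmetric couplings drawn
uniformly on (0, 0.6) (the graded-strength condition), multiplicative
log-normal observation noise with log-sd 0.05, sampled every 2 h to 24 h
then every 4 h to 36 h (t = 0 included). By default the two strains of a
pair share one per-capita rate and one lag — grown in the same medium,
differing in carrying capacity — so their trajectories stay proportional
and never cross; without this the smaller-asymptote strain would get the
faster relative rate, trajectories would intersect, and the x − y
denominator of z_mu would blow up at crossing times, burying the coupling
signal under descriptor singularities. Independent per-strain kinetics
remain available via `shared_kinetics=False`. The coupled-logistic
mechanism is a stand-in generator: the validation property only requires
that co/mono ratios encode the interaction sign and strength, which these
dynamics guarantee (plateau fold change 1/(1 − a) for symmetric coupling
a).

**Genotypes**: per SNP a segregating cross type (AB×AB with probability
0.5, AB×AA and AA×AB with 0.25 each), offspring drawn by Mendelian
segregation. Analytic expectations used in tests: AB×AB sibs share IBS
5/8, backcross SNPs 3/4, mixture 0.6875 at the default cross mix.

What the synthetic data do *not* emulate: real qPCR calibration error
structure, strain death phases, resource-explicit interaction mechanisms,
linkage between SNPs, and measurement correlation between co-culture and
monoculture replicates. Passing tests therefore demonstrate that the
pipeline recovers planted structure under its own assumptions, not that
those assumptions hold for any particular organism.

## Problem sizes and numerics

Unit tests use 12–25 co-culture pairs, 20–71-individual cohorts, and
200-replicate noise studies for growth-parameter recovery — sizes chosen so
the full suite documents the statistical claims while remaining quick to
run routinely. Root-finding tolerances are 1e-12 (brentq xtol) for
thresholds and 1e-10 for the cubic residual check; descriptor identities
are asserted at 1e-12 relative; growth fits use least-squares xtol 1e-12
with exponent clipping at ±700 to avoid overflow during line searches.

## Known limitations

* Tier ratios reported for the original co-reared carp cohort (data
  deposited at github.com/BeijingCCB/GoldenTheory) depend on that dataset
  *and* on a culling fraction that was not recorded; with both in hand
  they should be reproducible through `hawkdove networks --retention ...`,
  but they are treated as external validation, not as package-level
  expectations.
* The hawk-side "tit-for-tat" narrative for smaller antagonists is
  implemented only as the resist/surrender payoff comparison; no iterated
  game, mixed strategies or replicator dynamics are modelled (one-shot
  comparisons only).
* The directional-network orientation (larger → smaller for both aggression
  and altruism) encodes actor → recipient; for altruism this means the
  arrow points from the altruist (larger) to the egoist (smaller) —
  consistent with the aggression network's actor semantics, but opposite
  to "benefit flow" conventions used elsewhere in network ecology.
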