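# Methods

## The model family

Two asexual microbial genotypes compete: *G_p* carries programmed cell
death (PCD+), *G_n* does not (PCD−).  Each genotype expresses two
phenotypes, *A* and *B*, that differ only in which environmental
disaster kills them.  Disasters strike at random times, each targeting
one phenotype chosen uniformly; between disasters the population sits at
carrying capacity, so reproduction — and with it diversification by
stochastic phenotype switching (probability *p* per birth) — is only
possible when something dies.  PCD+ cells die with probability *c* per
round, and the assortment parameter *r* is the probability that a PCD
death is replaced by the dead cell's own genotype.  The package
implements the same underlying dynamics at three levels of spatial
realism: fixed *r* (closed forms plus stochastic competitions), a 2D
lattice where *r* is a measured local statistic, and a 3D patch-based
agent model where *r* emerges from demography.

Assumptions shared by all three levels: switching is tied to
reproduction (cells never switch in place); disasters are memoryless and
unbiased between phenotypes; regrowth after death is resource-free and
instantaneous up to capacity; and the two genotypes are identical except
for PCD.

## Closed-form layer (`analytic`)

The deterministic one-round map advances real-valued counts
(*A_p*, *B_p*, *A_n*, *B_n*): each PCD+ phenotype loses a fraction *c*,
recaptures *c·r* (of which a fraction *p* switches phenotype), and cedes
*c(1−r)* to the competitor, whose gain is split by its current phenotype
frequencies with switching.  The map conserves the total exactly, and
iterating it shrinks the PCD+ genotype by `(c(r−1)+1)^t` — the cost
factor.  When the competitor is extinct the ceded share returns to the
PCD+ genotype in proportion to its own phenotype frequencies (only
living cells can regrow); this convention keeps the map conservative and
reduces to *r* = 1 while the competitor is absent.

The benefit expressions treat *c·m* expected deaths as a real-valued
exponent (they are expectation-level formulas, not integer-trial laws);
the stochastic modules use integer deaths, and agreement is asserted
only within Monte-Carlo sampling error.  The benefit/cost odds are
evaluated in log space with `log1p`/`expm1` primitives: the denominator
`(c(1−r))^m` underflows double precision already at modest *m*, and the
factor `(1−p)^{−cmr} − 1` loses all relative precision at *p* ≲ 10⁻⁶ if
formed naively.  `c = 0` or `r = 1` make the extinction probability
exactly zero; the ratio reports infinity rather than raising.

The diversification timescale iterates the expected minority-frequency
recursion `x ← x(1−p) + (1−x)p` from 0 and reports the first generation
within `tol` of the 0.5 stationary point.  "Maximal diversity" is not a
sharp notion; the default `tol = 0.005` (1% of the stationary value) is
a documented, configurable choice.

## Well-mixed stochastic model (`wellmixed`)

Each round is: disaster with probability *d* (annihilating the targeted
phenotype of both genotypes), regrowth to capacity *N*, then one
PCD/replacement step.  The source text alternates "rounds of PCD" with
stochastic disasters without fixing an order; this ordering makes *t* in
the cost factor count exactly the PCD steps between disasters and is
exposed as `pcd_steps_per_round` for sensitivity checks.  PCD deaths are
binomial per phenotype; each dying cell is replaced own-genotype with
probability *r* (same phenotype, then switching) or by a competitor
birth drawn from the competitor's phenotype frequencies (then
switching) — the term-by-term stochastic counterpart of the
deterministic map, which the test suite verifies componentwise at 3-SE
tolerance.

Regrowth to capacity is a sequential-birth urn: every birth's parent is
drawn uniformly from the *current* population, offspring included, and
the offspring switches phenotype with its genotype's *p*.  Offspring
joining the parent pool means early switches are amplified
(reinforcement); the exact expectation obeys
`b_{t+1} = b_t + (b_t/t)(1−2p) + p`, which the tests use as the oracle.
The urn loop is compiled with numba, with all randomness pre-drawn from
the numpy Generator so runs are pure functions of their seeds.

Defaults: *N* = 10,000 started as *N*/4 of each of the four types (so
every phenotype exists), a 10,000-round cap, winner by extinction or
majority at the cap.  Exact ties and double extinctions are their own
outcome classes and are excluded from win fractions.  Each replicate's
stream is spawned from the root seed by (parameter-combination,
replicate) index, so enlarging a sweep never perturbs existing rows.

## Lattice model (`lattice`)

100×100 non-periodic grid, Moore (8-site) neighborhood; edge and corner
cells simply have 5 or 3 neighbors.  A round is: disaster with
probability *d* (lattice-wide annihilation of one phenotype), then
simultaneous PCD deaths, then pass-based repopulation: every empty site
with a living neighbor receives an offspring of a uniformly chosen
living neighbor (uniformity implemented as an argmax over i.i.d.
uniforms masked to living neighbors), and new offspring become available
as parents from the next pass.  Per-cell assortment of a PCD+ cell is
the fraction of its *living* neighbors sharing its genotype; cells with
no living neighbor are excluded, and the lattice-wide mean is over PCD+
cells only.

Initial configurations hit a target mean *r* by batch genotype swaps:
targets ≤ 0.52 use a uniform random 50:50 placement (mean *r* ≈ 0.5);
higher targets start from two half-grid blocks (*r* ≈ 0.99) and mix
downward, with batch size proportional to the remaining distance and
halved on overshoot.  The one-sided approach is deliberate: random
swaps readily *lower* assortment but greedy single swaps cannot climb it
from a mixed start in reasonable time.  Targets below the ≈0.5 floor of
a 50:50 mix fail with the achieved value rather than looping.

The per-round change Δr is measured after repopulation against the
state before the round's first death.  Δr statistics condition on three
round classes — no disaster, disaster repeating the previous target,
disaster switching targets — with a run's first disaster excluded from
the latter two (it has no predecessor).  The switch probability for
lattice runs defaults to 0.1, the value used in the fixed-*r*
competition figures; the lattice value is not independently documented,
so it is exposed as a parameter.

## 3D agent-based model (`abm`)

Patches on a 10×10×10 grid (configurable), each holding at most
*K* = 10 cells; adjacency is the 6 face-neighbors (a 26-neighbor variant
would be a one-line change; face adjacency is the simplest 3D choice).
A time step is, in order: (1) with probability *d* a global disaster
kills 99% of one phenotype (independent binomial survivors per patch);
(2) reproduction — each cell may produce one offspring into its own
patch, cells drawn in random order until the patch is full, offspring
switching with probability *p*; (3) migration — each cell moves with a
fixed probability to a uniformly chosen adjacent patch, blocked if the
destination is full at that moment; (4) PCD deaths.  Cell types are
stored as per-patch counts; because every per-cell rule here is
exchangeable within a patch, the count-level draws (binomial, and
multivariate-hypergeometric for "a uniform subset of cells reproduces")
are exact, not approximations.

Metrics: per-genotype phenotypic diversity is the normalized Shannon
entropy of the genotype's global A/B split (1 at 50:50, 0 when
monomorphic, undefined when absent); a patch-level alternative exists
but the global split is the reported default.  Assortment is the mean,
over PCD+ cells with at least one patch-mate, of the same-genotype
fraction among patch-mates — the patch analogue of the lattice
estimator.  A `max_steps` cap (default 20,000) is added so that sweeps
terminate; the underlying model runs to genotype extinction.

The ABM switch probability defaults to 0.1, matching the other two
models.  This choice matters: at much lower switch rates the
post-disaster rebound (1% of the targeted phenotype survives and
re-expands) dominates both genotypes' diversity and the PCD-driven
turnover signal disappears into founder-effect noise.  The regime in
which PCD visibly accelerates diversification is the one in which
switching per turnover event is non-negligible, and that is the regime
all three models probe.

## Synthetic study conditions, and what passing tests show

There are no external data; every input is a parameter set and every
fixture is generated by the models themselves.  The study conditions
baked into defaults are: well-mixed competitions at *N* = 10,000 for up
to 10,000 rounds; lattice competitions at disaster and PCD probabilities
0.05 with initial assortment in {0.5, 0.75, 0.95}; ABM worlds of
10×10×10×*K*10.  The acceptance runs use reduced replication chosen as
this package's own desk-scale conditions: 30 lattice runs capped at
5,000 rounds for the pooled Δr and plateau statistics (the test suite
uses 24 runs at 4,000), 200-seed well-mixed win fractions, and ABM
sweeps on 5×5×5 worlds with ~12 replicates per grid cell.  Monte-Carlo
assertions use 3-standard-error bands; directional claims use pooled
win counts across a grid axis.

Passing tests show that the implementation reproduces the internal
logic and the expected signs, orders of magnitude and closed-form
values of the model family.  They do not show that real microbial
populations behave this way: the models ignore resource dynamics,
growth-rate differences, age structure, within-patch space, correlated
or biased disasters, and the evolution of *c* and *p* themselves.

## Numerical and degenerate-case choices

- Probabilities validated at construction; a PCD− strain must have c = 0.
- Extinction is always an explicit outcome: regrowth of an empty
  population raises, it never silently respawns.
- Assortment summaries are flagged undefined (NaN + zero count) when no
  PCD+ cell qualifies, and empty Δr classes report NaN means.
- Win fractions exclude double extinctions and exact ties; an
  all-excluded cell reports NaN, not 0.
- All stochastic entry points take either an integer seed or a numpy
  Generator/SeedSequence; sweeps spawn child streams per (combination,
  replicate).
- Result tables carry version, model and seed in a commented header —
  no timestamps, so identical runs are byte-identical.
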