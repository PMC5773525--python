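# pcdhedge

Why would a single-celled organism ever commit suicide?  `pcdhedge`
simulates one candidate answer: programmed cell death (PCD) can act as an
*accessory to diversification bet hedging*.  Microbes that diversify by
stochastic phenotype switching only create variation when they reproduce;
in a population pinned at carrying capacity there is no reproduction, so
a genotype that kills a fraction of its own cells buys itself extra
rounds of (diversifying) regrowth.  The cost is that the freed resources
can be captured by a competitor that does not pay the suicide tax — a
cost that shrinks when the population is spatially structured, so that
dying cells are replaced by clonemates.

The package is aimed at evolutionary microbiologists and theorists who
want to explore when PCD+ genotypes beat PCD− competitors, and at anyone
who needs a clean, seeded reference implementation of the three nested
models:

1. **`pcdhedge.analytic`** — closed-form layer with fixed assortment
   *r*.  Two genotypes *G_p* (PCD+) and *G_n* (PCD−), each expressing
   phenotypes *A*/*B*; per-round PCD probability *c*; switch probability
   *p* per reproduction.  Between disasters the PCD+ genotype decays by
   the cost factor `(c(r−1)+1)^t`.  Starting from *m* PCD+ cells of one
   phenotype, the probability that only the PCD+ strain diversifies is
   `(1−p)^{cm(1−r)} − (1−p)^{cm}`, maximized at
   `p* = 1 − (1−r)^{1/(cmr)}`; the probability PCD alone exterminates
   the strain is `(c(1−r))^m`, and the benefit/cost odds are the ratio of
   the two.  A deterministic one-round map of the four cell-type counts
   serves as the oracle for everything stochastic.
2. **`pcdhedge.wellmixed`** — stochastic competitions under randomly
   timed disasters that annihilate one phenotype of both genotypes,
   regrowth to carrying capacity *N*, and binomial PCD with fixed *r*.
3. **`pcdhedge.lattice`** — a 100×100 grid (Moore neighborhood) where
   dead sites are refilled from living neighbors, so each PCD+ cell has
   its own local *r*; disasters carve space that clonal regrowth fronts
   refill, building assortment.
4. **`pcdhedge.abm`** — a 3D world of patches (default 10×10×10, ten
   cells per patch) with reproduction into free slots, migration between
   face-adjacent patches, 99%-lethal disasters and per-step PCD;
   assortment emerges from demography alone.

## Worked example

```python
import math
from pcdhedge import analytic
from pcdhedge.wellmixed import CompetitionParams, run_competition
from pcdhedge.params import StrainParams, EnvironmentParams

print(analytic.optimal_switch_rate(c=0.1, m=100, r=0.5))
print(analytic.cost_factor(0.1, 0.9, 20))
print(math.log10(analytic.benefit_cost_ratio(1e-6, 0.09, 11, 0.5)))

params = CompetitionParams(
    plus=StrainParams(switch_prob=0.1, pcd_prob=0.05, is_pcd_plus=True),
    minus=StrainParams(switch_prob=0.1),
    env=EnvironmentParams(disaster_prob=0.1, carrying_capacity=10_000,
                          assortment=0.9),
)
result = run_competition(params, max_rounds=2000, seed=0)
print(result.winner, result.rounds_elapsed)
```

prints

```
0.12944943670387588
0.8179069375972309
8.50926744208831
timeout_majority_pcd_plus 2000
```

Read: with 100 PCD+ cells at PCD rate 0.1 in a well-mixed population the
diversification advantage peaks at a switch rate of ≈0.13; twenty
disaster-free rounds at c = 0.1 cost a highly structured (r = 0.9) PCD+
strain ≈18% of its cells; at a realistically tiny switch rate (10⁻⁶) the
odds that one PCD round is beneficial rather than suicidal exceed eight
orders of magnitude; and in a structured stochastic competition with
frequent disasters the PCD+ strain holds the majority after 2,000 rounds
despite paying for its cell death.

A command-line interface mirrors the library:

```bash
pcdhedge analytic --formula cost_factor --param c=0.1 --param r=1.0 --param t=5
pcdhedge wellmixed sweep --config sweep.yaml --seed 1 --outdir results/
pcdhedge lattice run --config lattice.yaml --seed 1
pcdhedge abm sweep --config abm.yaml --seed 1
pcdhedge accept all            # recompute and check the reference numbers
```

All outputs are plain TSV with a commented header; identical configs and
seeds give byte-identical files.

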