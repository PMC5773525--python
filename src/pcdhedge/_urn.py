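"""Sequential-birth (Polya-urn) kernel for regrowth to carrying capacity.

Regrowth after a disaster draws each birth's parent uniformly from the
*current* population, offspring included, so the process is an urn with
reinforcement plus phenotype switching at birth.  The loop is compiled
with numba; randomness enters only through pre-drawn uniforms so the
result is a pure function of its inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def polya_births(counts, n_births, p_plus, p_minus, u_parent, u_switch):
    """Add ``n_births`` sequential births to ``counts`` in place.

    ``counts`` is the int64 vector (A+, B+, A-, B-).  ``u_parent[i]`` picks
    birth i's parent uniformly from the population at that moment;
    ``u_switch[i]`` decides the phenotype switch at the parent genotype's
    switch probability.
    """
    total = counts[0] + counts[1] + counts[2] + counts[3]
    for i in range(n_births):
        u = u_parent[i] * total
        if u < counts[0]:
            cat = 0
        elif u < counts[0] + counts[1]:
            cat = 1
        elif u < counts[0] + counts[1] + counts[2]:
            cat = 2
        else:
            cat = 3
        p = p_plus if cat < 2 else p_minus
        if u_switch[i] < p:
            cat ^= 1  # flip phenotype within the genotype
        counts[cat] += 1
        total += 1


def draw_births(counts: np.ndarray, n_births: int, p_plus: float, p_minus: float, rng) -> None:
    """Convenience wrapper drawing the uniforms from ``rng``."""
    if n_births <= 0:
        return
    u_parent = rng.random(n_births)
    u_switch = rng.random(n_births)
    polya_births(counts, n_births, p_plus, p_minus, u_parent, u_switch)
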