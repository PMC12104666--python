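"""Independent brute-force oracles shared across test modules."""

import numpy as np


def pi_brute(p):
    """P(two unrelated HWE genotypes identical) by genotype enumeration."""
    k = len(p)
    tot = 0.0
    for i in range(k):
        for j in range(i, k):
            pr = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            tot += pr * pr
    return tot


def pi_sib_brute(p):
    """P(two full sibs share a genotype): enumerate all parental pairs and
    the Mendelian child distribution for each."""
    k = len(p)
    tot = 0.0
    for a in range(k):
        for b in range(k):
            for c in range(k):
                for d in range(k):
                    pp = p[a] * p[b] * p[c] * p[d]
                    child = {}
                    for x in (a, b):
                        for y in (c, d):
                            g = (x, y) if x <= y else (y, x)
                            child[g] = child.get(g, 0.0) + 0.25
                    tot += pp * sum(v * v for v in child.values())
    return tot


def rayleigh_mc_p(r_obs: float, n: int, n_resamples: int,
                  rng: np.random.Generator, chunk: int = 100_000) -> float:
    """Monte-Carlo Rayleigh p-value from a uniform-bearings null."""
    hits = 0
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        th = rng.uniform(0.0, 2.0 * np.pi, (m, n))
        rnull = np.abs(np.exp(1j * th).sum(axis=1)) / n
        hits += int((rnull >= r_obs).sum())
        done += m
    return hits / n_resamples
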