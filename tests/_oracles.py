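"""Independent oracles used by the test suite.

These deliberately re-derive results through different formulations than
the package uses, so agreement is evidence of correctness rather than of
shared code.
"""

from __future__ import annotations

import numpy as np


def trim_oracle(seq_len: int, snp_offsets: list[int], flank: int):
    """Edge-trimming oracle by cut-point enumeration.

    Valid 5' cut points are 0 or one-past a SNP; a cut point a is feasible
    when no SNP lies within [a, a+flank).  The minimal feasible candidate
    equals the iterative greedy rule's result (any smaller candidate would
    have a SNP inside its opening window, which is exactly what forces the
    greedy cascade past it); symmetrically for the 3' side over the SNPs
    surviving the 5' cut.  Returns (kept_start, kept_end, kept_offsets) or
    None when no SNP survives.
    """
    snps = sorted(snp_offsets)
    left_candidates = [0] + [s + 1 for s in snps]
    feasible = [
        a
        for a in left_candidates
        if not any(a <= s < a + flank for s in snps)
    ]
    a = min(feasible)
    remaining = [s for s in snps if s >= a]
    right_candidates = [seq_len] + remaining
    feasible_b = [
        b
        for b in right_candidates
        if not any(b - flank <= s < b for s in remaining)
    ]
    b = max(feasible_b)
    kept = [s for s in remaining if s < b]
    if not kept:
        return None
    return a, b, kept


def wc_theta_oracle(pop_calls: list[np.ndarray]):
    """Loop transcription of the 1984 variance-component estimator.

    ``pop_calls`` holds, per population, an (n_i, 2) integer array of
    allele indices for one locus (no missing entries).  Returns the
    per-locus theta as sum_a(a) / sum_a(a + b + c), or NaN when undefined.
    Components are computed allele by allele with explicit scalar loops.
    """
    pops = [np.asarray(c) for c in pop_calls if len(c) > 0]
    r = len(pops)
    if r < 2:
        return float("nan")
    n = [len(c) for c in pops]
    n_bar = sum(n) / r
    if n_bar <= 1:
        return float("nan")
    n_c = (sum(n) - sum(v * v for v in n) / sum(n)) / (r - 1)
    if n_c <= 0:
        return float("nan")
    alleles = sorted({int(a) for c in pops for a in c.ravel()})

    A = B = C = 0.0
    for al in alleles:
        p = [np.mean(c == al) for c in pops]
        h = [np.mean((c == al).sum(axis=1) == 1) for c in pops]
        p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
        s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
        h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        A += a
        B += b
        C += c
    denom = A + B + C
    if denom == 0:
        return float("nan")
    return A / denom


def multinomial_loglik(counts: np.ndarray, pair: tuple[int, int], epsilon: float) -> float:
    """Direct multinomial log-likelihood of a genotype given read counts."""
    k = len(counts)
    w = np.zeros(k)
    i, j = pair
    if i == j:
        w[i] = 1.0
    else:
        w[i] = w[j] = 0.5
    p = (1 - epsilon) * w + epsilon / k
    return float(np.sum(counts * np.log(p)))
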