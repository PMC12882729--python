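"""Weir–Cockerham F-statistics from diploid genotype matrices.

Implements the 1984 variance-component estimators (a: among populations,
b: among individuals within populations, c: within individuals) for
arbitrary numbers of alleles per locus.  Multi-allelic loci are handled by
computing components per allele and summing; multilocus estimates are
ratios of summed components.  Temporal collections are treated as the
"populations".

The module is written array-first so that permutation tests can evaluate
thousands of relabelled datasets in one vectorized call: every function
broadcasts over arbitrary leading axes (e.g. a permutation axis).
"""

from __future__ import annotations

import numpy as np

from .model import MISSING, GenotypeMatrix

__all__ = [
    "individual_allele_arrays",
    "group_counts",
    "wc_components",
    "theta_from_components",
    "fis_from_components",
    "theta_per_locus",
    "multilocus_theta",
]


def individual_allele_arrays(gm: GenotypeMatrix):
    """Per-individual allele dosage, heterozygote-carrier and called arrays.

    Returns
    -------
    X : float64 array (n_ind, n_loci, A_max)
        Gene-copy counts per individual per allele (0, 1 or 2).
    H : float64 array (n_ind, n_loci, A_max)
        1 where the individual is heterozygous at the locus and carries the
        allele, else 0.
    C : float64 array (n_ind, n_loci)
        1 where the individual has a called genotype at the locus.
    """
    calls = gm.calls
    a_max = max((len(a) for a in gm.alleles), default=0)
    n, L = gm.n_individuals, gm.n_loci
    X = np.zeros((n, L, max(a_max, 1)))
    H = np.zeros_like(X)
    called = (calls[:, :, 0] != MISSING).astype(float)
    het = (calls[:, :, 0] != calls[:, :, 1]) & (calls[:, :, 0] != MISSING)
    for a in range(a_max):
        hit0 = calls[:, :, 0] == a
        hit1 = calls[:, :, 1] == a
        X[:, :, a] = hit0.astype(float) + hit1.astype(float)
        H[:, :, a] = ((hit0 | hit1) & het).astype(float)
    return X, H, called


def group_counts(X, H, C, groups, n_groups=None):
    """Aggregate individual arrays into per-population counts.

    ``groups`` assigns each individual to a population index.  Returns
    ``(AC, HC, N)`` with shapes (r, L, A), (r, L, A) and (r, L).
    """
    groups = np.asarray(groups)
    r = int(groups.max()) + 1 if n_groups is None else n_groups
    G = np.zeros((r, len(groups)))
    G[groups, np.arange(len(groups))] = 1.0
    AC = np.einsum("rn,nla->rla", G, X)
    HC = np.einsum("rn,nla->rla", G, H)
    N = G @ C
    return AC, HC, N


def wc_components(AC, HC, N):
    """Per-allele Weir–Cockerham variance components.

    Parameters
    ----------
    AC : (..., r, L, A) gene-copy counts per population/locus/allele.
    HC : (..., r, L, A) heterozygous-carrier counts.
    N : (..., r, L) called-individual counts per population/locus.

    Populations with no called genotype at a locus are excluded from that
    locus.  Loci with fewer than two informative populations, or with mean
    sample size <= 1, yield NaN components.

    Returns ``(a, b, c)`` arrays of shape (..., L, A).
    """
    AC = np.asarray(AC, dtype=float)
    HC = np.asarray(HC, dtype=float)
    N = np.asarray(N, dtype=float)

    present = N > 0  # (..., r, L)
    r_eff = present.sum(axis=-2)  # (..., L)
    n_sum = N.sum(axis=-2)
    n_sq_sum = (N**2).sum(axis=-2)

    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = n_sum / r_eff
        nc = (n_sum - n_sq_sum / n_sum) / (r_eff - 1)
        # allele frequencies per pop; undefined pops masked to 0 contribution
        p = np.where(present[..., None], AC / (2.0 * N[..., None]), 0.0)
        p_bar = AC.sum(axis=-3) / (2.0 * n_sum[..., None])
        dev = np.where(present[..., None], p - p_bar[..., None, :, :], 0.0)
        s2 = (N[..., None] * dev**2).sum(axis=-3) / (
            (r_eff - 1)[..., None] * n_bar[..., None]
        )
        h_bar = HC.sum(axis=-3) / n_sum[..., None]

        nb = n_bar[..., None]
        rr = r_eff[..., None]
        pq = p_bar * (1.0 - p_bar)
        inner = pq - (rr - 1.0) / rr * s2 - h_bar / 4.0
        a = (nb / nc[..., None]) * (s2 - inner / (nb - 1.0))
        b = (nb / (nb - 1.0)) * (pq - (rr - 1.0) / rr * s2 - (2.0 * nb - 1.0) / (4.0 * nb) * h_bar)
        c = h_bar / 2.0

        invalid = (r_eff < 2) | (n_bar <= 1.0) | ~np.isfinite(nc) | (nc <= 0)
    bad = invalid[..., None] & np.ones(a.shape, dtype=bool)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def theta_from_components(a, b, c, axis=None):
    """theta = sum(a) / sum(a + b + c) over the given axes.

    With ``axis=None`` the sums run over the trailing (L, A) axes of a
    single dataset.  Returns NaN where the denominator is zero (overall
    monomorphic) or components are undefined.
    """
    if axis is None:
        axis = (-2, -1)
    num = np.nansum(a, axis=axis)
    den = np.nansum(a + b + c, axis=axis)
    all_nan = np.isnan(a).all(axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = num / den
    theta = np.where((den == 0) | all_nan, np.nan, theta)
    return theta


def fis_from_components(b, c, axis=None):
    """f = 1 - sum(c) / sum(b + c) (Weir–Cockerham small-f)."""
    if axis is None:
        axis = (-2, -1)
    num = np.nansum(c, axis=axis)
    den = np.nansum(b + c, axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 - num / den
    return np.where(den == 0, np.nan, f)


def _grouped_arrays(gm: GenotypeMatrix, labels=None):
    if labels is None:
        labels = gm.collection_labels()
    index = {lab: k for k, lab in enumerate(labels)}
    groups = np.array([index[c] for c in gm.collections])
    X, H, C = individual_allele_arrays(gm)
    AC, HC, N = group_counts(X, H, C, groups, n_groups=len(labels))
    return AC, HC, N, labels


def theta_per_locus(gm: GenotypeMatrix):
    """Per-locus multi-allelic theta with collections as populations.

    Returns a float array of length n_loci; monomorphic or uninformative
    loci are NaN (undefined, never silently 0).
    """
    AC, HC, N = _grouped_arrays(gm)[:3]
    a, b, c = wc_components(AC, HC, N)
    return theta_from_components(a, b, c, axis=-1)


def multilocus_theta(gm: GenotypeMatrix, labels=None) -> float:
    """Multilocus theta (ratio of component sums over loci and alleles)."""
    AC, HC, N = _grouped_arrays(gm, labels)[:3]
    a, b, c = wc_components(AC, HC, N)
    return float(theta_from_components(a, b, c))
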