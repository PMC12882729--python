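"""Pre-panel locus filters: depth/missingness, Hardy–Weinberg, linkage.

The filter chain reduces a raw microhaplotype dataset to putatively
neutral, well-genotyped loci, in the order depth/missingness -> HWE -> LD:

* loci with mean read depth below 20 are discarded, and individuals with
  25% or more missing calls are dropped (boundary: depth exactly 20 is
  kept, missingness exactly 25% is dropped);
* a locus is discarded for Hardy–Weinberg disequilibrium only when the
  per-collection chi-square goodness-of-fit test is (correction-adjusted)
  significant in EVERY temporal collection — a deviation confined to a few
  years is treated as drift/sampling, not a bad locus;
* linkage disequilibrium is tested on one randomly chosen SNP per locus
  via the squared Pearson correlation of diploid dosages; from every
  significant pair one whole locus is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import MISSING, GenotypeMatrix, MicrohapLocus

__all__ = [
    "FilterReport",
    "depth_missingness_filter",
    "hwe_filter",
    "ld_filter",
    "apply_filters",
]


@dataclass
class FilterReport:
    """Outcome of one filtering stage (or of the whole chain)."""

    retained_loci: list
    excluded_loci: dict = field(default_factory=dict)  # locus -> reason
    retained_individuals: list = field(default_factory=list)
    excluded_individuals: list = field(default_factory=list)
    hwe_pvalues: pd.DataFrame | None = None  # collections x loci
    ld_table: pd.DataFrame | None = None

    def counts(self) -> dict:
        reasons: dict = {}
        for r in self.excluded_loci.values():
            reasons[r] = reasons.get(r, 0) + 1
        return {
            "retained": len(self.retained_loci),
            "excluded": reasons,
            "individuals_retained": len(self.retained_individuals),
            "individuals_excluded": len(self.excluded_individuals),
        }


def depth_missingness_filter(
    loci: list[MicrohapLocus],
    gm: GenotypeMatrix,
    min_mean_depth: float = 20.0,
    max_ind_missing: float = 0.25,
) -> FilterReport:
    """Discard low-coverage loci, then high-missingness individuals.

    A locus is excluded when its mean depth is strictly below
    ``min_mean_depth`` (depth exactly at the threshold is retained).  An
    individual is dropped when its missing fraction over the retained loci
    is ``>= max_ind_missing`` (strictly-less-than retains).
    """
    by_id = {l.locus_id: l for l in loci}
    unknown = [l for l in gm.loci if l not in by_id]
    if unknown:
        raise ValueError(f"loci absent from metadata: {unknown[:5]}")
    no_depth = [l.locus_id for l in loci if l.mean_depth is None]
    if no_depth:
        raise ValueError(f"loci missing depth metadata: {no_depth[:5]}")

    excluded = {
        lid: "depth"
        for lid in gm.loci
        if by_id[lid].mean_depth < min_mean_depth
    }
    retained_loci = [l for l in gm.loci if l not in excluded]

    sub = gm.subset_loci(retained_loci) if retained_loci else gm.subset_loci([])
    miss = sub.individual_missingness() if retained_loci else np.zeros(gm.n_individuals)
    keep = miss < max_ind_missing
    return FilterReport(
        retained_loci=retained_loci,
        excluded_loci=excluded,
        retained_individuals=[i for i, k in zip(gm.individuals, keep) if k],
        excluded_individuals=[i for i, k in zip(gm.individuals, keep) if not k],
    )


def _hwe_pvalue(calls: np.ndarray, n_alleles: int) -> float:
    """Chi-square goodness-of-fit p-value for one locus in one collection.

    ``calls`` is an (n, 2) slice of allele indices; missing calls are
    excluded.  Genotype classes are all unordered allele pairs; expected
    counts come from the collection's allele frequencies.  Collections
    with no called genotypes, or monomorphic ones, cannot reject (p = 1).
    """
    called = calls[calls[:, 0] != MISSING]
    n = len(called)
    if n == 0:
        return 1.0
    counts = np.bincount(called.ravel(), minlength=n_alleles).astype(float)
    p = counts / counts.sum()
    seg = np.flatnonzero(p > 0)
    k = len(seg)
    if k < 2:
        return 1.0
    # observed genotype class counts (unordered pairs over segregating alleles)
    classes = [(a, b) for i, a in enumerate(seg) for b in seg[i:]]
    obs = np.zeros(len(classes))
    index = {cl: i for i, cl in enumerate(classes)}
    for a, b in called:
        obs[index[(min(a, b), max(a, b))]] += 1
    exp = np.array(
        [n * (p[a] ** 2 if a == b else 2 * p[a] * p[b]) for a, b in classes]
    )
    df = len(classes) - 1 - (k - 1)
    if df <= 0:
        return 1.0
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(stat, df))


def hwe_filter(
    gm: GenotypeMatrix, alpha: float = 0.05, correction: str = "bonferroni"
) -> FilterReport:
    """Exclude loci out of Hardy–Weinberg equilibrium in ALL collections.

    Each collection is tested independently with the classic chi-square
    test on genotype classes; the multiple-testing correction is applied
    across loci within each collection.  A locus is excluded only when the
    corrected test is significant in every collection.
    """
    labels = gm.collection_labels()
    if not labels:
        raise ValueError("genotype matrix has no collections")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    threshold = alpha / gm.n_loci if correction == "bonferroni" else alpha

    groups = {lab: [i for i, c in enumerate(gm.collections) if c == lab] for lab in labels}
    pvals = np.ones((len(labels), gm.n_loci))
    for gi, lab in enumerate(labels):
        rows = groups[lab]
        for j in range(gm.n_loci):
            pvals[gi, j] = _hwe_pvalue(gm.calls[rows, j], len(gm.alleles[j]))

    significant_all = (pvals < threshold).all(axis=0)
    excluded = {gm.loci[j]: "HWE" for j in np.flatnonzero(significant_all)}
    return FilterReport(
        retained_loci=[l for l in gm.loci if l not in excluded],
        excluded_loci=excluded,
        retained_individuals=list(gm.individuals),
        hwe_pvalues=pd.DataFrame(pvals, index=labels, columns=gm.loci),
    )


def _snp_dosages(gm: GenotypeMatrix, rng) -> np.ndarray:
    """One randomly selected SNP per locus, as a diploid dosage matrix.

    Haplotype alleles are strings over the locus' SNP positions; a SNP is
    one character position.  The dosage counts copies of the reference
    (first sorted) base at the selected position; missing calls are NaN.
    """
    D = np.full((gm.n_individuals, gm.n_loci), np.nan)
    for j, cat in enumerate(gm.alleles):
        n_snps = len(cat[0]) if cat else 0
        pos = int(rng.integers(0, n_snps)) if n_snps > 0 else 0
        bases = sorted({h[pos] for h in cat}) if cat else []
        ref = bases[0] if bases else "A"
        col = gm.calls[:, j, :]
        called = col[:, 0] != MISSING
        base_is_ref = np.array([h[pos] == ref for h in cat]) if cat else np.array([])
        for i in np.flatnonzero(called):
            a, b = col[i]
            D[i, j] = float(base_is_ref[a]) + float(base_is_ref[b])
    return D


def _pairwise_r2(D: np.ndarray):
    """Squared pairwise-complete Pearson correlation of dosage columns.

    Returns ``(r2, n)`` where ``n`` is the per-pair count of individuals
    called at both loci.  Constant columns give NaN.
    """
    M = (~np.isnan(D)).astype(float)
    Z = np.where(np.isnan(D), 0.0, D)
    n = M.T @ M
    sxy = Z.T @ Z
    sx = Z.T @ M  # sum of x over rows where y called
    sxx = (Z**2).T @ M
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        r2 = cov**2 / (varx * varx.T)
    return r2, n


def ld_filter(
    gm: GenotypeMatrix,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    seed: int = 0,
) -> FilterReport:
    """Remove loci in significant pairwise linkage disequilibrium.

    One SNP per locus is selected with the given seed; r^2 is the squared
    Pearson correlation of diploid dosages over individuals called at both
    loci (a composite, phase-free measure); significance is n*r^2 against
    chi-square(1) with the correction applied over all pairs.  From each
    significant pair, the locus with higher missingness is removed (ties:
    lexicographically larger id), cascading until no significant pair
    remains among retained loci.
    """
    if gm.n_loci < 2:
        return FilterReport(
            retained_loci=list(gm.loci), retained_individuals=list(gm.individuals)
        )
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    rng = np.random.default_rng(seed)
    D = _snp_dosages(gm, rng)
    r2, n = _pairwise_r2(D)
    L = gm.n_loci
    n_pairs = L * (L - 1) // 2
    threshold = alpha / n_pairs if correction == "bonferroni" else alpha

    iu = np.triu_indices(L, k=1)
    stat = n[iu] * r2[iu]
    with np.errstate(invalid="ignore"):
        pvals = stats.chi2.sf(stat, df=1)
    pvals = np.where(np.isnan(stat), 1.0, pvals)
    sig = pvals < threshold

    table = pd.DataFrame(
        {
            "locus_a": [gm.loci[i] for i in iu[0]],
            "locus_b": [gm.loci[j] for j in iu[1]],
            "r2": r2[iu],
            "n": n[iu].astype(int),
            "p": pvals,
            "significant": sig,
        }
    )

    missingness = dict(zip(gm.loci, gm.missing_mask().mean(axis=0)))
    removed: set = set()
    sig_pairs = table[table["significant"]].sort_values("p", kind="stable")
    changed = True
    while changed:
        changed = False
        for _, row in sig_pairs.iterrows():
            a, b = row["locus_a"], row["locus_b"]
            if a in removed or b in removed:
                continue
            key = lambda l: (missingness[l], l)
            drop = max((a, b), key=key)
            removed.add(drop)
            changed = True
    return FilterReport(
        retained_loci=[l for l in gm.loci if l not in removed],
        excluded_loci={l: "LD" for l in removed},
        retained_individuals=list(gm.individuals),
        ld_table=table,
    )


def apply_filters(
    loci: list[MicrohapLocus],
    gm: GenotypeMatrix,
    min_mean_depth: float = 20.0,
    max_ind_missing: float = 0.25,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    seed: int = 0,
):
    """Run the full pre-panel chain: depth/missingness -> HWE -> LD.

    Returns ``(report, filtered_gm, filtered_loci)``; the combined report
    carries every exclusion with its reason.  Applying the chain to its
    own output changes nothing (idempotence).
    """
    r1 = depth_missingness_filter(loci, gm, min_mean_depth, max_ind_missing)
    gm1 = gm.subset_individuals(r1.retained_individuals).subset_loci(r1.retained_loci)
    r2 = hwe_filter(gm1, alpha=alpha, correction=correction)
    gm2 = gm1.subset_loci(r2.retained_loci)
    r3 = ld_filter(gm2, alpha=alpha, correction=correction, seed=seed)
    gm3 = gm2.subset_loci(r3.retained_loci)

    excluded = dict(r1.excluded_loci)
    excluded.update(r2.excluded_loci)
    excluded.update(r3.excluded_loci)
    report = FilterReport(
        retained_loci=list(gm3.loci),
        excluded_loci=excluded,
        retained_individuals=list(gm3.individuals),
        excluded_individuals=r1.excluded_individuals,
        hwe_pvalues=r2.hwe_pvalues,
        ld_table=r3.ld_table,
    )
    by_id = {l.locus_id: l for l in loci}
    return report, gm3, [by_id[l] for l in gm3.loci]
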