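"""Score candidate 500-locus panels against the full temporal dataset.

The selection strategy: rank loci by temporal Weir–Cockerham F_ST
(collections-as-populations), build candidate subsets mixing top-F_ST and
randomly drawn loci (e.g. Fst500, Rdm500, Fst250+Rdm250), and pick the
subset whose discriminant-analysis (DAPC) year centroids sit closest — in
mean Euclidean distance — to the centroids obtained from the complete
dataset.  Diversity summaries (rarefied allelic richness, observed and
expected heterozygosity, F_IS) and permutation-tested pairwise F_ST
support the comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.special import gammaln

from .fst import (
    fis_from_components,
    group_counts,
    individual_allele_arrays,
    theta_from_components,
    theta_per_locus,
    wc_components,
)
from .model import MISSING, GenotypeMatrix

__all__ = [
    "LocusFst",
    "SubsetScheme",
    "DiversityTable",
    "PairwiseFst",
    "DapcResult",
    "SelectionReport",
    "per_locus_temporal_fst",
    "build_subsets",
    "diversity_stats",
    "pairwise_fst",
    "dapc",
    "compare_subsets",
    "DEFAULT_SCHEMES",
]


@dataclass(frozen=True)
class LocusFst:
    locus_id: str
    theta: float  # NaN when undefined (monomorphic overall)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.theta)


@dataclass(frozen=True)
class SubsetScheme:
    """A panel-subset recipe: top-F_ST loci plus a random complement."""

    name: str
    n_top_fst: int
    n_random: int

    @property
    def total(self) -> int:
        return self.n_top_fst + self.n_random


#: The five 500-locus schemes compared in the workflow.
DEFAULT_SCHEMES = (
    SubsetScheme("Fst500", 500, 0),
    SubsetScheme("Rdm500", 0, 500),
    SubsetScheme("Fst350+Rdm150", 350, 150),
    SubsetScheme("Fst250+Rdm250", 250, 250),
    SubsetScheme("Fst150+Rdm350", 150, 350),
)


def per_locus_temporal_fst(gm: GenotypeMatrix) -> list[LocusFst]:
    """Per-locus multi-allelic theta with collections as populations."""
    if len(gm.collection_labels()) < 2:
        raise ValueError("temporal F_ST needs >= 2 collections")
    thetas = theta_per_locus(gm)
    return [LocusFst(l, float(t)) for l, t in zip(gm.loci, thetas)]


def build_subsets(
    fst: list[LocusFst], schemes, seed: int = 0
) -> dict[str, list[str]]:
    """Per-scheme locus id lists: top-n by theta plus a seeded random rest.

    Undefined-theta loci are excluded from the top ranking (they can still
    be drawn randomly); ties break by locus id; within a scheme the random
    complement is drawn without replacement from loci not already selected
    for that scheme's top block.
    """
    rng = np.random.default_rng(seed)
    defined = sorted(
        (f for f in fst if f.defined), key=lambda f: (-f.theta, f.locus_id)
    )
    all_ids = [f.locus_id for f in fst]
    out: dict[str, list[str]] = {}
    for scheme in schemes:
        if scheme.total > len(all_ids):
            raise ValueError(
                f"{scheme.name}: wants {scheme.total} loci, only {len(all_ids)} available"
            )
        if scheme.n_top_fst > len(defined):
            raise ValueError(f"{scheme.name}: not enough loci with defined theta")
        top = [f.locus_id for f in defined[: scheme.n_top_fst]]
        pool = [l for l in all_ids if l not in set(top)]
        random_part = list(rng.choice(pool, size=scheme.n_random, replace=False))
        out[scheme.name] = top + random_part
    return out


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

@dataclass
class DiversityTable:
    """Per-collection diversity summary with bootstrap CIs over loci."""

    table: pd.DataFrame  # index: collection; columns: n, A_R, H_O, H_E, F_IS, CIs
    rarefaction_g: int


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Exact hypergeometric expectation of distinct alleles in g copies."""
    counts = counts[counts > 0]
    N = counts.sum()
    if N < g:
        return np.nan
    miss = np.zeros(len(counts))
    ok = (N - counts) >= g
    miss[ok] = np.exp(_log_comb(N - counts[ok], g) - _log_comb(N, g))
    return float((1.0 - miss).sum())


def diversity_stats(
    gm: GenotypeMatrix,
    rarefaction_g="auto",
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> DiversityTable:
    """A_R, H_O, H_E and F_IS per collection, with bootstrap-over-loci CIs.

    H_E is Nei's unbiased expected heterozygosity (2n/(2n-1) correction),
    H_O the observed heterozygote fraction, F_IS the ratio-of-sums
    1 - sum(H_O)/sum(H_E) over polymorphic loci (monomorphic loci carry no
    inbreeding information and are excluded), and A_R the exact
    hypergeometric rarefaction to ``g`` gene copies (``auto``: twice the
    smallest per-collection-per-locus called-genotype count).  Loci with
    fewer than ``g`` copies in a collection are skipped for A_R.
    """
    labels = gm.collection_labels()
    rng = np.random.default_rng(seed)
    calls = gm.calls
    groups = {lab: [i for i, c in enumerate(gm.collections) if c == lab] for lab in labels}

    # per collection x locus primitives
    n_called = np.zeros((len(labels), gm.n_loci), dtype=int)
    ho = np.full((len(labels), gm.n_loci), np.nan)
    he = np.full((len(labels), gm.n_loci), np.nan)
    counts_by = {}
    for gi, lab in enumerate(labels):
        rows = np.array(groups[lab])
        sub = calls[rows]
        called = sub[:, :, 0] != MISSING
        n_called[gi] = called.sum(axis=0)
        for j in range(gm.n_loci):
            cj = sub[called[:, j], j]
            n = len(cj)
            if n == 0:
                continue
            ho[gi, j] = float((cj[:, 0] != cj[:, 1]).mean())
            cnt = np.bincount(cj.ravel(), minlength=len(gm.alleles[j])).astype(float)
            p = cnt / cnt.sum()
            he[gi, j] = (2 * n / (2 * n - 1)) * (1.0 - float((p**2).sum()))
            counts_by[(gi, j)] = cnt

    if rarefaction_g == "auto":
        pos = n_called[n_called > 0]
        g = 2 * int(pos.min()) if pos.size else 2
    else:
        g = int(rarefaction_g)

    ar = np.full((len(labels), gm.n_loci), np.nan)
    for (gi, j), cnt in counts_by.items():
        ar[gi, j] = _rarefied_richness(cnt, g)

    poly = he > 1e-12

    def _collect(gi, locus_idx):
        sel_ho = ho[gi, locus_idx]
        sel_he = he[gi, locus_idx]
        sel_ar = ar[gi, locus_idx]
        sel_poly = poly[gi, locus_idx]
        res = {
            "H_O": np.nanmean(sel_ho),
            "H_E": np.nanmean(sel_he),
            "A_R": np.nanmean(sel_ar),
        }
        ho_p, he_p = sel_ho[sel_poly], sel_he[sel_poly]
        res["F_IS"] = (
            1.0 - np.nansum(ho_p) / np.nansum(he_p) if np.nansum(he_p) > 0 else np.nan
        )
        return res

    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    all_idx = np.arange(gm.n_loci)
    for gi, lab in enumerate(labels):
        point = _collect(gi, all_idx)
        boots = {k: [] for k in point}
        for _ in range(n_boot):
            bidx = rng.integers(0, gm.n_loci, size=gm.n_loci)
            bs = _collect(gi, bidx)
            for k, v in bs.items():
                boots[k].append(v)
        row = {
            "collection": lab,
            "n": len(groups[lab]),
            "n_polymorphic": int(poly[gi].sum()),
        }
        for k, v in point.items():
            row[k] = v
            arr = np.array(boots[k], dtype=float)
            if np.isnan(arr).all():
                row[f"{k}_lo"] = row[f"{k}_hi"] = float("nan")
            else:
                row[f"{k}_lo"] = float(np.nanquantile(arr, lo_q))
                row[f"{k}_hi"] = float(np.nanquantile(arr, hi_q))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("collection")
    return DiversityTable(table, g)


# ---------------------------------------------------------------------------
# pairwise F_ST with permutations
# ---------------------------------------------------------------------------

@dataclass
class PairwiseFst:
    theta: pd.DataFrame  # symmetric matrix, NaN diagonal
    pvalues: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame


def _pair_theta_and_perms(X, H, C, n1, n_perm, rng, chunk=500):
    """Observed multilocus theta for a 2-collection split + permutation nulls.

    Individuals 0..n1-1 belong to collection 1.  Returns (theta_hat,
    perm_thetas, per-locus components (a_l, abc_l) for bootstrapping).
    """
    n = X.shape[0]
    groups = np.zeros(n, dtype=int)
    groups[n1:] = 1
    AC, HC, N = group_counts(X, H, C, groups, n_groups=2)
    a, b, c = wc_components(AC, HC, N)
    theta_hat = float(theta_from_components(a, b, c))
    a_l = np.nansum(a, axis=-1)
    abc_l = np.nansum(a + b + c, axis=-1)

    perm_thetas = np.empty(n_perm)
    done = 0
    ACt = AC.sum(axis=0)
    HCt = HC.sum(axis=0)
    Nt = N.sum(axis=0)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        G = np.zeros((m, n))
        for k in range(m):
            idx = rng.permutation(n)[:n1]
            G[k, idx] = 1.0
        AC1 = np.einsum("pn,nla->pla", G, X)
        HC1 = np.einsum("pn,nla->pla", G, H)
        N1 = G @ C
        ACp = np.stack([AC1, ACt[None] - AC1], axis=1)
        HCp = np.stack([HC1, HCt[None] - HC1], axis=1)
        Np = np.stack([N1, Nt[None] - N1], axis=1)
        ap, bp, cp = wc_components(ACp, HCp, Np)
        perm_thetas[done : done + m] = theta_from_components(ap, bp, cp)
        done += m
    return theta_hat, perm_thetas, a_l, abc_l


def pairwise_fst(
    gm: GenotypeMatrix,
    n_perm: int = 10_000,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> PairwiseFst:
    """Multilocus theta for every collection pair, with permutation
    p-values (one-sided, theta* >= theta_hat, +1/(n+1) correction) and
    bootstrap-over-loci CIs.  Pairs with fewer than two individuals on
    either side are left undefined.
    """
    labels = gm.collection_labels()
    if len(labels) < 2:
        raise ValueError("pairwise F_ST needs >= 2 collections")
    rng = np.random.default_rng(seed)
    X, H, C = individual_allele_arrays(gm)
    rows_by = {lab: [i for i, c in enumerate(gm.collections) if c == lab] for lab in labels}

    k = len(labels)
    mats = {
        name: pd.DataFrame(np.full((k, k), np.nan), index=labels, columns=labels)
        for name in ("theta", "p", "lo", "hi")
    }
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    for i in range(k):
        for j in range(i + 1, k):
            r1, r2 = rows_by[labels[i]], rows_by[labels[j]]
            if len(r1) < 2 or len(r2) < 2:
                continue
            idx = np.array(r1 + r2)
            th, perms, a_l, abc_l = _pair_theta_and_perms(
                X[idx], H[idx], C[idx], len(r1), n_perm, rng
            )
            p = (1.0 + np.sum(perms >= th)) / (n_perm + 1.0)
            L = len(a_l)
            bidx = rng.integers(0, L, size=(n_boot, L))
            with np.errstate(divide="ignore", invalid="ignore"):
                boots = np.nansum(a_l[bidx], axis=1) / np.nansum(abc_l[bidx], axis=1)
            mats["theta"].iloc[i, j] = mats["theta"].iloc[j, i] = th
            mats["p"].iloc[i, j] = mats["p"].iloc[j, i] = p
            mats["lo"].iloc[i, j] = mats["lo"].iloc[j, i] = np.nanquantile(boots, lo_q)
            mats["hi"].iloc[i, j] = mats["hi"].iloc[j, i] = np.nanquantile(boots, hi_q)
    return PairwiseFst(mats["theta"], mats["p"], mats["lo"], mats["hi"])


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcResult:
    centroids: pd.DataFrame  # groups x discriminant axes
    var_explained: np.ndarray
    n_pc: int
    a_scores: dict = field(default_factory=dict)  # n_pc -> a-score trace


def _dosage_table(gm: GenotypeMatrix) -> np.ndarray:
    """Per-allele dosage columns (n_ind x total alleles), NaN when missing."""
    cols = []
    for j, cat in enumerate(gm.alleles):
        col = gm.calls[:, j, :]
        called = col[:, 0] != MISSING
        for a in range(len(cat)):
            d = np.where(
                called, (col[:, 0] == a).astype(float) + (col[:, 1] == a), np.nan
            )
            cols.append(d)
    return np.column_stack(cols) if cols else np.empty((gm.n_individuals, 0))


def _impute_within_group(D: np.ndarray, groups: np.ndarray, how: str, seed: int):
    D = D.copy()
    if how == "mean":
        for g in np.unique(groups):
            rows = groups == g
            block = D[rows]
            mu = np.nanmean(block, axis=0)
            mu = np.where(np.isnan(mu), np.nanmean(D, axis=0), mu)
            mu = np.where(np.isnan(mu), 0.0, mu)
            inds = np.where(np.isnan(block))
            block[inds] = mu[inds[1]]
            D[rows] = block
    elif how == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        # regression-forest imputation within group: predict each column
        # with missing values from the mean-imputed remaining columns
        D0 = _impute_within_group(D, groups, "mean", seed)
        for g in np.unique(groups):
            rows = np.flatnonzero(groups == g)
            block = D[rows]
            for col in np.flatnonzero(np.isnan(block).any(axis=0)):
                miss = np.isnan(block[:, col])
                if miss.all() or (~miss).sum() < 3:
                    continue
                feats = np.delete(D0[rows], col, axis=1)
                rf = RandomForestRegressor(n_estimators=100, random_state=seed)
                rf.fit(feats[~miss], block[~miss, col])
                block[miss, col] = rf.predict(feats[miss])
            D[rows] = block
        # any column still missing falls back to group mean
        D = np.where(np.isnan(D), D0, D)
    else:
        raise ValueError(f"unknown imputation {how!r}")
    return D


def _fit_lda(scores, groups, n_df):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    n_df = min(n_df, len(np.unique(groups)) - 1, scores.shape[1])
    lda = LinearDiscriminantAnalysis(n_components=n_df)
    lda.fit(scores, groups)
    return lda


def dapc(
    gm: GenotypeMatrix,
    impute: str = "mean",
    n_pc="a-score",
    n_df: int = 2,
    seed: int = 0,
    a_score_perms: int = 10,
    a_score_grid=None,
) -> DapcResult:
    """Discriminant analysis of principal components on allele dosages.

    Genotypes become a per-allele dosage table; missing values are imputed
    within collection (mean by default, a regression-forest option
    otherwise); PCA runs without scaling; linear discriminant analysis on
    the retained PCs yields ``n_df`` axes.  ``n_pc`` may be a fixed count
    or ``"a-score"``: the mean over groups of (correct reassignment minus
    its label-permuted expectation), maximized over a candidate grid.
    Centroids are group means in discriminant space.
    """
    labels = gm.collection_labels()
    if len(labels) < 2:
        raise ValueError("DAPC needs >= 2 collections")
    counts = {lab: gm.collections.count(lab) for lab in labels}
    small = [lab for lab, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"collections with < 3 individuals: {small}")

    rng = np.random.default_rng(seed)
    index = {lab: i for i, lab in enumerate(labels)}
    groups = np.array([index[c] for c in gm.collections])
    D = _impute_within_group(_dosage_table(gm), groups, impute, seed)

    Dc = D - D.mean(axis=0)
    U, S, _ = np.linalg.svd(Dc, full_matrices=False)
    scores_all = U * S
    max_pc = int(min(50, gm.n_individuals - len(labels), scores_all.shape[1]))

    a_scores: dict[int, float] = {}
    if n_pc == "a-score":
        grid = a_score_grid or range(1, max_pc + 1)
        best, best_score = 1, -np.inf
        for npc in grid:
            sc = scores_all[:, :npc]
            lda = _fit_lda(sc, groups, n_df)
            pred = lda.predict(sc)
            obs = np.array(
                [np.mean(pred[groups == g] == g) for g in range(len(labels))]
            )
            null = np.zeros(len(labels))
            for _ in range(a_score_perms):
                perm = rng.permutation(groups)
                lda_p = _fit_lda(sc, perm, n_df)
                pred_p = lda_p.predict(sc)
                null += np.array(
                    [np.mean(pred_p[perm == g] == g) for g in range(len(labels))]
                )
            null /= a_score_perms
            a_scores[npc] = float(np.mean(obs - null))
            if a_scores[npc] > best_score:
                best, best_score = npc, a_scores[npc]
        n_pc_used = best
    else:
        n_pc_used = int(min(n_pc, max_pc))

    sc = scores_all[:, :n_pc_used]
    lda = _fit_lda(sc, groups, n_df)
    df_coords = lda.transform(sc)
    var = getattr(lda, "explained_variance_ratio_", np.array([]))
    cent = np.vstack([df_coords[groups == g].mean(axis=0) for g in range(len(labels))])
    centroids = pd.DataFrame(
        cent, index=labels, columns=[f"DF{k + 1}" for k in range(cent.shape[1])]
    )
    return DapcResult(centroids, np.asarray(var), n_pc_used, a_scores)


# ---------------------------------------------------------------------------
# subset comparison
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    distances: pd.DataFrame  # schemes x groups
    summary: pd.DataFrame  # mean/min/max distance per scheme, ranked
    chosen: str
    diversity: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)


def _align(A: np.ndarray, B: np.ndarray, alignment: str) -> np.ndarray:
    """Map subset centroids B into the complete-dataset space of A."""
    if alignment == "none":
        return B
    if alignment != "procrustes":
        raise ValueError(f"unknown alignment {alignment!r}")
    A_mean, B_mean = A.mean(axis=0), B.mean(axis=0)
    R, _ = orthogonal_procrustes(B - B_mean, A - A_mean)
    return (B - B_mean) @ R + A_mean


def compare_subsets(
    complete: DapcResult, subsets: dict[str, DapcResult], alignment: str = "procrustes"
) -> SelectionReport:
    """Euclidean distances of subset DAPC centroids to the complete ones.

    Each subset's centroid set is aligned to the complete-dataset space
    (orthogonal Procrustes: rotation+reflection, no scaling — DAPC axes
    from independent fits are arbitrary up to rotation/sign; ``none``
    compares raw coordinates).  Schemes are ranked by mean distance
    ascending; the winner has minimal mean distance.
    """
    groups = list(complete.centroids.index)
    A = complete.centroids.to_numpy()
    rows = {}
    for name, res in subsets.items():
        if list(res.centroids.index) != groups:
            raise ValueError(f"{name}: group mismatch with complete dataset")
        B = _align(A, res.centroids.to_numpy(), alignment)
        rows[name] = np.linalg.norm(B - A, axis=1)
    distances = pd.DataFrame(rows, index=groups).T
    summary = pd.DataFrame(
        {
            "mean_d": distances.mean(axis=1),
            "min_d": distances.min(axis=1),
            "max_d": distances.max(axis=1),
        }
    ).sort_values("mean_d", kind="stable")
    return SelectionReport(distances, summary, chosen=summary.index[0])
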