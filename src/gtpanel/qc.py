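"""Per-round GT-seq multiplex QC.

A sequencing round of a multiplexed amplicon library is assessed by:

* classifying every read as on-target (leads with a panel locus' forward
  primer and contains one of its probes), a primer interaction (leads
  with the forward primer of pair i but contains a primer of a different
  pair j — a chimeric amplification artifact), or unknown;
* counting allele-bearing reads per individual via the 17 nt probes and
  calling microhaplotype genotypes by maximum likelihood under a
  multinomial read-count model;
* measuring per-SNP genotype concordance against a reference dataset;
* recommending removals: pairs driving the interaction load (with the
  duo rule — two pairs that mostly interact with each other lose only the
  lower-F_ST member), over/under-amplifying loci, and SNPs below the
  accuracy threshold (a locus survives if another of its SNPs passes);
* the stopping rule: optimization ends once interactions are below one
  third of reads AND mean genotype accuracy exceeds 95%.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import product as iproduct

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, IUPAC_REVERSE, PanelEntry, revcomp

__all__ = [
    "ReadClassSummary",
    "AlleleCounts",
    "RoundAssessment",
    "RemovalPlan",
    "classify_reads",
    "count_alleles",
    "call_genotypes_ml",
    "genotype_concordance",
    "flag_representation",
    "recommend_removals",
    "assess_round",
    "assign_sex",
    "run_optimization",
]

UNRESOLVED = "UNRESOLVED"


# ---------------------------------------------------------------------------
# read input handling
# ---------------------------------------------------------------------------

def _iter_reads(source):
    """Yield (individual, sequence) from a FASTQ path, ReadPool, or list.

    FASTQ read names carry the individual as the prefix before ':'.
    """
    if hasattr(source, "reads"):  # ReadPool
        yield from source.reads
        return
    if isinstance(source, (list, tuple)):
        yield from source
        return
    with open(source) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            name = header[1:].strip().split()[0]
            ind = name.rsplit(":", 1)[0]
            yield ind, seq


def _iupac_regex(probe: str) -> str:
    return "".join(
        b if len(IUPAC_REVERSE.get(b, b)) == 1 else "[" + "".join(sorted(IUPAC_REVERSE[b])) + "]"
        for b in probe
    )


class _PanelIndex:
    """Compiled lookup structures for one active panel."""

    def __init__(self, panel: list[PanelEntry]):
        self.entries = [e for e in panel if e.active]
        if not self.entries:
            raise ValueError("no active panel entries")
        for e in self.entries:
            if e.primers is None:
                raise ValueError(f"{e.locus_id}: no primers")
        fwd = [(e.primers.fwd_seq, e.locus_id) for e in self.entries]
        # forward primers must be collision-free prefixes
        for i, (s1, l1) in enumerate(fwd):
            for s2, l2 in fwd[i + 1 :]:
                if s1.startswith(s2) or s2.startswith(s1):
                    raise ValueError(
                        f"forward primer prefix collision between {l1} and {l2}"
                    )
        self.by_len: dict[int, dict[str, str]] = {}
        for seq, lid in fwd:
            self.by_len.setdefault(len(seq), {})[seq] = lid
        self.by_id = {e.locus_id: e for e in self.entries}

        # probe regexes per locus (any allele of any SNP)
        self.probe_re = {}
        for e in self.entries:
            pats = [
                _iupac_regex(p) for rec in e.probes for p in rec.probes
            ]
            self.probe_re[e.locus_id] = re.compile("|".join(pats)) if pats else None

        # one alternation over all primer sequences (both orientations),
        # mapping each variant back to its owner locus
        variants: dict[str, str] = {}
        for e in self.entries:
            for s in (
                e.primers.fwd_seq,
                e.primers.rev_seq,
                revcomp(e.primers.fwd_seq),
                revcomp(e.primers.rev_seq),
            ):
                variants.setdefault(s, e.locus_id)
        self.variant_owner = variants
        alts = sorted(variants, key=len, reverse=True)
        self.primer_re = re.compile("|".join(re.escape(s) for s in alts))

    def lead_locus(self, read: str):
        for ln, table in self.by_len.items():
            lid = table.get(read[:ln])
            if lid is not None:
                return lid
        return None


@dataclass
class ReadClassSummary:
    """Read-class accounting for one sequencing round."""

    total: int
    on_target: dict  # locus -> count (every active locus present)
    interactions: dict  # (lead locus, partner locus) -> count
    unknown: int

    @property
    def n_interactions(self) -> int:
        return sum(self.interactions.values())

    @property
    def proportion_interactions(self) -> float:
        return self.n_interactions / self.total if self.total else 0.0

    def interaction_involvement(self) -> dict:
        """Per-locus count of interaction reads the locus participates in."""
        inv: dict = {}
        for (i, j), n in self.interactions.items():
            inv[i] = inv.get(i, 0) + n
            inv[j] = inv.get(j, 0) + n
        return inv


def classify_reads(source, panel: list[PanelEntry], return_labels: bool = False):
    """Classify every read of a round against the active panel.

    A read whose first bases exactly match the forward primer of locus i
    and which contains any probe of i is on-target(i); if it instead
    contains a primer sequence (fwd/rev, either orientation) of a
    different pair j it is an interaction(i, j); otherwise — including
    reads matching no forward primer at all — it is unknown.
    """
    idx = _PanelIndex(panel)
    on_target = {e.locus_id: 0 for e in idx.entries}
    interactions: dict = {}
    unknown = 0
    total = 0
    labels = [] if return_labels else None

    for _ind, read in _iter_reads(source):
        total += 1
        label = ("unknown",)
        lead = idx.lead_locus(read)
        if lead is not None:
            pr = idx.probe_re[lead]
            if pr is not None and pr.search(read):
                on_target[lead] += 1
                label = ("on_target", lead)
            else:
                partner = None
                for m in idx.primer_re.finditer(read):
                    owner = idx.variant_owner[m.group(0)]
                    if owner != lead:
                        partner = owner
                        break
                if partner is not None:
                    key = (lead, partner)
                    interactions[key] = interactions.get(key, 0) + 1
                    label = ("interaction", lead, partner)
                else:
                    unknown += 1
        else:
            unknown += 1
        if labels is not None:
            labels.append(label)

    summary = ReadClassSummary(total, on_target, interactions, unknown)
    return (summary, labels) if return_labels else summary


# ---------------------------------------------------------------------------
# allele counting
# ---------------------------------------------------------------------------

@dataclass
class AlleleCounts:
    """Per-individual allele-bearing read counts.

    ``snp_counts[ind][locus][snp_offset][allele]`` and
    ``hap_counts[ind][locus][haplotype]`` are read counts;
    ``depth[ind][locus]`` is the on-target read total.
    """

    snp_counts: dict
    hap_counts: dict
    depth: dict
    individuals: list


def count_alleles(source, panel: list[PanelEntry], individuals=None) -> AlleleCounts:
    """Count allele-bearing reads per individual via probe matching.

    For every on-target read, each SNP of its locus increments the count
    of the allele whose probe matches the read; reads matching no probe at
    a SNP (sequencing error in the window) are uncalled for that SNP.
    Reads called at every SNP also increment the phased haplotype count
    (all SNPs of a locus sit on one 150 bp read, so phase is read
    directly).
    """
    idx = _PanelIndex(panel)
    # per-locus per-SNP per-allele regexes
    allele_re = {
        e.locus_id: [
            {a: re.compile(_iupac_regex(p)) for a, p in zip(rec.alleles, rec.probes)}
            for rec in e.probes
        ]
        for e in idx.entries
    }

    snp_counts: dict = {}
    hap_counts: dict = {}
    depth: dict = {}
    seen_inds: dict = {}
    if individuals is not None:
        allowed = set(individuals)
    else:
        allowed = None

    for ind, read in _iter_reads(source):
        if allowed is not None and ind not in allowed:
            raise KeyError(f"individual {ind} absent from the provided map")
        seen_inds.setdefault(ind, None)
        lead = idx.lead_locus(read)
        if lead is None:
            continue
        pr = idx.probe_re[lead]
        if pr is None or not pr.search(read):
            continue
        d_ind = depth.setdefault(ind, {})
        d_ind[lead] = d_ind.get(lead, 0) + 1
        sc = snp_counts.setdefault(ind, {}).setdefault(lead, {})
        entry = idx.by_id[lead]
        calls = []
        for rec, res in zip(entry.probes, allele_re[lead]):
            table = sc.setdefault(rec.snp_offset, {a: 0 for a in rec.alleles})
            hit = None
            for allele, rx in res.items():
                if rx.search(read):
                    hit = allele
                    break
            if hit is not None:
                table[hit] += 1
            calls.append(hit)
        if all(c is not None for c in calls):
            hap = "".join(calls)
            hc = hap_counts.setdefault(ind, {}).setdefault(lead, {})
            hc[hap] = hc.get(hap, 0) + 1

    inds = list(individuals) if individuals is not None else list(seen_inds)
    return AlleleCounts(snp_counts, hap_counts, depth, inds)


# ---------------------------------------------------------------------------
# maximum-likelihood genotyping
# ---------------------------------------------------------------------------

def _ml_call(counts: np.ndarray, epsilon: float):
    """Argmax unordered allele pair under the multinomial read model.

    Expected allele-read proportions for genotype g over k alleles:
    p_l = (1 - eps) * w_l(g) + eps / k, with w = 1 for the homozygous
    allele, 0.5/0.5 for a heterozygote, 0 otherwise.
    """
    k = len(counts)
    best, best_ll = None, -np.inf
    for i in range(k):
        for j in range(i, k):
            w = np.zeros(k)
            if i == j:
                w[i] = 1.0
            else:
                w[i] = w[j] = 0.5
            p = (1.0 - epsilon) * w + epsilon / k
            ll = float(np.sum(counts * np.log(p)))
            if ll > best_ll:
                best, best_ll = (i, j), ll
    return best, best_ll


def call_genotypes_ml(
    ac: AlleleCounts,
    panel: list[PanelEntry],
    epsilon: float = 0.01,
    min_depth: int = 10,
    collection_map: dict | None = None,
) -> GenotypeMatrix:
    """Call microhaplotype genotypes from allele read counts.

    The allele catalogue of a locus is the Cartesian product of its SNP
    alleles; read counts per haplotype enter a multinomial likelihood with
    per-read misassignment rate ``epsilon``; individuals with total locus
    depth below ``min_depth`` are missing.
    """
    active = [e for e in panel if e.active]
    loci = [e.locus_id for e in active]
    catalogues = []
    for e in active:
        haps = ["".join(c) for c in iproduct(*(rec.alleles for rec in e.probes))]
        catalogues.append(sorted(haps))

    inds = ac.individuals
    calls = np.full((len(inds), len(loci), 2), MISSING, dtype=np.int16)
    for ii, ind in enumerate(inds):
        for jj, (lid, cat) in enumerate(zip(loci, catalogues)):
            hap_table = ac.hap_counts.get(ind, {}).get(lid, {})
            depth = sum(hap_table.values())
            if depth < min_depth:
                continue
            counts = np.array([hap_table.get(h, 0) for h in cat], dtype=float)
            pair, _ = _ml_call(counts, epsilon)
            calls[ii, jj] = sorted(pair)
    collections = [
        collection_map.get(i, "NA") if collection_map else "NA" for i in inds
    ]
    return GenotypeMatrix(inds, collections, loci, catalogues, calls)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass
class Concordance:
    per_snp: pd.DataFrame  # index snp id; columns accuracy, n_compared
    overall: float
    individuals_used: list


def _snp_genotype(call, cat, snp_index: int):
    if call[0] == MISSING:
        return None
    return tuple(sorted((cat[call[0]][snp_index], cat[call[1]][snp_index])))


def genotype_concordance(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    min_locus_callrate_per_ind: float = 0.70,
) -> Concordance:
    """Per-SNP genotype agreement between two datasets.

    Individuals genotyped for less than ``min_locus_callrate_per_ind`` of
    the shared loci (in either dataset) are excluded; per SNP, accuracy is
    the fraction of matching unordered genotypes among calls present in
    both; the overall figure is the mean over SNPs.
    """
    shared_inds = [i for i in a.individuals if i in set(b.individuals)]
    if not shared_inds:
        raise ValueError("no shared individuals between datasets")
    shared_loci = [l for l in a.loci if l in set(b.loci)]
    if not shared_loci:
        raise ValueError("no shared loci between datasets")

    a_s = a.subset_individuals(shared_inds).subset_loci(shared_loci)
    b_s = b.subset_individuals(shared_inds).subset_loci(shared_loci)
    callrate_a = 1.0 - a_s.individual_missingness()
    callrate_b = 1.0 - b_s.individual_missingness()
    keep = (callrate_a >= min_locus_callrate_per_ind) & (
        callrate_b >= min_locus_callrate_per_ind
    )
    used = [i for i, k in zip(shared_inds, keep) if k]
    a_s = a_s.subset_individuals(used)
    b_s = b_s.subset_individuals(used)

    rows = {}
    for j, lid in enumerate(shared_loci):
        cat_a, cat_b = a_s.alleles[j], b_s.alleles[j]
        # compare only SNP positions both datasets carry (a panel locus may
        # retain fewer SNPs than the discovery dataset)
        n_a = len(cat_a[0]) if cat_a else 0
        n_b = len(cat_b[0]) if cat_b else 0
        n_snps = min(n_a, n_b)
        for s in range(n_snps):
            match = compared = 0
            for ii in range(len(used)):
                ga = _snp_genotype(a_s.calls[ii, j], cat_a, s)
                gb = _snp_genotype(b_s.calls[ii, j], cat_b, s)
                if ga is None or gb is None:
                    continue
                compared += 1
                match += ga == gb
            if compared:
                rows[f"{lid}:{s}"] = {
                    "accuracy": match / compared,
                    "n_compared": compared,
                }
    per_snp = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=["accuracy", "n_compared"])
    overall = float(per_snp["accuracy"].mean()) if len(per_snp) else float("nan")
    return Concordance(per_snp, overall, used)


# ---------------------------------------------------------------------------
# representation and removal recommendations
# ---------------------------------------------------------------------------

def flag_representation(
    rc: ReadClassSummary, over_fold: float = 10.0, under_fold: float = 0.1
):
    """Loci with disproportionally high or low on-target read share.

    The reference is the mean on-target count over panel loci; a locus is
    over-represented above ``over_fold`` times the mean and
    under-represented below ``under_fold`` times it.
    """
    counts = rc.on_target
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no on-target reads")
    mean = total / len(counts)
    over = [l for l, n in counts.items() if n > over_fold * mean]
    under = [l for l, n in counts.items() if n < under_fold * mean]
    return over, under


@dataclass
class RemovalPlan:
    removals: dict  # locus -> reason (interaction | over_amp | under_amp | low_accuracy)
    snps_dropped: list = field(default_factory=list)

    def loci(self) -> list:
        return list(self.removals)


def recommend_removals(
    rc: ReadClassSummary,
    per_locus_fst: dict | None = None,
    snp_accuracy: dict | None = None,
    interaction_share_cutoff: float = 0.90,
    accuracy_cutoff: float = 0.90,
    over_fold: float = 10.0,
    under_fold: float = 0.1,
    protected=(),
) -> RemovalPlan:
    """Recommend primer pairs / loci / SNPs to drop before the next round.

    Interaction pruning walks loci by interaction involvement (descending)
    until the removed set covers ``interaction_share_cutoff`` of all
    interaction reads.  A locus whose interactions are predominantly
    (>50%) with one single partner forms a duo: only the member with the
    lower temporal F_ST is removed (no F_ST available: the member with
    more interactions goes).  SNPs below ``accuracy_cutoff`` are dropped;
    their locus is removed only when no SNP of it passes.  Over- and
    under-represented loci are appended.  ``protected`` loci (e.g. a sex
    marker) are never removed; their duo partner is removed instead.
    """
    per_locus_fst = per_locus_fst or {}
    protected = set(protected)
    removals: dict = {}

    total_int = rc.n_interactions
    if total_int > 0:
        inv = rc.interaction_involvement()
        # partner tallies per locus, orientation-blind
        partners: dict = {}
        for (i, j), n in rc.interactions.items():
            partners.setdefault(i, {})[j] = partners.setdefault(i, {}).get(j, 0) + n
            partners.setdefault(j, {})[i] = partners.setdefault(j, {}).get(i, 0) + n

        def covered() -> int:
            return sum(
                n
                for (i, j), n in rc.interactions.items()
                if i in removals or j in removals
            )

        ranking = sorted(inv, key=lambda l: (-inv[l], l))
        for locus in ranking:
            if covered() / total_int >= interaction_share_cutoff:
                break
            if locus in removals:
                continue
            part = partners.get(locus, {})
            top_partner, top_n = (None, 0)
            for pl, n in sorted(part.items()):
                if n > top_n:
                    top_partner, top_n = pl, n
            target = locus
            if top_partner is not None and top_n > 0.5 * inv[locus]:
                # duo: keep the higher-F_ST member
                t_l, t_p = per_locus_fst.get(locus), per_locus_fst.get(top_partner)
                if t_l is None or t_p is None or math.isnan(t_l) or math.isnan(t_p):
                    target = locus if inv[locus] >= inv.get(top_partner, 0) else top_partner
                else:
                    target = locus if t_l < t_p else top_partner
            if target in protected:
                target = top_partner if target == locus else locus
            if target is None or target in protected or target in removals:
                continue
            removals[target] = "interaction"

    if snp_accuracy:
        by_locus: dict = {}
        for snp_id, acc in snp_accuracy.items():
            lid = snp_id.rsplit(":", 1)[0]
            by_locus.setdefault(lid, []).append((snp_id, acc))
        plan_snps = []
        for lid, snps in by_locus.items():
            failing = [s for s, acc in snps if acc < accuracy_cutoff]
            plan_snps.extend(failing)
            if len(failing) == len(snps) and failing and lid not in protected:
                removals.setdefault(lid, "low_accuracy")
    else:
        plan_snps = []

    try:
        over, under = flag_representation(rc, over_fold, under_fold)
    except ValueError:
        over, under = [], []
    for lid in over:
        if lid not in protected:
            removals.setdefault(lid, "over_amp")
    for lid in under:
        if lid not in protected:
            removals.setdefault(lid, "under_amp")
    return RemovalPlan(removals, plan_snps)


# ---------------------------------------------------------------------------
# stopping rule and sex assignment
# ---------------------------------------------------------------------------

@dataclass
class RoundAssessment:
    proportion_interactions: float
    accuracy: float | None  # None when not estimable (genotyping rate too low)
    stop: bool
    reason: str
    active_loci: int | None = None  # panel size entering the round


def assess_round(rc_or_proportion, accuracy) -> RoundAssessment:
    """Apply the stopping rule to one optimization round.

    Stop when the interaction proportion is below one third AND mean
    genotype accuracy exceeds 0.95; an unavailable accuracy never stops.
    """
    prop = (
        rc_or_proportion.proportion_interactions
        if hasattr(rc_or_proportion, "proportion_interactions")
        else float(rc_or_proportion)
    )
    if accuracy is None or (isinstance(accuracy, float) and math.isnan(accuracy)):
        return RoundAssessment(prop, None, False, "accuracy unavailable")
    if prop < 1.0 / 3.0 and accuracy > 0.95:
        return RoundAssessment(prop, accuracy, True, "criteria met")
    if prop >= 1.0 / 3.0:
        return RoundAssessment(prop, accuracy, False, "interactions >= 1/3")
    return RoundAssessment(prop, accuracy, False, "accuracy <= 0.95")


def assign_sex(gm: GenotypeMatrix, locus_id: str, mapping: dict) -> dict:
    """Look up each individual's two-SNP diplotype in a sex mapping.

    ``mapping`` maps unordered diplotypes — tuples of two haplotype
    strings — to sex labels.  A missing call at the sex locus, or a
    diplotype absent from the mapping, yields ``UNRESOLVED``.
    """
    if not mapping or not all(
        isinstance(k, tuple) and len(k) == 2 for k in mapping
    ):
        raise ValueError("sex mapping must map (hap1, hap2) tuples to labels")
    norm = {tuple(sorted(k)): v for k, v in mapping.items()}
    j = gm.loci.index(locus_id)
    out = {}
    for i, ind in enumerate(gm.individuals):
        call = gm.calls[i, j]
        if call[0] == MISSING:
            out[ind] = UNRESOLVED
            continue
        cat = gm.alleles[j]
        diplo = tuple(sorted((cat[call[0]], cat[call[1]])))
        out[ind] = norm.get(diplo, UNRESOLVED)
    return out


# ---------------------------------------------------------------------------
# the optimization loop
# ---------------------------------------------------------------------------

def run_optimization(
    panel: list[PanelEntry],
    genotypes: GenotypeMatrix,
    read_params,
    per_locus_fst: dict | None = None,
    max_rounds: int = 6,
    epsilon: float = 0.01,
    min_depth: int = 10,
    interaction_share_cutoff: float = 0.90,
    accuracy_cutoff: float = 0.90,
    min_genotyping_rate: float = 0.05,
    protected=(),
    seed: int = 0,
):
    """Iterate simulate -> classify -> genotype -> prune until the stop rule.

    Emulates the wet-lab optimization loop on synthetic reads: each round
    re-simulates the multiplex with the currently active panel (the
    interaction load scales with the remaining pair mass), assesses it,
    and applies the removal recommendations.  Returns
    ``(assessments, panel)`` with per-round :class:`RoundAssessment`.
    """
    from dataclasses import replace as _replace

    from .simulate import simulate_amplicon_reads

    full_ids = [e.locus_id for e in panel if e.active]
    assessments = []
    for rnd in range(max_rounds):
        rp = _replace(read_params, seed=seed + rnd)
        pool = simulate_amplicon_reads(
            [e for e in panel if e.active], genotypes, rp, full_panel_ids=full_ids
        )
        active_entries = [e for e in panel if e.active]
        rc = classify_reads(pool, active_entries)
        ac = count_alleles(pool, active_entries, individuals=genotypes.individuals)
        called = call_genotypes_ml(
            ac, active_entries, epsilon=epsilon, min_depth=min_depth
        )
        genotyping_rate = 1.0 - called.missing_mask().mean() if called.n_loci else 0.0
        if genotyping_rate < min_genotyping_rate:
            accuracy = None
            snp_acc = None
        else:
            conc = genotype_concordance(genotypes, called, min_locus_callrate_per_ind=0.70)
            accuracy = conc.overall
            snp_acc = dict(conc.per_snp["accuracy"]) if len(conc.per_snp) else None
        assessment = assess_round(rc, accuracy)
        assessment.active_loci = len(active_entries)
        assessments.append(assessment)
        if assessment.stop:
            break
        plan = recommend_removals(
            rc,
            per_locus_fst=per_locus_fst,
            snp_accuracy=snp_acc,
            interaction_share_cutoff=interaction_share_cutoff,
            accuracy_cutoff=accuracy_cutoff,
            protected=protected,
        )
        for k, e in enumerate(panel):
            if e.active and e.locus_id in plan.removals:
                panel[k] = e.deactivate(plan.removals[e.locus_id])
    return assessments, panel
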