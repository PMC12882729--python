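"""Synthetic temporal datasets, references and amplicon read pools.

Everything the panel-development workflow consumes can be generated here
with known truth, so every stage is testable without external data:

* :func:`simulate_temporal_genotypes` — multinomial Wright–Fisher drift on
  microhaplotype allele frequencies across a multi-year sampling schedule
  (default: twelve collections spanning 1999–2018 with a two-year
  bottleneck in 2013–2014, ~30 diploid individuals per collection), with
  genotypes drawn from Hardy–Weinberg proportions at the sampled year and
  i.i.d. missingness.
* :func:`simulate_reference_with_loci` — a random reference sequence with
  microhaplotype loci embedded at known coordinates (optionally with a
  duplicated copy, to create a known off-target primer site).
* :func:`simulate_amplicon_reads` — single-end 150 bp read pools for a
  primer/probe panel, mixing on-target reads with chimeric
  primer-interaction reads at a configurable fraction, with per-read truth
  labels.

All generators are seeded; the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    MISSING,
    GenotypeMatrix,
    IUPAC_REVERSE,
    MicrohapLocus,
    PanelEntry,
    PrimerPair,
    SnpSite,
    revcomp,
)

__all__ = [
    "DriftParams",
    "ReadSimParams",
    "TemporalTruth",
    "ReadPool",
    "simulate_temporal_genotypes",
    "simulate_reference_with_loci",
    "simulate_amplicon_reads",
    "embed_loci_for_catalogues",
    "naive_primer_candidates",
    "panel_for_genotypes",
    "simulate_sex_genotypes",
    "DEFAULT_YEARS",
]

_BASES = np.array(list("ACGT"))

#: Default sampling schedule: twelve collections over twenty years.
DEFAULT_YEARS = (1999, 2000, 2002, 2004, 2006, 2008, 2009, 2010, 2012, 2015, 2017, 2018)


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


@dataclass
class DriftParams:
    """Parameters of the temporal Wright–Fisher genotype simulator.

    The defaults emulate a two-decade monitoring series of a short-lived
    riverine fish: one generation per calendar year, a stable effective
    size of 500 with a two-year bottleneck at Ne=50 (2013–2014), twelve
    sampling years with ~30 diploid individuals each, loci of two to four
    microhaplotype alleles, and ~3% missing calls.
    """

    n_loci: int = 675
    years: tuple = DEFAULT_YEARS
    samples_per_year: int = 30
    base_ne: int = 500
    bottleneck_years: tuple = (2013, 2014)
    bottleneck_ne: int = 50
    generations_per_year: int = 1
    #: probability of a locus having 2, 3 or 4 haplotype alleles
    allele_number_probs: tuple = (0.60, 0.25, 0.15)
    dirichlet_concentration: float = 1.0
    missingness: float = 0.03
    seed: int = 0

    def ne_at(self, year: int) -> int:
        return self.bottleneck_ne if year in self.bottleneck_years else self.base_ne

    def validate(self) -> None:
        if self.base_ne < 1 or self.bottleneck_ne < 1:
            raise ValueError("Ne must be >= 1")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValueError("missingness must be in [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if abs(sum(self.allele_number_probs) - 1.0) > 1e-9:
            raise ValueError("allele_number_probs must sum to 1")
        n = self.samples_per_year
        for y in self.years:
            if n > 2 * self.ne_at(y):
                raise ValueError(f"sample size {n} exceeds 2*Ne at year {y}")


@dataclass
class TemporalTruth:
    """True per-year allele frequencies recorded by the simulator."""

    years: tuple
    loci: list
    alleles: list  # per-locus haplotype catalogues
    freqs: dict  # year -> (n_loci, max_alleles) array, NaN-padded

    def freq(self, year, locus_index: int) -> np.ndarray:
        k = len(self.alleles[locus_index])
        return self.freqs[year][locus_index, :k]


def _haplotype_catalogue(rng, k: int) -> tuple[list[str], list[SnpSite]]:
    """Draw k distinct haplotype strings and the SnpSites they imply.

    Biallelic loci carry one SNP; tri/tetra-allelic loci carry two SNPs
    (microhaplotypes), matching the 2–4 allele range of short amplicons.
    Offsets are assigned later, when the locus is embedded in a sequence.
    """
    n_snps = 1 if k == 2 else 2
    while True:
        site_alleles = []
        for _ in range(n_snps):
            site_alleles.append(list(rng.choice(_BASES, size=2, replace=False)))
        from itertools import product

        combos = ["".join(c) for c in product(*site_alleles)]
        if len(combos) >= k:
            haps = list(rng.choice(combos, size=k, replace=False))
            # every site must stay polymorphic within the chosen haplotypes
            if all(len({h[i] for h in haps}) > 1 for i in range(n_snps)):
                return haps, site_alleles


def simulate_temporal_genotypes(p: DriftParams):
    """Simulate a temporal genotype matrix under Wright–Fisher drift.

    Allele frequencies follow multinomial resampling of 2*Ne gene copies
    per generation; at each sampling year, ``samples_per_year`` diploid
    genotypes are drawn from Hardy–Weinberg proportions at that year's
    frequencies, then masked missing i.i.d. at ``missingness``.

    Returns ``(GenotypeMatrix, TemporalTruth)``.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)

    ks = rng.choice([2, 3, 4], size=p.n_loci, p=p.allele_number_probs)
    loci = [f"mh{i:05d}" for i in range(p.n_loci)]
    alleles = []
    for k in ks:
        haps, _sites = _haplotype_catalogue(rng, int(k))
        alleles.append(sorted(haps))
    a_max = max((len(a) for a in alleles), default=1)

    # initial frequencies from a symmetric Dirichlet
    freqs = np.zeros((p.n_loci, a_max))
    for i, k in enumerate(ks):
        freqs[i, :k] = rng.dirichlet(np.full(int(k), p.dirichlet_concentration))

    first, last = min(p.years), max(p.years)
    sampled: dict = {}
    truth_freqs: dict = {}
    year = first
    while year <= last:
        if year in p.years:
            truth_freqs[year] = freqs.copy()
            truth_freqs[year][
                np.arange(a_max)[None, :] >= ks[:, None]
            ] = np.nan
            sampled[year] = _sample_genotypes(rng, freqs, ks, p.samples_per_year)
        if year == last:
            break
        two_ne = 2 * p.ne_at(year + 1)
        for _ in range(p.generations_per_year):
            counts = rng.multinomial(two_ne, freqs)
            freqs = counts / two_ne
        year += 1

    individuals, collections, rows = [], [], []
    for year in p.years:
        for j in range(p.samples_per_year):
            individuals.append(f"y{year}_i{j:03d}")
            collections.append(year)
        rows.append(sampled[year])
    calls = np.concatenate(rows, axis=0)

    if p.missingness > 0:
        mask = rng.random(calls.shape[:2]) < p.missingness
        calls[mask] = MISSING

    gm = GenotypeMatrix(individuals, collections, loci, alleles, calls)
    truth = TemporalTruth(tuple(p.years), loci, alleles, truth_freqs)
    return gm, truth


def _sample_genotypes(rng, freqs, ks, n):
    """Draw n diploid HWE genotypes per locus; returns (n, L, 2) int16."""
    L, a_max = freqs.shape
    cum = np.cumsum(freqs, axis=1)
    cum[np.arange(L), ks - 1] = 1.0  # guard against rounding
    u = rng.random((n, L, 2))
    # allele index = number of cumulative bins below u
    idx = (u[:, :, :, None] >= cum[None, :, None, :]).sum(axis=-1)
    return np.asarray(idx, dtype=np.int16)


# ---------------------------------------------------------------------------
# reference with embedded loci
# ---------------------------------------------------------------------------

def simulate_reference_with_loci(
    n_loci: int,
    locus_len: int = 150,
    genome_len: int = 100_000,
    seed: int = 0,
    duplicate: bool = False,
    snps_per_locus=(1, 2),
    contig_name: str = "contig1",
):
    """Random reference with microhaplotype loci at known coordinates.

    Loci are embedded non-overlapping; with ``duplicate=True`` an extra
    verbatim copy of the first locus is inserted, creating a known
    off-target site for primer-specificity tests.  SNP sites are placed
    uniformly on each locus (1 SNP for biallelic loci, 2 for
    microhaplotypes, per ``snps_per_locus`` choices).

    Returns ``(reference, loci)`` where ``reference`` maps contig name to
    sequence and each :class:`MicrohapLocus` carries contig/start.
    """
    rng = np.random.default_rng(seed)
    n_slots = n_loci + (1 if duplicate else 0)
    if genome_len < n_slots * locus_len:
        raise ValueError("genome too short to embed loci without overlap")

    genome = list(_random_seq(rng, genome_len))
    # choose non-overlapping starts: partition the free space
    free = genome_len - n_slots * locus_len
    gaps = rng.multinomial(free, np.full(n_slots + 1, 1.0 / (n_slots + 1)))
    starts = []
    pos = 0
    for s in range(n_slots):
        pos += gaps[s]
        starts.append(pos)
        pos += locus_len

    loci = []
    for i in range(n_loci):
        locus_id = f"mh{i:05d}"
        seq = list(_random_seq(rng, locus_len))
        n_snps = int(rng.choice(snps_per_locus))
        offsets = sorted(rng.choice(locus_len, size=n_snps, replace=False))
        snps = []
        for off in offsets:
            alt = rng.choice([b for b in "ACGT" if b != seq[off]])
            snps.append(SnpSite(locus_id, int(off), (seq[off], alt)))
        seq = "".join(seq)
        start = starts[i]
        genome[start : start + locus_len] = seq
        loci.append(
            MicrohapLocus(
                locus_id,
                seq,
                tuple(snps),
                contig=contig_name,
                start=start,
                mean_depth=float(rng.gamma(4.0, 15.0)),
            )
        )

    if duplicate:
        start = starts[-1]
        genome[start : start + locus_len] = loci[0].sequence

    return {contig_name: "".join(genome)}, loci


def embed_loci_for_catalogues(
    locus_ids,
    catalogues,
    locus_len: int = 150,
    genome_len: int = 400_000,
    seed: int = 0,
    contig_name: str = "contig1",
    snp_margin: int = 0,
):
    """Embed loci matching given haplotype catalogues into a random genome.

    For each locus, the number of SNP sites equals the haplotype string
    length of its catalogue and the site alleles are the bases observed at
    that haplotype position; the reference sequence carries the first
    (sorted) base at each site.  SNP offsets are uniform on the locus
    (within ``snp_margin`` of the ends when set — margin >= 33 yields loci
    that survive SNP-position trimming untouched, i.e. ready-made panel
    candidates).  Returns ``(reference, loci)``.
    """
    rng = np.random.default_rng(seed)
    n = len(locus_ids)
    if genome_len < n * locus_len:
        raise ValueError("genome too short to embed loci without overlap")
    genome = list(_random_seq(rng, genome_len))
    free = genome_len - n * locus_len
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    pos = 0
    loci = []
    for i, (lid, cat) in enumerate(zip(locus_ids, catalogues)):
        pos += int(gaps[i])
        start = pos
        pos += locus_len
        n_snps = len(cat[0])
        lo, hi = snp_margin, locus_len - snp_margin
        if hi - lo < n_snps:
            raise ValueError("snp_margin leaves too little room for SNP sites")
        offsets = sorted(
            int(o) + lo for o in rng.choice(hi - lo, size=n_snps, replace=False)
        )
        seq = list(_random_seq(rng, locus_len))
        snps = []
        for k, off in enumerate(offsets):
            bases = tuple(sorted({h[k] for h in cat}))
            seq[off] = bases[0]
            snps.append(SnpSite(lid, off, bases))
        seq = "".join(seq)
        genome[start : start + locus_len] = seq
        loci.append(
            MicrohapLocus(
                lid,
                seq,
                tuple(snps),
                contig=contig_name,
                start=start,
                mean_depth=float(rng.gamma(4.0, 15.0)),
            )
        )
    return {contig_name: "".join(genome)}, loci


# ---------------------------------------------------------------------------
# amplicon read pools
# ---------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    """Parameters of the amplicon read-pool simulator.

    ``interaction_fraction`` is the per-read probability of producing a
    chimeric primer-interaction read when the full panel is multiplexed;
    with ``interaction_weights`` set, removing high-weight pairs from the
    panel lowers the realized fraction proportionally to the remaining
    pairwise interaction mass (so re-simulating a pruned panel emulates a
    new optimization round).
    """

    depth_mean: float = 50.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    error_rate: float = 0.001
    errors_in_primers: bool = False
    interaction_fraction: float = 0.0
    #: per-locus interaction propensity, keyed by locus id (default 1.0)
    interaction_weights: dict = field(default_factory=dict)
    read_len: int = 150
    quality_char: str = "?"  # Phred+33 Q30
    seed: int = 0

    def validate(self):
        if not (0.0 <= self.interaction_fraction < 1.0):
            raise ValueError("interaction_fraction must be in [0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth mean must be positive")


@dataclass
class ReadPool:
    """A simulated read pool with per-read truth.

    ``reads`` is a list of ``(individual, sequence)``; ``truth`` the
    parallel list of per-read class labels: ``("on_target", locus)``,
    ``("interaction", locus_i, locus_j)`` or ``("unknown",)``.
    ``hap_counts`` maps individual -> locus -> per-haplotype on-target read
    counts before sequencing error.
    """

    reads: list
    truth: list
    hap_counts: dict

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for serial, (ind, seq) in enumerate(self.reads):
                fh.write(f"@{ind}:{serial}\n{seq}\n+\n{'?' * len(seq)}\n")

    @property
    def n_interaction(self) -> int:
        return sum(1 for t in self.truth if t[0] == "interaction")


def _probe_hits(read: str, probes) -> bool:
    """IUPAC-aware containment of any probe in the read (simulator-side)."""
    for probe in probes:
        plen = len(probe)
        for s in range(len(read) - plen + 1):
            if all(read[s + i] in IUPAC_REVERSE[b] for i, b in enumerate(probe)):
                return True
    return False


def _pair_mass(weights: np.ndarray) -> float:
    return float(weights.sum() ** 2 - (weights**2).sum())


def simulate_amplicon_reads(
    panel: list[PanelEntry],
    genotypes: GenotypeMatrix,
    rp: ReadSimParams,
    full_panel_ids=None,
):
    """Simulate a single-end GT-seq read pool for a panel.

    On-target reads are the forward primer plus the amplicon carrying the
    individual's haplotype allele (base-substitution errors applied outside
    the primer unless ``errors_in_primers``), padded to ``read_len`` with an
    adapter-like tail.  Interaction reads are the forward primer of pair i
    followed by filler containing a primer (fwd/rev, either orientation)
    of a different pair j, drawn with probability proportional to
    ``w_i * w_j``.

    ``full_panel_ids`` anchors the interaction mass: when the panel passed
    in is a pruned subset of an original multiplex, the realized
    interaction fraction scales down with the remaining pairwise mass.

    Returns a :class:`ReadPool`.
    """
    rp.validate()
    rng = np.random.default_rng(rp.seed)
    active = [e for e in panel if e.active]
    for e in active:
        if e.primers is None or not e.probes:
            raise ValueError(f"panel locus {e.locus_id} lacks primers or probes")

    ids = [e.locus_id for e in active]
    w = np.array([rp.interaction_weights.get(i, 1.0) for i in ids])
    if full_panel_ids is not None:
        w_full = np.array(
            [rp.interaction_weights.get(i, 1.0) for i in full_panel_ids]
        )
        mass_full = _pair_mass(w_full)
    else:
        mass_full = _pair_mass(w)
    mass_active = _pair_mass(w)
    f = rp.interaction_fraction
    if f > 0 and mass_full > 0 and len(active) >= 2:
        f_active = f * mass_active / mass_full
    else:
        f_active = 0.0

    # per-lead-locus interaction probability: ordered pair (i, j) occurs at a
    # rate proportional to w_i * w_j, so the panel-wide fraction is f_active
    # while hot pairs dominate the chimeras.
    if f_active > 0:
        s = w * (w.sum() - w)  # lead-locus share of the pair mass
        f_lead = np.minimum(f_active * len(active) * s / s.sum(), 0.95)
    else:
        f_lead = np.zeros(len(active))
    adapter = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

    loc_index = {l: j for j, l in enumerate(genotypes.loci)}
    reads, truth = [], []
    hap_counts: dict = {}
    p_nb = rp.depth_dispersion / (rp.depth_dispersion + rp.depth_mean)

    for i_ind, ind in enumerate(genotypes.individuals):
        hc_ind = hap_counts.setdefault(ind, {})
        for e_pos, e in enumerate(active):
            j = loc_index.get(e.locus_id)
            if j is None:
                continue
            depth = int(rng.negative_binomial(rp.depth_dispersion, p_nb))
            if depth == 0:
                continue
            fl = float(f_lead[e_pos])
            n_int = int(rng.binomial(depth, fl)) if fl > 0 else 0
            n_on = depth - n_int
            call = genotypes.calls[i_ind, j]
            cat = genotypes.alleles[j]
            counts = hc_ind.setdefault(e.locus_id, np.zeros(len(cat), dtype=int))
            if call[0] != MISSING:
                which = rng.integers(0, 2, size=n_on)
                for hap_slot in which:
                    hap_idx = int(call[hap_slot])
                    counts[hap_idx] += 1
                    reads.append((ind, _on_target_read(rng, e, cat[hap_idx], rp, adapter)))
                    probes = [p for prr in e.probes for p in prr.probes]
                    label = (
                        ("on_target", e.locus_id)
                        if _probe_hits(reads[-1][1], probes)
                        else ("unknown",)
                    )
                    truth.append(label)
            if n_int:
                partner_w = w.copy()
                partner_w[e_pos] = 0.0
                partner_p = partner_w / partner_w.sum()
                partners = rng.choice(len(active), size=n_int, p=partner_p)
                for b_j in partners:
                    reads.append(
                        (ind, _interaction_read(rng, e, active[int(b_j)], rp, adapter))
                    )
                    truth.append(("interaction", e.locus_id, ids[int(b_j)]))
    return ReadPool(reads, truth, hap_counts)


def _apply_errors(rng, seq: list, rate: float, start: int) -> None:
    if rate <= 0:
        return
    for i in range(start, len(seq)):
        if rng.random() < rate:
            seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))


def _on_target_read(rng, entry: PanelEntry, hap: str, rp: ReadSimParams, adapter: str) -> str:
    template = list(entry.locus.sequence)
    for snp, base in zip(entry.locus.snps, hap):
        template[snp.offset] = base
    err_start = 0 if rp.errors_in_primers else len(entry.primers.fwd_seq)
    _apply_errors(rng, template, rp.error_rate, err_start)
    read = "".join(template)
    while len(read) < rp.read_len:
        read += adapter
    return read[: rp.read_len]


def _interaction_read(rng, lead: PanelEntry, other: PanelEntry, rp: ReadSimParams, adapter: str) -> str:
    fwd = lead.primers.fwd_seq
    embedded = [
        other.primers.fwd_seq,
        other.primers.rev_seq,
        revcomp(other.primers.fwd_seq),
        revcomp(other.primers.rev_seq),
    ][int(rng.integers(0, 4))]
    gap = int(rng.integers(0, 30))
    read = fwd + _random_seq(rng, gap) + embedded
    while len(read) < rp.read_len:
        read += adapter
    return read[: rp.read_len]


# ---------------------------------------------------------------------------
# helpers used by tests, examples and the pipeline
# ---------------------------------------------------------------------------

def panel_for_genotypes(
    genotypes: GenotypeMatrix,
    seed: int = 0,
    locus_len: int = 150,
    snp_margin: int = 40,
):
    """A ready-made primer/probe panel matching a genotype matrix.

    Embeds one locus per genotype-matrix column into a random reference
    (SNPs kept ``snp_margin`` bases away from the template edges so every
    locus survives trimming untouched), designs exact-substring candidate
    primers and runs the full preparation chain.  Returns
    ``(reference, panel)``; raises if any locus fails preparation.
    """
    from .primers import prepare_panel

    genome, loci = embed_loci_for_catalogues(
        genotypes.loci,
        genotypes.alleles,
        locus_len=locus_len,
        genome_len=max(locus_len * len(genotypes.loci) * 3, 20_000),
        seed=seed,
        snp_margin=snp_margin,
    )
    candidates = {l.locus_id: naive_primer_candidates for l in loci}
    panel, removals = prepare_panel(loci, genome, candidates)
    if removals:
        raise RuntimeError(f"panel construction lost loci: {removals}")
    return genome, panel

def naive_primer_candidates(template: str, locus_id: str, n_candidates: int = 1):
    """Exact-substring primer candidates from a trimmed template.

    Synthetic stand-in for an external thermodynamic primer designer: rank
    k uses the 20-mer starting at offset k-1 as the forward primer and the
    reverse-complement of the 20-mer ending at len-(k-1) as the reverse
    primer, so every candidate amplifies the (slightly shrinking) template.
    Candidates whose product would fall below the 100 bp floor are skipped.
    """
    out = []
    for rank in range(1, n_candidates + 1):
        off = rank - 1
        start, end = off, len(template) - off
        if end - start < PrimerPair.MIN_PRODUCT or end - start > PrimerPair.MAX_PRODUCT:
            continue
        fwd = template[start : start + 20]
        rev = revcomp(template[end - 20 : end])
        out.append(
            PrimerPair(locus_id, fwd, rev, rank=rank, product_start=start, product_end=end)
        )
    return out


def simulate_sex_genotypes(n: int, mapping: dict, rng=None, labels=("F", "M")):
    """Draw individual sexes and the matching two-SNP diplotypes.

    ``mapping`` maps an unordered diplotype (tuple of two haplotype
    strings, sorted) to a sex label; the simulator inverts it, assigning
    each individual a sex uniformly and the corresponding diplotype.
    Returns ``(sexes, diplotypes)``.
    """
    rng = np.random.default_rng(rng)
    by_label: dict = {}
    for diplo, lab in mapping.items():
        by_label.setdefault(lab, []).append(tuple(sorted(diplo)))
    missing = [lab for lab in labels if lab not in by_label]
    if missing:
        raise ValueError(f"mapping lacks diplotypes for labels {missing}")
    sexes, diplos = [], []
    for _ in range(n):
        lab = labels[int(rng.integers(0, len(labels)))]
        options = by_label[lab]
        sexes.append(lab)
        diplos.append(options[int(rng.integers(0, len(options)))])
    return sexes, diplos
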