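"""Core domain types for GT-seq panel development.

The toolkit models a panel-design workflow for targeted amplicon genotyping
(GT-seq): short reference-anchored loci carrying one or more SNPs
(microhaplotypes), diploid genotype matrices labelled by temporal collection
(sampling year), candidate PCR primer pairs, and allele-specific in-silico
probes used to count allele-bearing reads.

Conventions
-----------
* All internal coordinates are 0-based, half-open.  1-based coordinates
  appear only at VCF / report boundaries.
* A missing diploid call is the dedicated sentinel :data:`MISSING`
  (never a valid allele index).
* Microhaplotype alleles are short haplotype strings ("ACT"); single-SNP
  loci degenerate to single bases ("A").  Serialized calls join the two
  haplotypes with "/" ("ACT/ATT").
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MISSING",
    "IUPAC",
    "IUPAC_REVERSE",
    "SnpSite",
    "MicrohapLocus",
    "GenotypeMatrix",
    "PrimerPair",
    "ProbeRecord",
    "PanelEntry",
    "TrimmedLocus",
    "revcomp",
    "iupac_code",
]

#: Sentinel allele index for a missing diploid call.
MISSING: int = -1

_DNA = frozenset("ACGT")

#: IUPAC degenerate codes keyed by the sorted base set they cover.
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

#: Base-set expansion of every IUPAC code.
IUPAC_REVERSE = {code: bases for bases, code in IUPAC.items()}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMP)[::-1]


def iupac_code(bases) -> str:
    """Degenerate code covering a collection of bases (e.g. {G,T} -> 'K')."""
    key = frozenset(b.upper() for b in bases)
    try:
        return IUPAC[key]
    except KeyError:
        raise ValueError(f"not a DNA base set: {sorted(key)}") from None


@dataclass(frozen=True)
class SnpSite:
    """A single polymorphic site within a locus sequence.

    ``offset`` is the 0-based position of the site on the locus sequence;
    ``alleles`` is the ordered tuple of observed single-base alleles
    (reference base first by convention of the loaders).
    """

    locus_id: str
    offset: int
    alleles: tuple[str, ...]

    def __post_init__(self):
        if self.offset < 0:
            raise ValueError(f"{self.locus_id}: negative SNP offset {self.offset}")
        alleles = tuple(a.upper() for a in self.alleles)
        object.__setattr__(self, "alleles", alleles)
        if len(alleles) < 2:
            raise ValueError(f"{self.locus_id}@{self.offset}: need >=2 alleles")
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"{self.locus_id}@{self.offset}: duplicate alleles")
        bad = set(alleles) - _DNA
        if bad:
            raise ValueError(f"{self.locus_id}@{self.offset}: non-ACGT alleles {bad}")


@dataclass(frozen=True)
class MicrohapLocus:
    """A reference-anchored locus sequence with its SNP sites.

    ``snps`` must be ordered by strictly increasing offset, every offset must
    fall inside ``sequence``, and the allele set at each offset must include
    the base the sequence itself carries there (the reference base).
    ``contig``/``start`` optionally anchor the locus on a reference assembly
    (``start`` is 0-based).  ``mean_depth`` is the average read depth used by
    the coverage filter.
    """

    locus_id: str
    sequence: str
    snps: tuple[SnpSite, ...] = ()
    contig: str | None = None
    start: int | None = None
    mean_depth: float | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "snps", tuple(self.snps))
        if not seq:
            raise ValueError(f"{self.locus_id}: empty sequence")
        offsets = [s.offset for s in self.snps]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError(f"{self.locus_id}: SNP offsets not strictly increasing")
        for s in self.snps:
            if s.offset >= len(seq):
                raise ValueError(
                    f"{self.locus_id}: SNP offset {s.offset} beyond sequence "
                    f"length {len(seq)}"
                )
            ref_base = seq[s.offset]
            if ref_base in _DNA and ref_base not in s.alleles:
                raise ValueError(
                    f"{self.locus_id}@{s.offset}: reference base {ref_base} "
                    f"not among alleles {s.alleles}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def haplotype_alleles(self) -> list[str]:
        """All combinatorially possible haplotype strings over the SNP sites.

        The observed allele catalogue of a dataset is usually a subset; this
        enumerates the Cartesian product in allele-index order.
        """
        from itertools import product

        combos = product(*(s.alleles for s in self.snps))
        return ["".join(c) for c in combos]

    def haplotype_from_sequence(self) -> str:
        """Haplotype string spelled by the reference sequence itself."""
        return "".join(self.sequence[s.offset] for s in self.snps)


class GenotypeMatrix:
    """Diploid microhaplotype calls for individuals x loci with year labels.

    Parameters
    ----------
    individuals : ordered individual identifiers.
    collections : per-individual collection (year) label, same length.
    loci : ordered locus identifiers.
    alleles : per-locus allele catalogue (list of haplotype strings).
    calls : int16 array of shape (n_individuals, n_loci, 2) holding allele
        indices into the locus catalogue, or :data:`MISSING` in both slots.
        Call pairs are unordered; they are stored sorted (low, high).

    The container is deliberately thin: analyses consume the numpy array
    directly, and :meth:`to_frame` renders the human-readable table.
    """

    def __init__(self, individuals, collections, loci, alleles, calls):
        self.individuals = list(individuals)
        self.collections = list(collections)
        self.loci = list(loci)
        self.alleles = [list(a) for a in alleles]
        calls = np.asarray(calls, dtype=np.int16)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(self.collections) != len(self.individuals):
            raise ValueError("one collection label required per individual")
        if len(self.alleles) != len(self.loci):
            raise ValueError("one allele catalogue required per locus")
        # normalize: unordered pairs stored sorted; missing in either slot
        # makes the whole call missing.
        calls = np.sort(calls, axis=2)
        miss = (calls < 0).any(axis=2)
        calls[miss] = MISSING
        for j, cat in enumerate(self.alleles):
            col = calls[:, j, :]
            valid = col[col >= 0]
            if valid.size and valid.max() >= len(cat):
                raise ValueError(
                    f"locus {self.loci[j]}: allele index {int(valid.max())} "
                    f"outside catalogue of size {len(cat)}"
                )
        self.calls = calls

    # -- basic protocol ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.individuals == other.individuals
            and self.collections == other.collections
            and self.loci == other.loci
            and self.alleles == other.alleles
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals, "
            f"{self.n_loci} loci, {len(set(self.collections))} collections)"
        )

    # -- derived quantities ------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_ind, n_loci) array, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def individual_missingness(self) -> np.ndarray:
        """Fraction of loci with a missing call, per individual."""
        if self.n_loci == 0:
            return np.zeros(self.n_individuals)
        return self.missing_mask().mean(axis=1)

    def collection_labels(self) -> list:
        """Distinct collection labels in order of first appearance."""
        seen: dict = {}
        for c in self.collections:
            seen.setdefault(c, None)
        return list(seen)

    def call_string(self, i: int, j: int) -> str:
        """Serialize call (i, j) as 'ACT/ATT', or '.' when missing."""
        a, b = self.calls[i, j]
        if a == MISSING:
            return "."
        cat = self.alleles[j]
        return f"{cat[a]}/{cat[b]}"

    # -- subsetting ---------------------------------------------------------
    def subset_individuals(self, keep) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) if isinstance(i, str) else i for i in keep]
        return GenotypeMatrix(
            [self.individuals[i] for i in idx],
            [self.collections[i] for i in idx],
            self.loci,
            self.alleles,
            self.calls[idx],
        )

    def subset_loci(self, keep) -> "GenotypeMatrix":
        idx = [self.loci.index(l) if isinstance(l, str) else l for l in keep]
        return GenotypeMatrix(
            self.individuals,
            self.collections,
            [self.loci[j] for j in idx],
            [self.alleles[j] for j in idx],
            self.calls[:, idx, :],
        )

    def to_frame(self):
        """Render as a pandas DataFrame of call strings (individuals x loci)."""
        import pandas as pd

        data = {
            loc: [self.call_string(i, j) for i in range(self.n_individuals)]
            for j, loc in enumerate(self.loci)
        }
        frame = pd.DataFrame(data, index=self.individuals)
        frame.insert(0, "collection", self.collections)
        return frame


@dataclass(frozen=True)
class PrimerPair:
    """A candidate forward/reverse primer pair for one locus.

    ``rank`` is the 1-based order assigned by the external primer designer
    (best first); ``product_start``/``product_end`` delimit the amplicon on
    the locus template, 0-based half-open.
    """

    locus_id: str
    fwd_seq: str
    rev_seq: str
    rank: int = 1
    product_start: int = 0
    product_end: int | None = None

    MIN_PRIMER = 18
    MAX_PRIMER = 25
    MIN_PRODUCT = 100
    MAX_PRODUCT = 150

    def __post_init__(self):
        object.__setattr__(self, "fwd_seq", self.fwd_seq.upper())
        object.__setattr__(self, "rev_seq", self.rev_seq.upper())
        for name, seq in (("fwd", self.fwd_seq), ("rev", self.rev_seq)):
            if not (self.MIN_PRIMER <= len(seq) <= self.MAX_PRIMER):
                raise ValueError(
                    f"{self.locus_id} {name} primer length {len(seq)} outside "
                    f"[{self.MIN_PRIMER}, {self.MAX_PRIMER}]"
                )
        if self.product_end is not None:
            plen = self.product_end - self.product_start
            if not (self.MIN_PRODUCT <= plen <= self.MAX_PRODUCT):
                raise ValueError(
                    f"{self.locus_id}: product length {plen} outside "
                    f"[{self.MIN_PRODUCT}, {self.MAX_PRODUCT}]"
                )


@dataclass(frozen=True)
class ProbeRecord:
    """Allele-specific probes for one SNP of a panel locus.

    Probes are 17 nt (8-nt flanks + allele base) unless truncated at a
    template edge, in which case ``truncated`` is set.  Flanking positions
    that themselves carry a retained SNP are encoded as IUPAC degenerate
    bases, so a probe matches reads carrying any neighbouring allele.
    """

    locus_id: str
    snp_offset: int
    alleles: tuple[str, ...]
    probes: tuple[str, ...]
    truncated: bool = False

    def __post_init__(self):
        if len(self.alleles) != len(self.probes):
            raise ValueError(f"{self.locus_id}@{self.snp_offset}: one probe per allele")
        if not self.truncated and any(len(p) != 17 for p in self.probes):
            raise ValueError(
                f"{self.locus_id}@{self.snp_offset}: probe length != 17 "
                "without truncation flag"
            )


@dataclass
class PanelEntry:
    """One assay-ready locus: trimmed template, chosen primers, probes."""

    locus: "MicrohapLocus"
    primers: PrimerPair | None
    probes: tuple[ProbeRecord, ...] = ()
    active: bool = True
    removed_reason: str | None = None

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id

    def deactivate(self, reason: str) -> "PanelEntry":
        return replace(self, active=False, removed_reason=reason)


@dataclass(frozen=True)
class TrimmedLocus:
    """Result of SNP-position trimming on one locus.

    ``kept_start``/``kept_end`` give the retained interval on the original
    sequence (0-based half-open); retained SNP offsets are re-based onto the
    trimmed sequence.  ``discarded_snps`` counts SNPs removed by trimming.
    """

    locus_id: str
    sequence: str
    snps: tuple[SnpSite, ...]
    kept_start: int
    kept_end: int
    discarded_snps: int = 0

    def to_locus(self, **kw) -> MicrohapLocus:
        return MicrohapLocus(self.locus_id, self.sequence, self.snps, **kw)
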