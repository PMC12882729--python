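"""Make loci assayable: SNP-position trimming, probes, primer screening.

An amplicon read must start with a locus-specific forward primer (25 bp
of clean flank) and carry an 8 nt probe window around every retained SNP,
so a SNP closer than 33 bp (= 25 + 8) to either end of a locus cannot be
assayed.  The trimming rule deletes from the sequence end up to and
including any such SNP and rescans iteratively, keeping the locus alive
whenever at least one interior SNP survives; templates longer than the
150 bp read are then dropped.  Probes are 17 nt allele-specific windows
(8 nt flanks), with neighbouring retained SNPs encoded as IUPAC
degenerate bases.  Primer specificity is an exact full-length match
search on both strands of the reference: any match outside the source
locus interval disqualifies the pair, and candidate pairs are consumed
in external-designer rank order until one is specific.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    MicrohapLocus,
    PanelEntry,
    PrimerPair,
    ProbeRecord,
    SnpSite,
    TrimmedLocus,
    iupac_code,
    revcomp,
)

__all__ = [
    "Removed",
    "OffTargetHit",
    "trim_snps_for_primers",
    "filter_template_length",
    "build_probes",
    "screen_primer_pair",
    "select_primer_pair",
    "prepare_panel",
    "DEFAULT_FLANK",
]

#: 25 bp for the primer + 8 bp for the probe flank.
DEFAULT_FLANK = 33


@dataclass(frozen=True)
class Removed:
    """A locus (or candidate set) rejected by a preparation step."""

    locus_id: str
    reason: str


@dataclass(frozen=True)
class OffTargetHit:
    """An exact primer match outside the target locus interval."""

    contig: str
    start: int  # 0-based, on the forward strand
    end: int
    strand: str  # "+" or "-"
    primer: str  # "fwd" or "rev"


def trim_snps_for_primers(locus: MicrohapLocus, flank: int = DEFAULT_FLANK):
    """Iteratively discard edge-proximal SNPs and the sequence beyond them.

    Greedy from the 5' end: while the first remaining SNP lies within the
    first ``flank`` bases of the current sequence, delete from the current
    start through that SNP inclusive and rescan; symmetrically from the
    3' end.  Returns a :class:`TrimmedLocus` with retained SNP offsets
    re-based, or ``Removed(no_snps)`` when no SNP survives.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if not locus.snps:
        raise ValueError(f"{locus.locus_id}: locus has no SNPs to trim around")

    offsets = [s.offset for s in locus.snps]
    start, end = 0, len(locus.sequence)

    remaining = list(range(len(offsets)))
    # 5' pass to fixpoint
    while remaining and offsets[remaining[0]] - start <= flank - 1:
        cut_snp = offsets[remaining[0]]
        start = cut_snp + 1
        remaining = [i for i in remaining if offsets[i] >= start]
    # 3' pass to fixpoint
    while remaining and (end - 1) - offsets[remaining[-1]] <= flank - 1:
        cut_snp = offsets[remaining[-1]]
        end = cut_snp
        remaining = [i for i in remaining if offsets[i] < end]

    if not remaining:
        return Removed(locus.locus_id, "no_snps")
    kept = tuple(
        SnpSite(locus.locus_id, locus.snps[i].offset - start, locus.snps[i].alleles)
        for i in remaining
    )
    return TrimmedLocus(
        locus_id=locus.locus_id,
        sequence=locus.sequence[start:end],
        snps=kept,
        kept_start=start,
        kept_end=end,
        discarded_snps=len(offsets) - len(remaining),
    )


def filter_template_length(t: TrimmedLocus, max_len: int = 150):
    """Drop templates strictly longer than the read length (150 kept)."""
    if len(t.sequence) > max_len:
        return Removed(t.locus_id, "too_long")
    return t


def build_probes(t: TrimmedLocus, probe_flank: int = 8) -> list[ProbeRecord]:
    """17 nt allele-specific probes for every retained SNP.

    Each probe is the SNP allele with ``probe_flank`` bases of template on
    both sides; any other retained SNP falling inside the window is
    written as the IUPAC code covering its alleles, so the probe matches
    reads carrying any neighbouring allele.
    """
    seq = t.sequence
    by_offset = {s.offset: s for s in t.snps}
    records = []
    for snp in t.snps:
        o = snp.offset
        if o < probe_flank or o + probe_flank >= len(seq):
            raise ValueError(
                f"{t.locus_id}@{o}: insufficient probe flank "
                f"(violates the trimming contract)"
            )
        window = list(seq[o - probe_flank : o + probe_flank + 1])
        for k in range(len(window)):
            pos = o - probe_flank + k
            if pos != o and pos in by_offset:
                window[k] = iupac_code(by_offset[pos].alleles)
        probes = []
        for allele in snp.alleles:
            w = list(window)
            w[probe_flank] = allele
            probes.append("".join(w))
        records.append(ProbeRecord(t.locus_id, o, snp.alleles, tuple(probes)))
    return records


def _find_all(haystack: str, needle: str):
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def screen_primer_pair(
    pair: PrimerPair, genome: dict, target_region: tuple | None = None
) -> list[OffTargetHit]:
    """Exact-match specificity screen of both primers on both strands.

    ``genome`` maps contig name to uppercase sequence; ``target_region``
    is ``(contig, start, end)`` of the source locus (0-based half-open) —
    matches falling entirely inside it never count.  Returns the list of
    off-target hits (empty list = UNIQUE).  A primer with no match
    anywhere raises ``ValueError`` (template/genome mismatch).
    """
    hits: list[OffTargetHit] = []
    for which, seq in (("fwd", pair.fwd_seq), ("rev", pair.rev_seq)):
        found = False
        for contig, ref in genome.items():
            for strand, needle in (("+", seq), ("-", revcomp(seq))):
                for s in _find_all(ref, needle):
                    found = True
                    e = s + len(needle)
                    if target_region is not None:
                        t_contig, t_start, t_end = target_region
                        if contig == t_contig and s >= t_start and e <= t_end:
                            continue  # the on-target match itself never counts
                    hits.append(OffTargetHit(contig, s, e, strand, which))
        if not found:
            raise ValueError(
                f"{pair.locus_id}: {which} primer not found in genome "
                "(template/genome mismatch)"
            )
    return hits


def select_primer_pair(
    candidates: list[PrimerPair], genome: dict, target_region: tuple | None = None
):
    """First specificity-passing pair in designer rank order.

    Returns the chosen :class:`PrimerPair`, or ``Removed`` when the
    candidate list is empty (``no_candidates``) or every pair has an
    off-target hit (``no_specific_pair``).
    """
    if not candidates:
        return Removed("?", "no_candidates")
    locus_id = candidates[0].locus_id
    for pair in sorted(candidates, key=lambda p: p.rank):
        if not screen_primer_pair(pair, genome, target_region):
            return pair
    return Removed(locus_id, "no_specific_pair")


def prepare_panel(
    loci: list[MicrohapLocus],
    genome: dict,
    candidates_by_locus: dict,
    flank: int = DEFAULT_FLANK,
    max_template_len: int = 150,
    probe_flank: int = 8,
):
    """Run the full preparation chain over a list of loci.

    ``candidates_by_locus`` maps locus id to a callable
    ``f(template, locus_id) -> list[PrimerPair]`` or to a pre-built
    candidate list (coordinates on the trimmed template).  Returns
    ``(panel, removals)`` where ``removals`` maps locus id to the reason
    it fell out of the chain.
    """
    panel: list[PanelEntry] = []
    removals: dict[str, str] = {}
    for locus in loci:
        trimmed = trim_snps_for_primers(locus, flank=flank)
        if isinstance(trimmed, Removed):
            removals[locus.locus_id] = trimmed.reason
            continue
        gated = filter_template_length(trimmed, max_template_len)
        if isinstance(gated, Removed):
            removals[locus.locus_id] = gated.reason
            continue
        probes = build_probes(gated, probe_flank=probe_flank)
        source = candidates_by_locus.get(locus.locus_id, [])
        candidates = (
            source(gated.sequence, locus.locus_id) if callable(source) else source
        )
        if locus.contig is not None and locus.start is not None:
            region = (
                locus.contig,
                locus.start + gated.kept_start,
                locus.start + gated.kept_end,
            )
        else:
            region = None
        chosen = select_primer_pair(candidates, genome, region)
        if isinstance(chosen, Removed):
            removals[locus.locus_id] = chosen.reason
            continue
        new_start = (
            locus.start + gated.kept_start if locus.start is not None else None
        )
        panel.append(
            PanelEntry(
                gated.to_locus(
                    contig=locus.contig, start=new_start, mean_depth=locus.mean_depth
                ),
                chosen,
                tuple(probes),
            )
        )
    return panel, removals
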