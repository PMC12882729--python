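"""SNP-position trimming, probe construction and primer screening."""

import numpy as np
import pytest

from gtpanel.model import MicrohapLocus, PrimerPair, SnpSite, revcomp
from gtpanel.primers import (
    Removed,
    build_probes,
    filter_template_length,
    screen_primer_pair,
    select_primer_pair,
    trim_snps_for_primers,
)
from gtpanel.simulate import simulate_reference_with_loci

from _oracles import trim_oracle


def _locus(length, offsets, lid="L", alleles=("A", "C")):
    seq = ["G"] * length
    snps = []
    for o in offsets:
        seq[o] = alleles[0]
        snps.append(SnpSite(lid, o, alleles))
    return MicrohapLocus(lid, "".join(seq), tuple(snps))


class TestTrimming:
    def test_centered_snp_untouched(self):
        t = trim_snps_for_primers(_locus(100, [49]), flank=33)
        assert (t.kept_start, t.kept_end) == (0, 100)
        assert [s.offset for s in t.snps] == [49]

    def test_single_edge_snp_removes_locus(self):
        out = trim_snps_for_primers(_locus(120, [10]), flank=33)
        assert isinstance(out, Removed) and out.reason == "no_snps"

    def test_cascade_rescans_after_cut(self):
        # SNP at 10 forces a cut through 10; SNP at 40 is then within 33 bp
        # of the new start (11) and is cut too; SNP at 90 survives.
        t = trim_snps_for_primers(_locus(130, [10, 40, 90]), flank=33)
        assert t.kept_start == 41
        assert [s.offset for s in t.snps] == [90 - 41]
        assert t.discarded_snps == 2

    def test_flank_validation(self):
        with pytest.raises(ValueError, match="flank"):
            trim_snps_for_primers(_locus(100, [50]), flank=0)
        with pytest.raises(ValueError, match="no SNPs"):
            trim_snps_for_primers(MicrohapLocus("L", "ACGT"), flank=5)

    def test_matches_enumeration_oracle_randomized(self):
        rng = np.random.default_rng(77)
        for _ in range(2000):
            length = int(rng.integers(12, 81))
            n_snps = int(rng.integers(1, 6))
            offsets = sorted(rng.choice(length, size=min(n_snps, length), replace=False))
            locus = _locus(length, [int(o) for o in offsets])
            got = trim_snps_for_primers(locus, flank=5)
            want = trim_oracle(length, [int(o) for o in offsets], flank=5)
            if want is None:
                assert isinstance(got, Removed)
            else:
                a, b, kept = want
                assert (got.kept_start, got.kept_end) == (a, b)
                assert [s.offset + a for s in got.snps] == kept

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            length = int(rng.integers(30, 120))
            offsets = sorted(
                rng.choice(length, size=int(rng.integers(1, 5)), replace=False)
            )
            t = trim_snps_for_primers(_locus(length, [int(o) for o in offsets]), flank=8)
            if isinstance(t, Removed):
                continue
            again = trim_snps_for_primers(t.to_locus(), flank=8)
            assert (again.kept_start, again.kept_end) == (0, len(t.sequence))
            assert again.snps == t.snps

    def test_retained_snps_respect_flanks(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            length = int(rng.integers(12, 100))
            offsets = sorted(
                rng.choice(length, size=int(rng.integers(1, 6)), replace=False)
            )
            t = trim_snps_for_primers(_locus(length, [int(o) for o in offsets]), flank=7)
            if isinstance(t, Removed):
                continue
            for s in t.snps:
                assert s.offset >= 7
                assert len(t.sequence) - 1 - s.offset >= 7


class TestTemplateLength:
    @pytest.mark.parametrize(
        "length,kept", [(150, True), (151, False), (40, True)]
    )
    def test_strict_boundary(self, length, kept):
        t = trim_snps_for_primers(_locus(length, [length // 2]), flank=5)
        out = filter_template_length(t, max_len=150)
        if kept:
            assert out is t
        else:
            assert isinstance(out, Removed) and out.reason == "too_long"


class TestProbes:
    def test_isolated_snp_two_probes_differ_at_center(self):
        t = trim_snps_for_primers(_locus(100, [50], alleles=("A", "C")), flank=33)
        (rec,) = build_probes(t)
        assert len(rec.probes) == 2
        p1, p2 = rec.probes
        assert len(p1) == len(p2) == 17
        diff = [i for i in range(17) if p1[i] != p2[i]]
        assert diff == [8]
        assert p1[8] == "A" and p2[8] == "C"

    def test_neighbour_snp_encoded_as_iupac(self):
        # SNPs 5 bp apart; the neighbour (G/T) appears as K in the flank
        seq = list("C" * 60)
        seq[30] = "A"
        seq[35] = "G"
        locus = MicrohapLocus(
            "L",
            "".join(seq),
            (SnpSite("L", 30, ("A", "C")), SnpSite("L", 35, ("G", "T"))),
        )
        t = trim_snps_for_primers(locus, flank=10)
        recs = build_probes(t)
        first = recs[0]
        for probe in first.probes:
            assert probe[8 + 5] == "K"
        second = recs[1]
        for probe in second.probes:
            assert probe[8 - 5] == "M"  # A/C neighbour

    def test_monomorphic_flank_probes_are_template_substrings(self):
        t = trim_snps_for_primers(_locus(90, [45], alleles=("G", "T")), flank=33)
        (rec,) = build_probes(t)
        for allele, probe in zip(rec.alleles, rec.probes):
            tpl = list(t.sequence)
            tpl[45] = allele
            assert probe in "".join(tpl)

    def test_flank_shortfall_errors(self):
        locus = _locus(40, [3])
        t = trim_snps_for_primers(locus, flank=2)
        with pytest.raises(ValueError, match="flank"):
            build_probes(t, probe_flank=8)


@pytest.fixture(scope="module")
def genomes():
    unique = simulate_reference_with_loci(3, locus_len=120, genome_len=4000, seed=4)
    dup = simulate_reference_with_loci(
        3, locus_len=120, genome_len=4000, seed=4, duplicate=True
    )
    return unique, dup


class TestScreening:

    @staticmethod
    def _pair(locus):
        return PrimerPair(
            locus.locus_id,
            locus.sequence[:20],
            revcomp(locus.sequence[-20:]),
            product_start=0,
            product_end=len(locus.sequence),
        )

    def test_unique_locus_passes(self, genomes):
        (genome, loci), _ = genomes
        l = loci[0]
        hits = screen_primer_pair(
            self._pair(l), genome, (l.contig, l.start, l.start + len(l.sequence))
        )
        assert hits == []

    def test_duplicate_copy_reported_with_coordinates(self, genomes):
        _, (genome, loci) = genomes
        l = loci[0]
        hits = screen_primer_pair(
            self._pair(l), genome, (l.contig, l.start, l.start + len(l.sequence))
        )
        assert hits
        seq = genome[l.contig]
        for h in hits:
            if h.strand == "+":
                assert seq[h.start : h.end] in (l.sequence[:20], revcomp(l.sequence[-20:]))

    def test_reverse_strand_site_detected(self):
        genome, loci = simulate_reference_with_loci(1, locus_len=120, genome_len=3000, seed=9)
        l = loci[0]
        contig = genome[l.contig]
        # plant the reverse-complement of the fwd primer far from the locus
        insert_at = (l.start + 500) % (len(contig) - 30)
        if l.start <= insert_at <= l.start + 120:
            insert_at = (l.start + 1000) % (len(contig) - 30)
        planted = contig[:insert_at] + revcomp(l.sequence[:20]) + contig[insert_at + 20 :]
        hits = screen_primer_pair(
            self._pair(l),
            {l.contig: planted},
            (l.contig, l.start, l.start + len(l.sequence)),
        )
        assert any(h.strand == "-" and h.primer == "fwd" for h in hits)

    def test_primer_absent_everywhere_errors(self, genomes):
        (genome, loci), _ = genomes
        pair = PrimerPair("ghost", "A" * 20, "C" * 20)
        with pytest.raises(ValueError, match="not found"):
            screen_primer_pair(pair, genome)


class TestCandidateIteration:
    def _candidates(self, locus, n):
        out = []
        for rank in range(1, n + 1):
            off = rank - 1
            out.append(
                PrimerPair(
                    locus.locus_id,
                    locus.sequence[off : off + 20],
                    revcomp(locus.sequence[len(locus.sequence) - off - 20 : len(locus.sequence) - off]),
                    rank=rank,
                    product_start=off,
                    product_end=len(locus.sequence) - off,
                )
            )
        return out

    def test_rank1_unique_returned(self):
        genome, loci = simulate_reference_with_loci(1, locus_len=130, genome_len=3000, seed=11)
        l = loci[0]
        region = (l.contig, l.start, l.start + 130)
        chosen = select_primer_pair(self._candidates(l, 3), genome, region)
        assert isinstance(chosen, PrimerPair) and chosen.rank == 1

    def test_rank1_offtarget_falls_through_to_rank2(self):
        genome, loci = simulate_reference_with_loci(1, locus_len=130, genome_len=4000, seed=12)
        l = loci[0]
        contig = genome[l.contig]
        cands = self._candidates(l, 3)
        # plant a copy of the rank-1 fwd primer elsewhere
        spot = l.start + 1000 if l.start + 1030 < len(contig) else 10
        planted = contig[:spot] + cands[0].fwd_seq + contig[spot + 20 :]
        region = (l.contig, l.start, l.start + 130)
        chosen = select_primer_pair(cands, {l.contig: planted}, region)
        assert isinstance(chosen, PrimerPair) and chosen.rank == 2

    def test_all_offtarget_removed(self):
        genome, loci = simulate_reference_with_loci(
            1, locus_len=130, genome_len=4000, seed=13, duplicate=True
        )
        l = loci[0]
        region = (l.contig, l.start, l.start + 130)
        out = select_primer_pair(self._candidates(l, 5), genome, region)
        assert isinstance(out, Removed) and out.reason == "no_specific_pair"

    def test_empty_candidates(self):
        out = select_primer_pair([], {}, None)
        assert isinstance(out, Removed) and out.reason == "no_candidates"
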