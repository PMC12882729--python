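"""Domain-type invariants and format round trips."""

import numpy as np
import pytest

from gtpanel.io import (
    ParseError,
    load_genotypes,
    load_reference,
    read_panel_tables,
    write_fasta,
    write_genotypes,
    write_panel_tables,
)
from gtpanel.model import (
    MISSING,
    GenotypeMatrix,
    MicrohapLocus,
    PanelEntry,
    PrimerPair,
    SnpSite,
    iupac_code,
    revcomp,
)
from gtpanel.primers import build_probes, trim_snps_for_primers
from gtpanel.simulate import DriftParams, simulate_temporal_genotypes

from conftest import build_panel_for_gm


class TestDomainTypes:
    def test_snp_site_rejects_bad_alleles(self):
        with pytest.raises(ValueError):
            SnpSite("l", 3, ("A",))
        with pytest.raises(ValueError):
            SnpSite("l", 3, ("A", "A"))
        with pytest.raises(ValueError):
            SnpSite("l", 3, ("A", "N"))

    def test_locus_requires_reference_allele_and_order(self):
        with pytest.raises(ValueError, match="reference base"):
            MicrohapLocus("l", "AAAA", (SnpSite("l", 1, ("C", "G")),))
        with pytest.raises(ValueError, match="increasing"):
            MicrohapLocus(
                "l",
                "ACGT",
                (SnpSite("l", 2, ("G", "T")), SnpSite("l", 1, ("C", "A"))),
            )
        with pytest.raises(ValueError, match="beyond"):
            MicrohapLocus("l", "ACG", (SnpSite("l", 5, ("A", "C")),))

    def test_primer_pair_length_bounds(self):
        with pytest.raises(ValueError, match="length"):
            PrimerPair("l", "ACGT", "ACGTACGTACGTACGTACGT")
        with pytest.raises(ValueError, match="product"):
            PrimerPair(
                "l",
                "ACGTACGTACGTACGTACGT",
                "ACGTACGTACGTACGTACGT",
                product_start=0,
                product_end=50,
            )

    def test_missing_call_normalization(self):
        calls = np.array([[[0, MISSING]], [[1, 0]]], dtype=np.int16)
        gm = GenotypeMatrix(["a", "b"], [1, 1], ["l"], [["A", "C"]], calls)
        assert gm.call_string(0, 0) == "."
        assert gm.call_string(1, 0) == "A/C"  # unordered pairs stored sorted

    def test_revcomp_and_iupac(self):
        assert revcomp("ACGT") == "ACGT"
        assert revcomp("AAK") == "MTT"
        assert iupac_code({"G", "T"}) == "K"
        with pytest.raises(ValueError):
            iupac_code({"A", "X"})


class TestGenotypeTables:
    def test_empty_table_yields_empty_matrix(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("individual\tcollection\tl1\tl2\n")
        gm = load_genotypes(p)
        assert gm.n_individuals == 0
        assert gm.loci == ["l1", "l2"]

    def test_two_individuals_one_locus(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "individual\tcollection\tl1\n" "i1\t1999\tA/C\n" "i2\t1999\tC/C\n"
        )
        gm = load_genotypes(p)
        assert gm.alleles[0] == ["A", "C"]
        assert gm.call_string(0, 0) == "A/C"
        assert gm.call_string(1, 0) == "C/C"

    def test_unknown_allele_code_names_line(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("individual\tcollection\tl1\ni1\t1999\tA/Q\n")
        with pytest.raises(ParseError, match="line 2"):
            load_genotypes(p)

    def test_individual_without_label_errors(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("individual\tl1\ni1\tA/A\n")
        with pytest.raises(ParseError, match="collection label"):
            load_genotypes(p, collection_map={"other": 2000})

    def test_round_trip_through_writer(self, tmp_path, small_temporal_gm):
        gm, _ = small_temporal_gm
        path = tmp_path / "roundtrip.tsv"
        write_genotypes(gm, path)
        back = load_genotypes(path)
        assert back.individuals == gm.individuals
        assert [str(c) for c in back.collections] == [str(c) for c in gm.collections]
        assert back.loci == gm.loci
        for i in range(gm.n_individuals):
            for j in range(gm.n_loci):
                assert back.call_string(i, j) == gm.call_string(i, j)


class TestVcf:
    VCF = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=c1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
        "c1\t101\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t./.\n"
    )

    def test_single_record_matrix(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(self.VCF)
        gm = load_genotypes(p, collection_map={"s1": 1, "s2": 1, "s3": 2})
        # 1-based VCF position 101 becomes 0-based 100 in the locus id
        assert gm.loci == ["c1:100"]
        assert gm.call_string(0, 0) == "A/A"
        assert gm.call_string(1, 0) == "A/C"
        assert gm.call_string(2, 0) == "."

    def test_collection_map_required(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(self.VCF)
        with pytest.raises(ParseError):
            load_genotypes(p, collection_map={"s1": 1})


class TestFasta:
    def test_simple_and_wrapped_records(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">c1\nACGT\n>c2\nacg\ntta\n")
        ref = load_reference(p)
        assert ref["c1"] == "ACGT"
        assert ref["c2"] == "ACGTTA"  # wrapped lines concatenated, uppercased

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(ParseError, match="duplicate"):
            load_reference(p)

    def test_write_read_round_trip(self, tmp_path):
        seqs = {"a": "ACGT" * 40, "b": "TTTTA"}
        path = tmp_path / "w.fa"
        write_fasta(seqs, path, width=13)
        assert load_reference(path) == seqs


class TestPanelTables:
    def _panel_one_locus(self, n_snps=1):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        offsets = [50] if n_snps == 1 else [50, 60]
        seq_l = list(seq)
        snps = []
        for o in offsets:
            seq_l[o] = "A"
            snps.append(SnpSite("L1", o, ("A", "C")))
        locus = MicrohapLocus("L1", "".join(seq_l), tuple(snps), contig="c1", start=7, mean_depth=33.0)
        t = trim_snps_for_primers(locus, flank=33)
        probes = build_probes(t)
        pair = PrimerPair("L1", t.sequence[:20], revcomp(t.sequence[-20:]), product_start=0, product_end=len(t.sequence))
        return [PanelEntry(t.to_locus(contig="c1", start=7, mean_depth=33.0), pair, tuple(probes))]

    def test_single_snp_row_shape(self, tmp_path):
        panel = self._panel_one_locus()
        paths = write_panel_tables(panel, tmp_path)
        rows = [
            ln.split("\t")
            for ln in open(paths["probes"]).read().splitlines()
            if not ln.startswith("#")
        ]
        assert len(rows) == 2  # header + one SNP
        body = rows[1]
        assert body[0] == "L1"
        assert body[2].split(",") == ["A", "C"]
        assert len(body[3].split(",")) == 2

    def test_two_snp_locus_gets_two_rows(self, tmp_path):
        panel = self._panel_one_locus(n_snps=2)
        paths = write_panel_tables(panel, tmp_path)
        body = [
            ln
            for ln in open(paths["probes"]).read().splitlines()
            if not ln.startswith("#") and not ln.startswith("locus")
        ]
        assert len(body) == 2
        assert all(ln.startswith("L1\t") for ln in body)

    @pytest.mark.parametrize("n_snps", [1, 2])
    def test_round_trip_identity(self, tmp_path, n_snps):
        panel = self._panel_one_locus(n_snps=n_snps)
        write_panel_tables(panel, tmp_path)
        back = read_panel_tables(tmp_path)
        assert len(back) == 1
        a, b = panel[0], back[0]
        assert a.locus == b.locus
        assert a.primers == b.primers
        assert a.probes == b.probes
        assert (a.active, a.removed_reason) == (b.active, b.removed_reason)

    def test_random_panels_round_trip(self, tmp_path):
        from gtpanel.simulate import simulate_temporal_genotypes

        gm, _ = simulate_temporal_genotypes(DriftParams(n_loci=12, seed=3))
        _genome, panel = build_panel_for_gm(gm, seed=3)
        write_panel_tables(panel, tmp_path)
        back = read_panel_tables(tmp_path)
        assert [(e.locus, e.primers, e.probes) for e in back] == [
            (e.locus, e.primers, e.probes) for e in panel
        ]

    def test_entry_without_primers_rejected(self, tmp_path):
        panel = self._panel_one_locus()
        panel.append(PanelEntry(panel[0].locus, None))
        with pytest.raises(ParseError, match="L1"):
            write_panel_tables(panel, tmp_path)

    def test_strict_reader_rejects_unknown_layout(self, tmp_path):
        panel = self._panel_one_locus()
        paths = write_panel_tables(panel, tmp_path)
        content = open(paths["probes"]).read().replace("ploidy", "Ploidy")
        open(paths["probes"], "w").write(content)
        with pytest.raises(ParseError, match="layout"):
            read_panel_tables(tmp_path, strict=True)
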