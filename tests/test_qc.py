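"""Read classification, allele counting, ML genotyping, round assessment."""

import numpy as np
import pytest
from scipy import stats

from gtpanel.model import MISSING, GenotypeMatrix, revcomp
from gtpanel.qc import (
    UNRESOLVED,
    ReadClassSummary,
    assess_round,
    assign_sex,
    call_genotypes_ml,
    classify_reads,
    count_alleles,
    flag_representation,
    genotype_concordance,
    recommend_removals,
)
from gtpanel.simulate import (
    DriftParams,
    ReadSimParams,
    simulate_amplicon_reads,
    simulate_sex_genotypes,
    simulate_temporal_genotypes,
)

from _oracles import multinomial_loglik
from conftest import build_panel_for_gm, make_matrix


@pytest.fixture(scope="module")
def pool_setup():
    gm, _ = simulate_temporal_genotypes(
        DriftParams(n_loci=12, years=(2000,), samples_per_year=15, missingness=0.0, seed=17)
    )
    genome, panel = build_panel_for_gm(gm, seed=17)
    return gm, panel


class TestClassifyReads:
    def test_zero_interaction_pool(self, pool_setup):
        gm, panel = pool_setup
        pool = simulate_amplicon_reads(
            panel, gm, ReadSimParams(interaction_fraction=0.0, error_rate=0.0, seed=1)
        )
        rc = classify_reads(pool, panel)
        assert rc.proportion_interactions == 0.0
        assert rc.unknown == 0
        assert sum(rc.on_target.values()) == rc.total

    def test_labels_match_simulator_truth_exactly(self, pool_setup):
        gm, panel = pool_setup
        pool = simulate_amplicon_reads(
            panel,
            gm,
            ReadSimParams(interaction_fraction=0.3, error_rate=0.002, seed=2),
        )
        rc, labels = classify_reads(pool, panel, return_labels=True)
        agree = sum(a == b for a, b in zip(labels, pool.truth))
        assert agree == len(labels)

    def test_constructed_interaction_read(self, pool_setup):
        gm, panel = pool_setup
        i, j = panel[0], panel[1]
        read = i.primers.fwd_seq + "T" * 30 + j.primers.rev_seq
        read = read + "A" * (150 - len(read))
        rc, labels = classify_reads([("x", read)], panel, return_labels=True)
        assert labels == [("interaction", i.locus_id, j.locus_id)]
        # reverse-complement embedding classifies identically
        read2 = i.primers.fwd_seq + "T" * 30 + revcomp(j.primers.fwd_seq)
        read2 = read2 + "A" * (150 - len(read2))
        _, labels2 = classify_reads([("x", read2)], panel, return_labels=True)
        assert labels2 == [("interaction", i.locus_id, j.locus_id)]

    def test_no_leading_primer_is_unknown(self, pool_setup):
        _, panel = pool_setup
        rc = classify_reads([("x", "T" * 150)], panel)
        assert rc.unknown == 1

    def test_empty_input(self, pool_setup):
        _, panel = pool_setup
        rc = classify_reads([], panel)
        assert rc.total == 0 and rc.proportion_interactions == 0.0

    def test_prefix_collision_rejected(self, pool_setup):
        _, panel = pool_setup
        from dataclasses import replace

        clash = panel[1]
        bad = replace(clash.primers, fwd_seq=panel[0].primers.fwd_seq)
        panel_bad = [panel[0], type(clash)(clash.locus, bad, clash.probes)]
        with pytest.raises(ValueError, match="collision"):
            classify_reads([], panel_bad)

    def test_fastq_path_round_trip(self, pool_setup, tmp_path):
        gm, panel = pool_setup
        pool = simulate_amplicon_reads(
            panel, gm, ReadSimParams(interaction_fraction=0.1, error_rate=0.0, seed=3)
        )
        fq = tmp_path / "reads.fastq"
        pool.write_fastq(fq)
        rc_mem = classify_reads(pool, panel)
        rc_file = classify_reads(str(fq), panel)
        assert rc_mem.on_target == rc_file.on_target
        assert rc_mem.interactions == rc_file.interactions


class TestCountAlleles:
    def test_homozygote_counts(self, pool_setup):
        gm, panel = pool_setup
        entry = panel[0]
        hap = gm.alleles[0][0]
        template = list(entry.locus.sequence)
        for snp, base in zip(entry.locus.snps, hap):
            template[snp.offset] = base
        read = "".join(template)
        reads = [("ind1", read)] * 30
        ac = count_alleles(reads, [entry])
        table = ac.snp_counts["ind1"][entry.locus_id]
        for rec, base in zip(entry.probes, hap):
            assert table[rec.snp_offset][base] == 30
            for other in rec.alleles:
                if other != base:
                    assert table[rec.snp_offset][other] == 0
        assert ac.hap_counts["ind1"][entry.locus_id] == {hap: 30}

    def test_heterozygote_counts_binomial(self, pool_setup):
        gm, panel = pool_setup
        entry = panel[0]
        cat = gm.alleles[0]
        depth = 2000
        rng = np.random.default_rng(1)
        reads = []
        for _ in range(depth):
            hap = cat[0] if rng.random() < 0.5 else cat[1]
            template = list(entry.locus.sequence)
            for snp, base in zip(entry.locus.snps, hap):
                template[snp.offset] = base
            reads.append(("het", "".join(template)))
        ac = count_alleles(reads, [entry])
        hap_counts = ac.hap_counts["het"][entry.locus_id]
        lo, hi = stats.binom.interval(0.999, depth, 0.5)
        assert lo <= hap_counts.get(cat[0], 0) <= hi

    def test_probe_window_mismatch_uncounted(self, pool_setup):
        gm, panel = pool_setup
        entry = panel[0]
        snp = entry.locus.snps[0]
        template = list(entry.locus.sequence)
        # corrupt one base inside the probe window but off the SNP itself
        pos = snp.offset + 3
        template[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[template[pos]]
        # read still matched by... nothing at this SNP if no IUPAC covers it
        read = "".join(template)
        ac = count_alleles([("x", read)], [entry])
        if ac.snp_counts:  # read may fail the on-target probe check entirely
            table = ac.snp_counts.get("x", {}).get(entry.locus_id, {})
            if snp.offset in table:
                assert all(v == 0 for v in table[snp.offset].values())

    def test_unknown_individual_rejected_with_map(self, pool_setup):
        _, panel = pool_setup
        with pytest.raises(KeyError, match="ghost"):
            count_alleles([("ghost", "A" * 150)], panel, individuals=["known"])


class TestMlCalling:
    def _single_snp_panel(self):
        gm, _ = simulate_temporal_genotypes(
            DriftParams(
                n_loci=1,
                years=(2000,),
                samples_per_year=5,
                allele_number_probs=(1.0, 0.0, 0.0),
                missingness=0.0,
                seed=23,
            )
        )
        _, panel = build_panel_for_gm(gm, seed=23)
        return gm, panel

    def _counts_to_ac(self, panel, counts):
        from gtpanel.qc import AlleleCounts

        entry = panel[0]
        cat = sorted("".join(c) for c in __import__("itertools").product(*(r.alleles for r in entry.probes)))
        haps = {h: int(n) for h, n in zip(cat, counts) if n}
        return AlleleCounts(
            {"i": {entry.locus_id: {}}},
            {"i": {entry.locus_id: haps}},
            {"i": {entry.locus_id: int(sum(counts))}},
            ["i"],
        )

    def test_clear_homozygote(self):
        _, panel = self._single_snp_panel()
        gm = call_genotypes_ml(self._counts_to_ac(panel, [20, 0]), panel)
        assert gm.call_string(0, 0).split("/")[0] == gm.call_string(0, 0).split("/")[1]

    def test_balanced_heterozygote_beats_homozygote(self):
        _, panel = self._single_snp_panel()
        counts = np.array([10.0, 10.0])
        gm = call_genotypes_ml(self._counts_to_ac(panel, counts), panel)
        a, b = gm.call_string(0, 0).split("/")
        assert a != b
        ll_het = multinomial_loglik(counts, (0, 1), 0.01)
        ll_hom = max(multinomial_loglik(counts, (0, 0), 0.01), multinomial_loglik(counts, (1, 1), 0.01))
        assert ll_het > ll_hom

    def test_below_min_depth_missing(self):
        _, panel = self._single_snp_panel()
        gm = call_genotypes_ml(self._counts_to_ac(panel, [4, 3]), panel, min_depth=10)
        assert gm.call_string(0, 0) == "."

    def test_scale_consistency(self):
        _, panel = self._single_snp_panel()
        rng = np.random.default_rng(3)
        for _ in range(50):
            c = rng.integers(0, 30, size=2)
            if c.sum() < 10:
                continue
            g1 = call_genotypes_ml(self._counts_to_ac(panel, c), panel)
            g2 = call_genotypes_ml(self._counts_to_ac(panel, c * 10), panel)
            assert g1.call_string(0, 0) == g2.call_string(0, 0)


class TestConcordance:
    def _gm_pair(self, n=40, L=25, seed=0):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 2, size=(n, L, 2)).astype(np.int16)
        gm = make_matrix([calls])
        return gm

    def test_identity_is_perfect(self):
        gm = self._gm_pair()
        conc = genotype_concordance(gm, gm)
        assert conc.overall == pytest.approx(1.0)
        assert (conc.per_snp["accuracy"] == 1.0).all()

    def test_exact_five_percent_corruption(self):
        gm = self._gm_pair(n=40, L=50)
        calls = gm.calls.copy()
        n_flip = int(0.05 * 40 * 50)
        flat = [(i, j) for i in range(40) for j in range(50)]
        rng = np.random.default_rng(1)
        for k in rng.choice(len(flat), size=n_flip, replace=False):
            i, j = flat[k]
            a, b = calls[i, j]
            calls[i, j] = (1 - a, 1 - a)  # guaranteed different unordered pair
        gm2 = GenotypeMatrix(gm.individuals, gm.collections, gm.loci, gm.alleles, calls)
        conc = genotype_concordance(gm, gm2)
        # every SNP sees 40 comparisons; exactly 5% of all calls flipped
        total_matches = (conc.per_snp["accuracy"] * conc.per_snp["n_compared"]).sum()
        assert total_matches == 40 * 50 - n_flip
        assert (
            total_matches / conc.per_snp["n_compared"].sum() == pytest.approx(0.95)
        )

    def test_low_callrate_individual_excluded(self):
        gm = self._gm_pair(n=10, L=10)
        calls = gm.calls.copy()
        calls[0, :4] = MISSING  # 60% call rate for individual 0
        gm2 = GenotypeMatrix(gm.individuals, gm.collections, gm.loci, gm.alleles, calls)
        conc = genotype_concordance(gm, gm2, min_locus_callrate_per_ind=0.70)
        assert gm.individuals[0] not in conc.individuals_used

    def test_no_shared_individuals_errors(self):
        gm = self._gm_pair(n=4, L=3)
        other = GenotypeMatrix(
            [f"z{i}" for i in range(4)], gm.collections, gm.loci, gm.alleles, gm.calls
        )
        with pytest.raises(ValueError, match="shared individuals"):
            genotype_concordance(gm, other)


class TestRepresentationAndRemovals:
    def _rc(self, on_target, interactions=None):
        inter = interactions or {}
        total = sum(on_target.values()) + sum(inter.values())
        return ReadClassSummary(total, on_target, inter, 0)

    def test_uniform_counts_no_flags(self):
        rc = self._rc({f"l{i}": 100 for i in range(20)})
        over, under = flag_representation(rc)
        assert over == [] and under == []

    def test_dominant_locus_flagged_over(self):
        counts = {f"l{i}": 10 for i in range(99)}
        counts["hog"] = 990  # 50% of all reads across 100 loci
        rc = self._rc(counts)
        over, _ = flag_representation(rc)
        assert over == ["hog"]

    def test_zero_read_locus_flagged_under(self):
        counts = {f"l{i}": 100 for i in range(10)}
        counts["dead"] = 0
        _, under = flag_representation(self._rc(counts))
        assert under == ["dead"]

    def test_single_dominant_pair_removed_alone(self):
        on = {f"l{i}": 100 for i in range(6)}
        inter = {("l0", "l1"): 970, ("l2", "l3"): 15, ("l4", "l5"): 15}
        rc = self._rc(on, inter)
        plan = recommend_removals(
            rc, per_locus_fst={f"l{i}": 0.01 * i for i in range(6)}
        )
        # the duo (l0, l1) dominates; only its lower-theta member goes
        assert plan.removals.get("l0") == "interaction"
        assert "l1" not in plan.removals

    def test_duo_keeps_higher_fst_member(self):
        on = {"a": 100, "b": 100}
        rc = self._rc(on, {("a", "b"): 500, ("b", "a"): 400})
        plan = recommend_removals(rc, per_locus_fst={"a": 0.2, "b": 0.05})
        assert "b" in plan.removals and "a" not in plan.removals

    def test_protected_locus_never_removed(self):
        on = {"sex": 100, "b": 100}
        rc = self._rc(on, {("sex", "b"): 500})
        plan = recommend_removals(rc, per_locus_fst={"sex": 0.0, "b": 0.5}, protected={"sex"})
        assert "sex" not in plan.removals and "b" in plan.removals

    def test_accurate_snps_keep_locus(self):
        rc = self._rc({"a": 100, "b": 100})
        plan = recommend_removals(
            rc, snp_accuracy={"a:0": 0.99, "a:1": 0.5, "b:0": 0.3, "b:1": 0.2}
        )
        assert "a" not in plan.removals  # one SNP passes
        assert plan.removals.get("b") == "low_accuracy"
        assert set(plan.snps_dropped) == {"a:1", "b:0", "b:1"}


class TestStoppingRule:
    @pytest.mark.parametrize(
        "prop,acc,stop",
        [
            (0.20, 0.983, True),
            (0.355, 0.953, False),  # interactions still >= 1/3
            (0.10, None, False),
            (0.10, 0.94, False),
        ],
    )
    def test_rule(self, prop, acc, stop):
        out = assess_round(prop, acc)
        assert out.stop is stop
        if acc is None:
            assert out.reason == "accuracy unavailable"


class TestSexAssignment:
    MAPPING = {("AG", "AG"): "F", ("AG", "CT"): "M"}

    def _gm(self, diplos):
        alleles = sorted({h for d in diplos for h in d})
        idx = {h: k for k, h in enumerate(alleles)}
        calls = np.array([[sorted((idx[a], idx[b]))] for a, b in diplos], dtype=np.int16)
        return GenotypeMatrix(
            [f"i{k}" for k in range(len(diplos))],
            [1] * len(diplos),
            ["HAM6"],
            [alleles],
            calls,
        )

    def test_mapping_lookup_and_unresolved(self):
        gm = self._gm([("AG", "AG"), ("AG", "CT"), ("CT", "CT")])
        out = assign_sex(gm, "HAM6", self.MAPPING)
        assert out["i0"] == "F" and out["i1"] == "M"
        assert out["i2"] == UNRESOLVED  # diplotype absent from the mapping

    def test_missing_call_unresolved(self):
        gm = self._gm([("AG", "AG")])
        gm.calls[0, 0] = MISSING
        out = assign_sex(gm, "HAM6", self.MAPPING)
        assert out["i0"] == UNRESOLVED

    def test_malformed_mapping_rejected(self):
        gm = self._gm([("AG", "AG")])
        with pytest.raises(ValueError, match="mapping"):
            assign_sex(gm, "HAM6", {"AG/AG": "F"})

    def test_simulated_cohort_round_trips(self):
        sexes, diplos = simulate_sex_genotypes(60, self.MAPPING, rng=5)
        gm = self._gm(diplos)
        out = assign_sex(gm, "HAM6", self.MAPPING)
        assert [out[f"i{k}"] for k in range(60)] == sexes
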