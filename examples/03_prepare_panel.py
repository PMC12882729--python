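"""Make loci assayable: SNP trimming, probe design, primer screening.

A SNP within 33 bp of a locus end (25 bp primer + 8 bp probe flank)
cannot be assayed; the trimming rule cuts through such SNPs iteratively.
Each retained SNP gets one 17 nt probe per allele, and candidate primer
pairs are screened for exact off-target matches on the reference.
"""

from gtpanel.model import MicrohapLocus, SnpSite
from gtpanel.primers import (
    Removed,
    build_probes,
    prepare_panel,
    trim_snps_for_primers,
)
from gtpanel.simulate import naive_primer_candidates, simulate_reference_with_loci

# the trimming rule on a locus with one edge-proximal and one interior SNP
seq = list("G" * 140)
seq[10] = "A"
seq[80] = "A"
demo = MicrohapLocus(
    "demo", "".join(seq), (SnpSite("demo", 10, ("A", "C")), SnpSite("demo", 80, ("A", "T")))
)
t = trim_snps_for_primers(demo)
print(f"demo locus: kept interval [{t.kept_start}, {t.kept_end}), "
      f"{len(t.snps)} SNP retained, {t.discarded_snps} discarded")
print("probes for the surviving SNP (17 nt, allele at the centre):")
for rec in build_probes(t):
    for allele, probe in zip(rec.alleles, rec.probes):
        print(f"  {allele}: {probe}")

# full preparation chain over simulated loci embedded in a reference
genome, loci = simulate_reference_with_loci(40, locus_len=150, genome_len=60_000, seed=3)
candidates = {l.locus_id: naive_primer_candidates for l in loci}
panel, removals = prepare_panel(loci, genome, candidates)
print(f"\n{len(loci)} candidate loci -> {len(panel)} panel entries")
reasons = {}
for r in removals.values():
    reasons[r] = reasons.get(r, 0) + 1
print("removals by reason:", reasons)
print("('no_snps' = all SNPs edge-proximal; 'no_candidates' = template too short",
      "\n for a 100-150 bp product after trimming)")
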