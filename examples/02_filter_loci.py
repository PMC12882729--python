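"""Pre-panel locus filtering: depth/missingness -> HWE -> LD.

A locus must have mean read depth >= 20, individuals must miss < 25% of
calls, Hardy-Weinberg disequilibrium must appear in EVERY temporal
collection before a locus is discarded, and one of each significantly
linked locus pair is removed.
"""

from gtpanel.filters import apply_filters
from gtpanel.simulate import (
    DriftParams,
    embed_loci_for_catalogues,
    simulate_temporal_genotypes,
)

gm, _ = simulate_temporal_genotypes(DriftParams(n_loci=300, seed=2))
_, loci = embed_loci_for_catalogues(gm.loci, gm.alleles, genome_len=200_000, seed=2)

report, gm_f, loci_f = apply_filters(loci, gm, seed=2)
print("input loci:     ", gm.n_loci)
print("retained loci:  ", len(report.retained_loci))
print("exclusions:     ", report.counts()["excluded"] or "none")
print("individuals:    ", f"{len(report.retained_individuals)} kept,",
      f"{len(report.excluded_individuals)} dropped for missingness")
print("\nEach exclusion reason maps to one filter: 'depth' = coverage < 20x,")
print("'HWE' = out of equilibrium in all 12 collections, 'LD' = linked pair member.")
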