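"""Assign sex from a two-SNP sex-linked locus diplotype.

The sex marker is a microhaplotype locus whose two SNPs (e.g. A/C and
G/T) form haplotypes like "AG" and "CT"; a configured mapping from
unordered diplotypes to labels assigns each individual, with UNRESOLVED
for missing calls or diplotypes outside the mapping.
"""

import numpy as np

from gtpanel.model import GenotypeMatrix, MISSING
from gtpanel.qc import assign_sex
from gtpanel.simulate import simulate_sex_genotypes

MAPPING = {("AG", "AG"): "F", ("AG", "CT"): "M"}  # ZW-style: one het sex

sexes, diplos = simulate_sex_genotypes(40, MAPPING, rng=6)
alleles = sorted({h for d in diplos for h in d})
idx = {h: k for k, h in enumerate(alleles)}
calls = np.array([[sorted((idx[a], idx[b]))] for a, b in diplos], dtype=np.int16)
calls[0, 0] = MISSING  # one failed genotype
gm = GenotypeMatrix(
    [f"fish{k:02d}" for k in range(40)], [2018] * 40, ["HAM6"], [alleles], calls
)

out = assign_sex(gm, "HAM6", MAPPING)
agree = sum(out[f"fish{k:02d}"] == s for k, s in enumerate(sexes) if k != 0)
print("individual  diplotype  assigned  truth")
for k in range(5):
    ind = f"fish{k:02d}"
    print(f"{ind}      {gm.call_string(k, 0):9} {out[ind]:9} {sexes[k]}")
print(f"...\nagreement on called individuals: {agree}/39")
print(f"fish00 (missing call) -> {out['fish00']}")
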