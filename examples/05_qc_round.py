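"""QC one multiplexed amplicon sequencing round and apply the stop rule.

Reads are classified as on-target, primer interaction (chimera) or
unknown; allele-bearing reads are counted via probes; genotypes are
called by maximum likelihood; accuracy is measured against the known
genotypes; the optimization loop prunes interaction-driving pairs until
interactions < 1/3 of reads and accuracy > 95%.
"""

import numpy as np

from gtpanel.qc import run_optimization
from gtpanel.selection import per_locus_temporal_fst
from gtpanel.simulate import (
    DriftParams,
    ReadSimParams,
    panel_for_genotypes,
    simulate_temporal_genotypes,
)

gm, _ = simulate_temporal_genotypes(
    DriftParams(n_loci=60, years=(2000, 2010), samples_per_year=12, missingness=0.0, seed=5)
)
_, panel = panel_for_genotypes(gm, seed=5)
fst_by = {f.locus_id: f.theta for f in per_locus_temporal_fst(gm)}

# designate a hot set of loci that drives the interaction load
rng = np.random.default_rng(5)
hot = set(rng.choice(gm.loci, size=15, replace=False))
weights = {l: (16.0 if l in hot else 1.0) for l in gm.loci}
rp = ReadSimParams(
    depth_mean=40, interaction_fraction=0.8, interaction_weights=weights, seed=5
)

assessments, panel_out = run_optimization(
    list(panel), gm, rp, per_locus_fst=fst_by, max_rounds=6, seed=5
)
print("round  interactions  accuracy  stop")
for k, a in enumerate(assessments, 1):
    acc = "NA" if a.accuracy is None else f"{100 * a.accuracy:5.1f}%"
    print(f"  {k}     {100 * a.proportion_interactions:5.1f}%      {acc}   {a.stop}")
kept = sum(e.active for e in panel_out)
print(f"\npanel: {len(panel)} -> {kept} loci after pruning interaction-driving pairs")
print("(the loop stops once interactions < 33.3% AND accuracy > 95%)")
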