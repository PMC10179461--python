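"""Predict cis (co-location) and trans (co-expression) lncRNA targets.

cis: coding genes within 10 kb of an lncRNA on the same chromosome.
trans: |Pearson r| > 0.95 with p < 0.01 across all six samples.
Recovery is scored against the generator's planted pairs.
"""

from lncdosage import SimulationConfig, cis_targets, simulate_dataset, trans_targets
from lncdosage.expression import cpm

config = SimulationConfig(nb_dispersion=0.01, n_cis_planted=20, n_trans_planted=20, seed=1)
dataset = simulate_dataset(config)

lncs = [g for g in dataset.annotation if g.biotype == "lncRNA"]
coding = [g for g in dataset.annotation if g.biotype == "coding"]

cis = cis_targets(lncs, coding, window=10_000)
norm = cpm(dataset.counts)
trans = trans_targets(
    norm.loc[[g.gene_id for g in lncs]],
    norm.loc[[g.gene_id for g in coding]],
    r_min=0.95,
    alpha=0.01,
)

found_cis = {(p.lncrna_id, p.target_id) for p in cis}
found_trans = {(p.lncrna_id, p.target_id) for p in trans}
planted_cis = [(p.lncrna_id, p.target_id) for p in dataset.truth_targets if p.mode == "cis"]
planted_trans = [(p.lncrna_id, p.target_id) for p in dataset.truth_targets if p.mode == "trans"]

print(f"cis pairs found:   {len(cis):5d}  planted recovered: "
      f"{sum(p in found_cis for p in planted_cis)}/{len(planted_cis)}")
print(f"trans pairs found: {len(trans):5d}  planted recovered: "
      f"{sum(p in found_trans for p in planted_trans)}/{len(planted_trans)}")

# cis recall is 1.0 by construction (planted lncRNAs sit inside the 10 kb
# window); trans recall ~0.95 at the strict joint threshold.  Trans counts
# exceed the planted pairs because genes sharing a dosage class co-vary
# across the pooled case/control samples, as in real two-group designs.
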