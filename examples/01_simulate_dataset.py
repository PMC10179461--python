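"""Generate a synthetic metafemale-vs-diploid experiment and inspect it.

The generator plants per-gene dosage classes (ratios 1.5 / 1.0 / 2/3 / 4/9),
draws negative-binomial counts for 3 replicates per group, and records the
ground truth so downstream recovery can be scored.
"""

from collections import Counter

from lncdosage import SimulationConfig, simulate_dataset

config = SimulationConfig(seed=1)
dataset = simulate_dataset(config)

n_lnc = sum(1 for g in dataset.annotation if g.biotype == "lncRNA")
print(f"genes: {len(dataset.annotation)} ({n_lnc} lncRNAs), "
      f"samples: {dataset.counts.counts.shape[1]}")
print("planted dosage classes:",
      dict(Counter(c.label for c in dataset.truth_class.values())))
print("planted targets:",
      dict(Counter(p.mode for p in dataset.truth_targets)))

# The printed class mixture is the ground truth that the ratio-distribution
# analysis (example 02) should recover from the counts alone.
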