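"""Classifying evolved strategies.

Runs a short evolutionary simulation, then classifies every final genotype
by its likely response (cooperate / defect / divorce) to each interaction
outcome, at three prior emotional states.  The same genotype can act as a
cooperator when its emotional state is positive and as a trigger or
defector when it is negative — that context dependence is the signature of
emotional bookkeeping.
"""

from pairbond import NoiseSpec, PriorEmotion, SimConfig, run_replicate
from pairbond.classify import classify_genotype_table

cfg = SimConfig(N=100, iterations=5_000, m=0.01,
                noise=NoiseSpec("perceptual", 0.08), c_div=4.0, seed=7)
summary = run_replicate(cfg)

table = classify_genotype_table(summary.genotypes,
                                priors=list(PriorEmotion.presets().values()),
                                bookkeeping=cfg.enable_bookkeeping)
for prior, sub in table.groupby("prior", sort=False):
    print(f"\nprior emotional state: {prior}")
    for _, row in sub.sort_values("fraction", ascending=False).iterrows():
        name = ("Generous " if row.generous else "") + row.category
        print(f"  {name:<22} {row.fraction:6.1%}")

print("\nFractions are shares of the final population. Expect cooperative"
      "\ncategories to dominate at the positive prior and harsher ones"
      "\n(Trigger, Defector, Quitter) to grow as the prior turns negative.")
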