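"""Emotional bookkeeping in a single pair.

Builds one bonded pair, feeds it a fixed sequence of interaction outcomes,
and prints how the focal agent's attachment and cooperativeness states
integrate the history.  Positive outcomes (R) push the states up by twice
the response trait, defections (S) pull them down, and the decay trait
drags everything back toward the genetic base.
"""

import numpy as np

from pairbond import Genotype, update_emotion
from pairbond.core import OUTCOMES

genotype = Genotype.from_traits(
    ab=0.2, av=0.2, aR=0.3, aS=-0.5, aT=-0.1, aP=-0.2,
    cb=0.1, cv=0.2, cR=0.4, cS=-0.6, cT=-0.2, cP=-0.3,
)

history = ["R", "R", "R", "S", "R", "S", "S", "R", "R", "R"]
s_a, s_c = genotype["ab"], genotype["cb"]
print(f"{'outcome':>8} {'attachment':>11} {'cooperativeness':>16}")
print(f"{'(start)':>8} {s_a:11.3f} {s_c:16.3f}")
for outcome in history:
    code = OUTCOMES.index(outcome)
    s_a = update_emotion(s_a, genotype["ab"], genotype["av"],
                         genotype.response(0, code))
    s_c = update_emotion(s_c, genotype["cb"], genotype["cv"],
                         genotype.response(1, code))
    print(f"{outcome:>8} {s_a:11.3f} {s_c:16.3f}")

print("\nEach R raises both states; each S (partner defected) cuts them"
      "\nsharply. Because the states persist between rounds, a streak of"
      "\ndefections drives attachment toward divorce territory (<= 0) even"
      "\nthough no single round is decisive.")
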