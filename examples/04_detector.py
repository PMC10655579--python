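"""Detecting stochastic defectors through emotional bookkeeping.

A partner who defects a small fraction of the time under perceptual noise
cannot be caught from any single interaction.  But attachment traits with
G_aR > 0 and G_aS < 0 accumulate evidence: the mean-field equilibrium
attachment is positive exactly when the partner's cooperation probability
x exceeds a chosen threshold 1 - epsilon (possible whenever noise < 1/2).
"""

import numpy as np

from pairbond import build_detector, detector_fixed_point

epsilon, xi = 0.10, 0.12
spec = build_detector(epsilon=epsilon, xi=xi)
print(f"detector traits for epsilon={epsilon}, xi={xi}:")
print(f"  G_ab = {spec.G_ab:+.3f}   (base attachment)")
print(f"  G_aR = {spec.G_aR:+.3f}   (response to mutual cooperation)")
print(f"  G_aS = {spec.G_aS:+.3f}   (response to being suckered)")

print("\npartner cooperation x   equilibrium attachment   verdict")
for x in np.linspace(0.80, 1.0, 9):
    s_star = detector_fixed_point(spec, x)
    verdict = "keep" if s_star > 0 else "divorce"
    print(f"{x:>21.3f}   {s_star:>22.3f}   {verdict}")

print(f"\nThe sign changes at x = {1 - epsilon:.2f}: partners sneaking in more"
      f"\nthan {epsilon:.0%} defection are eventually divorced, even though every"
      "\nsingle defection could have been noise.  Run during courtship, this"
      "\nscreening costs only the (cheap) courtship interactions.")
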