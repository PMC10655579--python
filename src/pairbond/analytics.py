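"""Mean-field approximation of emotion dynamics under perceptual noise.

For two agents cooperating with probabilities p and p', the focal agent's
outcome probabilities are

    omega = (p*p', p*(1-p'), (1-p)*p', (1-p)*(1-p'))    over (R, S, T, P)

and the expected next value of an emotional state s_e (unbounded traits
and states, nonnegative decay G_ev) is

    E[s_e(t+1)] = s_e(1 - G_ev) + G_eb*G_ev
                  + 2*(1 - G_ev) * sum_i omega_i * ((1-xi)*G_i + xi*G_flip(i))

where perceptual noise at rate xi swaps R<->S and T<->P.  In the
small-decay limit the per-interaction attachment drift against a partner
cooperating with probability x (focal cooperating deterministically) is

    delta(x) = G_aR*((1-xi)*x + (1-x)*xi) + G_aS*(xi*x + (1-x)*(1-xi)),

linear and increasing in x whenever G_aR > G_aS and xi < 1/2.  A
"stochastic-defector detector" exploits this: attachment traits G_ab > 0,
G_aR > 0, G_aS < 0 can place the equilibrium attachment's sign change
exactly at x = 1 - epsilon, so partners defecting more often than epsilon
of the time are eventually divorced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FLIP_OUTCOME

__all__ = [
    "OutcomeDistribution",
    "DetectorSpec",
    "outcome_distribution",
    "expected_update",
    "delta_attachment",
    "delta_attachment_grid",
    "detector_fixed_point",
    "build_detector",
]


@dataclass(frozen=True)
class OutcomeDistribution:
    """Focal agent's outcome probabilities, ordered (R, S, T, P)."""

    omega_R: float
    omega_S: float
    omega_T: float
    omega_P: float

    def as_array(self) -> np.ndarray:
        return np.array([self.omega_R, self.omega_S, self.omega_T, self.omega_P])


@dataclass(frozen=True)
class DetectorSpec:
    """Attachment traits implementing a stochastic-defector detector.

    Equilibrium attachment is positive iff the partner's cooperation
    probability x exceeds 1 - epsilon (valid for xi < 1/2).
    """

    epsilon: float
    xi: float
    G_ab: float
    G_aR: float
    G_aS: float
    G_av: float = 0.01


def outcome_distribution(p_focal: float, p_partner: float) -> OutcomeDistribution:
    """Outcome probabilities for independent cooperation probabilities."""
    p, q = float(p_focal), float(p_partner)
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise ValueError("cooperation probabilities must lie in [0, 1]")
    return OutcomeDistribution(p * q, p * (1 - q), (1 - p) * q, (1 - p) * (1 - q))


def expected_update(s_e: float, base: float, decay: float,
                    responses: np.ndarray, omega: OutcomeDistribution | np.ndarray,
                    xi: float) -> float:
    """Expected next emotional state (unclamped mean-field recursion).

    `responses` holds the outcome-response traits ordered (R, S, T, P).
    Decay must be nonnegative (its magnitude is not taken here).
    """
    if decay < 0:
        raise ValueError("the mean-field model requires nonnegative decay")
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (4,):
        raise ValueError("need one response trait per outcome (R, S, T, P)")
    w = omega.as_array() if isinstance(omega, OutcomeDistribution) else np.asarray(omega, float)
    effective = (1 - xi) * responses + xi * responses[FLIP_OUTCOME]
    return float(s_e * (1 - decay) + base * decay + w @ (2 * (1 - decay) * effective))


def delta_attachment(x: float, xi: float, G_aR: float, G_aS: float,
                     include_update_factor: bool = False) -> float:
    """Per-interaction expected attachment drift against an x-cooperator.

    The focal agent cooperates deterministically, so only R and S occur
    (possibly swapped by noise).  With `include_update_factor` the value is
    doubled to match the raw state increment of the update rule; the
    default reports the undoubled weighted-response term.  Either way the
    drift is linear in x with slope (G_aR - G_aS)*(1 - 2*xi).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("partner cooperation probability must lie in [0, 1]")
    d = (G_aR * ((1 - xi) * x + (1 - x) * xi)
         + G_aS * (xi * x + (1 - x) * (1 - xi)))
    return 2.0 * d if include_update_factor else d


def delta_attachment_grid(xis, G_aR: float, G_aS: float, n_x: int = 21,
                          out_csv=None):
    """Attachment drift tabulated over partner cooperation x for each noise
    level; optionally written to CSV for plotting."""
    import pandas as pd

    xs = np.linspace(0.0, 1.0, n_x)
    rows = [
        {"xi": xi, "x": x, "delta": delta_attachment(x, xi, G_aR, G_aS)}
        for xi in xis for x in xs
    ]
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def detector_fixed_point(spec: DetectorSpec, x: float) -> float:
    """Equilibrium attachment against a partner cooperating with probability x.

    Closed form of the fixed point of the mean-field recursion with focal
    cooperation probability 1 and small positive decay.
    """
    if spec.G_av <= 0:
        raise ValueError("detector fixed point needs positive decay")
    drift = delta_attachment(x, spec.xi, spec.G_aR, spec.G_aS)
    return spec.G_ab + 2.0 * (1 - spec.G_av) / spec.G_av * drift


def build_detector(epsilon: float, xi: float, G_av: float = 0.01,
                   G_ab: float = 0.5) -> DetectorSpec:
    """Construct attachment traits whose equilibrium attachment changes sign
    at partner cooperation probability x = 1 - epsilon.

    Solves the fixed-point condition for G_aS given G_ab > 0 and a G_aR
    chosen inside the trait bounds; raises if xi >= 1/2 (noise then masks
    stochastic defection entirely) or if no in-bounds traits exist.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    if xi >= 0.5:
        raise ValueError("detection requires xi < 1/2")
    if xi < 0:
        raise ValueError("xi must be nonnegative")
    if not 0 < G_av < 1:
        raise ValueError("decay must lie in (0, 1)")
    if not 0 < G_ab <= 1:
        raise ValueError("base attachment must lie in (0, 1]")

    x0 = 1.0 - epsilon
    w_R = (1 - xi) * x0 + (1 - x0) * xi      # weight on G_aR at the threshold
    w_S = xi * x0 + (1 - x0) * (1 - xi)      # weight on G_aS at the threshold
    target = -G_ab * G_av / (2.0 * (1 - G_av))   # required drift at x0

    # G_aS = (target - G_aR * w_R) / w_S; keep both traits inside (-1, 1)
    g_max = (target + w_S) / w_R             # largest G_aR with G_aS >= -1
    if g_max <= 0:
        raise ValueError(f"no in-bounds detector exists for epsilon={epsilon}, xi={xi}")
    G_aR = min(0.25, 0.9 * g_max)
    G_aS = (target - G_aR * w_R) / w_S
    spec = DetectorSpec(epsilon=epsilon, xi=xi, G_ab=G_ab, G_aR=G_aR, G_aS=G_aS, G_av=G_av)
    if not (spec.G_aR > 0 and spec.G_aS < 0):
        raise ValueError(f"no valid detector for epsilon={epsilon}, xi={xi}")
    return spec
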