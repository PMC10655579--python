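"""Genetic architecture, emotional state, and decision primitives.

Agents carry four emotional states — attachment, cooperativeness, deceit
and courtship — each a real value in [-1, 1].  Every state is governed by
six heritable traits: a base value, a decay rate, and one response per
prisoner's-dilemma outcome (R, T, P, S), for 24 evolvable traits in all.

After each interaction a state is updated from the *perceived* outcome:

    s_hat = s + 2 * G_response(outcome)
    s'    = s_hat + (G_base - s_hat) * |G_decay|      (then clamped to [-1, 1])

Decisions are Bernoulli draws through a sigmoid of the relevant state; the
default is the piecewise-linear sigmoid pi(s) = clip(s + 1/2, 0, 1), which
is linear on [-1/2, 1/2) and deterministic outside that range.

All functions here accept scalars or numpy arrays element-wise; the
population engine calls the same code on whole index vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EMOTIONS",
    "E_ATT",
    "E_COOP",
    "E_DEC",
    "E_COURT",
    "TRAIT_NAMES",
    "T_BASE",
    "T_DECAY",
    "T_R",
    "T_T",
    "T_P",
    "T_S",
    "OUTCOMES",
    "O_R",
    "O_S",
    "O_T",
    "O_P",
    "OUTCOME_TRAIT_COL",
    "FLIP_OUTCOME",
    "ConfigurationError",
    "Genotype",
    "EmotionalState",
    "SigmoidSpec",
    "init_genotype",
    "mutate",
    "reset_emotions",
    "update_emotion",
    "emotion_without_bookkeeping",
    "decision_probability",
    "sample_choice",
]

# Emotional-state axis: attachment, cooperativeness, deceit, courtship.
EMOTIONS = ("a", "c", "d", "p")
E_ATT, E_COOP, E_DEC, E_COURT = range(4)

# Trait axis per emotion: base, decay, and the four outcome responses.
TRAIT_NAMES = ("b", "v", "R", "T", "P", "S")
T_BASE, T_DECAY, T_R, T_T, T_P, T_S = range(6)

# Outcome codes, ordered (R, S, T, P) to match the analytical outcome vector.
OUTCOMES = ("R", "S", "T", "P")
O_R, O_S, O_T, O_P = range(4)

# outcome code -> column of the trait matrix holding the response to it
OUTCOME_TRAIT_COL = np.array([T_R, T_S, T_T, T_P], dtype=np.intp)

# Perceiving the partner's opposite action maps R<->S and T<->P.
FLIP_OUTCOME = np.array([O_S, O_R, O_P, O_T], dtype=np.intp)

TRAIT_MIN, TRAIT_MAX = -1.0, 1.0


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid before any simulation."""


def _clamp_traits(x: np.ndarray) -> np.ndarray:
    return np.clip(x, TRAIT_MIN, TRAIT_MAX)


@dataclass
class Genotype:
    """The 24 heritable traits of one agent, as a (4 emotions, 6 traits) array.

    Rows follow :data:`EMOTIONS` (a, c, d, p); columns follow
    :data:`TRAIT_NAMES` (b, v, R, T, P, S).  The array may be a view into a
    population's trait tensor, in which case writes flow through.
    """

    traits: np.ndarray = field(default_factory=lambda: np.zeros((4, 6)))

    def __post_init__(self) -> None:
        self.traits = np.asarray(self.traits, dtype=float)
        if self.traits.shape != (4, 6):
            raise ValueError(f"genotype must be (4, 6), got {self.traits.shape}")

    @classmethod
    def zeros(cls) -> "Genotype":
        return cls(np.zeros((4, 6)))

    @classmethod
    def from_traits(cls, **traits: float) -> "Genotype":
        """Build a genotype from named traits such as ``cR=1.0`` or ``av=0.5``.

        A key is the emotion letter (a, c, d, p) followed by the trait letter
        (b, v, R, T, P, S).  Unnamed traits default to zero.
        """
        g = cls.zeros()
        for key, value in traits.items():
            g[key] = value
        return g

    @staticmethod
    def _index(key: str) -> tuple[int, int]:
        if len(key) != 2 or key[0] not in EMOTIONS or key[1] not in TRAIT_NAMES:
            raise KeyError(f"unknown trait {key!r}; expected e.g. 'cR', 'ab', 'av'")
        return EMOTIONS.index(key[0]), TRAIT_NAMES.index(key[1])

    def __getitem__(self, key: str) -> float:
        i, j = self._index(key)
        return float(self.traits[i, j])

    def __setitem__(self, key: str, value: float) -> None:
        i, j = self._index(key)
        self.traits[i, j] = value

    def copy(self) -> "Genotype":
        return Genotype(self.traits.copy())

    def response(self, emotion: int, outcome: int) -> float:
        """Trait response of one emotion to an outcome code (O_R..O_P)."""
        return float(self.traits[emotion, OUTCOME_TRAIT_COL[outcome]])


class EmotionalState:
    """Four bounded scalars (s_a, s_c, s_d, s_p) over a shared length-4 array.

    May wrap a view into the population's emotion matrix, so assignments to
    ``s_a`` etc. write through to the simulation state.
    """

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray | None = None):
        if values is None:
            values = np.zeros(4)
        values = np.asarray(values, dtype=float)
        if values.shape != (4,):
            raise ValueError("emotional state must have exactly four values")
        self.values = values

    def _get(self, i: int) -> float:
        return float(self.values[i])

    def _set(self, i: int, v: float) -> None:
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"emotional state must lie in [-1, 1], got {v}")
        self.values[i] = v

    s_a = property(lambda self: self._get(E_ATT), lambda self, v: self._set(E_ATT, v))
    s_c = property(lambda self: self._get(E_COOP), lambda self, v: self._set(E_COOP, v))
    s_d = property(lambda self: self._get(E_DEC), lambda self, v: self._set(E_DEC, v))
    s_p = property(lambda self: self._get(E_COURT), lambda self, v: self._set(E_COURT, v))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"EmotionalState(s_a={self.s_a}, s_c={self.s_c}, s_d={self.s_d}, s_p={self.s_p})"


@dataclass(frozen=True)
class SigmoidSpec:
    """Choice of decision sigmoid.

    ``piecewise_linear`` is the default policy map; ``smooth`` is the
    logistic 1/(1 + exp(-a*s)) used for sensitivity comparison, with slope
    ``a`` ignored by the piecewise kind.
    """

    kind: str = "piecewise_linear"
    a: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("piecewise_linear", "smooth"):
            raise ConfigurationError(f"unknown sigmoid kind {self.kind!r}")
        if self.kind == "smooth" and not self.a > 0:
            raise ConfigurationError("smooth sigmoid slope must be positive")


def init_genotype(rng: np.random.Generator, init_sigma: float = 0.25) -> Genotype:
    """Draw a founder genotype: 24 iid Normal(0, init_sigma) traits, clamped."""
    if not init_sigma > 0:
        raise ConfigurationError("init_sigma must be positive")
    return Genotype(_clamp_traits(rng.normal(0.0, init_sigma, size=(4, 6))))


def mutate(g: Genotype, rng: np.random.Generator, mut_sigma: float = 0.04) -> Genotype:
    """Return a mutated copy: iid Normal(0, mut_sigma) added per trait, clamped."""
    if mut_sigma < 0:
        raise ConfigurationError("mut_sigma must be nonnegative")
    return Genotype(_clamp_traits(g.traits + rng.normal(0.0, mut_sigma, size=(4, 6))))


def reset_emotions(agent) -> EmotionalState:
    """Set every emotional state to its genetic base value (new partner)."""
    agent.emotions.values[:] = agent.genotype.traits[:, T_BASE]
    return agent.emotions


def update_emotion(s, base, decay, response):
    """One emotional-bookkeeping update from a perceived outcome.

    ``response`` is the genetic response trait for the perceived outcome.
    The raw effect doubles the response; the result then decays toward the
    base at rate |decay| and is clamped to [-1, 1].  Element-wise over
    arrays.
    """
    s_hat = np.asarray(s, dtype=float) + 2.0 * np.asarray(response, dtype=float)
    out = s_hat + (np.asarray(base, dtype=float) - s_hat) * np.abs(decay)
    out = np.clip(out, -1.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out

def emotion_without_bookkeeping(g: Genotype, emotion: int, outcome: int) -> float:
    """Single-interaction memory: the state becomes the outcome response trait.

    Used when emotional bookkeeping is disabled; the prior state is ignored
    and no doubling or decay applies.
    """
    return g.response(emotion, outcome)


def decision_probability(s, spec: SigmoidSpec = SigmoidSpec()):
    """Map an emotional state to an action probability through the sigmoid.

    Piecewise-linear: 0 for s < -1/2, (2s+1)/2 on [-1/2, 1/2), 1 for
    s >= 1/2.  Smooth: logistic with slope ``spec.a``.  Element-wise.
    """
    s = np.asarray(s, dtype=float)
    if spec.kind == "piecewise_linear":
        p = np.clip(s + 0.5, 0.0, 1.0)
    else:
        p = 1.0 / (1.0 + np.exp(-spec.a * s))
    if p.ndim == 0:
        return float(p)
    return p


def sample_choice(p: float, rng: np.random.Generator) -> bool:
    """Bernoulli draw: True with probability ``p`` from the supplied stream."""
    if not 0.0 <= p <= 1.0:
        raise RuntimeError(f"decision probability {p} outside [0, 1]: sigmoid bug")
    return bool(rng.random() < p)
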