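"""One courtship or bonded interaction between two partnered agents.

The round proceeds: intended actions from the cooperativeness sigmoid;
action noise (trembling hand) may flip executed actions; payoffs follow the
*actual* actions (bonded context only); a defector may deceive, paying a
cost so its partner perceives it as having cooperated; perceptual noise may
flip each agent's perceived outcome (R<->S, T<->P); finally both agents
update their emotional states from their own perceived outcome.

`play_rounds` is the vectorized kernel over index arrays of a population;
`play_round` is the two-agent wrapper returning an :class:`InteractionResult`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .core import (
    E_COOP,
    E_DEC,
    FLIP_OUTCOME,
    OUTCOME_TRAIT_COL,
    OUTCOMES,
    T_BASE,
    T_DECAY,
    ConfigurationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimConfig
    from .dynamics import Population

__all__ = [
    "PayoffMatrix",
    "NoiseSpec",
    "InteractionResult",
    "outcome_of",
    "flip_perceived",
    "play_round",
    "play_rounds",
]

COOPERATE = "cooperate"
DEFECT = "defect"


@dataclass(frozen=True)
class PayoffMatrix:
    """2x2 game payoffs: reward, temptation, sucker, punishment."""

    R: float = 3.0
    T: float = 5.0
    S: float = -1.0
    P: float = 0.0

    @classmethod
    def preset(cls, name: str) -> "PayoffMatrix":
        presets = {
            "pd": cls(R=3, T=5, S=-1, P=0),
            "staghunt": cls(R=3, T=1, S=-1, P=1),
            "snowdrift": cls(R=1, T=3, S=1, P=-1),
        }
        try:
            return presets[name]
        except KeyError:
            raise ConfigurationError(f"unknown payoff preset {name!r}") from None

    def is_prisoners_dilemma(self) -> bool:
        return self.T > self.R > self.P > self.S and 2 * self.R > self.T + self.S

    def by_outcome(self) -> np.ndarray:
        """Payoffs ordered by outcome code (R, S, T, P)."""
        return np.array([self.R, self.S, self.T, self.P], dtype=float)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise channel: perceptual (signal corrupted), action (tremble), none."""

    kind: str = "none"
    xi: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("perceptual", "action", "none"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if not 0.0 <= self.xi <= 1.0:
            raise ConfigurationError("noise level xi must lie in [0, 1]")


@dataclass
class InteractionResult:
    """Record of one round between partners A and B."""

    intended_action_a: str
    intended_action_b: str
    actual_action_a: str
    actual_action_b: str
    payoff_a: float
    payoff_b: float
    perceived_outcome_a: str
    perceived_outcome_b: str
    deceived_a: bool
    deceived_b: bool
    context: str


def outcome_of(own_action: str, partner_action: str) -> str:
    """Outcome label from the two actions: (C,C)->R, (C,D)->S, (D,C)->T, (D,D)->P."""
    for a in (own_action, partner_action):
        if a not in (COOPERATE, DEFECT):
            raise ValueError(f"unknown action {a!r}")
    code = _outcome_code(
        np.array([own_action == COOPERATE]), np.array([partner_action == COOPERATE])
    )[0]
    return OUTCOMES[code]


def flip_perceived(outcome: str) -> str:
    """Outcome perceived if the partner's action is inverted: R<->S, T<->P."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    return OUTCOMES[FLIP_OUTCOME[OUTCOMES.index(outcome)]]


def _outcome_code(own_coop: np.ndarray, partner_coop: np.ndarray) -> np.ndarray:
    """Outcome codes (O_R, O_S, O_T, O_P) from boolean cooperation flags."""
    return 2 * (~own_coop) + (~partner_coop)


def _pi(s: np.ndarray, sigmoid) -> np.ndarray:
    """Decision sigmoid on an array, minimal-overhead form of
    :func:`pairbond.core.decision_probability`."""
    if sigmoid.kind == "piecewise_linear":
        p = s + 0.5
        np.minimum(p, 1.0, out=p)
        np.maximum(p, 0.0, out=p)
        return p
    return 1.0 / (1.0 + np.exp(-sigmoid.a * s))


_EMO_COLS = np.arange(4)[None, :]


def _update_emotions(pop: "Population", idx: np.ndarray, perceived: np.ndarray,
                     bookkeeping: bool) -> None:
    """Update all four emotional states of agents `idx` from perceived outcomes."""
    rows = pop.geno[idx]  # (k, 4, 6) one gather, then cheap views
    k = idx.size
    resp = rows[np.arange(k)[:, None], _EMO_COLS, OUTCOME_TRAIT_COL[perceived][:, None]]
    if bookkeeping:
        emo = pop.emo[idx]
        s_hat = emo + 2.0 * resp
        out = s_hat + (rows[:, :, T_BASE] - s_hat) * np.abs(rows[:, :, T_DECAY])
        np.minimum(out, 1.0, out=out)
        np.maximum(out, -1.0, out=out)
        pop.emo[idx] = out
    else:
        pop.emo[idx] = resp


def play_rounds(pop: "Population", ia: np.ndarray, ib: np.ndarray,
                cfg: "SimConfig", context: str, rng: np.random.Generator) -> dict:
    """Play one round for every pair (ia[k], ib[k]); mutates population state.

    Returns a dict of per-pair arrays: intended/actual cooperation flags,
    perceived outcome codes, deceit flags, and payoffs credited (zero in the
    courting context).
    """
    ia = np.asarray(ia, dtype=np.intp)
    ib = np.asarray(ib, dtype=np.intp)
    k = ia.size
    if k == 0:
        return _empty_batch()
    # both sides share each array op: index 0..k-1 is side A, k..2k-1 side B
    iab = np.concatenate([ia, ib])

    # 1. intended actions from the cooperativeness state
    intend = rng.random(2 * k) < _pi(pop.emo[iab, E_COOP], cfg.sigmoid)

    # 2. action noise: executed action flips independently with prob xi
    if cfg.noise.kind == "action" and cfg.noise.xi > 0:
        act = intend ^ (rng.random(2 * k) < cfg.noise.xi)
    else:
        act = intend
    act_a, act_b = act[:k], act[k:]
    act_partner = np.concatenate([act_b, act_a])

    # 3. payoffs from actual actions (bonded rounds only)
    if context == "bonded":
        pay = cfg.payoffs.by_outcome()[_outcome_code(act, act_partner)]
        pop.payoff[iab] += pay
        pop.pd_total[iab] += pay
    else:
        pay = np.zeros(2 * k)

    # 4. deceit: an actual defector may pay c_dec so its partner perceives C
    if cfg.enable_deceit:
        dec = ~act & (rng.random(2 * k) < _pi(pop.emo[iab, E_DEC], cfg.sigmoid))
        pop.payoff[iab[dec]] -= cfg.c_dec
        pop.n_deceits[iab[dec]] += 1
        dec_partner = np.concatenate([dec[k:], dec[:k]])
    else:
        dec = dec_partner = np.zeros(2 * k, dtype=bool)

    # perceived partner action: actual, overridden to cooperate by deceit
    perc = _outcome_code(act, act_partner | dec_partner)

    # 5. perceptual noise: one flip event per agent covers all four states
    if cfg.noise.kind == "perceptual" and cfg.noise.xi > 0:
        flip = rng.random(2 * k) < cfg.noise.xi
        perc = np.where(flip, FLIP_OUTCOME[perc], perc)

    # 6. emotion updates from each agent's own perceived outcome
    _update_emotions(pop, iab, perc, cfg.enable_bookkeeping)

    return {
        "intended_coop_a": intend[:k],
        "intended_coop_b": intend[k:],
        "actual_coop_a": act_a,
        "actual_coop_b": act_b,
        "perceived_a": perc[:k],
        "perceived_b": perc[k:],
        "deceived_a": dec[:k],
        "deceived_b": dec[k:],
        "payoff_a": pay[:k],
        "payoff_b": pay[k:],
    }


def _empty_batch() -> dict:
    z = np.zeros(0, dtype=bool)
    return {
        "intended_coop_a": z, "intended_coop_b": z,
        "actual_coop_a": z, "actual_coop_b": z,
        "perceived_a": np.zeros(0, dtype=np.intp),
        "perceived_b": np.zeros(0, dtype=np.intp),
        "deceived_a": z, "deceived_b": z,
        "payoff_a": np.zeros(0), "payoff_b": np.zeros(0),
    }


def play_round(agent_a, agent_b, cfg: "SimConfig", context: str,
               rng: np.random.Generator) -> InteractionResult:
    """Play one round between two partnered agents of the same population."""
    if agent_a.population is not agent_b.population:
        raise RuntimeError("agents belong to different populations")
    pop = agent_a.population
    if pop.partner[agent_a.id] != agent_b.id or pop.partner[agent_b.id] != agent_a.id:
        raise RuntimeError("play_round called on agents that are not partners")
    batch = play_rounds(pop, np.array([agent_a.id]), np.array([agent_b.id]),
                        cfg, context, rng)
    act = lambda c: COOPERATE if c else DEFECT
    return InteractionResult(
        intended_action_a=act(batch["intended_coop_a"][0]),
        intended_action_b=act(batch["intended_coop_b"][0]),
        actual_action_a=act(batch["actual_coop_a"][0]),
        actual_action_b=act(batch["actual_coop_b"][0]),
        payoff_a=float(batch["payoff_a"][0]),
        payoff_b=float(batch["payoff_b"][0]),
        perceived_outcome_a=OUTCOMES[batch["perceived_a"][0]],
        perceived_outcome_b=OUTCOMES[batch["perceived_b"][0]],
        deceived_a=bool(batch["deceived_a"][0]),
        deceived_b=bool(batch["deceived_b"][0]),
        context=context,
    )
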