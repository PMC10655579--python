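"""Per-iteration life cycle: pairing, courtship, bonded rounds, Moran step.

Each iteration, all unattached agents are paired at random.  A new pair
courts (repeated costly no-payoff interactions, up to a cap) until both
consent to bond, either ends it, or the cap dissolves it.  Every bonded
pair — new or persisting — plays one prisoner's-dilemma round; unless
divorce is prohibited, either partner may then end the bond at cost c_div
to both.  Finally a death–birth Moran step kills each agent with
probability m and replaces the dead with mutated clones of survivors
chosen proportionally to lifetime payoff.

The population is stored as a struct of numpy arrays; the per-pair
operations (`courtship_phase`, `bonded_phase`, `play_round`) are singleton
calls into the same vectorized kernels used by `run_iteration`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig
from .core import E_ATT, E_COURT, T_BASE, EmotionalState, Genotype
from .interactions import _pi, play_rounds

__all__ = [
    "Agent",
    "Population",
    "PairingEvent",
    "MetricsRecord",
    "pair_unattached",
    "courtship_phase",
    "bonded_phase",
    "moran_step",
    "run_iteration",
]

_FITNESS_FLOOR = 1e-6

# courtship resolutions
BONDED, DISSOLVED, CAP_REACHED = "bonded", "dissolved_in_courtship", "courtship_cap_reached"


@dataclass
class PairingEvent:
    """Outcome of one pair's courtship phase."""

    agent_a: int
    agent_b: int
    n_courtship_rounds: int
    resolution: str


@dataclass
class MetricsRecord:
    """Per-iteration population metrics."""

    iteration: int
    mutual_cooperation_rate: float
    n_bonded_pairs: int
    n_new_pairings: int
    n_divorces: int
    n_deceptions: int
    mean_courtship_rounds: float
    mean_lifetime_payoff: float


class Agent:
    """View of one individual inside a :class:`Population`.

    Attribute writes flow through to the population arrays.
    """

    __slots__ = ("population", "id")

    def __init__(self, population: "Population", index: int):
        self.population = population
        self.id = int(index)

    @property
    def genotype(self) -> Genotype:
        return Genotype(self.population.geno[self.id])

    @property
    def emotions(self) -> EmotionalState:
        return EmotionalState(self.population.emo[self.id])

    @property
    def lifetime_payoff(self) -> float:
        return float(self.population.payoff[self.id])

    @lifetime_payoff.setter
    def lifetime_payoff(self, v: float) -> None:
        self.population.payoff[self.id] = v

    @property
    def birth_iteration(self) -> int:
        return int(self.population.birth[self.id])

    @property
    def status(self):
        pid = int(self.population.partner[self.id])
        if pid < 0:
            return ("unattached",)
        kind = "bonded" if self.population.bonded_flag[self.id] else "courting"
        return (kind, pid)


class Population:
    """N agents as a struct of arrays, plus per-agent payoff accounting."""

    def __init__(self, geno: np.ndarray, iteration: int = 0):
        geno = np.asarray(geno, dtype=float)
        if geno.ndim != 3 or geno.shape[1:] != (4, 6):
            raise ValueError("genotype tensor must have shape (N, 4, 6)")
        n = geno.shape[0]
        self.geno = geno
        self.emo = geno[:, :, T_BASE].copy()
        self.payoff = np.zeros(n)
        self.partner = np.full(n, -1, dtype=np.intp)
        self.bonded_flag = np.zeros(n, dtype=bool)
        self.birth = np.full(n, iteration, dtype=np.int64)
        self.iteration = iteration
        # accounting for the payoff ledger invariant
        self.pd_total = np.zeros(n)
        self.n_courtships = np.zeros(n, dtype=np.int64)
        self.n_deceits = np.zeros(n, dtype=np.int64)
        self.n_divorces = np.zeros(n, dtype=np.int64)

    @classmethod
    def founders(cls, cfg: SimConfig, rng: np.random.Generator) -> "Population":
        """Found a population of N agents with iid Normal(0, init_sigma) traits."""
        geno = np.clip(rng.normal(0.0, cfg.init_sigma, size=(cfg.N, 4, 6)), -1.0, 1.0)
        return cls(geno)

    @classmethod
    def from_genotypes(cls, genotypes) -> "Population":
        """Build a population from explicit :class:`Genotype` objects."""
        return cls(np.stack([g.traits for g in genotypes]))

    @property
    def n(self) -> int:
        return self.geno.shape[0]

    def agent(self, i: int) -> Agent:
        return Agent(self, i)

    def unattached(self) -> np.ndarray:
        return np.flatnonzero(self.partner < 0)

    def bonded_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (ia, ib) of bonded pairs, each pair listed once."""
        ia = np.flatnonzero(self.bonded_flag & (self.partner > np.arange(self.n)))
        return ia, self.partner[ia]

    def courting_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        ia = np.flatnonzero(~self.bonded_flag & (self.partner > np.arange(self.n)))
        return ia, self.partner[ia]

    def validate(self) -> None:
        """Raise if partnership symmetry or ledger balance is violated."""
        attached = np.flatnonzero(self.partner >= 0)
        if not np.all(self.partner[self.partner[attached]] == attached):
            raise AssertionError("partnership symmetry violated")
        if np.any(self.partner == np.arange(self.n)):
            raise AssertionError("agent partnered with itself")

    def ledger_residual(self, cfg: SimConfig) -> np.ndarray:
        """Lifetime payoff minus (PD total - costs); zero when books balance."""
        expected = (self.pd_total
                    - cfg.c_cou * self.n_courtships
                    - cfg.c_dec * self.n_deceits
                    - cfg.c_div * self.n_divorces)
        return self.payoff - expected

    def _separate(self, idx: np.ndarray) -> None:
        """Detach agents `idx` and their partners (no cost)."""
        partners = self.partner[idx]
        self.partner[idx] = -1
        self.partner[partners[partners >= 0]] = -1
        self.bonded_flag[idx] = False
        self.bonded_flag[partners[partners >= 0]] = False


def pair_unattached(pop: Population, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Randomly pair all unattached agents; an odd one waits an iteration.

    Both members of every new pair have their emotions reset to the genetic
    base values.  Returns index arrays (ia, ib) of the new pairs.
    """
    free = pop.unattached()
    order = rng.permutation(free.size)
    free = free[order]
    k = free.size // 2
    ia, ib = free[:2 * k:2], free[1:2 * k:2]
    pop.partner[ia] = ib
    pop.partner[ib] = ia
    pop.bonded_flag[ia] = False
    pop.bonded_flag[ib] = False
    both = np.concatenate([ia, ib])
    pop.emo[both] = pop.geno[both, :, T_BASE]
    return ia, ib


def _courtship_arrays(pop: Population, ia: np.ndarray, ib: np.ndarray,
                      cfg: SimConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Courtship loop over new pairs. Returns (rounds, resolution, n_deceptions).

    resolution codes: 0 bonded, 1 dissolved, 2 cap reached.
    """
    k = ia.size
    rounds = np.zeros(k, dtype=np.int64)
    resolution = np.full(k, 2, dtype=np.intp)
    deceptions = 0
    if k == 0:
        return rounds, resolution, 0

    if not cfg.enable_courtship:
        # newly paired agents bond immediately
        resolution[:] = 0
        pop.bonded_flag[ia] = True
        pop.bonded_flag[ib] = True
        return rounds, resolution, 0

    active = np.arange(k)
    for _ in range(cfg.max_courtship):
        m = active.size
        aabb = np.concatenate([ia[active], ib[active]])
        # court-vs-bond: bonding requires consensus (neither courts)
        court = rng.random(2 * m) < _pi(pop.emo[aabb, E_COURT], cfg.sigmoid)
        bond = ~court[:m] & ~court[m:]
        resolution[active[bond]] = 0
        active = active[~bond]
        if active.size == 0:
            break
        m = active.size
        aabb = np.concatenate([ia[active], ib[active]])
        # one courtship interaction: fixed cost to both, no PD payoff
        pop.payoff[aabb] -= cfg.c_cou
        pop.n_courtships[aabb] += 1
        rounds[active] += 1
        batch = play_rounds(pop, ia[active], ib[active], cfg, "courting", rng)
        deceptions += int(batch["deceived_a"].sum() + batch["deceived_b"].sum())
        # remain-attached: ending is unilateral and free during courtship
        cont = rng.random(2 * m) < _pi(pop.emo[aabb, E_ATT], cfg.sigmoid)
        end = ~(cont[:m] & cont[m:])
        resolution[active[end]] = 1
        active = active[~end]
        if active.size == 0:
            break

    bonded = resolution == 0
    pop.bonded_flag[ia[bonded]] = True
    pop.bonded_flag[ib[bonded]] = True
    failed = ~bonded
    pop._separate(ia[failed])
    return rounds, resolution, deceptions


def courtship_phase(pair: tuple[Agent, Agent], cfg: SimConfig,
                    rng: np.random.Generator) -> PairingEvent:
    """Run the courtship loop for one newly formed pair."""
    a, b = pair
    pop = a.population
    rounds, resolution, _ = _courtship_arrays(
        pop, np.array([a.id]), np.array([b.id]), cfg, rng)
    return PairingEvent(a.id, b.id, int(rounds[0]),
                        (BONDED, DISSOLVED, CAP_REACHED)[resolution[0]])


def _bonded_arrays(pop: Population, ia: np.ndarray, ib: np.ndarray,
                   cfg: SimConfig, rng: np.random.Generator) -> dict:
    """One bonded PD round per pair, then the divorce decision."""
    batch = play_rounds(pop, ia, ib, cfg, "bonded", rng)
    k = ia.size
    if cfg.divorce_mode == "prohibited" or k == 0:
        divorced = np.zeros(k, dtype=bool)
    else:
        u = rng.random((2, k))
        cont_a = u[0] < _pi(pop.emo[ia, E_ATT], cfg.sigmoid)
        cont_b = u[1] < _pi(pop.emo[ib, E_ATT], cfg.sigmoid)
        divorced = ~(cont_a & cont_b)
        da, db = ia[divorced], ib[divorced]
        pop.payoff[da] -= cfg.c_div
        pop.payoff[db] -= cfg.c_div
        pop.n_divorces[da] += 1
        pop.n_divorces[db] += 1
        pop._separate(da)
    batch["divorced"] = divorced
    return batch


def bonded_phase(pair: tuple[Agent, Agent], cfg: SimConfig,
                 rng: np.random.Generator) -> str:
    """One bonded round plus divorce decision; 'still_bonded' or 'divorced'."""
    a, b = pair
    batch = _bonded_arrays(a.population, np.array([a.id]), np.array([b.id]), cfg, rng)
    return "divorced" if batch["divorced"][0] else "still_bonded"


def moran_step(pop: Population, cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Death–birth Moran step: random death, payoff-proportional reproduction.

    Each agent dies independently with probability m.  The surviving partner
    of a dead agent becomes unattached at no cost.  Each dead agent is
    replaced in place by a mutated clone of a survivor drawn with
    probability proportional to (lifetime payoff - min + epsilon); if no
    one survives, parents are drawn uniformly from the pre-death population.
    """
    dead = rng.random(pop.n) < cfg.m
    ndead = int(dead.sum())
    if ndead == 0:
        return pop
    dead_idx = np.flatnonzero(dead)
    surv_idx = np.flatnonzero(~dead)

    # widowed survivors become unattached (no divorce cost)
    widowed = pop.partner[dead_idx]
    widowed = widowed[widowed >= 0]
    pop.partner[widowed] = -1
    pop.bonded_flag[widowed] = False

    if surv_idx.size == 0:
        parents = rng.integers(0, pop.n, size=ndead)
        parent_geno = pop.geno.copy()[parents]
    else:
        fitness = pop.payoff[surv_idx]
        weights = fitness - fitness.min() + _FITNESS_FLOOR
        parents = rng.choice(surv_idx, size=ndead, p=weights / weights.sum())
        parent_geno = pop.geno[parents]

    child = np.clip(parent_geno + rng.normal(0.0, cfg.mut_sigma, size=(ndead, 4, 6)),
                    -1.0, 1.0)
    pop.geno[dead_idx] = child
    pop.emo[dead_idx] = child[:, :, T_BASE]
    pop.payoff[dead_idx] = 0.0
    pop.partner[dead_idx] = -1
    pop.bonded_flag[dead_idx] = False
    pop.birth[dead_idx] = pop.iteration
    pop.pd_total[dead_idx] = 0.0
    pop.n_courtships[dead_idx] = 0
    pop.n_deceits[dead_idx] = 0
    pop.n_divorces[dead_idx] = 0
    return pop


def run_iteration(pop: Population, cfg: SimConfig, rng: np.random.Generator) -> MetricsRecord:
    """Advance the population by one full iteration and return its metrics."""
    ia_new, ib_new = pair_unattached(pop, rng)
    rounds, resolution, court_deceptions = _courtship_arrays(pop, ia_new, ib_new, cfg, rng)

    ia, ib = pop.bonded_pairs()
    batch = _bonded_arrays(pop, ia, ib, cfg, rng)
    both_coop = batch["actual_coop_a"] & batch["actual_coop_b"]
    n_bonded = ia.size
    n_deceptions = court_deceptions + int(batch["deceived_a"].sum() + batch["deceived_b"].sum())

    record = MetricsRecord(
        iteration=pop.iteration,
        mutual_cooperation_rate=float(both_coop.mean()) if n_bonded else 0.0,
        n_bonded_pairs=n_bonded,
        n_new_pairings=int(ia_new.size),
        n_divorces=int(batch["divorced"].sum()),
        n_deceptions=n_deceptions,
        mean_courtship_rounds=float(rounds.mean()) if rounds.size else 0.0,
        mean_lifetime_payoff=float(pop.payoff.mean()),
    )
    moran_step(pop, cfg, rng)
    pop.iteration += 1
    return record
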