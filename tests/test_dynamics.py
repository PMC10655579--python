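"""Unit tests for the per-iteration life cycle and the Moran process."""

import numpy as np
import pytest

from pairbond import (
    Genotype,
    NoiseSpec,
    Population,
    SimConfig,
    bonded_phase,
    courtship_phase,
    moran_step,
    pair_unattached,
    run_iteration,
)
from pairbond.core import E_ATT, E_COOP, E_COURT

from conftest import make_pair_population


def config(**kw):
    defaults = dict(N=4, iterations=1, c_div=0.0)
    defaults.update(kw)
    return SimConfig(**defaults)


def fresh_population(n, rng, cfg=None):
    return Population.founders(cfg or config(N=n), rng)


class TestPairing:
    @pytest.mark.parametrize("n,pairs,leftover", [(4, 2, 0), (5, 2, 1), (1, 0, 1), (0, 0, 0)])
    def test_parity(self, n, pairs, leftover, rng):
        pop = fresh_population(max(n, 2), rng, config(N=max(n, 2)))
        pop.partner[:] = 0  # mark everyone attached...
        pop.partner[:n] = -1  # ...except the first n
        ia, ib = pair_unattached(pop, rng)
        assert ia.size == pairs
        assert np.sum(pop.partner[:n] < 0) == leftover

    def test_pairing_resets_emotions_to_base(self, rng):
        pop = make_pair_population(Genotype.from_traits(ab=0.5, cb=-0.25),
                                   Genotype.zeros())
        pop.partner[:] = -1
        pop.emo[:] = 0.9
        pair_unattached(pop, rng)
        assert pop.emo[0, E_ATT] == 0.5 and pop.emo[0, E_COOP] == -0.25

    def test_fixed_seed_reproducible(self):
        cfg = config(N=10)
        p1 = fresh_population(10, np.random.default_rng(4), cfg)
        p2 = fresh_population(10, np.random.default_rng(4), cfg)
        pair_unattached(p1, np.random.default_rng(11))
        pair_unattached(p2, np.random.default_rng(11))
        np.testing.assert_array_equal(p1.partner, p2.partner)

    def test_partnership_symmetry(self, rng):
        pop = fresh_population(9, rng, config(N=9))
        pair_unattached(pop, rng)
        pop.validate()


class TestCourtship:
    def test_bond_immediately_when_never_courting(self, rng):
        """Courtship probability 0 (base s_p = -1) bonds with zero rounds."""
        g = Genotype.from_traits(pb=-1.0)
        pop = make_pair_population(g, g, bonded=False)
        pop.emo[:, E_COURT] = -1.0
        ev = courtship_phase((pop.agent(0), pop.agent(1)), config(), rng)
        assert ev.resolution == "bonded" and ev.n_courtship_rounds == 0
        assert pop.bonded_flag.all()

    def test_cap_dissolves_permanent_courtiers(self, rng):
        """Always-court, always-stay agents hit the 20-interaction cap."""
        g = Genotype.from_traits(pb=1.0, ab=1.0, pR=1.0, aR=1.0, pS=1.0, aS=1.0,
                                 pT=1.0, aT=1.0, pP=1.0, aP=1.0)
        pop = make_pair_population(g, g, bonded=False)
        pop.emo[:] = pop.geno[:, :, 0]
        ev = courtship_phase((pop.agent(0), pop.agent(1)), config(), rng)
        assert ev.n_courtship_rounds == 20
        assert ev.resolution == "courtship_cap_reached"
        assert not pop.bonded_flag.any() and (pop.partner < 0).all()

    def test_courtship_costs_accrue(self, rng):
        g = Genotype.from_traits(pb=1.0, ab=1.0, pR=1.0, aR=1.0, pS=1.0, aS=1.0,
                                 pT=1.0, aT=1.0, pP=1.0, aP=1.0)
        pop = make_pair_population(g, g, bonded=False)
        pop.emo[:] = pop.geno[:, :, 0]
        courtship_phase((pop.agent(0), pop.agent(1)), config(c_cou=0.4), rng)
        assert pop.payoff[0] == pytest.approx(-0.4 * 20)
        assert pop.n_courtships[0] == 20

    def test_unilateral_ending_dissolves(self, rng):
        """One partner with attachment pinned at -1 ends courtship at once."""
        stay = Genotype.from_traits(pb=1.0, ab=1.0, aR=1.0, aS=1.0, aT=1.0, aP=1.0)
        leave = Genotype.from_traits(pb=1.0, ab=-1.0, aR=-1.0, aS=-1.0, aT=-1.0, aP=-1.0)
        pop = make_pair_population(stay, leave, bonded=False)
        pop.emo[:] = pop.geno[:, :, 0]
        ev = courtship_phase((pop.agent(0), pop.agent(1)), config(), rng)
        assert ev.resolution == "dissolved_in_courtship"
        assert ev.n_courtship_rounds == 1
        assert (pop.partner < 0).all()

    def test_disabled_courtship_bonds_at_zero_rounds(self, rng):
        g = Genotype.from_traits(pb=1.0)  # would always court if allowed
        pop = make_pair_population(g, g, bonded=False)
        pop.emo[:, E_COURT] = 1.0
        ev = courtship_phase((pop.agent(0), pop.agent(1)),
                             config(enable_courtship=False), rng)
        assert ev.resolution == "bonded" and ev.n_courtship_rounds == 0
        assert pop.bonded_flag.all()


class TestBondedPhase:
    def test_mutual_commitment_persists(self, rng):
        g = Genotype.from_traits(ab=1.0, aR=1.0, aS=1.0, aT=1.0, aP=1.0, cb=1.0,
                                 cR=1.0, cS=1.0, cT=1.0, cP=1.0)
        pop = make_pair_population(g, g)
        pop.emo[:] = pop.geno[:, :, 0]
        assert bonded_phase((pop.agent(0), pop.agent(1)), config(), rng) == "still_bonded"
        assert pop.payoff[0] == 3.0

    def test_divorce_charges_both(self, rng):
        leaver = Genotype.from_traits(ab=-1.0, aR=-1.0, aS=-1.0, aT=-1.0, aP=-1.0)
        pop = make_pair_population(Genotype.zeros(), leaver)
        pop.emo[1, E_ATT] = -1.0
        out = bonded_phase((pop.agent(0), pop.agent(1)), config(c_div=4.0), rng)
        assert out == "divorced"
        # both paid 4 on top of whatever the PD round gave
        assert pop.payoff[0] == pytest.approx(pop.pd_total[0] - 4.0)
        assert pop.payoff[1] == pytest.approx(pop.pd_total[1] - 4.0)
        assert pop.n_divorces.tolist() == [1, 1]
        assert (pop.partner < 0).all()

    def test_prohibited_divorce_ignores_attachment(self, rng):
        leaver = Genotype.from_traits(aR=-1.0, aS=-1.0, aT=-1.0, aP=-1.0)
        pop = make_pair_population(leaver, leaver)
        pop.emo[:, E_ATT] = -1.0
        out = bonded_phase((pop.agent(0), pop.agent(1)),
                           config(divorce_mode="prohibited", c_div=4.0), rng)
        assert out == "still_bonded"
        assert pop.bonded_flag.all() and pop.n_divorces.sum() == 0


class TestMoran:
    def test_zero_mortality_changes_nothing(self, rng):
        cfg = config(N=20, m=0.0)
        pop = fresh_population(20, rng, cfg)
        geno = pop.geno.copy()
        moran_step(pop, cfg, rng)
        np.testing.assert_array_equal(pop.geno, geno)

    def test_size_conserved_and_newborns_clean(self):
        cfg = config(N=50, m=0.5, c_div=1.0)
        rng = np.random.default_rng(8)
        pop = fresh_population(50, rng, cfg)
        pop.payoff[:] = rng.uniform(-5, 10, 50)
        pop.pd_total[:] = pop.payoff
        pop.iteration = 5
        pair_unattached(pop, rng)
        pop.bonded_flag[pop.partner >= 0] = True
        moran_step(pop, cfg, rng)
        assert pop.n == 50
        newborn = pop.birth == pop.iteration
        assert newborn.any()
        assert np.all(pop.payoff[newborn] == 0.0)
        assert np.all(pop.partner[newborn] == -1)
        pop.validate()

    def test_widows_are_released_without_cost(self):
        cfg = config(N=2, m=1.0)
        # force exactly agent 1 to die by controlling the uniform draws
        class Rig:
            def __init__(self):
                self.inner = np.random.default_rng(0)
            def random(self, n=None):
                return np.array([0.99, 0.0])  # agent 0 survives, agent 1 dies
            def choice(self, a, size=None, p=None):
                return np.array([0])
            def normal(self, loc, scale, size):
                return np.zeros(size)
        cfg = config(N=2, m=0.5, c_div=7.0)
        pop = make_pair_population(Genotype.zeros(), Genotype.zeros())
        pop.payoff[:] = 5.0
        moran_step(pop, cfg, Rig())
        assert pop.partner[0] == -1 and not pop.bonded_flag[0]
        assert pop.payoff[0] == 5.0  # no divorce cost on widowhood
        assert pop.payoff[1] == 0.0  # replaced by a newborn

    def test_uniform_choice_when_payoffs_equal(self):
        cfg = config(N=400, m=0.2)
        rng = np.random.default_rng(13)
        pop = fresh_population(400, rng, cfg)
        pop.payoff[:] = 2.5
        moran_step(pop, cfg, rng)  # exercises the degenerate-proportional branch
        assert pop.n == 400


class TestRunIteration:
    def test_deterministic_cooperators_cooperate_fully(self, rng):
        g = Genotype.from_traits(cb=1.0, cR=1.0, cS=1.0, cT=1.0, cP=1.0,
                                 ab=1.0, aR=1.0, aS=1.0, aT=1.0, aP=1.0, pb=-1.0)
        cfg = config(N=6, m=0.0)
        pop = Population.from_genotypes([g] * 6)
        rec = run_iteration(pop, cfg, rng)
        assert rec.mutual_cooperation_rate == 1.0
        assert rec.n_bonded_pairs == 3

    def test_all_dissolving_population_plays_no_pd(self, rng):
        """Agents that always court and always end never bond: the iteration
        has zero bonded rounds and zero payoff."""
        g = Genotype.from_traits(pb=1.0, ab=-1.0)
        cfg = config(N=6, m=0.0)
        pop = Population.from_genotypes([g] * 6)
        rec = run_iteration(pop, cfg, rng)
        assert rec.n_bonded_pairs == 0
        assert rec.mutual_cooperation_rate == 0.0
        assert np.all(pop.pd_total == 0.0)

    def test_population_invariants_over_many_iterations(self):
        cfg = SimConfig(N=30, iterations=0, m=0.05, c_div=4.0, c_cou=0.4,
                        noise=NoiseSpec("perceptual", 0.1),
                        enable_deceit=True, c_dec=0.8)
        rng = np.random.default_rng(42)
        pop = Population.founders(cfg, rng)
        for _ in range(300):
            run_iteration(pop, cfg, rng)
            assert pop.n == cfg.N
            pop.validate()
            assert np.all(pop.emo >= -1) and np.all(pop.emo <= 1)
            assert np.all(pop.geno >= -1) and np.all(pop.geno <= 1)
            np.testing.assert_allclose(pop.ledger_residual(cfg), 0.0, atol=1e-9)

    def test_no_divorce_means_bonds_end_only_by_death(self):
        cfg = SimConfig(N=20, iterations=0, m=0.0, divorce_mode="prohibited",
                        c_div=4.0)
        rng = np.random.default_rng(3)
        pop = Population.founders(cfg, rng)
        bonded_before = np.zeros(20, dtype=bool)
        for _ in range(50):
            run_iteration(pop, cfg, rng)
            # once bonded, always bonded (m = 0: no deaths)
            assert np.all(pop.bonded_flag[bonded_before])
            bonded_before |= pop.bonded_flag
        assert pop.n_divorces.sum() == 0

    def test_courtship_disabled_invariants(self):
        cfg = SimConfig(N=20, iterations=0, m=0.01, enable_courtship=False,
                        c_div=4.0)
        rng = np.random.default_rng(17)
        pop = Population.founders(cfg, rng)
        for _ in range(100):
            rec = run_iteration(pop, cfg, rng)
            assert rec.mean_courtship_rounds == 0.0
        assert pop.n_courtships.sum() == 0
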