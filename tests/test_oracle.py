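"""Chemical-master-equation oracle and SSA-vs-CME agreement."""

import numpy as np
import pytest

from camkiisim.engines import EngineConfig, SystemState, simulate_state
from camkiisim.oracle import (
    StateSpaceCapError,
    derive_parameters,
    enumerate_cme,
    solve_cme,
)
from camkiisim.rates import Pools, RateTable
from camkiisim.rules import rule_table
from camkiisim.states import CamState, Conformation, Docking, T286
from camkiisim.stimulus import StimulusProtocol


def _subset(rules, names):
    return [r for r in rules if r.name in names]


class TestDeriveParameters:
    def test_frozen_values(self):
        d = derive_parameters()
        assert d["K_docking"] == pytest.approx(1.8e6 / 1e8)
        assert d["k_undock"] == pytest.approx(0.63)
        assert d["k_off_CaM_ini"] == pytest.approx(590.0)
        assert d["initial_vs_full_occupancy"] == pytest.approx(1.14e-5, rel=0.01)
        assert d["K_M_PP"] == pytest.approx(8.33e-7, rel=0.01)
        assert d["p_act"] == pytest.approx(0.002, rel=0.01)


class TestEnumeration:
    def test_activation_only_two_states(self, rates):
        rules = _subset(rule_table(rates), {"activate", "inactivate"})
        sys = enumerate_cme(1, Pools(free_apo_cam=0, free_cam4=0, free_pp=0),
                            rules, rates)
        assert sys.n_states == 2
        Q = sys.generator.toarray()
        assert np.allclose(Q, [[-2e4, 2e4], [1e7, -1e7]])

    def test_docking_and_activation_four_states(self, rates):
        rules = _subset(rule_table(rates),
                        {"activate", "inactivate", "dock", "undock"})
        sys = enumerate_cme(1, Pools(free_apo_cam=0, free_cam4=0, free_pp=0),
                            rules, rates)
        assert sys.n_states == 4

    def test_zero_subunits_rejected(self, rates):
        with pytest.raises(ValueError):
            enumerate_cme(0, Pools(), rule_table(rates), rates)

    def test_cap_enforced(self, rates, small_pools):
        with pytest.raises(StateSpaceCapError):
            enumerate_cme(2, small_pools, rule_table(rates), rates, cap=3)

    def test_generator_rows_sum_to_zero(self, rates, small_pools):
        sys = enumerate_cme(1, small_pools, rule_table(rates), rates)
        rows = np.asarray(sys.generator.sum(axis=1)).ravel()
        assert np.allclose(rows, 0.0, atol=1e-8)
        off_diag = sys.generator.toarray() - np.diag(sys.generator.diagonal())
        assert (off_diag >= 0).all()


class TestSolve:
    def test_stationary_open_probability(self, rates):
        rules = _subset(rule_table(rates), {"activate", "inactivate"})
        sys = enumerate_cme(1, Pools(free_apo_cam=0, free_cam4=0, free_pp=0),
                            rules, rates)
        p = solve_cme(sys, stationary=True)
        pa = sys.marginal(p, lambda s: s[0][0].conformation == Conformation.ACTIVE)
        assert pa == pytest.approx(2e4 / 1.002e7, rel=1e-6)

    def test_stationary_undocked_probability(self, rates):
        rules = _subset(rule_table(rates), {"dock", "undock"})
        sys = enumerate_cme(1, Pools(free_apo_cam=0, free_cam4=0, free_pp=0),
                            rules, rates)
        p = solve_cme(sys, stationary=True)
        pu = sys.marginal(p, lambda s: s[0][0].docking == Docking.UNDOCKED)
        assert pu == pytest.approx(0.018 / 1.018, rel=1e-6)

    def test_t0_returns_initial_distribution(self, rates, small_pools):
        sys = enumerate_cme(1, small_pools, rule_table(rates), rates)
        assert np.array_equal(solve_cme(sys, t=0.0), sys.p0)

    def test_normalization_preserved(self, rates, small_pools):
        sys = enumerate_cme(1, small_pools, rule_table(rates), rates)
        p = solve_cme(sys, t=0.5)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (p >= -1e-12).all()


class TestSsaAgainstCme:
    def test_explicit_flicker_time_average(self, rates):
        """A long exact-SSA trajectory of the bare flicker reproduces the
        stationary open probability 0.002 (batch-means tolerance)."""
        zeroed = RateTable(
            k_dock=0, k_undock=0, k_on_CaM=0, k_off_CaM_ini=0,
            k_ini_to_full=0, k_full_to_ini=0, k_autophos=0,
            k_phos_T306=0, k_on_PP=0, k_off_PP=0, k_cat_PP=0,
        )
        sys = SystemState.fragment(1, zeroed, Pools(free_apo_cam=0, free_cam4=0, free_pp=0))
        cfg = EngineConfig(scheme="ssa", t_end=0.6, record_interval=1e-4,
                           n_replicates=1, seed=8, validate_frames=False)
        _, frames = simulate_state(sys, cfg)
        active = frames[:, 0]
        batches = active[1:].reshape(20, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(batches.mean() - 0.001996) <= 3 * se + 1e-4

    def test_one_subunit_all_flags_matches_transient_marginals(self, rates, small_pools):
        """QSSA samples of the full one-subunit rule system (5 CaM4, 1 PP)
        match the marginalised CME transient at t = 1 s within 3 SE."""
        rules = rule_table(rates)
        cme = enumerate_cme(1, small_pools, rules, rates, marginalize_conf=True)
        p = solve_cme(cme, t=1.0)
        targets = {
            "cam_bound": lambda s: s[0][0].cam != CamState.UNBOUND,
            "undocked": lambda s: s[0][0].docking == Docking.UNDOCKED,
            "pT306": lambda s: int(s[0][0].t306) == 1,
        }
        expected = {k: cme.marginal(p, fn) for k, fn in targets.items()}

        n_rep = 400
        hits = {k: 0 for k in targets}
        for r in range(n_rep):
            sys = SystemState.fragment(1, rates, small_pools.copy())
            cfg = EngineConfig(scheme="qssa", t_end=1.0, record_interval=1.0,
                               n_replicates=1, seed=5000 + r,
                               validate_frames=False)
            # continuous bolus keeps released CaM in the CaM4 pool, matching
            # the static-pool CME
            _, frames = simulate_state(
                sys, cfg, StimulusProtocol(mode="continuous_bolus")
            )
            last = frames[-1]
            hits["cam_bound"] += (last[1] + last[2]) > 0
            hits["undocked"] += last[6] == 0
            hits["pT306"] += last[5] > 0
        for k in targets:
            phat = hits[k] / n_rep
            se = np.sqrt(max(expected[k] * (1 - expected[k]), 1e-6) / n_rep)
            assert abs(phat - expected[k]) <= 3 * se + 1e-3, (k, phat, expected[k])

    def test_two_subunit_chain_autophosphorylation(self, rates):
        """The neighbour-gated autophosphorylation statistics of a
        substrate+kinase chain fragment match the marginalised CME."""
        pools = Pools(free_apo_cam=0, free_cam4=450, free_pp=0)
        rules = rule_table(rates)
        cme = enumerate_cme(2, pools, rules, rates, marginalize_conf=True)
        t_probe = 15.0
        p = solve_cme(cme, t=t_probe)
        # substrate is subunit 0 (its kinase is subunit 1)
        expected = cme.marginal(p, lambda s: s[0][0].t286 != T286.UNPHOS)
        assert expected > 0.05  # the probe must actually exercise the rule

        n_rep = 400
        hits = 0
        for r in range(n_rep):
            sys = SystemState.fragment(2, rates, pools.copy())
            cfg = EngineConfig(scheme="qssa", t_end=t_probe,
                               record_interval=t_probe, n_replicates=1,
                               seed=9000 + r, validate_frames=False)
            _, frames = simulate_state(
                sys, cfg, StimulusProtocol(mode="continuous_bolus")
            )
            hits += (frames[-1][3] + frames[-1][4]) > 0  # pT286 or PP-bound
        phat = hits / n_rep
        se = np.sqrt(expected * (1 - expected) / n_rep)
        assert abs(phat - expected) <= 3 * se + 1e-3, (phat, expected)
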