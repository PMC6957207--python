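"""The guarded rule table: guards, effects, exclusivity and interpretation."""

import numpy as np
import pytest

from camkiisim.rates import Pools, RateTable
from camkiisim.rules import (
    GuardContractError,
    guard_eval,
    propensity,
    rule_table,
    serialize_rules,
)
from camkiisim.states import (
    CamState,
    Conformation,
    Docking,
    SubunitState,
    T286,
    T306,
)
from camkiisim.variants import set_exclusivity


def _by_name(rules):
    return {r.name: r for r in rules}


ACTIVE_UNDOCKED = SubunitState(
    docking=Docking.UNDOCKED, conformation=Conformation.ACTIVE
)


class TestRuleTable:
    def test_exclusive_guard_clauses(self, rates):
        rules = _by_name(rule_table(rates))
        assert "cam_unbound" in rules["pp_bind"].guard
        assert "t286_not_pp_bound" in rules["cam_bind_initial"].guard

    def test_non_exclusive_guard_clauses(self):
        rules = _by_name(rule_table(RateTable(exclusivity="non_exclusive")))
        assert rules["pp_bind"].guard == ("pT286",)
        assert "t286_not_pp_bound" not in rules["cam_bind_initial"].guard

    def test_no_rule_reverses_pT306(self, rates):
        for r in rule_table(rates):
            assert ("t306", int(T306.UNPHOS)) not in r.sets

    def test_exclusivity_differs_in_exactly_two_clauses(self, rates):
        """Serialised rule tables of the two variants differ only in the two
        steric-exclusion guard clauses."""
        excl = serialize_rules(rule_table(rates))
        nonx = serialize_rules(rule_table(rates.with_(exclusivity="non_exclusive")))
        diffs = []
        for a, b in zip(excl, nonx):
            assert a["name"] == b["name"]
            ga, gb = set(a["guard"]), set(b["guard"])
            diffs.extend(ga ^ gb)
            a2 = {k: v for k, v in a.items() if k != "guard"}
            b2 = {k: v for k, v in b.items() if k != "guard"}
            assert a2 == b2
        assert sorted(diffs) == ["cam_unbound", "t286_not_pp_bound"]

    def test_set_exclusivity_matches_rule_table(self, rates):
        converted = set_exclusivity(rule_table(rates), "non_exclusive")
        direct = rule_table(rates.with_(exclusivity="non_exclusive"))
        assert serialize_rules(converted) == serialize_rules(direct)
        back = set_exclusivity(converted, "exclusive")
        assert serialize_rules(back) == serialize_rules(rule_table(rates))

    def test_kon_pp_scale_propagates(self):
        rules = _by_name(rule_table(RateTable(kon_PP_scale=10.0)))
        assert rules["pp_bind"].rate_scale == 10.0


class TestGuardEval:
    def test_docked_subunit_cannot_bind_cam(self, rates):
        rule = _by_name(rule_table(rates))["cam_bind_initial"]
        assert not guard_eval(rule, SubunitState())  # docked default
        assert guard_eval(rule, ACTIVE_UNDOCKED)

    def test_autophos_requires_active_neighbor(self, rates):
        rule = _by_name(rule_table(rates))["autophosphorylate_T286"]
        substrate = ACTIVE_UNDOCKED
        inactive_neighbor = SubunitState(docking=Docking.UNDOCKED)
        active_neighbor = ACTIVE_UNDOCKED
        assert not guard_eval(rule, substrate, inactive_neighbor)
        assert guard_eval(rule, substrate, active_neighbor)

    def test_inactivation_blocked_by_full_cam(self, rates):
        rule = _by_name(rule_table(rates))["inactivate"]
        stabilized = SubunitState(
            docking=Docking.UNDOCKED,
            conformation=Conformation.ACTIVE,
            cam=CamState.FULL,
        )
        assert not guard_eval(rule, stabilized)
        assert guard_eval(rule, ACTIVE_UNDOCKED)

    def test_neighbor_contract_enforced(self, rates):
        rules = _by_name(rule_table(rates))
        with pytest.raises(GuardContractError):
            guard_eval(rules["autophosphorylate_T286"], ACTIVE_UNDOCKED, None)
        with pytest.raises(GuardContractError):
            guard_eval(rules["undock"], SubunitState(), ACTIVE_UNDOCKED)


class TestInterpretedPropensity:
    def test_bimolecular_scales_with_pool(self, rates):
        rule = _by_name(rule_table(rates))["cam_bind_initial"]
        p5 = propensity(rule, ACTIVE_UNDOCKED, None, rates,
                        Pools(free_apo_cam=0, free_cam4=5, free_pp=0))
        p10 = propensity(rule, ACTIVE_UNDOCKED, None, rates,
                         Pools(free_apo_cam=0, free_cam4=10, free_pp=0))
        assert p10 == pytest.approx(2 * p5)
        assert p5 == pytest.approx(5 * 5.0626, rel=1e-3)

    def test_marginalized_autophos_carries_factor_per_participant(self, rates):
        rule = _by_name(rule_table(rates))["autophosphorylate_T286"]
        pools = Pools(free_apo_cam=0, free_cam4=0, free_pp=0)
        plain = SubunitState(docking=Docking.UNDOCKED)
        stab = SubunitState(
            docking=Docking.UNDOCKED, conformation=Conformation.ACTIVE,
            cam=CamState.FULL,
        )
        p = rates.p_act
        # both participants marginalised -> p_act squared
        a = propensity(rule, plain, plain, rates, pools, marginalize_conf=True)
        assert a == pytest.approx(rates.k_autophos * p * p)
        # stabilised kinase, marginalised substrate -> one factor
        a = propensity(rule, plain, stab, rates, pools, marginalize_conf=True)
        assert a == pytest.approx(rates.k_autophos * p)
        # both stabilised -> full rate
        stab_sub = SubunitState(
            docking=Docking.UNDOCKED, conformation=Conformation.ACTIVE,
            cam=CamState.FULL,
        )
        a = propensity(rule, stab_sub, stab, rates, pools, marginalize_conf=True)
        assert a == pytest.approx(rates.k_autophos)

    def test_marginalized_ini_to_full_rate(self, rates):
        rule = _by_name(rule_table(rates))["cam_bind_full"]
        sub = SubunitState(docking=Docking.UNDOCKED, cam=CamState.INITIAL)
        a = propensity(rule, sub, None, rates,
                       Pools(free_apo_cam=0, free_cam4=0, free_pp=0),
                       marginalize_conf=True)
        assert a == pytest.approx(0.699, rel=2e-3)

    def test_k_cat_disable(self, rates):
        rule = _by_name(rule_table(rates))["pp_dephosphorylate"]
        sub = SubunitState(
            docking=Docking.UNDOCKED, conformation=Conformation.ACTIVE,
            t286=T286.PP_BOUND,
        )
        pools = Pools(free_apo_cam=0, free_cam4=0, free_pp=0)
        assert propensity(rule, sub, None, rates, pools) == pytest.approx(2.0)
        assert propensity(rule, sub, None, rates, pools, k_cat_enabled=False) == 0.0


def test_engine_propensities_match_interpreted_rules(rng):
    """The vectorised engine propensity builder agrees with the interpreted
    declarative rule table on random (not necessarily reachable) states, in
    both explicit-flicker and marginalised modes."""
    from camkiisim.engines import (
        CHANNEL_RULE_NAMES,
        ModelConfig,
        SystemState,
        build_propensities,
    )

    for _ in range(25):
        excl = bool(rng.integers(2))
        rates = RateTable(
            exclusivity="exclusive" if excl else "non_exclusive",
            dof=int(rng.integers(1, 4)),
            kon_PP_scale=float(rng.choice([0.1, 1.0, 10.0])),
        )
        model = ModelConfig(
            n_holo=1, rates=rates,
            pools=Pools(
                free_apo_cam=0,
                free_cam4=int(rng.integers(0, 6)),
                free_pp=int(rng.integers(0, 3)),
            ),
        )
        sys = SystemState(model)
        n = sys.n_sub
        sys.docked = rng.integers(0, 2, n).astype(bool)
        sys.conf = rng.integers(0, 2, n).astype(np.int8)
        sys.cam = rng.integers(0, 3, n).astype(np.int8)
        sys.t286 = rng.integers(0, 3, n).astype(np.int8)
        sys.t306 = rng.integers(0, 2, n).astype(bool)
        sys.inhib = rng.integers(0, 2, n).astype(bool)
        sys.k_cat_enabled = bool(rng.integers(2))
        rules = _by_name(rule_table(rates))
        pools = Pools(free_apo_cam=0, free_cam4=sys.free_cam4,
                      free_pp=sys.free_pp, volume=sys.volume)

        def sub_state(i):
            return SubunitState(
                Docking(int(not sys.docked[i])),
                Conformation(int(sys.conf[i])),
                CamState(int(sys.cam[i])),
                T286(int(sys.t286[i])),
                T306(int(sys.t306[i])),
                bool(sys.inhib[i]),
            )

        for marg in (False, True):
            R, A = build_propensities(sys, marg)
            for ch, rname in enumerate(CHANNEL_RULE_NAMES[:12]):
                for i in range(n):
                    a = propensity(
                        rules[rname], sub_state(i), None, rates, pools,
                        marginalize_conf=marg,
                        k_cat_enabled=sys.k_cat_enabled,
                    )
                    assert R[ch, i] == pytest.approx(a), (rname, i, marg)
            for e, (si, ki) in enumerate(zip(sys.sub_e, sys.kin_e)):
                a = propensity(
                    rules["autophosphorylate_T286"], sub_state(si),
                    sub_state(ki), rates, pools, marginalize_conf=marg,
                )
                assert A[e] == pytest.approx(a)
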