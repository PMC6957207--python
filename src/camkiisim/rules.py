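"""Guarded transition rules for the two-state-CaM holoenzyme model.

Each rule names a transition of one subunit flag (optionally consuming or
releasing a free ligand, optionally gated on a neighbouring subunit), a guard
expressed as a tuple of named clauses over the subunit's flags, and a rate
symbol resolved against a :class:`~camkiisim.rates.RateTable`.  Keeping guards
declarative lets the same rule objects drive the stochastic engines, the
chemical-master-equation oracle, rule-table serialisation, and structural
diffs between model variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from camkiisim.rates import RateTable, Pools, bimolecular_propensity
from camkiisim.states import CamState, Conformation, Docking, SubunitState, T286, T306

# ---------------------------------------------------------------------------
# Guard clauses

_SUBUNIT_CLAUSES = {
    "docked": lambda s: s.docking == Docking.DOCKED,
    "undocked": lambda s: s.docking == Docking.UNDOCKED,
    "active": lambda s: s.conformation == Conformation.ACTIVE,
    "inactive": lambda s: s.conformation == Conformation.INACTIVE,
    "cam_unbound": lambda s: s.cam == CamState.UNBOUND,
    "cam_initial": lambda s: s.cam == CamState.INITIAL,
    "cam_full": lambda s: s.cam == CamState.FULL,
    "cam_not_full": lambda s: s.cam != CamState.FULL,
    "uT286": lambda s: s.t286 == T286.UNPHOS,
    "pT286": lambda s: s.t286 == T286.PHOS,
    "pp_bound": lambda s: s.t286 == T286.PP_BOUND,
    "t286_not_phos": lambda s: s.t286 != T286.PHOS,
    "t286_not_pp_bound": lambda s: s.t286 != T286.PP_BOUND,
    "uT306": lambda s: s.t306 == T306.UNPHOS,
    "not_inhibited": lambda s: not s.inhibitor_bound,
}

_NEIGHBOR_CLAUSES = {
    "neighbor_active": lambda s: s.conformation == Conformation.ACTIVE,
    "neighbor_undocked": lambda s: s.docking == Docking.UNDOCKED,
    "neighbor_not_inhibited": lambda s: not s.inhibitor_bound,
}

#: Clauses that read the conformational flicker; these are the clauses the
#: quasi-steady-state reduction replaces by occupancy factors.
CONF_CLAUSES = frozenset({"active", "inactive", "neighbor_active"})


class GuardContractError(TypeError):
    """Neighbour supplied for a non-neighbour rule, or missing for one."""


@dataclass(frozen=True)
class Rule:
    """One guarded state transition.

    ``participants`` is one of ``unimolecular_subunit``,
    ``bimolecular_subunit_pool`` (consumes one molecule of ``consumes``) or
    ``neighbor_gated`` (guard additionally constrains the kinase neighbour).
    ``sets`` lists the flag updates applied on firing; ``releases`` credits a
    free pool.  ``rate`` names a :class:`RateTable` attribute and
    ``rate_scale`` a static multiplier (used for the k_on^PP sensitivity
    scans).
    """

    name: str
    participants: str
    guard: tuple[str, ...]
    rate: str
    sets: tuple[tuple[str, int], ...]
    neighbor_guard: tuple[str, ...] = ()
    rate_scale: float = 1.0
    consumes: str | None = None
    releases: str | None = None

    def __post_init__(self):
        for c in self.guard:
            if c not in _SUBUNIT_CLAUSES:
                raise ValueError(f"unknown guard clause {c!r} in rule {self.name}")
        for c in self.neighbor_guard:
            if c not in _NEIGHBOR_CLAUSES:
                raise ValueError(f"unknown neighbour clause {c!r} in rule {self.name}")
        if self.participants == "neighbor_gated" and not self.neighbor_guard:
            raise ValueError(f"neighbor_gated rule {self.name} has no neighbour guard")
        if self.participants == "bimolecular_subunit_pool" and not self.consumes:
            raise ValueError(f"bimolecular rule {self.name} names no pool")

    def apply(self, sub: SubunitState) -> SubunitState:
        """Subunit state after this rule fires (flags in ``sets`` updated)."""
        return sub.with_(**{f: v for f, v in self.sets})


def guard_eval(rule: Rule, subunit: SubunitState, neighbor: SubunitState | None = None) -> bool:
    """True iff every guard clause of ``rule`` holds for the given states.

    A neighbour state must be supplied exactly when the rule is
    neighbour-gated; anything else is a contract violation.
    """
    if rule.participants == "neighbor_gated":
        if neighbor is None:
            raise GuardContractError(f"rule {rule.name} requires a neighbour state")
    elif neighbor is not None:
        raise GuardContractError(f"rule {rule.name} takes no neighbour state")
    for c in rule.guard:
        if not _SUBUNIT_CLAUSES[c](subunit):
            return False
    for c in rule.neighbor_guard:
        if not _NEIGHBOR_CLAUSES[c](neighbor):
            return False
    return True


# ---------------------------------------------------------------------------
# The rule table

def rule_table(rates: RateTable) -> list[Rule]:
    """Emit the full transition rule set for the two-state-CaM model.

    The exclusivity variant changes exactly two guard clauses: phosphatase
    binding requires ``cam_unbound`` and initial CaM binding requires
    ``t286_not_pp_bound`` only in the exclusive model.  No rule ever reverses
    pThr-306.  The conformational activate/inactivate rules are part of the
    table; the QSSA engine marginalises rather than simulates them.
    """
    excl = rates.exclusive
    dock_guard = ["undocked", "cam_unbound", "uT306"]
    if rates.dock_requires_inactive:
        dock_guard.append("inactive")
    inact_guard = ["active", "cam_not_full", "t286_not_phos"]
    if rates.pp_bound_counts_as_phospho:
        inact_guard.append("t286_not_pp_bound")
    cam_on_guard = ["undocked", "cam_unbound", "uT306"]
    if excl:
        cam_on_guard.append("t286_not_pp_bound")
    pp_on_guard = ["pT286"]
    if excl:
        pp_on_guard.append("cam_unbound")
    autophos_neighbor = ["neighbor_active", "neighbor_undocked"]
    if rates.k252a_blocks_kinase_role:
        autophos_neighbor.append("neighbor_not_inhibited")

    u = "unimolecular_subunit"
    b = "bimolecular_subunit_pool"
    return [
        Rule("undock", u, ("docked",), "k_undock",
             (("docking", Docking.UNDOCKED),)),
        Rule("dock", u, tuple(dock_guard), "k_dock",
             (("docking", Docking.DOCKED),)),
        Rule("activate", u, ("inactive",), "k_activate",
             (("conformation", Conformation.ACTIVE),)),
        Rule("inactivate", u, tuple(inact_guard), "k_inactivate",
             (("conformation", Conformation.INACTIVE),)),
        Rule("cam_bind_initial", b, tuple(cam_on_guard), "k_on_CaM",
             (("cam", CamState.INITIAL),), consumes="free_cam4"),
        Rule("cam_release_initial", u, ("cam_initial",), "k_off_CaM_ini",
             (("cam", CamState.UNBOUND),), releases="free_cam4"),
        Rule("cam_bind_full", u, ("cam_initial", "active"), "k_ini_to_full",
             (("cam", CamState.FULL),)),
        Rule("cam_full_to_initial", u, ("cam_full",), "k_full_to_ini",
             (("cam", CamState.INITIAL),)),
        Rule("autophosphorylate_T286", "neighbor_gated",
             ("uT286", "undocked", "active", "not_inhibited"), "k_autophos",
             (("t286", T286.PHOS),), neighbor_guard=tuple(autophos_neighbor)),
        Rule("pp_bind", b, tuple(pp_on_guard), "k_on_PP",
             (("t286", T286.PP_BOUND),), rate_scale=rates.kon_PP_scale,
             consumes="free_pp"),
        Rule("pp_release", u, ("pp_bound",), "k_off_PP",
             (("t286", T286.PHOS),), releases="free_pp"),
        Rule("pp_dephosphorylate", u, ("pp_bound",), "k_cat_PP",
             (("t286", T286.UNPHOS),), releases="free_pp"),
        Rule("phosphorylate_T306", u, ("uT306", "active", "cam_unbound"),
             "k_phos_T306", (("t306", T306.PHOS),)),
    ]


#: Names of the conformational flicker rules removed by the QSSA reduction.
CONF_RULE_NAMES = frozenset({"activate", "inactivate"})


def is_stabilized(sub: SubunitState, rates: RateTable) -> bool:
    """Whether the inactivation guard pins this subunit in the active state.

    Fully CaM-bound or pThr-286 subunits cannot inactivate and therefore sit
    at open probability 1 under the quasi-steady-state reduction.  A
    PP-occupied Thr-286 counts only when ``pp_bound_counts_as_phospho``.
    """
    if sub.cam == CamState.FULL or sub.t286 == T286.PHOS:
        return True
    return rates.pp_bound_counts_as_phospho and sub.t286 == T286.PP_BOUND


def _conf_factor(clause: str, sub: SubunitState, rates: RateTable) -> float:
    p = rates.p_act
    if clause in ("active", "neighbor_active"):
        return 1.0 if is_stabilized(sub, rates) else p
    # 'inactive': stabilised subunits are never inactive
    return 0.0 if is_stabilized(sub, rates) else 1.0 - p


def propensity(
    rule: Rule,
    subunit: SubunitState,
    neighbor: SubunitState | None,
    rates: RateTable,
    pools: Pools,
    marginalize_conf: bool = False,
    k_cat_enabled: bool = True,
) -> float:
    """Stochastic firing rate of one rule instance in the given state.

    With ``marginalize_conf`` the conformational clauses are replaced by
    quasi-steady-state occupancy factors (the autophosphorylation rule may
    carry the factor twice, once per non-stabilised participant) and the
    flicker rules themselves report zero.  Bimolecular rules multiply the
    per-pair propensity by the current free-pool count.  ``k_cat_enabled``
    implements the time-dependent phosphatase catalytic rate used by the
    phosphatase-inhibition protocol.
    """
    if not k_cat_enabled and rule.name == "pp_dephosphorylate":
        return 0.0
    factor = 1.0
    if marginalize_conf:
        if rule.name in CONF_RULE_NAMES:
            return 0.0
        for c in rule.guard:
            if c in CONF_CLAUSES:
                factor *= _conf_factor(c, subunit, rates)
            elif not _SUBUNIT_CLAUSES[c](subunit):
                return 0.0
        for c in rule.neighbor_guard:
            if c in CONF_CLAUSES:
                factor *= _conf_factor(c, neighbor, rates)
            elif not _NEIGHBOR_CLAUSES[c](neighbor):
                return 0.0
    else:
        if not guard_eval(rule, subunit, neighbor):
            return 0.0
    base = getattr(rates, rule.rate) * rule.rate_scale
    if rule.participants == "bimolecular_subunit_pool":
        per_pair = bimolecular_propensity(base, pools.volume)
        return per_pair * getattr(pools, rule.consumes) * factor
    return base * factor


def serialize_rules(rules: list[Rule], rates: RateTable | None = None) -> list[dict]:
    """Structured text form of the rule table for audit and export."""
    out = []
    for r in rules:
        rec = {
            "name": r.name,
            "participants": r.participants,
            "guard": list(r.guard),
            "neighbor_guard": list(r.neighbor_guard),
            "rate": r.rate,
            "rate_scale": r.rate_scale,
            "consumes": r.consumes,
            "releases": r.releases,
            "sets": [[f, int(v)] for f, v in r.sets],
        }
        if rates is not None:
            rec["rate_value"] = getattr(rates, r.rate) * r.rate_scale
        out.append(rec)
    return out
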