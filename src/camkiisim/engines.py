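"""Stochastic time-advancement engines for the holoenzyme rule system.

Three interchangeable schemes advance the same jump process:

* ``ssa`` -- exact stochastic simulation with the conformational flicker
  (activation 2e4 s^-1, inactivation 1e7 s^-1) simulated explicitly; only
  practical for small systems or short windows.
* ``qssa`` -- the production engine: the flicker is marginalised out, every
  rule gated on the active conformation carries the stationary open
  probability p_act = k_act/(k_act + k_inact) per non-stabilised gated
  participant (the autophosphorylation rule may carry it twice), while
  subunits pinned active by full CaM or pThr-286 carry factor 1.  The
  reported "active" count is the conditional expectation
  ``n_stabilised + p_act * n_other``.
* ``fixed_step`` -- a fixed-timestep Bernoulli sampler in which every
  eligible rule instance fires independently with probability 1 - exp(-a dt)
  and conflicting firings on one subunit are resolved by a uniform random
  choice; it refuses time steps coarse enough that any per-instance firing
  probability exceeds 0.1.

Stimulus changepoints (pulse edges, inhibitor times) are hard time barriers:
the jump clock never crosses one, and free-CaM forcing conversions are
applied deterministically at the barrier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from camkiisim.rates import (
    DEFAULT_VOLUME_L,
    Pools,
    RateTable,
    bimolecular_propensity,
)
from camkiisim.states import ConfigurationError, SUBUNITS_PER_HOLOENZYME, kinase_edges
from camkiisim.stimulus import (
    ACTIVATING,
    INACTIVATING,
    StimulusProtocol,
    forcing_phase,
    phase_boundaries,
)

__all__ = [
    "EngineConfig",
    "ModelConfig",
    "SystemState",
    "TrajectoryEnsemble",
    "EngineError",
    "run_ssa",
    "run_qssa",
    "run_fixed",
    "run_replicates",
    "build_propensities",
    "OBSERVABLE_COLUMNS",
]


class EngineError(RuntimeError):
    """Raised when an engine cannot honour its contract (e.g. dt too coarse)."""


#: Observable columns recorded at every frame.  "active" is a float under the
#: QSSA (a conditional expectation), an integer census under the exact SSA.
OBSERVABLE_COLUMNS = (
    "active",
    "cam_initial",
    "cam_full",
    "pT286",
    "pp_bound",
    "pT306",
    "docked",
    "free_apo_cam",
    "free_cam4",
    "free_pp",
)

# Per-subunit channel indices
CH_UNDOCK = 0
CH_DOCK = 1
CH_CAM_ON = 2
CH_CAM_OFF = 3
CH_INI_FULL = 4
CH_FULL_INI = 5
CH_PP_ON = 6
CH_PP_OFF = 7
CH_PP_CAT = 8
CH_T306 = 9
CH_ACT = 10
CH_INACT = 11
N_SUB_CHANNELS = 12
CH_EDGE = 12  # autophosphorylation, indexed per directed edge

#: Rule-table names corresponding to each engine channel (cross-checked in
#: the test suite against the interpreted rule propensities).
CHANNEL_RULE_NAMES = (
    "undock",
    "dock",
    "cam_bind_initial",
    "cam_release_initial",
    "cam_bind_full",
    "cam_full_to_initial",
    "pp_bind",
    "pp_release",
    "pp_dephosphorylate",
    "phosphorylate_T306",
    "activate",
    "inactivate",
    "autophosphorylate_T286",
)


@dataclass
class EngineConfig:
    """Scheme selection, time grid and replicate management."""

    scheme: str = "qssa"
    dt: float = 1e-7
    t_end: float = 20.0
    record_interval: float = 0.01
    seed: int = 0
    n_replicates: int = 50
    validate_frames: bool = True

    def __post_init__(self):
        if self.scheme not in ("fixed_step", "ssa", "qssa"):
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.t_end <= 0:
            raise ConfigurationError("t_end must be > 0")
        if self.record_interval <= 0:
            raise ConfigurationError("record_interval must be > 0")
        if self.scheme == "fixed_step" and self.record_interval < self.dt:
            raise ConfigurationError("record_interval must be >= dt for fixed_step")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


@dataclass
class ModelConfig:
    """Initial composition of the simulated compartment."""

    n_holo: int = 30
    rates: RateTable = field(default_factory=RateTable)
    pools: Pools = field(default_factory=Pools)

    def __post_init__(self):
        if self.n_holo < 1:
            raise ConfigurationError(f"n_holo must be >= 1, got {self.n_holo}")


class SystemState:
    """Mutable flat-array state of all subunits plus the free pools."""

    def __init__(self, model: ModelConfig):
        self.rates = model.rates
        n = model.n_holo * SUBUNITS_PER_HOLOENZYME
        self.n_sub = n
        self.n_holo = model.n_holo
        self.docked = np.ones(n, dtype=bool)
        self.conf = np.zeros(n, dtype=np.int8)  # explicit-flicker engines only
        self.cam = np.zeros(n, dtype=np.int8)
        self.t286 = np.zeros(n, dtype=np.int8)
        self.t306 = np.zeros(n, dtype=bool)
        self.inhib = np.zeros(n, dtype=bool)
        self.volume = model.pools.volume
        self.free_apo_cam = model.pools.free_apo_cam
        self.free_cam4 = model.pools.free_cam4
        self.free_pp = model.pools.free_pp
        self.total_cam = model.pools.free_apo_cam + model.pools.free_cam4
        self.total_pp = model.pools.free_pp
        self.k_cat_enabled = True
        self.phase = INACTIVATING
        sub_e, kin_e, trans_e = kinase_edges(model.n_holo, model.rates.dof)
        self.sub_e = sub_e
        self.kin_e = kin_e
        self.trans_e = trans_e
        self.n_edges = len(sub_e)
        # incident edge lists per subunit (substrate role / kinase role)
        in_e: list[list[int]] = [[] for _ in range(n)]
        out_e: list[list[int]] = [[] for _ in range(n)]
        for e, (s, k) in enumerate(zip(sub_e, kin_e)):
            in_e[s].append(e)
            out_e[k].append(e)
        self.in_edges = [np.asarray(v, dtype=np.int64) for v in in_e]
        self.out_edges = [np.asarray(v, dtype=np.int64) for v in out_e]

    @classmethod
    def fragment(cls, n_subunits: int, rates: RateTable, pools: Pools) -> "SystemState":
        """Open-chain fragment of ``n_subunits`` (kinase of i is i+1).

        Used for validation against the chemical-master-equation oracle,
        where a full dodecamer would be gratuitous: the chain exercises the
        neighbour-gated autophosphorylation rule with the same directed
        convention as a ring.
        """
        if n_subunits < 1:
            raise ConfigurationError("n_subunits must be >= 1")
        obj = cls.__new__(cls)
        obj.rates = rates
        obj.n_sub = n_subunits
        obj.n_holo = 0
        obj.docked = np.ones(n_subunits, dtype=bool)
        obj.conf = np.zeros(n_subunits, dtype=np.int8)
        obj.cam = np.zeros(n_subunits, dtype=np.int8)
        obj.t286 = np.zeros(n_subunits, dtype=np.int8)
        obj.t306 = np.zeros(n_subunits, dtype=bool)
        obj.inhib = np.zeros(n_subunits, dtype=bool)
        obj.volume = pools.volume
        obj.free_apo_cam = pools.free_apo_cam
        obj.free_cam4 = pools.free_cam4
        obj.free_pp = pools.free_pp
        obj.total_cam = pools.free_apo_cam + pools.free_cam4
        obj.total_pp = pools.free_pp
        obj.k_cat_enabled = True
        obj.phase = INACTIVATING
        sub = np.arange(n_subunits - 1, dtype=np.int64)
        obj.sub_e = sub
        obj.kin_e = sub + 1
        obj.trans_e = np.zeros(len(sub), dtype=bool)
        obj.n_edges = len(sub)
        in_e: list[list[int]] = [[] for _ in range(n_subunits)]
        out_e: list[list[int]] = [[] for _ in range(n_subunits)]
        for e, (s, k) in enumerate(zip(obj.sub_e, obj.kin_e)):
            in_e[s].append(e)
            out_e[k].append(e)
        obj.in_edges = [np.asarray(v, dtype=np.int64) for v in in_e]
        obj.out_edges = [np.asarray(v, dtype=np.int64) for v in out_e]
        return obj

    # -- census -----------------------------------------------------------
    def stabilized(self) -> np.ndarray:
        st = (self.cam == 2) | (self.t286 == 1)
        if self.rates.pp_bound_counts_as_phospho:
            st |= self.t286 == 2
        return st

    def counts(self, marginalize: bool) -> tuple:
        if marginalize:
            n_stab = int(self.stabilized().sum())
            active = n_stab + self.rates.p_act * (self.n_sub - n_stab)
        else:
            active = float(self.conf.sum())
        return (
            active,
            float((self.cam == 1).sum()),
            float((self.cam == 2).sum()),
            float((self.t286 == 1).sum()),
            float((self.t286 == 2).sum()),
            float(self.t306.sum()),
            float(self.docked.sum()),
            float(self.free_apo_cam),
            float(self.free_cam4),
            float(self.free_pp),
        )

    def bound_cam(self) -> int:
        return int((self.cam > 0).sum())

    def check_invariants(self) -> None:
        """Raise if any structural invariant or conservation law is violated."""
        if np.any(self.docked & (self.cam != 0)):
            raise AssertionError("docked subunit holds CaM")
        if np.any(self.t306 & (self.cam != 0)):
            raise AssertionError("pThr-306 subunit holds CaM")
        if not self._marginalized_conf and np.any((self.cam == 2) & (self.conf == 0)):
            raise AssertionError("fully CaM-bound subunit is inactive")
        if self.rates.exclusive and np.any((self.t286 == 2) & (self.cam != 0)):
            raise AssertionError("PP-bound subunit holds CaM in exclusive variant")
        cam_total = self.free_apo_cam + self.free_cam4 + self.bound_cam()
        if cam_total != self.total_cam:
            raise AssertionError(f"CaM not conserved: {cam_total} != {self.total_cam}")
        pp_total = self.free_pp + int((self.t286 == 2).sum())
        if pp_total != self.total_pp:
            raise AssertionError(f"PP not conserved: {pp_total} != {self.total_pp}")
        if self.free_apo_cam < 0 or self.free_cam4 < 0 or self.free_pp < 0:
            raise AssertionError("negative pool count")

    _marginalized_conf = False

    def snapshot(self) -> dict:
        return {
            "docked": self.docked.copy(),
            "conf": self.conf.copy(),
            "cam": self.cam.copy(),
            "t286": self.t286.copy(),
            "t306": self.t306.copy(),
            "inhib": self.inhib.copy(),
            "free_apo_cam": self.free_apo_cam,
            "free_cam4": self.free_cam4,
            "free_pp": self.free_pp,
        }


def build_propensities(sys: SystemState, marginalize: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised propensity matrix for the whole system.

    Returns ``(R, A)`` where ``R`` has shape (12, n_sub) -- one row per
    per-subunit channel -- and ``A`` has one entry per directed
    autophosphorylation edge.  This builder is the single source of truth for
    the engines; the incremental per-event updates are cross-checked against
    it (and against the interpreted rule table) in the test suite.
    """
    r = sys.rates
    n = sys.n_sub
    R = np.zeros((N_SUB_CHANNELS, n))
    excl = r.exclusive
    p = r.p_act
    if marginalize:
        stab = sys.stabilized()
        fa = np.where(stab, 1.0, p)
        f_inact = np.where(stab, 0.0, 1.0 - p)
    else:
        fa = sys.conf.astype(float)
        f_inact = 1.0 - fa

    c_cam = bimolecular_propensity(r.k_on_CaM, sys.volume)
    c_pp = bimolecular_propensity(r.effective_k_on_PP(), sys.volume)

    undocked = ~sys.docked
    cam_u = sys.cam == 0
    R[CH_UNDOCK] = r.k_undock * sys.docked
    dock_ok = undocked & cam_u & ~sys.t306
    R[CH_DOCK] = r.k_dock * dock_ok * (f_inact if r.dock_requires_inactive else 1.0)
    cam_on_ok = undocked & cam_u & ~sys.t306
    if excl:
        cam_on_ok = cam_on_ok & (sys.t286 != 2)
    R[CH_CAM_ON] = c_cam * sys.free_cam4 * cam_on_ok
    R[CH_CAM_OFF] = r.k_off_CaM_ini * (sys.cam == 1)
    R[CH_INI_FULL] = r.k_ini_to_full * (sys.cam == 1) * fa
    R[CH_FULL_INI] = r.k_full_to_ini * (sys.cam == 2)
    pp_on_ok = sys.t286 == 1
    if excl:
        pp_on_ok = pp_on_ok & cam_u
    R[CH_PP_ON] = c_pp * sys.free_pp * pp_on_ok
    R[CH_PP_OFF] = r.k_off_PP * (sys.t286 == 2)
    R[CH_PP_CAT] = (r.k_cat_PP if sys.k_cat_enabled else 0.0) * (sys.t286 == 2)
    R[CH_T306] = r.k_phos_T306 * (~sys.t306 & cam_u) * fa
    if not marginalize:
        R[CH_ACT] = r.k_activate * (sys.conf == 0)
        inact_ok = (sys.conf == 1) & (sys.cam != 2) & (sys.t286 != 1)
        if r.pp_bound_counts_as_phospho:
            inact_ok &= sys.t286 != 2
        R[CH_INACT] = r.k_inactivate * inact_ok

    s_ok = (sys.t286[sys.sub_e] == 0) & ~sys.docked[sys.sub_e] & ~sys.inhib[sys.sub_e]
    k_ok = ~sys.docked[sys.kin_e]
    if r.k252a_blocks_kinase_role:
        k_ok = k_ok & ~sys.inhib[sys.kin_e]
    A = r.k_autophos * s_ok * fa[sys.sub_e] * k_ok * fa[sys.kin_e]
    return R, np.asarray(A, dtype=float)


class _JumpEngine:
    """Shared direct-method SSA core with incremental propensity updates."""

    def __init__(self, sys: SystemState, marginalize: bool, rng: np.random.Generator):
        self.sys = sys
        self.marginalize = marginalize
        if marginalize:
            sys._marginalized_conf = True
        self.rng = rng
        r = sys.rates
        self._c_cam = bimolecular_propensity(r.k_on_CaM, sys.volume)
        self._c_pp = bimolecular_propensity(r.effective_k_on_PP(), sys.volume)
        self._events_since_resync = 0
        self.rebuild()

    # -- propensity bookkeeping ------------------------------------------
    def rebuild(self) -> None:
        self.R, self.A = build_propensities(self.sys, self.marginalize)
        sys = self.sys
        # eligibility masks let pool changes rescale the bimolecular rows
        # instead of recomputing them (the CaM bind/unbind flicker is by far
        # the most frequent event class)
        ok = ~sys.docked & (sys.cam == 0) & ~sys.t306
        if sys.rates.exclusive:
            ok = ok & (sys.t286 != 2)
        self._cam_elig = ok
        self._n_cam_elig = int(ok.sum())
        ok2 = sys.t286 == 1
        if sys.rates.exclusive:
            ok2 = ok2 & (sys.cam == 0)
        self._pp_elig = ok2
        self._n_pp_elig = int(ok2.sum())
        self._resync()

    def _resync(self) -> None:
        self.S = np.empty(N_SUB_CHANNELS + 1)
        self.S[:N_SUB_CHANNELS] = self.R.sum(axis=1)
        self.S[CH_EDGE] = self.A.sum()
        self._events_since_resync = 0

    def _set(self, ch: int, i: int, val: float) -> None:
        old = self.R[ch, i]
        if val != old:
            self.R[ch, i] = val
            self.S[ch] += val - old

    def _set_edge(self, e: int, val: float) -> None:
        old = self.A[e]
        if val != old:
            self.A[e] = val
            self.S[CH_EDGE] += val - old

    def _factor(self, i: int) -> float:
        sys = self.sys
        if self.marginalize:
            st = sys.cam[i] == 2 or sys.t286[i] == 1 or (
                sys.rates.pp_bound_counts_as_phospho and sys.t286[i] == 2
            )
            return 1.0 if st else sys.rates.p_act
        return float(sys.conf[i])

    def _refresh_edges(self, edges: np.ndarray) -> None:
        sys = self.sys
        r = sys.rates
        for e in edges:
            s = sys.sub_e[e]
            k = sys.kin_e[e]
            ok = (
                sys.t286[s] == 0
                and not sys.docked[s]
                and not sys.inhib[s]
                and not sys.docked[k]
            )
            if ok and r.k252a_blocks_kinase_role and sys.inhib[k]:
                ok = False
            val = r.k_autophos * self._factor(s) * self._factor(k) if ok else 0.0
            self._set_edge(e, val)

    def _refresh_subunit(self, i: int) -> None:
        sys = self.sys
        r = sys.rates
        fa = self._factor(i)
        docked = sys.docked[i]
        cam = sys.cam[i]
        t286 = sys.t286[i]
        t306 = sys.t306[i]
        self._set(CH_UNDOCK, i, r.k_undock if docked else 0.0)
        dock_ok = not docked and cam == 0 and not t306
        if dock_ok and r.dock_requires_inactive:
            if self.marginalize:
                st = cam == 2 or t286 == 1 or (r.pp_bound_counts_as_phospho and t286 == 2)
                f_in = 0.0 if st else 1.0 - r.p_act
            else:
                f_in = 1.0 - fa
            self._set(CH_DOCK, i, r.k_dock * f_in)
        else:
            self._set(CH_DOCK, i, r.k_dock if dock_ok else 0.0)
        cam_on_ok = not docked and cam == 0 and not t306
        if r.exclusive and t286 == 2:
            cam_on_ok = False
        if cam_on_ok != self._cam_elig[i]:
            self._cam_elig[i] = cam_on_ok
            self._n_cam_elig += 1 if cam_on_ok else -1
        self._set(CH_CAM_ON, i, self._c_cam * sys.free_cam4 if cam_on_ok else 0.0)
        self._set(CH_CAM_OFF, i, r.k_off_CaM_ini if cam == 1 else 0.0)
        self._set(CH_INI_FULL, i, r.k_ini_to_full * fa if cam == 1 else 0.0)
        self._set(CH_FULL_INI, i, r.k_full_to_ini if cam == 2 else 0.0)
        pp_on_ok = t286 == 1 and (not r.exclusive or cam == 0)
        if pp_on_ok != self._pp_elig[i]:
            self._pp_elig[i] = pp_on_ok
            self._n_pp_elig += 1 if pp_on_ok else -1
        self._set(CH_PP_ON, i, self._c_pp * sys.free_pp if pp_on_ok else 0.0)
        self._set(CH_PP_OFF, i, r.k_off_PP if t286 == 2 else 0.0)
        self._set(
            CH_PP_CAT, i,
            r.k_cat_PP if (t286 == 2 and sys.k_cat_enabled) else 0.0,
        )
        self._set(CH_T306, i, r.k_phos_T306 * fa if (not t306 and cam == 0) else 0.0)
        if not self.marginalize:
            conf = sys.conf[i]
            self._set(CH_ACT, i, r.k_activate if conf == 0 else 0.0)
            inact_ok = conf == 1 and cam != 2 and t286 != 1
            if inact_ok and r.pp_bound_counts_as_phospho and t286 == 2:
                inact_ok = False
            self._set(CH_INACT, i, r.k_inactivate if inact_ok else 0.0)
        if len(sys.in_edges[i]):
            self._refresh_edges(sys.in_edges[i])
        if len(sys.out_edges[i]):
            self._refresh_edges(sys.out_edges[i])

    def _refresh_cam_on_row(self, old_pool: int) -> None:
        sys = self.sys
        new = sys.free_cam4
        if old_pool > 0 and new > 0:
            self.R[CH_CAM_ON] *= new / old_pool
        else:
            np.multiply(self._cam_elig, self._c_cam * new, out=self.R[CH_CAM_ON])
        self.S[CH_CAM_ON] = self._c_cam * new * self._n_cam_elig

    def _refresh_pp_on_row(self, old_pool: int) -> None:
        sys = self.sys
        new = sys.free_pp
        if old_pool > 0 and new > 0:
            self.R[CH_PP_ON] *= new / old_pool
        else:
            np.multiply(self._pp_elig, self._c_pp * new, out=self.R[CH_PP_ON])
        self.S[CH_PP_ON] = self._c_pp * new * self._n_pp_elig

    # -- event firing -----------------------------------------------------
    def fire(self, ch: int, i: int) -> None:
        sys = self.sys
        if ch == CH_UNDOCK:
            sys.docked[i] = False
        elif ch == CH_DOCK:
            sys.docked[i] = True
        elif ch == CH_CAM_ON:
            old = sys.free_cam4
            sys.cam[i] = 1
            sys.free_cam4 -= 1
            self._refresh_cam_on_row(old)
        elif ch == CH_CAM_OFF:
            sys.cam[i] = 0
            if sys.phase == ACTIVATING:
                old = sys.free_cam4
                sys.free_cam4 += 1
                self._refresh_cam_on_row(old)
            else:
                sys.free_apo_cam += 1
        elif ch == CH_INI_FULL:
            sys.cam[i] = 2
        elif ch == CH_FULL_INI:
            sys.cam[i] = 1
        elif ch == CH_PP_ON:
            old = sys.free_pp
            sys.t286[i] = 2
            sys.free_pp -= 1
            self._refresh_pp_on_row(old)
        elif ch == CH_PP_OFF:
            old = sys.free_pp
            sys.t286[i] = 1
            sys.free_pp += 1
            self._refresh_pp_on_row(old)
        elif ch == CH_PP_CAT:
            old = sys.free_pp
            sys.t286[i] = 0
            sys.free_pp += 1
            self._refresh_pp_on_row(old)
        elif ch == CH_T306:
            sys.t306[i] = True
        elif ch == CH_ACT:
            sys.conf[i] = 1
        elif ch == CH_INACT:
            sys.conf[i] = 0
        elif ch == CH_EDGE:
            # i is an edge index; the substrate acquires pThr-286
            i = int(sys.sub_e[i])
            sys.t286[i] = 1
        else:  # pragma: no cover
            raise EngineError(f"unknown channel {ch}")
        self._refresh_subunit(i)
        self._events_since_resync += 1
        if self._events_since_resync >= 8192:
            self._resync()

    def sample(self, t: float, t_limit: float) -> tuple[float, int, int] | None:
        """Sample the next event; None if it falls beyond ``t_limit``."""
        total = float(self.S.sum())
        if total <= 0.0:
            return None
        tau = self.rng.exponential(1.0 / total)
        t_next = t + tau
        if t_next >= t_limit:
            return None
        u = self.rng.random() * total
        acc = 0.0
        ch = N_SUB_CHANNELS  # fall through to the edge channel
        for c in range(N_SUB_CHANNELS + 1):
            acc += self.S[c]
            if u < acc:
                ch = c
                break
        row = self.A if ch == CH_EDGE else self.R[ch]
        target = self.rng.random() * float(self.S[ch])
        cs = np.cumsum(row)
        idx = int(np.searchsorted(cs, target, side="right"))
        if idx >= len(row):  # numerical edge: pick the last positive entry
            idx = int(np.flatnonzero(row)[-1])
        return t_next, ch, idx


def _barrier_schedule(protocol: StimulusProtocol, t_end: float) -> list[tuple[float, str, str | None]]:
    """Merged, sorted (time, action, payload) barrier list on (0, t_end).

    Actions: ``phase`` (payload = new phase) and ``event`` (payload = event
    kind).
    """
    items: list[tuple[float, str, str | None]] = []
    for t, phase in phase_boundaries(protocol, t_end):
        items.append((t, "phase", phase))
    for t, kind in protocol.events:
        if 0.0 < t < t_end:
            items.append((t, "event", kind))
    items.sort(key=lambda x: x[0])
    return items


def _apply_action(sys: SystemState, action: str, payload: str | None) -> None:
    import warnings

    if action == "phase":
        sys.phase = payload
        if payload == ACTIVATING:
            sys.free_cam4 += sys.free_apo_cam
            sys.free_apo_cam = 0
        else:
            sys.free_apo_cam += sys.free_cam4
            sys.free_cam4 = 0
    elif action == "event":
        if payload == "kinase_inhibitor":
            sys.inhib[:] = True
        elif payload == "phosphatase_inhibitor":
            sys.k_cat_enabled = False
        elif payload == "chelate_Ca":
            warnings.warn(
                "chelate_Ca is a no-op in the two-state CaM model "
                "(free Ca2+ is not modelled explicitly)",
                stacklevel=2,
            )
        else:  # pragma: no cover
            raise EngineError(f"unknown event kind {payload!r}")
    else:  # pragma: no cover
        raise EngineError(f"unknown barrier action {action!r}")


def _record_times(t_end: float, interval: float) -> np.ndarray:
    n = int(np.floor(t_end / interval + 1e-9)) + 1
    return np.arange(n) * interval


def _run_jump(
    sys: SystemState,
    cfg: EngineConfig,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    marginalize: bool,
) -> np.ndarray:
    times = _record_times(cfg.t_end, cfg.record_interval)
    frames = np.empty((len(times), len(OBSERVABLE_COLUMNS)))
    rec_i = 0

    sys.phase = forcing_phase(0.0, protocol)
    if sys.phase == ACTIVATING:
        sys.free_cam4 += sys.free_apo_cam
        sys.free_apo_cam = 0
    for t, kind in protocol.events:
        if t == 0.0:
            _apply_action(sys, "event", kind)

    eng = _JumpEngine(sys, marginalize, rng)

    def record_upto(t_incl: float) -> None:
        nonlocal rec_i
        while rec_i < len(times) and times[rec_i] <= t_incl + 1e-12:
            frames[rec_i] = sys.counts(marginalize)
            if cfg.validate_frames:
                sys.check_invariants()
            rec_i += 1

    record_upto(0.0)
    barriers = _barrier_schedule(protocol, cfg.t_end)
    t = 0.0
    seg_starts = barriers + [(cfg.t_end, "end", None)]
    for t_next_barrier, action, payload in seg_starts:
        while True:
            ev = eng.sample(t, t_next_barrier)
            if ev is None:
                t = t_next_barrier
                break
            t_ev, ch, idx = ev
            record_upto(t_ev - 1e-9)
            eng.fire(ch, idx)
            t = t_ev
        if action == "end":
            break
        record_upto(t - 1e-9)
        _apply_action(sys, action, payload)
        eng.rebuild()
        record_upto(t)
    record_upto(cfg.t_end)
    return frames


def _run_fixed(
    sys: SystemState,
    cfg: EngineConfig,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fixed-timestep Bernoulli sampler (explicit conformational flicker)."""
    dt = cfg.dt
    times = _record_times(cfg.t_end, cfg.record_interval)
    frames = np.empty((len(times), len(OBSERVABLE_COLUMNS)))
    rec_i = 0
    sys.phase = forcing_phase(0.0, protocol)
    if sys.phase == ACTIVATING:
        sys.free_cam4 += sys.free_apo_cam
        sys.free_apo_cam = 0
    for t, kind in protocol.events:
        if t == 0.0:
            _apply_action(sys, "event", kind)
    barriers = _barrier_schedule(protocol, cfg.t_end)
    b_i = 0
    n_steps = int(round(cfg.t_end / dt))
    t = 0.0
    if times[rec_i] <= 1e-15:
        frames[rec_i] = sys.counts(False)
        rec_i += 1
    p_R = p_A = None  # rebuilt lazily: the state only changes when
    # something fired or a barrier was crossed
    for step in range(n_steps):
        while b_i < len(barriers) and barriers[b_i][0] <= t + 1e-15:
            _, action, payload = barriers[b_i]
            _apply_action(sys, action, payload)
            b_i += 1
            p_R = None
        if p_R is None:
            R, A = build_propensities(sys, marginalize=False)
            amax = max(R.max(initial=0.0), A.max(initial=0.0))
            p_max = -np.expm1(-amax * dt)
            if p_max > 0.1:
                raise EngineError(
                    f"fixed_step dt={dt:g} gives a per-instance firing "
                    f"probability {p_max:.3f} > 0.1; reduce dt"
                )
            # independent Bernoulli draws per eligible rule instance
            p_R = -np.expm1(-R * dt)
            p_A = -np.expm1(-A * dt)
        fired: list[tuple[int, int]] = []
        hits = np.argwhere(rng.random(R.shape) < p_R)
        for ch, i in hits:
            fired.append((int(ch), int(i)))
        hits_e = np.flatnonzero(rng.random(A.shape) < p_A)
        for e in hits_e:
            fired.append((CH_EDGE, int(e)))
        if fired:
            # conflicting firings on one subunit: uniform choice of a winner
            by_sub: dict[int, list[tuple[int, int]]] = {}
            for ch, i in fired:
                s = int(sys.sub_e[i]) if ch == CH_EDGE else i
                by_sub.setdefault(s, []).append((ch, i))
            winners = []
            for s, cands in by_sub.items():
                winners.append(cands[rng.integers(len(cands))] if len(cands) > 1 else cands[0])
            order = rng.permutation(len(winners))
            for w in order:
                ch, i = winners[w]
                if ch == CH_CAM_ON and sys.free_cam4 <= 0:
                    continue
                if ch == CH_PP_ON and sys.free_pp <= 0:
                    continue
                _fire_plain(sys, ch, i)
            p_R = None
        t = (step + 1) * dt
        while rec_i < len(times) and times[rec_i] <= t + 1e-12:
            frames[rec_i] = sys.counts(False)
            if cfg.validate_frames:
                sys.check_invariants()
            rec_i += 1
    while rec_i < len(times):
        frames[rec_i] = sys.counts(False)
        rec_i += 1
    return frames


def _fire_plain(sys: SystemState, ch: int, i: int) -> None:
    """Apply one event to the raw state (no propensity bookkeeping)."""
    if ch == CH_EDGE:
        sys.t286[int(sys.sub_e[i])] = 1
        return
    if ch == CH_UNDOCK:
        sys.docked[i] = False
    elif ch == CH_DOCK:
        sys.docked[i] = True
    elif ch == CH_CAM_ON:
        sys.cam[i] = 1
        sys.free_cam4 -= 1
    elif ch == CH_CAM_OFF:
        sys.cam[i] = 0
        if sys.phase == ACTIVATING:
            sys.free_cam4 += 1
        else:
            sys.free_apo_cam += 1
    elif ch == CH_INI_FULL:
        sys.cam[i] = 2
    elif ch == CH_FULL_INI:
        sys.cam[i] = 1
    elif ch == CH_PP_ON:
        sys.t286[i] = 2
        sys.free_pp -= 1
    elif ch == CH_PP_OFF:
        sys.t286[i] = 1
        sys.free_pp += 1
    elif ch == CH_PP_CAT:
        sys.t286[i] = 0
        sys.free_pp += 1
    elif ch == CH_T306:
        sys.t306[i] = True
    elif ch == CH_ACT:
        sys.conf[i] = 1
    elif ch == CH_INACT:
        sys.conf[i] = 0
    else:  # pragma: no cover
        raise EngineError(f"unknown channel {ch}")


def simulate_state(
    sys: SystemState,
    engine_cfg: EngineConfig,
    stimulus: StimulusProtocol | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance a pre-built state in place; return (times, frames).

    Lower-level entry used for fragments and oracle comparisons; the scheme
    is taken from ``engine_cfg``.
    """
    protocol = stimulus if stimulus is not None else StimulusProtocol(mode="none")
    rng = np.random.default_rng(engine_cfg.seed)
    times = _record_times(engine_cfg.t_end, engine_cfg.record_interval)
    if engine_cfg.scheme == "fixed_step":
        frames = _run_fixed(sys, engine_cfg, protocol, rng)
    else:
        frames = _run_jump(
            sys, engine_cfg, protocol, rng,
            marginalize=engine_cfg.scheme == "qssa",
        )
    return times, frames


@dataclass
class TrajectoryEnsemble:
    """Recorded observable time courses for a set of seeded replicates."""

    times: np.ndarray
    data: np.ndarray  # shape (n_replicates, n_frames, n_observables)
    columns: tuple[str, ...]
    seeds: tuple[int, ...]
    scheme: str
    volume: float
    n_sub: int
    final_states: list[dict] = field(default_factory=list)
    config_fingerprint: str = ""

    @property
    def n_replicates(self) -> int:
        return self.data.shape[0]

    def column(self, name: str) -> np.ndarray:
        """(n_replicates, n_frames) slice for one observable."""
        return self.data[:, :, self.columns.index(name)]

    def mean(self, name: str) -> np.ndarray:
        return self.column(name).mean(axis=0)

    def sem(self, name: str) -> np.ndarray | None:
        if self.n_replicates < 2:
            return None
        return self.column(name).std(axis=0, ddof=1) / np.sqrt(self.n_replicates)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in range(self.n_replicates):
            df = pd.DataFrame(self.data[r], columns=list(self.columns))
            df.insert(0, "time", self.times)
            df.insert(1, "replicate", r)
            recs.append(df)
        return pd.concat(recs, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _fingerprint(model: ModelConfig, cfg: EngineConfig, protocol: StimulusProtocol) -> str:
    blob = json.dumps(
        {
            "n_holo": model.n_holo,
            "rates": {k: getattr(model.rates, k) for k in vars(model.rates)},
            "pools": {
                "free_apo_cam": model.pools.free_apo_cam,
                "free_cam4": model.pools.free_cam4,
                "free_pp": model.pools.free_pp,
                "volume": model.pools.volume,
            },
            "engine": {
                "scheme": cfg.scheme,
                "dt": cfg.dt,
                "t_end": cfg.t_end,
                "record_interval": cfg.record_interval,
            },
            "stimulus": {
                "mode": protocol.mode,
                "frequency": protocol.frequency,
                "pulse_width": protocol.pulse_width,
                "bolus_duration": protocol.bolus_duration,
                "events": list(protocol.events),
            },
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha1(blob.encode()).hexdigest()[:16]


def _run_one(
    model: ModelConfig,
    cfg: EngineConfig,
    protocol: StimulusProtocol,
    seed: int,
) -> tuple[np.ndarray, dict]:
    sys = SystemState(model)
    rng = np.random.default_rng(seed)
    if cfg.scheme == "qssa":
        frames = _run_jump(sys, cfg, protocol, rng, marginalize=True)
    elif cfg.scheme == "ssa":
        frames = _run_jump(sys, cfg, protocol, rng, marginalize=False)
    else:
        frames = _run_fixed(sys, cfg, protocol, rng)
    return frames, sys.snapshot()


def run_replicates(
    model: ModelConfig,
    engine_cfg: EngineConfig,
    stimulus: StimulusProtocol | None = None,
) -> TrajectoryEnsemble:
    """Run ``n_replicates`` seeded trajectories; replicate r uses seed+r."""
    protocol = stimulus if stimulus is not None else StimulusProtocol(mode="none")
    times = _record_times(engine_cfg.t_end, engine_cfg.record_interval)
    seeds = tuple(engine_cfg.seed + r for r in range(engine_cfg.n_replicates))
    data = np.empty((len(seeds), len(times), len(OBSERVABLE_COLUMNS)))
    finals = []
    for r, s in enumerate(seeds):
        frames, snap = _run_one(model, engine_cfg, protocol, s)
        data[r] = frames
        finals.append(snap)
    return TrajectoryEnsemble(
        times=times,
        data=data,
        columns=OBSERVABLE_COLUMNS,
        seeds=seeds,
        scheme=engine_cfg.scheme,
        volume=model.pools.volume,
        n_sub=model.n_holo * SUBUNITS_PER_HOLOENZYME,
        final_states=finals,
        config_fingerprint=_fingerprint(model, engine_cfg, protocol),
    )


def run_ssa(model: ModelConfig, engine_cfg: EngineConfig, stimulus=None) -> TrajectoryEnsemble:
    """Single-replicate exact SSA trajectory (explicit flicker)."""
    cfg = replace(engine_cfg, scheme="ssa", n_replicates=1)
    return run_replicates(model, cfg, stimulus)


def run_qssa(model: ModelConfig, engine_cfg: EngineConfig, stimulus=None) -> TrajectoryEnsemble:
    """Single-replicate QSSA-accelerated trajectory."""
    cfg = replace(engine_cfg, scheme="qssa", n_replicates=1)
    return run_replicates(model, cfg, stimulus)


def run_fixed(model: ModelConfig, engine_cfg: EngineConfig, stimulus=None) -> TrajectoryEnsemble:
    """Single-replicate fixed-timestep trajectory."""
    cfg = replace(engine_cfg, scheme="fixed_step", n_replicates=1)
    return run_replicates(model, cfg, stimulus)
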