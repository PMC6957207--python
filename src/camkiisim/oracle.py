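"""Independent verification: closed-form parameter derivations and exact
chemical-master-equation (CME) solutions for small instances.

The CME treats the free-ligand pools as part of the global state (finite
counts, per-pair propensities), so its solutions are exact for the same jump
process the stochastic engines sample.  State spaces beyond a few subunits
are astronomically large -- that is the point of the stochastic engines -- so
enumeration is capped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from camkiisim.rates import Pools, RateTable
from camkiisim.rules import Rule, propensity
from camkiisim.states import SubunitState


def derive_parameters() -> dict[str, float]:
    """Closed-form derived constants implied by the measured inputs.

    * ``K_docking`` -- ratio of CaM on-rates for free peptide vs full-length
      kinase, 1.8e6 / 1e8 = 0.018; sets the undocked:docked equilibrium.
    * ``k_undock`` -- k_dock * K_docking = 35 * 0.018 = 0.63 s^-1.
    * ``k_off_CaM_ini`` -- K_D(initial contact) * k_on = 5.9e-6 * 1e8
      = 590 s^-1.
    * ``initial_vs_full_occupancy`` -- k_full_to_ini / k_ini_to_full
      = 4e-3 / 350 ~ 1.1e-5 (a bound CaM is essentially always fully
      wrapped).
    * ``K_M_PP`` -- (k_off + k_cat) / k_on = 2.5 / 3e6 ~ 8.3e-7 M.
    * ``p_act`` -- stationary open probability 2e4 / (2e4 + 1e7) ~ 0.002.
    """
    K_docking = 1.8e6 / 1.0e8
    return {
        "K_docking": K_docking,
        "k_undock": 35.0 * K_docking,
        "k_off_CaM_ini": 5.9e-6 * 1.0e8,
        "initial_vs_full_occupancy": 4.0e-3 / 350.0,
        "K_M_PP": (0.5 + 2.0) / 3.0e6,
        "p_act": 2.0e4 / (2.0e4 + 1.0e7),
    }


class StateSpaceCapError(RuntimeError):
    """Raised when reachable-state enumeration exceeds the configured cap."""


@dataclass
class CMESystem:
    """Enumerated finite state space with its sparse generator.

    ``states`` are ``(subunit_tuple, pools_tuple)`` pairs where
    ``subunit_tuple`` holds one :class:`SubunitState` per subunit and
    ``pools_tuple`` is ``(free_cam4, free_pp)``.  ``generator`` is the CME
    generator Q with Q[i, j] the rate from state i to state j and rows
    summing to zero.
    """

    states: list
    index: dict
    generator: sparse.csr_matrix
    p0: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.states)

    def marginal(self, p: np.ndarray, fn) -> float:
        """Probability mass of states for which ``fn(state)`` is true."""
        return float(sum(pi for s, pi in zip(self.states, p) if fn(s)))


def _neighbors_chain(n_subunits: int) -> list[int | None]:
    """Open-chain kinase assignment: subunit i's kinase is subunit i+1.

    Mirrors the counter-clockwise convention on a ring fragment; the last
    subunit has no kinase.
    """
    return [i + 1 if i + 1 < n_subunits else None for i in range(n_subunits)]


def enumerate_cme(
    n_subunits: int,
    pools: Pools,
    rules: list[Rule],
    rates: RateTable,
    initial: tuple | None = None,
    marginalize_conf: bool = False,
    cap: int = 10**6,
) -> CMESystem:
    """Reachable-state enumeration of a small open-chain system.

    ``n_subunits`` must be 1-3 (the oracle exists to validate rules, not to
    solve holoenzymes).  Bimolecular rules consume from the finite pools in
    the state, at per-pair propensity times pool count, making the oracle
    exact rather than mean-field.
    """
    if n_subunits < 1 or n_subunits > 3:
        raise ValueError(f"n_subunits must be 1..3, got {n_subunits}")
    kin_of = _neighbors_chain(n_subunits)
    default = SubunitState()
    init_subs = initial if initial is not None else tuple(default for _ in range(n_subunits))
    init = (tuple(init_subs), (pools.free_cam4, pools.free_pp))

    def transitions(state):
        subs, (cam4, pp) = state
        cur_pools = replace(pools, free_cam4=cam4, free_pp=pp)
        out = []
        for i, sub in enumerate(subs):
            for rule in rules:
                neighbor = None
                if rule.participants == "neighbor_gated":
                    k = kin_of[i]
                    if k is None:
                        continue
                    neighbor = subs[k]
                a = propensity(
                    rule, sub, neighbor, rates, cur_pools,
                    marginalize_conf=marginalize_conf,
                )
                if a <= 0.0:
                    continue
                new_subs = list(subs)
                new_subs[i] = rule.apply(sub)
                d_cam4, d_pp = 0, 0
                if rule.consumes == "free_cam4":
                    d_cam4 -= 1
                elif rule.consumes == "free_pp":
                    d_pp -= 1
                if rule.releases == "free_cam4":
                    d_cam4 += 1
                elif rule.releases == "free_pp":
                    d_pp += 1
                out.append(((tuple(new_subs), (cam4 + d_cam4, pp + d_pp)), a))
        return out

    states = [init]
    index = {init: 0}
    rows, cols, vals = [], [], []
    frontier = [init]
    while frontier:
        nxt = []
        for s in frontier:
            si = index[s]
            for target, a in transitions(s):
                if target not in index:
                    if len(states) >= cap:
                        raise StateSpaceCapError(
                            f"state space exceeds cap of {cap} states"
                        )
                    index[target] = len(states)
                    states.append(target)
                    nxt.append(target)
                rows.append(si)
                cols.append(index[target])
                vals.append(a)
        frontier = nxt

    n = len(states)
    Q = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    diag = np.asarray(Q.sum(axis=1)).ravel()
    Q = Q - sparse.diags(diag)
    p0 = np.zeros(n)
    p0[0] = 1.0
    return CMESystem(states=states, index=index, generator=Q.tocsr(), p0=p0)


def solve_cme(
    system: CMESystem,
    t: float | None = None,
    stationary: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Transient or stationary distribution of the enumerated system.

    Transient solutions integrate the forward equation dp/dt = Q^T p with a
    stiff (BDF) integrator; the stationary distribution is the normalised
    null vector of Q^T.  Normalisation is preserved to ~1e-9.
    """
    QT = system.generator.T.tocsr()
    if stationary:
        dense = QT.toarray()
        w, v = np.linalg.eig(dense)
        k = int(np.argmin(np.abs(w)))
        p = np.real(v[:, k])
        if p.sum() < 0:
            p = -p
        p = np.clip(p, 0.0, None)
        return p / p.sum()
    if t is None:
        raise ValueError("either t or stationary=True is required")
    if t == 0:
        return system.p0.copy()

    def rhs(_, p):
        return QT @ p

    sol = solve_ivp(
        rhs, (0.0, t), system.p0, method="BDF", rtol=rtol, atol=atol,
        jac=QT,
    )
    if not sol.success:
        raise RuntimeError(f"CME integration failed: {sol.message}")
    p = sol.y[:, -1]
    if abs(p.sum() - 1.0) > 1e-6:
        raise RuntimeError(f"CME solution lost normalisation: sum={p.sum():.2e}")
    return p / p.sum()
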