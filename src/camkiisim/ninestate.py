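"""Nine-state-one-step CaM variant with explicit Ca2+ binding and trapping.

In this variant the docking and conformational-activation flags are removed:
a subunit is "active" exactly when CaM (in any of its nine Ca2+-loading
states) is bound.  CaM carries 0-2 Ca2+ per lobe (N and C), giving nine
states with (0, 0) = apo-CaM; every state may bind CaMKII in a single step
with state-specific kinetics, and Ca2+ may bind or leave CaM lobes while the
CaM sits on the kinase.  CaM trapping is modelled as a division of the
CaM-CaMKII off-rate by ``trapping_factor`` (default 1000) on pThr-286
subunits.  Ca2+ is a discrete pool; a ``chelate_Ca`` stimulus event removes
all free Ca2+ at its event time.

The default rate set shipped with the package
(``data/nine_state_rates_synthetic.yaml``) anchors the CaM2C and apo-CaM
dissociation constants to published equilibrium values and fills the
remaining entries with a documented synthetic interpolation; see the file
header and docs/methods.md.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from camkiisim.engines import EngineConfig, TrajectoryEnsemble, _record_times
from camkiisim.rates import RateTable, bimolecular_propensity, DEFAULT_VOLUME_L
from camkiisim.states import ConfigurationError, SUBUNITS_PER_HOLOENZYME, kinase_edges
from camkiisim.stimulus import StimulusProtocol

__all__ = [
    "NineStateCaM",
    "NineStateRates",
    "NineStateModel",
    "build_nine_state_model",
    "default_nine_state_rates",
    "run_nine_state",
    "NINE_STATE_COLUMNS",
]

#: All (n_lobe_ca, c_lobe_ca) pairs in index order 0..8.
CAM_STATES = [(n, c) for n in range(3) for c in range(3)]
_STATE_INDEX = {s: i for i, s in enumerate(CAM_STATES)}
CAM4_INDEX = _STATE_INDEX[(2, 2)]
APO_INDEX = _STATE_INDEX[(0, 0)]


@dataclass(frozen=True)
class NineStateCaM:
    """One CaM molecule's Ca2+ loading: 0-2 ions per lobe."""

    n_lobe_ca: int
    c_lobe_ca: int

    def __post_init__(self):
        if not (0 <= self.n_lobe_ca <= 2 and 0 <= self.c_lobe_ca <= 2):
            raise ConfigurationError("lobe occupancies must be 0..2")

    @property
    def index(self) -> int:
        return _STATE_INDEX[(self.n_lobe_ca, self.c_lobe_ca)]

    @property
    def is_apo(self) -> bool:
        return self.n_lobe_ca == 0 and self.c_lobe_ca == 0


@dataclass
class NineStateRates:
    """Kinetic constants of the nine-state CaM network.

    ``ca_free`` / ``ca_bound`` give sequential two-site Ca2+ (kon, koff)
    pairs per lobe for free and CaMKII-bound CaM.  ``camkii_kon`` /
    ``camkii_koff`` are per-CaM-state binding constants to CaMKII subunits;
    on pThr-286 subunits the off-rate is divided by ``trapping_factor``
    (uniformly across states when ``trap_all_states``, otherwise only for
    fully loaded CaM4).
    """

    ca_free_on: dict = field(default_factory=dict)   # lobe -> [k1, k2]
    ca_free_off: dict = field(default_factory=dict)
    ca_bound_on: dict = field(default_factory=dict)
    ca_bound_off: dict = field(default_factory=dict)
    camkii_kon: dict = field(default_factory=dict)   # (n, c) -> M^-1 s^-1
    camkii_koff: dict = field(default_factory=dict)  # (n, c) -> s^-1
    trapping_factor: float = 1000.0
    trap_all_states: bool = True
    autophos_rate: float = 1.0

    def missing_keys(self) -> list[str]:
        missing = []
        for lobe in ("N", "C"):
            for table, nm in (
                (self.ca_free_on, "ca_free.kon"),
                (self.ca_free_off, "ca_free.koff"),
                (self.ca_bound_on, "ca_bound.kon"),
                (self.ca_bound_off, "ca_bound.koff"),
            ):
                if lobe not in table or len(table[lobe]) != 2:
                    missing.append(f"{nm}[{lobe}]")
        for s in CAM_STATES:
            if s not in self.camkii_kon:
                missing.append(f"camkii_kon[{s}]")
            if s not in self.camkii_koff:
                missing.append(f"camkii_koff[{s}]")
        return missing

    def koff_camkii(self, state_idx: int, pT286: bool) -> float:
        s = CAM_STATES[state_idx]
        k = self.camkii_koff[s]
        if pT286 and (self.trap_all_states or state_idx == CAM4_INDEX):
            k /= self.trapping_factor
        return k


def default_nine_state_rates() -> NineStateRates:
    """Load the shipped (synthetic, anchor-calibrated) default rate set."""
    ref = importlib.resources.files("camkiisim.data") / "nine_state_rates_synthetic.yaml"
    raw = yaml.safe_load(ref.read_text())
    camkii_kon, camkii_koff = {}, {}
    for key, entry in raw["camkii"].items():
        n, c = (int(x) for x in key.split(","))
        camkii_kon[(n, c)] = float(entry["kon"])
        camkii_koff[(n, c)] = float(entry["koff"])
    return NineStateRates(
        ca_free_on={l: [float(x) for x in raw["ca_free"][l]["kon"]] for l in ("N", "C")},
        ca_free_off={l: [float(x) for x in raw["ca_free"][l]["koff"]] for l in ("N", "C")},
        ca_bound_on={l: [float(x) for x in raw["ca_bound"][l]["kon"]] for l in ("N", "C")},
        ca_bound_off={l: [float(x) for x in raw["ca_bound"][l]["koff"]] for l in ("N", "C")},
        camkii_kon=camkii_kon,
        camkii_koff=camkii_koff,
        trapping_factor=float(raw["trapping_factor"]),
        trap_all_states=bool(raw["trap_all_states"]),
        autophos_rate=float(raw["autophos_rate"]),
    )


EXCLUSION_MODES = ("exclusive", "non_exclusive", "cam4_only")

#: Observable columns of the nine-state trajectories.  "active" counts
#: CaM-bound subunits (activation is defined by CaM binding here).
NINE_STATE_COLUMNS = (
    "active",
    "pT286",
    "pp_bound",
    "apo_bound",
    "cam4_bound",
    "free_ca",
    "bound_ca",
    "free_pp",
    "free_cam",
)


@dataclass
class NineStateModel:
    """Validated nine-state model: rates, exclusion mode and topology."""

    rates9: NineStateRates
    base: RateTable
    exclusion: str = "exclusive"

    def __post_init__(self):
        if self.exclusion not in EXCLUSION_MODES:
            raise ConfigurationError(
                f"exclusion must be one of {EXCLUSION_MODES}, got {self.exclusion!r}"
            )
        missing = self.rates9.missing_keys()
        if missing:
            raise ConfigurationError(
                "nine-state rate set incomplete; missing: " + ", ".join(missing)
            )

    def rule_records(self) -> list[dict]:
        """Serialisable listing of the variant's transition rules."""
        recs = []
        for lobe in ("N", "C"):
            for site in range(2):
                for loc in ("free", "bound"):
                    on = (self.rates9.ca_free_on if loc == "free" else self.rates9.ca_bound_on)[lobe][site]
                    off = (self.rates9.ca_free_off if loc == "free" else self.rates9.ca_bound_off)[lobe][site]
                    recs.append({"name": f"ca_{lobe}{site + 1}_bind_{loc}", "kon": on})
                    recs.append({"name": f"ca_{lobe}{site + 1}_release_{loc}", "koff": off})
        for s in CAM_STATES:
            recs.append({
                "name": f"cam{s}_bind_subunit",
                "kon": self.rates9.camkii_kon[s],
                "guard": ["cam_unbound"] + (["t286_not_pp_bound"] if self.exclusion == "exclusive" else []),
            })
            recs.append({
                "name": f"cam{s}_release_subunit",
                "koff": self.rates9.camkii_koff[s],
                "trapped_koff": self.rates9.koff_camkii(_STATE_INDEX[s], True),
            })
        pp_guard = ["pT286"]
        if self.exclusion == "exclusive":
            pp_guard.append("cam_unbound")
        elif self.exclusion == "cam4_only":
            pp_guard.append("cam_not_cam4")
        recs.append({"name": "pp_bind", "kon": self.base.effective_k_on_PP(), "guard": pp_guard})
        recs.append({"name": "pp_release", "koff": self.base.k_off_PP})
        recs.append({"name": "pp_dephosphorylate", "kcat": self.base.k_cat_PP})
        recs.append({
            "name": "autophosphorylate_T286",
            "rate": self.rates9.autophos_rate,
            "guard": ["uT286", "cam_bound"],
            "neighbor_guard": ["neighbor_cam_bound"],
        })
        return recs


def build_nine_state_model(
    rates9: NineStateRates | None = None,
    base: RateTable | None = None,
    exclusion: str = "exclusive",
) -> NineStateModel:
    """Assemble and validate the nine-state-one-step model.

    Raises a configuration error listing absent rate keys if the rate set is
    incomplete.  ``exclusion`` chooses which bound CaM states block
    phosphatase binding: all of them (``exclusive``), none
    (``non_exclusive``), or only fully loaded CaM4 (``cam4_only``).
    """
    return NineStateModel(
        rates9=rates9 if rates9 is not None else default_nine_state_rates(),
        base=base if base is not None else RateTable(),
        exclusion=exclusion,
    )


class NineStateSystem:
    """Mutable state of the nine-state simulation."""

    def __init__(self, model: NineStateModel, n_holo: int, n_cam: int, n_ca: int,
                 n_pp: int, volume: float = DEFAULT_VOLUME_L):
        if n_holo < 1:
            raise ConfigurationError("n_holo must be >= 1")
        self.model = model
        n = n_holo * SUBUNITS_PER_HOLOENZYME
        self.n_sub = n
        self.cam_idx = np.full(n, -1, dtype=np.int8)  # -1 unbound else 0..8
        self.t286 = np.zeros(n, dtype=np.int8)  # 0 uT286, 1 pT286, 2 PP-bound
        self.free_cam = np.zeros(9, dtype=np.int64)
        self.free_cam[APO_INDEX] = n_cam
        self.free_ca = n_ca
        self.free_pp = n_pp
        self.volume = volume
        self.k_cat_enabled = True
        sub_e, kin_e, _ = kinase_edges(n_holo, model.base.dof)
        self.sub_e = sub_e
        self.kin_e = kin_e
        self.total_cam = n_cam
        self.total_ca = n_ca
        self.total_pp = n_pp

    def bound_ca(self) -> int:
        tot = 0
        for i in range(self.n_sub):
            s = self.cam_idx[i]
            if s >= 0:
                n, c = CAM_STATES[s]
                tot += n + c
        free_lobe = sum(
            cnt * (CAM_STATES[s][0] + CAM_STATES[s][1])
            for s, cnt in enumerate(self.free_cam)
        )
        return tot + free_lobe

    def check_invariants(self) -> None:
        bound = int((self.cam_idx >= 0).sum())
        if int(self.free_cam.sum()) + bound != self.total_cam:
            raise AssertionError("CaM not conserved in nine-state model")
        if self.free_pp + int((self.t286 == 2).sum()) != self.total_pp:
            raise AssertionError("PP not conserved in nine-state model")
        if self.free_ca + self.bound_ca() != self.total_ca:
            raise AssertionError("Ca2+ not conserved in nine-state model")
        if self.model.exclusion == "exclusive" and np.any(
            (self.t286 == 2) & (self.cam_idx >= 0)
        ):
            raise AssertionError("PP-bound subunit holds CaM in exclusive mode")

    def counts(self) -> tuple:
        bound = self.cam_idx >= 0
        return (
            float(bound.sum()),
            float((self.t286 == 1).sum()),
            float((self.t286 == 2).sum()),
            float((self.cam_idx == APO_INDEX).sum()),
            float((self.cam_idx == CAM4_INDEX).sum()),
            float(self.free_ca),
            float(self.bound_ca()),
            float(self.free_pp),
            float(self.free_cam.sum()),
        )


def _build_channels(sys: NineStateSystem):
    """Enumerate (rate, action) pairs for the current state."""
    m = sys.model
    r9 = m.rates9
    base = m.base
    V = sys.volume
    ch: list[tuple[float, tuple]] = []
    ca_pair = {
        ("free", "N", 0): bimolecular_propensity(r9.ca_free_on["N"][0], V),
        ("free", "N", 1): bimolecular_propensity(r9.ca_free_on["N"][1], V),
        ("free", "C", 0): bimolecular_propensity(r9.ca_free_on["C"][0], V),
        ("free", "C", 1): bimolecular_propensity(r9.ca_free_on["C"][1], V),
        ("bound", "N", 0): bimolecular_propensity(r9.ca_bound_on["N"][0], V),
        ("bound", "N", 1): bimolecular_propensity(r9.ca_bound_on["N"][1], V),
        ("bound", "C", 0): bimolecular_propensity(r9.ca_bound_on["C"][0], V),
        ("bound", "C", 1): bimolecular_propensity(r9.ca_bound_on["C"][1], V),
    }
    # free-CaM lobe transitions (pool level)
    for s, (n, c) in enumerate(CAM_STATES):
        cnt = int(sys.free_cam[s])
        if cnt == 0:
            continue
        if n < 2 and sys.free_ca > 0:
            a = ca_pair[("free", "N", n)] * sys.free_ca * cnt
            ch.append((a, ("free_lobe", s, _STATE_INDEX[(n + 1, c)], +1)))
        if n > 0:
            a = r9.ca_free_off["N"][n - 1] * cnt
            ch.append((a, ("free_lobe", s, _STATE_INDEX[(n - 1, c)], -1)))
        if c < 2 and sys.free_ca > 0:
            a = ca_pair[("free", "C", c)] * sys.free_ca * cnt
            ch.append((a, ("free_lobe", s, _STATE_INDEX[(n, c + 1)], +1)))
        if c > 0:
            a = r9.ca_free_off["C"][c - 1] * cnt
            ch.append((a, ("free_lobe", s, _STATE_INDEX[(n, c - 1)], -1)))
    # per-subunit channels
    kon_pair = [bimolecular_propensity(r9.camkii_kon[s], V) for s in CAM_STATES]
    c_pp = bimolecular_propensity(base.effective_k_on_PP(), V)
    for i in range(sys.n_sub):
        s = int(sys.cam_idx[i])
        t = int(sys.t286[i])
        if s < 0:
            if not (m.exclusion == "exclusive" and t == 2):
                for st in range(9):
                    cnt = int(sys.free_cam[st])
                    if cnt:
                        ch.append((kon_pair[st] * cnt, ("cam_bind", i, st)))
        else:
            ch.append((r9.koff_camkii(s, t == 1), ("cam_release", i)))
            n, c = CAM_STATES[s]
            if n < 2 and sys.free_ca > 0:
                ch.append((ca_pair[("bound", "N", n)] * sys.free_ca,
                           ("bound_lobe", i, _STATE_INDEX[(n + 1, c)], +1)))
            if n > 0:
                ch.append((r9.ca_bound_off["N"][n - 1],
                           ("bound_lobe", i, _STATE_INDEX[(n - 1, c)], -1)))
            if c < 2 and sys.free_ca > 0:
                ch.append((ca_pair[("bound", "C", c)] * sys.free_ca,
                           ("bound_lobe", i, _STATE_INDEX[(n, c + 1)], +1)))
            if c > 0:
                ch.append((r9.ca_bound_off["C"][c - 1],
                           ("bound_lobe", i, _STATE_INDEX[(n, c - 1)], -1)))
        if t == 1 and sys.free_pp > 0:
            blocked = (
                (m.exclusion == "exclusive" and s >= 0)
                or (m.exclusion == "cam4_only" and s == CAM4_INDEX)
            )
            if not blocked:
                ch.append((c_pp * sys.free_pp, ("pp_bind", i)))
        elif t == 2:
            ch.append((base.k_off_PP, ("pp_release", i)))
            if sys.k_cat_enabled:
                ch.append((base.k_cat_PP, ("pp_cat", i)))
    # autophosphorylation edges: both substrate and kinase must be CaM-bound
    for s_i, k_i in zip(sys.sub_e, sys.kin_e):
        if sys.t286[s_i] == 0 and sys.cam_idx[s_i] >= 0 and sys.cam_idx[k_i] >= 0:
            ch.append((r9.autophos_rate, ("autophos", int(s_i))))
    return ch


def _apply_nine(sys: NineStateSystem, action: tuple) -> None:
    kind = action[0]
    if kind == "free_lobe":
        _, s_from, s_to, d_ca = action
        sys.free_cam[s_from] -= 1
        sys.free_cam[s_to] += 1
        sys.free_ca -= d_ca
    elif kind == "bound_lobe":
        _, i, s_to, d_ca = action
        sys.cam_idx[i] = s_to
        sys.free_ca -= d_ca
    elif kind == "cam_bind":
        _, i, st = action
        sys.free_cam[st] -= 1
        sys.cam_idx[i] = st
    elif kind == "cam_release":
        _, i = action
        sys.free_cam[int(sys.cam_idx[i])] += 1
        sys.cam_idx[i] = -1
    elif kind == "pp_bind":
        _, i = action
        sys.t286[i] = 2
        sys.free_pp -= 1
    elif kind == "pp_release":
        _, i = action
        sys.t286[i] = 1
        sys.free_pp += 1
    elif kind == "pp_cat":
        _, i = action
        sys.t286[i] = 0
        sys.free_pp += 1
    elif kind == "autophos":
        _, i = action
        sys.t286[i] = 1
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown nine-state action {kind!r}")


def run_nine_state(
    model: NineStateModel,
    engine_cfg: EngineConfig,
    n_holo: int = 30,
    n_cam: int = 450,
    n_ca: int = 2000,
    n_pp: int = 17,
    volume: float = DEFAULT_VOLUME_L,
    stimulus: StimulusProtocol | None = None,
) -> TrajectoryEnsemble:
    """Seeded replicate ensemble of the nine-state model.

    The conformational QSSA does not apply here (there is no activation
    flag), so every scheme runs the same exact jump process.  The standard
    Ca2+-pulse protocol instantiates all Ca2+ at t = 0 and removes the free
    pool at a ``chelate_Ca`` event.
    """
    protocol = stimulus if stimulus is not None else StimulusProtocol(
        mode="none", events=((2.0, "chelate_Ca"),)
    )
    times = _record_times(engine_cfg.t_end, engine_cfg.record_interval)
    seeds = tuple(engine_cfg.seed + r for r in range(engine_cfg.n_replicates))
    data = np.empty((len(seeds), len(times), len(NINE_STATE_COLUMNS)))
    finals = []
    chel_times = sorted(t for t, kind in protocol.events if kind == "chelate_Ca")
    for r, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        sys = NineStateSystem(model, n_holo, n_cam, n_ca, n_pp, volume)
        other_events = [(t, k) for t, k in protocol.events if k != "chelate_Ca"]
        barriers = sorted(
            [(t, "chelate") for t in chel_times]
            + [(t, k) for t, k in other_events]
            + [(engine_cfg.t_end, "end")]
        )
        t = 0.0
        rec_i = 0
        frames = np.empty((len(times), len(NINE_STATE_COLUMNS)))

        def record_upto(t_incl):
            nonlocal rec_i
            while rec_i < len(times) and times[rec_i] <= t_incl + 1e-12:
                frames[rec_i] = sys.counts()
                if engine_cfg.validate_frames:
                    sys.check_invariants()
                rec_i += 1

        record_upto(0.0)
        for t_b, act in barriers:
            while True:
                channels = _build_channels(sys)
                total = sum(a for a, _ in channels)
                if total <= 0:
                    t = t_b
                    break
                tau = rng.exponential(1.0 / total)
                if t + tau >= t_b:
                    t = t_b
                    break
                t += tau
                record_upto(t - 1e-9)
                u = rng.random() * total
                acc = 0.0
                chosen = channels[-1][1]
                for a, action in channels:
                    acc += a
                    if u < acc:
                        chosen = action
                        break
                _apply_nine(sys, chosen)
            if act == "end":
                break
            record_upto(t - 1e-9)
            if act == "chelate":
                # one-time removal of the free pool; Ca2+ already on CaM
                # lobes stays until it dissociates (total Ca2+ is conserved
                # between chelation events, not across them)
                sys.total_ca -= sys.free_ca
                sys.free_ca = 0
            elif act == "kinase_inhibitor":
                # blocking the catalytic site: no further autophosphorylation
                sys.model = NineStateModel(
                    rates9=_zero_autophos(model.rates9),
                    base=model.base,
                    exclusion=model.exclusion,
                )
            elif act == "phosphatase_inhibitor":
                sys.k_cat_enabled = False
            record_upto(t)
        record_upto(engine_cfg.t_end)
        data[r] = frames
        finals.append({"cam_idx": sys.cam_idx.copy(), "t286": sys.t286.copy()})
    return TrajectoryEnsemble(
        times=times,
        data=data,
        columns=NINE_STATE_COLUMNS,
        seeds=seeds,
        scheme="ssa",
        volume=volume,
        n_sub=n_holo * SUBUNITS_PER_HOLOENZYME,
        final_states=finals,
        config_fingerprint="",
    )


def _zero_autophos(r9: NineStateRates) -> NineStateRates:
    from dataclasses import replace

    return replace(r9, autophos_rate=0.0)
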