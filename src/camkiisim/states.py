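"""Subunit state flags, holoenzyme topology and state-space enumeration.

A CaMKII subunit is described by five flags:

* ``docking`` -- compact against the central hub (CaM-inaccessible) or
  extended/undocked (CaM-accessible);
* ``conformation`` -- autoinhibited (inactive) or catalytically open (active);
* ``cam`` -- no CaM bound, CaM initially bound (low-affinity contact on the
  regulatory domain) or CaM fully bound (complete wrap, active-only);
* ``t286`` -- Thr-286 unphosphorylated, phosphorylated, or occupied by a bound
  protein phosphatase;
* ``t306`` -- Thr-306 unphosphorylated or phosphorylated (blocks CaM binding).

An additional boolean overlay marks subunits bound by the kinase inhibitor
K252a.  The holoenzyme is two radially symmetric rings of six subunits each;
autophosphorylation of Thr-286 is a neighbour-directed reaction whose directed
kinase->substrate adjacency depends on the configured number of degrees of
freedom (DOF).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

SUBUNITS_PER_RING = 6
RINGS_PER_HOLOENZYME = 2
SUBUNITS_PER_HOLOENZYME = SUBUNITS_PER_RING * RINGS_PER_HOLOENZYME


class Docking(IntEnum):
    DOCKED = 0
    UNDOCKED = 1


class Conformation(IntEnum):
    INACTIVE = 0
    ACTIVE = 1


class CamState(IntEnum):
    UNBOUND = 0
    INITIAL = 1
    FULL = 2


class T286(IntEnum):
    UNPHOS = 0
    PHOS = 1
    PP_BOUND = 2


class T306(IntEnum):
    UNPHOS = 0
    PHOS = 1


class ConfigurationError(ValueError):
    """Raised for invalid model configuration (bad DOF, empty system, ...)."""


@dataclass(frozen=True)
class SubunitState:
    """Immutable snapshot of one CaMKII subunit's flags."""

    docking: Docking = Docking.DOCKED
    conformation: Conformation = Conformation.INACTIVE
    cam: CamState = CamState.UNBOUND
    t286: T286 = T286.UNPHOS
    t306: T306 = T306.UNPHOS
    inhibitor_bound: bool = False

    def invariant_violations(self, exclusive: bool = False) -> list[str]:
        """Return human-readable descriptions of violated state invariants.

        The core invariants are: a docked subunit cannot hold CaM, a
        pThr-306 subunit cannot hold CaM, and a fully CaM-bound subunit must
        be in the active conformation.  Under the exclusive binding variant a
        phosphatase-occupied subunit additionally cannot hold CaM.
        """
        bad = []
        if self.docking == Docking.DOCKED and self.cam != CamState.UNBOUND:
            bad.append("docked subunit holds CaM")
        if self.t306 == T306.PHOS and self.cam != CamState.UNBOUND:
            bad.append("pThr-306 subunit holds CaM")
        if self.cam == CamState.FULL and self.conformation != Conformation.ACTIVE:
            bad.append("fully CaM-bound subunit is inactive")
        if exclusive and self.t286 == T286.PP_BOUND and self.cam != CamState.UNBOUND:
            bad.append("PP-bound subunit holds CaM (exclusive variant)")
        return bad

    def is_valid(self, exclusive: bool = False) -> bool:
        return not self.invariant_violations(exclusive)

    def with_(self, **changes) -> "SubunitState":
        return replace(self, **changes)


def per_subunit_state_count(constrained: bool) -> int:
    """Number of distinct per-subunit flag combinations.

    Unconstrained this is the plain product of flag cardinalities,
    2 x 2 x 3 x 3 x 2 = 72.  With the three structural invariants (docked or
    pThr-306 implies CaM-unbound; fully bound implies active) exhaustive
    enumeration leaves 33 states.  The inhibitor overlay is not counted.
    """
    if not constrained:
        return len(Docking) * len(Conformation) * len(CamState) * len(T286) * len(T306)
    n = 0
    for d, c, m, p6, p3 in itertools.product(Docking, Conformation, CamState, T286, T306):
        if SubunitState(d, c, m, p6, p3).is_valid(exclusive=False):
            n += 1
    return n


def _edges_for_holoenzyme(dof: int) -> list[tuple[int, int]]:
    """Directed (substrate, kinase) index pairs within one holoenzyme.

    Indexing convention: subunit ``ring * 6 + pos`` with positions 0-5
    ordered counter-clockwise.  The counter-clockwise kinase of substrate
    ``pos`` is ``(pos + 1) % 6``; DOF 2 adds the clockwise neighbour
    ``(pos - 1) % 6``; DOF 3 additionally pairs each subunit with the directly
    apposed subunit at the same position in the other ring (both directions).
    """
    edges: list[tuple[int, int]] = []
    for ring in range(RINGS_PER_HOLOENZYME):
        base = ring * SUBUNITS_PER_RING
        for pos in range(SUBUNITS_PER_RING):
            sub = base + pos
            edges.append((sub, base + (pos + 1) % SUBUNITS_PER_RING))
            if dof >= 2:
                edges.append((sub, base + (pos - 1) % SUBUNITS_PER_RING))
            if dof >= 3:
                other = (1 - ring) * SUBUNITS_PER_RING + pos
                edges.append((sub, other))
    return edges


def kinase_edges(n_holo: int, dof: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed kinase->substrate adjacency for ``n_holo`` holoenzymes.

    Returns ``(substrate_idx, kinase_idx, trans_ring)`` arrays over global
    subunit indices.  Edge count is 12, 24 or 36 per holoenzyme for DOF 1, 2
    and 3 respectively.
    """
    if dof not in (1, 2, 3):
        raise ConfigurationError(f"dof must be 1, 2 or 3, got {dof!r}")
    per_holo = _edges_for_holoenzyme(dof)
    sub, kin, trans = [], [], []
    for h in range(n_holo):
        off = h * SUBUNITS_PER_HOLOENZYME
        for s, k in per_holo:
            sub.append(off + s)
            kin.append(off + k)
            trans.append((s // SUBUNITS_PER_RING) != (k // SUBUNITS_PER_RING))
    return (
        np.asarray(sub, dtype=np.int64),
        np.asarray(kin, dtype=np.int64),
        np.asarray(trans, dtype=bool),
    )


@dataclass
class Holoenzyme:
    """Twelve subunits in two rings plus the directed kinase adjacency."""

    subunits: list[SubunitState] = field(
        default_factory=lambda: [SubunitState() for _ in range(SUBUNITS_PER_HOLOENZYME)]
    )
    dof: int = 1

    def __post_init__(self):
        if len(self.subunits) != SUBUNITS_PER_HOLOENZYME:
            raise ConfigurationError(
                f"holoenzyme needs {SUBUNITS_PER_HOLOENZYME} subunits, "
                f"got {len(self.subunits)}"
            )
        if self.dof not in (1, 2, 3):
            raise ConfigurationError(f"dof must be 1, 2 or 3, got {self.dof!r}")

    @property
    def kinase_map(self) -> list[tuple[int, int]]:
        """Directed (substrate, kinase) pairs for this holoenzyme."""
        return _edges_for_holoenzyme(self.dof)

    def ring(self, which: int) -> list[SubunitState]:
        base = which * SUBUNITS_PER_RING
        return self.subunits[base : base + SUBUNITS_PER_RING]


def build_holoenzyme(n_holo: int, dof: int) -> list[Holoenzyme]:
    """Create ``n_holo`` holoenzymes of all-docked, inactive, unmodified subunits."""
    if n_holo < 1:
        raise ConfigurationError(f"n_holo must be >= 1, got {n_holo}")
    if dof not in (1, 2, 3):
        raise ConfigurationError(f"dof must be 1, 2 or 3, got {dof!r}")
    return [Holoenzyme(dof=dof) for _ in range(n_holo)]
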