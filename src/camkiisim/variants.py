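"""Model variants: binding exclusivity, autophosphorylation degrees of
freedom, and access to the nine-state CaM model."""

from __future__ import annotations

from dataclasses import replace

from camkiisim.ninestate import (  # noqa: F401  (re-exported variant builder)
    NineStateRates,
    build_nine_state_model,
)
from camkiisim.rules import Rule
from camkiisim.states import Holoenzyme


def set_exclusivity(rules: list[Rule], mode: str) -> list[Rule]:
    """Return a rule set with the CaM/PP steric-exclusion clauses set.

    The exclusive and non-exclusive variants differ in exactly two guard
    clauses: phosphatase binding requires the subunit to be CaM-unbound, and
    initial CaM binding requires the subunit not to be phosphatase-occupied,
    only in the exclusive model.  Everything else is untouched.  Variants are
    static: changing mode mid-simulation is not supported.
    """
    if mode not in ("exclusive", "non_exclusive"):
        raise ValueError(f"mode must be 'exclusive' or 'non_exclusive', got {mode!r}")
    out = []
    for r in rules:
        if r.name == "pp_bind":
            guard = [c for c in r.guard if c != "cam_unbound"]
            if mode == "exclusive":
                guard.append("cam_unbound")
            out.append(replace(r, guard=tuple(guard)))
        elif r.name == "cam_bind_initial":
            guard = [c for c in r.guard if c != "t286_not_pp_bound"]
            if mode == "exclusive":
                guard.append("t286_not_pp_bound")
            out.append(replace(r, guard=tuple(guard)))
        else:
            out.append(r)
    return out


def set_dof(holo: Holoenzyme, dof: int) -> Holoenzyme:
    """Rebuild a holoenzyme's directed kinase map for a new DOF setting.

    DOF 1: counter-clockwise intra-ring neighbour only; DOF 2: both
    intra-ring directions; DOF 3: additionally the directly apposed subunit
    in the other ring.
    """
    if dof not in (1, 2, 3):
        raise ValueError(f"dof must be 1, 2 or 3, got {dof!r}")
    return Holoenzyme(subunits=list(holo.subunits), dof=dof)
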