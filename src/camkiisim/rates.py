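"""Kinetic constants, free-ligand pools and stochastic unit conversions.

All macroscopic association constants are in M^-1 s^-1 and are converted to
per-pair stochastic propensities by dividing by (Avogadro x volume).  The
default compartment is the 0.0328 fL cube in which 1.52 uM CaMKII corresponds
to 30 holoenzymes (360 subunits), 22.8 uM CaM to 450 molecules and 0.86 uM
phosphatase to 17 molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

AVOGADRO = 6.02214076e23

#: Default compartment volume in liters (a 0.32 um cube).
DEFAULT_VOLUME_L = 0.0328e-15


class RateError(ValueError):
    """Raised for negative or otherwise unusable kinetic parameters."""


def bimolecular_propensity(k_on: float, volume: float) -> float:
    """Per-pair stochastic rate (s^-1) for a bimolecular association.

    ``k_on`` is the macroscopic association constant in M^-1 s^-1; in a
    well-mixed compartment of ``volume`` liters a single reactant pair
    collides productively at ``k_on / (N_A * V)`` per second.
    """
    if k_on < 0:
        raise RateError(f"k_on must be >= 0, got {k_on}")
    if volume <= 0:
        raise RateError(f"volume must be > 0, got {volume}")
    return k_on / (AVOGADRO * volume)


def concentration_to_count(conc: float, volume: float) -> int:
    """Nearest integer molecule count for a molar concentration."""
    if conc < 0:
        raise RateError(f"concentration must be >= 0, got {conc}")
    if volume <= 0:
        raise RateError(f"volume must be > 0, got {volume}")
    return round(conc * AVOGADRO * volume)


def count_to_concentration(count: float, volume: float) -> float:
    """Molar concentration of ``count`` molecules in ``volume`` liters."""
    if volume <= 0:
        raise RateError(f"volume must be > 0, got {volume}")
    return count / (AVOGADRO * volume)


@dataclass
class RateTable:
    """All kinetic constants plus the static variant switches.

    Rates (s^-1 unless noted):

    * ``k_dock`` / ``k_undock`` -- hub docking and undocking; their ratio is
      the docking equilibrium constant 0.018 inferred from the 50-fold gap
      between CaM binding to free peptide and to full-length kinase.
    * ``k_activate`` / ``k_inactivate`` -- the conformational flicker; the
      stationary open probability is ~0.002.
    * ``k_on_CaM`` (M^-1 s^-1) / ``k_off_CaM_ini`` -- initial CaM contact.
    * ``k_ini_to_full`` / ``k_full_to_ini`` -- CaM compaction to the
      high-affinity fully-wrapped state and its (slow) reversal.
    * ``k_autophos`` -- Thr-286 trans-autophosphorylation per directed edge.
    * ``k_phos_T306`` -- Thr-306 autophosphorylation, 50-fold slower.
    * ``k_on_PP`` (M^-1 s^-1) / ``k_off_PP`` / ``k_cat_PP`` -- phosphatase
      binding, release, and catalytic dephosphorylation (Michaelis constant
      (k_off + k_cat)/k_on = 8.3e-7 M).

    Variant switches: ``exclusivity`` selects whether bound CaM and bound PP
    sterically exclude each other; ``dof`` the number of directed kinase
    neighbours per subunit; ``kon_PP_scale`` a multiplier on ``k_on_PP`` for
    sensitivity scans.
    """

    k_dock: float = 35.0
    k_undock: float = 0.63
    k_activate: float = 2.0e4
    k_inactivate: float = 1.0e7
    k_on_CaM: float = 1.0e8
    k_off_CaM_ini: float = 590.0
    k_ini_to_full: float = 350.0
    k_full_to_ini: float = 4.0e-3
    k_autophos: float = 1.0
    k_phos_T306: float = 0.02
    k_on_PP: float = 3.0e6
    k_off_PP: float = 0.5
    k_cat_PP: float = 2.0
    exclusivity: str = "exclusive"
    dof: int = 1
    kon_PP_scale: float = 1.0
    # Behavioural toggles for ambiguous rule readings (defaults follow the
    # literal flag semantics; see docs/methods.md).
    pp_bound_counts_as_phospho: bool = False
    dock_requires_inactive: bool = False
    k252a_blocks_kinase_role: bool = True

    def __post_init__(self):
        for name in (
            "k_dock", "k_undock", "k_activate", "k_inactivate", "k_on_CaM",
            "k_off_CaM_ini", "k_ini_to_full", "k_full_to_ini", "k_autophos",
            "k_phos_T306", "k_on_PP", "k_off_PP", "k_cat_PP",
        ):
            v = getattr(self, name)
            if v < 0:
                raise RateError(f"{name} must be >= 0, got {v}")
        if self.kon_PP_scale <= 0:
            raise RateError(f"kon_PP_scale must be > 0, got {self.kon_PP_scale}")
        if self.exclusivity not in ("exclusive", "non_exclusive"):
            raise RateError(
                f"exclusivity must be 'exclusive' or 'non_exclusive', "
                f"got {self.exclusivity!r}"
            )
        if self.dof not in (1, 2, 3):
            raise RateError(f"dof must be 1, 2 or 3, got {self.dof!r}")

    @property
    def exclusive(self) -> bool:
        return self.exclusivity == "exclusive"

    @property
    def p_act(self) -> float:
        """Stationary open probability of the conformational flicker."""
        return self.k_activate / (self.k_activate + self.k_inactivate)

    @property
    def K_docking(self) -> float:
        """Docking equilibrium constant k_undock / k_dock."""
        return self.k_undock / self.k_dock

    @property
    def K_M_PP(self) -> float:
        """Michaelis constant of the phosphatase, (k_off + k_cat)/k_on, in M."""
        return (self.k_off_PP + self.k_cat_PP) / self.k_on_PP

    def effective_k_on_PP(self) -> float:
        return self.k_on_PP * self.kon_PP_scale

    def with_(self, **changes) -> "RateTable":
        return replace(self, **changes)


@dataclass
class Pools:
    """Free-ligand counts in the shared compartment.

    Total CaM (free apo + free CaM4 + subunit-bound) and total PP (free +
    subunit-bound) are conserved over any trajectory; the engines assert this
    at every recorded frame.
    """

    free_apo_cam: int = 450
    free_cam4: int = 0
    free_pp: int = 17
    free_k252a: int = 0
    volume: float = DEFAULT_VOLUME_L

    def __post_init__(self):
        for name in ("free_apo_cam", "free_cam4", "free_pp", "free_k252a"):
            if getattr(self, name) < 0:
                raise RateError(f"{name} must be >= 0")
        if self.volume <= 0:
            raise RateError(f"volume must be > 0, got {self.volume}")

    @property
    def total_free_cam(self) -> int:
        return self.free_apo_cam + self.free_cam4

    def copy(self) -> "Pools":
        return replace(self)
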