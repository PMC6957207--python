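"""Ca2+/CaM forcing protocols and timed interventions.

Free CaM is driven between its apo and fully Ca2+-loaded (CaM4) forms by a
pair of square-wave forcing functions standing in for Ca2+ flux: during an
"activating" phase all free CaM is CaM4, during an "inactivating" phase all
free CaM is apo.  Because the nominal conversion rate (1e8 s^-1) exceeds every
other rate in the model by at least five orders of magnitude, the conversion
is applied deterministically at phase boundaries.  CaM bound to a subunit is
untouched; a CaM released during an inactivating phase joins the apo pool.

Timed interventions: a saturating dose of the kinase inhibitor K252a (flags
every subunit as inhibitor-bound), a phosphatase inhibitor (zeroes the
catalytic rate while preserving binding), and Ca2+ chelation for the
nine-state CaM variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from camkiisim.rates import Pools

ACTIVATING = "activating"
INACTIVATING = "inactivating"

EVENT_KINDS = ("kinase_inhibitor", "phosphatase_inhibitor", "chelate_Ca")


class ProtocolError(ValueError):
    """Raised for ill-formed stimulus protocols."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Square-wave Ca2+/CaM forcing plus timed intervention events.

    ``mode``:

    * ``continuous_bolus`` -- CaM4 available for the whole run;
    * ``pulse_train`` -- pulses of ``pulse_width`` seconds at ``frequency``
      Hz, the first pulse starting at t = 0;
    * ``finite_bolus`` -- CaM4 available on [0, ``bolus_duration``) only;
    * ``none`` -- free CaM stays apo throughout.

    ``events`` is a list of ``(time, kind)`` pairs with ``kind`` one of
    ``kinase_inhibitor``, ``phosphatase_inhibitor`` or ``chelate_Ca``.
    """

    mode: str = "continuous_bolus"
    frequency: float | None = None
    pulse_width: float = 0.01
    bolus_duration: float | None = None
    events: tuple[tuple[float, str], ...] = ()

    def __post_init__(self):
        if self.mode not in ("continuous_bolus", "pulse_train", "finite_bolus", "none"):
            raise ProtocolError(f"unknown stimulus mode {self.mode!r}")
        if self.mode == "pulse_train":
            if self.frequency is None or self.frequency <= 0:
                raise ProtocolError("pulse_train requires frequency > 0")
            if self.pulse_width <= 0:
                raise ProtocolError("pulse_width must be > 0")
            if self.pulse_width > 1.0 / self.frequency:
                raise ProtocolError(
                    f"pulse_width {self.pulse_width} exceeds the pulse period "
                    f"{1.0 / self.frequency}"
                )
        if self.mode == "finite_bolus":
            if self.bolus_duration is None or self.bolus_duration <= 0:
                raise ProtocolError("finite_bolus requires bolus_duration > 0")
        for t, kind in self.events:
            if t < 0:
                raise ProtocolError(f"event time must be >= 0, got {t}")
            if kind not in EVENT_KINDS:
                raise ProtocolError(f"unknown event kind {kind!r}")

    def with_events(self, events) -> "StimulusProtocol":
        return replace(self, events=tuple(events))


def forcing_phase(t: float, protocol: StimulusProtocol) -> str:
    """Forcing phase ("activating" or "inactivating") at time ``t``.

    For a pulse train the activating windows are [k/f, k/f + width) for
    k = 0, 1, 2, ...; a continuous bolus is always activating; a finite bolus
    is activating while t < bolus_duration.
    """
    if t < 0:
        raise ProtocolError(f"t must be >= 0, got {t}")
    if protocol.mode == "continuous_bolus":
        return ACTIVATING
    if protocol.mode == "none":
        return INACTIVATING
    if protocol.mode == "finite_bolus":
        return ACTIVATING if t < protocol.bolus_duration else INACTIVATING
    period = 1.0 / protocol.frequency
    # position within the current pulse period; guard the edge where
    # floating-point division lands exactly on a pulse onset
    k = math.floor(t / period)
    offset = t - k * period
    if period - offset < 1e-12:
        offset = 0.0
    return ACTIVATING if offset < protocol.pulse_width else INACTIVATING


def phase_boundaries(protocol: StimulusProtocol, t_end: float) -> list[tuple[float, str]]:
    """Sorted (time, phase-entered) changepoints on (0, t_end).

    The phase at t = 0 is ``forcing_phase(0, protocol)``; the returned list
    holds every subsequent switch strictly before ``t_end``.
    """
    out: list[tuple[float, str]] = []
    if protocol.mode in ("continuous_bolus", "none"):
        return out
    if protocol.mode == "finite_bolus":
        if protocol.bolus_duration < t_end:
            out.append((protocol.bolus_duration, INACTIVATING))
        return out
    period = 1.0 / protocol.frequency
    k = 0
    while True:
        onset = k * period
        off = onset + protocol.pulse_width
        if off < t_end and protocol.pulse_width < period:
            out.append((off, INACTIVATING))
        nxt = (k + 1) * period
        if nxt >= t_end:
            break
        if protocol.pulse_width < period:
            out.append((nxt, ACTIVATING))
        k += 1
    return sorted(out)


def apply_forcing(pools: Pools, phase: str) -> Pools:
    """Convert the free CaM pool to match the forcing phase.

    Activating: all free apo-CaM becomes CaM4.  Inactivating: all free CaM4
    becomes apo.  Bound CaM is untouched.
    """
    if phase == ACTIVATING:
        return replace(
            pools,
            free_cam4=pools.free_cam4 + pools.free_apo_cam,
            free_apo_cam=0,
        )
    if phase == INACTIVATING:
        return replace(
            pools,
            free_apo_cam=pools.free_apo_cam + pools.free_cam4,
            free_cam4=0,
        )
    raise ProtocolError(f"unknown phase {phase!r}")


def apply_event(state, kind: str, t: float = 0.0):
    """Apply a timed intervention to a live system state, in place.

    ``kinase_inhibitor`` flags every subunit as inhibitor-bound (saturating
    dose); ``phosphatase_inhibitor`` zeroes the catalytic rate while leaving
    binding untouched; ``chelate_Ca`` is a no-op with a warning in the
    two-state model (free Ca2+ is only modelled explicitly in the nine-state
    variant).  The engines apply scheduled events through the same code at
    their exact times; this entry point exists for interactive use.
    """
    if kind not in EVENT_KINDS:
        raise ProtocolError(f"unknown event kind {kind!r}")
    from camkiisim.engines import _apply_action  # deferred: engines imports us

    _apply_action(state, "event", kind)
    return state


# ---------------------------------------------------------------------------
# Canonical protocol presets

def bolus_continuous() -> StimulusProtocol:
    return StimulusProtocol(mode="continuous_bolus")


def pulse_train(frequency: float, pulse_width: float = 0.01) -> StimulusProtocol:
    return StimulusProtocol(mode="pulse_train", frequency=frequency, pulse_width=pulse_width)


def finite_bolus(duration: float) -> StimulusProtocol:
    return StimulusProtocol(mode="finite_bolus", bolus_duration=duration)


def bolus_with_inhibitor(kind: str, t_event: float = 30.0, duration: float = 2.0) -> StimulusProtocol:
    """2 s CaM4 bolus followed by a timed kinase or phosphatase inhibitor."""
    return StimulusProtocol(
        mode="finite_bolus",
        bolus_duration=duration,
        events=((t_event, kind),),
    )
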