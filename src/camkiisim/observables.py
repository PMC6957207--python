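"""Derived quantities: flag censuses, ensemble statistics, decay and
frequency-response fits, and consecutive-pThr-286 run statistics.

Counts convert to molar concentration through the compartment volume
(count / (N_A * V)); for the standard 0.0328 fL compartment one subunit is
~0.0506 uM, so 360 subunits are the printed 18.24 uM total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from camkiisim.rates import count_to_concentration
from camkiisim.states import (
    Holoenzyme,
    SUBUNITS_PER_RING,
    T286,
)


@dataclass(frozen=True)
class FlagCounts:
    """Census of subunit flags at one instant."""

    n_active: float
    n_cam_initial: int
    n_cam_full: int
    n_pT286: int
    n_PP_bound: int
    n_pT306: int
    n_docked: int

    def concentration(self, field: str, volume: float) -> float:
        """Molar concentration of one census field."""
        return count_to_concentration(getattr(self, field), volume)


def count_flags(state, count_pp_bound_as_pT286: bool = False) -> FlagCounts:
    """Exact flag census of a :class:`~camkiisim.engines.SystemState`.

    ``n_active`` is the conformation-flag count under the exact engines and
    the conditional expectation under the QSSA.  By default the pThr-286
    census reads the flag literally, so a phosphatase-occupied subunit is
    counted as PP-bound, not as pThr-286; ``count_pp_bound_as_pT286``
    switches to the chemical reading (the site is still phosphorylated while
    the phosphatase sits on it).
    """
    n_p = int((state.t286 == 1).sum())
    n_b = int((state.t286 == 2).sum())
    if state._marginalized_conf:
        n_stab = int(state.stabilized().sum())
        active = n_stab + state.rates.p_act * (state.n_sub - n_stab)
    else:
        active = float(state.conf.sum())
    return FlagCounts(
        n_active=active,
        n_cam_initial=int((state.cam == 1).sum()),
        n_cam_full=int((state.cam == 2).sum()),
        n_pT286=n_p + n_b if count_pp_bound_as_pT286 else n_p,
        n_PP_bound=n_b,
        n_pT306=int(state.t306.sum()),
        n_docked=int(state.docked.sum()),
    )


def ensemble_stats(ensemble, name: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Pointwise ensemble mean and standard error for one observable.

    SEM is the sample standard deviation over replicates divided by sqrt(N);
    with a single replicate it is reported as ``None``.
    """
    mean = ensemble.mean(name)
    sem = ensemble.sem(name)
    return mean, sem


def fit_decay_constant(
    times: np.ndarray,
    trace: np.ndarray,
    window: tuple[float, float] = (5.0, 120.0),
) -> float:
    """Exponential decay constant of a positive trace over a time window.

    Least-squares slope of ln(trace) versus time on [t0, t1]; the signed
    result is the rate constant in s^-1 (negative for decay, ~0 for a stable
    trace).  The window must follow the peak: nonpositive values inside it
    are an error.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"window must satisfy t1 > t0, got {window}")
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    mask = (times >= t0) & (times <= t1)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than two samples")
    y = trace[mask]
    if np.any(y <= 0):
        raise ValueError("trace must be strictly positive on the fit window")
    slope, _ = np.polyfit(times[mask], np.log(y), 1)
    return float(slope)


def frequency_response(
    endpoints: dict[float, float],
) -> tuple[float, float, float]:
    """Ordinary least-squares line through endpoint response vs frequency.

    Returns ``(slope, intercept, r_squared)``.  Needs at least three
    frequencies.  If all responses are identical the variance is degenerate
    and (0, response, 0) is returned.
    """
    if len(endpoints) < 3:
        raise ValueError("frequency_response needs at least 3 frequencies")
    freqs = np.array(sorted(endpoints))
    vals = np.array([endpoints[f] for f in freqs], dtype=float)
    if np.allclose(vals, vals[0]):
        return 0.0, float(vals[0]), 0.0
    res = stats.linregress(freqs, vals)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _cyclic_runs(flags: np.ndarray) -> list[int]:
    """Maximal runs of consecutive True values around a cyclic ring."""
    n = len(flags)
    if flags.all():
        return [n]
    if not flags.any():
        return []
    # rotate so position 0 is False, then scan linearly
    start = int(np.flatnonzero(~flags)[0])
    rolled = np.roll(flags, -start)
    runs = []
    count = 0
    for v in rolled:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def pT286_run_lengths(holo) -> list[list[int]]:
    """Per-ring maximal cyclic runs of phosphorylated subunits.

    A subunit counts as phosphorylated when its Thr-286 flag is pThr-286 or
    PP-bound (the site stays phosphorylated under a bound phosphatase).
    Accepts a :class:`~camkiisim.states.Holoenzyme` or a length-12 array of
    t286 flag codes.  A fully phosphorylated ring reports run length 6.
    """
    if isinstance(holo, Holoenzyme):
        codes = np.array([int(s.t286) for s in holo.subunits], dtype=np.int8)
    else:
        codes = np.asarray(holo, dtype=np.int8)
    if codes.shape != (2 * SUBUNITS_PER_RING,):
        raise ValueError("expected 12 subunit t286 codes")
    phos = (codes == int(T286.PHOS)) | (codes == int(T286.PP_BOUND))
    return [
        _cyclic_runs(phos[:SUBUNITS_PER_RING]),
        _cyclic_runs(phos[SUBUNITS_PER_RING:]),
    ]


def mean_run_length(ensemble) -> float:
    """Mean maximal consecutive-pThr-286 run length over final states.

    Rings with no phosphorylated subunit contribute nothing; an ensemble in
    which nothing phosphorylated returns 0.
    """
    runs: list[int] = []
    for snap in ensemble.final_states:
        codes = snap["t286"]
        for h in range(len(codes) // 12):
            for ring in pT286_run_lengths(codes[h * 12 : (h + 1) * 12]):
                runs.extend(ring)
    return float(np.mean(runs)) if runs else 0.0


def endpoint_value(ensemble, name: str, t: float | None = None) -> float:
    """Ensemble-mean observable at time ``t`` (default: the final frame)."""
    mean = ensemble.mean(name)
    if t is None:
        return float(mean[-1])
    idx = int(np.argmin(np.abs(ensemble.times - t)))
    return float(mean[idx])
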