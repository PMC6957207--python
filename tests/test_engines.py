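"""Engine behaviour: determinism, conservation, inhibitor semantics and the
fixed-step contract."""

import numpy as np
import pytest

from camkiisim.engines import (
    CH_EDGE,
    EngineConfig,
    EngineError,
    ModelConfig,
    SystemState,
    _JumpEngine,
    build_propensities,
    run_replicates,
    simulate_state,
)
from camkiisim.rates import Pools, RateTable
from camkiisim.states import ConfigurationError
from camkiisim.stimulus import StimulusProtocol, pulse_train


def small_model(rates=None, cam4=30, pp=3, n_holo=1):
    return ModelConfig(
        n_holo=n_holo,
        rates=rates if rates is not None else RateTable(),
        pools=Pools(free_apo_cam=0, free_cam4=cam4, free_pp=pp),
    )


class TestDeterminism:
    def test_same_seed_identical_ensemble(self):
        model = small_model()
        cfg = EngineConfig(scheme="qssa", t_end=1.0, n_replicates=3, seed=42)
        a = run_replicates(model, cfg, StimulusProtocol(mode="continuous_bolus"))
        b = run_replicates(model, cfg, StimulusProtocol(mode="continuous_bolus"))
        assert np.array_equal(a.data, b.data)
        assert a.seeds == b.seeds == (42, 43, 44)

    def test_replicates_differ(self):
        model = small_model()
        cfg = EngineConfig(scheme="qssa", t_end=2.0, n_replicates=2, seed=7)
        ens = run_replicates(model, cfg, StimulusProtocol(mode="continuous_bolus"))
        assert not np.array_equal(ens.data[0], ens.data[1])


class TestDegenerateSystems:
    def test_zero_rates_freeze_the_state(self):
        """With every rule rate zero the state at t_end equals the state at
        time zero (and QSSA open probability is zero)."""
        rates = RateTable(
            k_dock=0, k_undock=0, k_activate=0, k_inactivate=1e7,
            k_on_CaM=0, k_off_CaM_ini=0, k_ini_to_full=0, k_full_to_ini=0,
            k_autophos=0, k_phos_T306=0, k_on_PP=0, k_off_PP=0, k_cat_PP=0,
        )
        model = small_model(rates)
        cfg = EngineConfig(scheme="qssa", t_end=1.0, n_replicates=1, seed=0)
        ens = run_replicates(model, cfg, StimulusProtocol(mode="continuous_bolus"))
        assert np.array_equal(ens.data[0, 0], ens.data[0, -1])
        assert ens.mean("docked")[-1] == 12

    def test_no_cam_no_autophosphorylation(self):
        """Without CaM, unassisted autophosphorylation needs two simultaneous
        spontaneous activations (p ~ 0.002 each): over 20 s fewer than 1% of
        subunits ever reach pThr-286."""
        model = ModelConfig(
            n_holo=30, rates=RateTable(),
            pools=Pools(free_apo_cam=0, free_cam4=0, free_pp=17),
        )
        cfg = EngineConfig(scheme="qssa", t_end=20.0, n_replicates=2, seed=3)
        ens = run_replicates(model, cfg, StimulusProtocol(mode="none"))
        frac = (ens.column("pT286") + ens.column("pp_bound")).max() / 360
        assert frac < 0.01


class TestConservationAndInvariants:
    def test_bolus_run_conserves_cam_and_pp(self):
        model = small_model(cam4=30, pp=3, n_holo=2)
        cfg = EngineConfig(scheme="qssa", t_end=3.0, n_replicates=1, seed=5)
        ens = run_replicates(model, cfg, pulse_train(10.0))
        cam_total = (
            ens.column("free_apo_cam") + ens.column("free_cam4")
            + ens.column("cam_initial") + ens.column("cam_full")
        )
        assert np.all(cam_total == 30)
        pp_total = ens.column("free_pp") + ens.column("pp_bound")
        assert np.all(pp_total == 3)

    def test_frame_validation_runs_every_frame(self):
        # validate_frames=True raises on any invariant breach; completing a
        # run with PP and pulses exercises every rule class
        model = small_model(cam4=40, pp=5, n_holo=2)
        cfg = EngineConfig(
            scheme="qssa", t_end=4.0, n_replicates=1, seed=11,
            validate_frames=True,
        )
        run_replicates(model, cfg, pulse_train(5.0))

    def test_cumulative_phosphate_monotone_without_catalysis(self):
        """With k_cat_PP = 0 the phosphate count #pT286 + #PP_bound can
        never decrease."""
        model = small_model(RateTable(k_cat_PP=0.0), cam4=40, pp=5, n_holo=2)
        cfg = EngineConfig(scheme="qssa", t_end=8.0, n_replicates=2, seed=9)
        ens = run_replicates(model, cfg, StimulusProtocol(mode="continuous_bolus"))
        phos = ens.column("pT286") + ens.column("pp_bound")
        assert np.all(np.diff(phos, axis=1) >= 0)


class TestInhibitorEvents:
    def test_kinase_inhibitor_stops_phosphorylation(self):
        model = small_model(cam4=60, pp=2, n_holo=3)
        proto = StimulusProtocol(
            mode="continuous_bolus", events=((3.0, "kinase_inhibitor"),)
        )
        cfg = EngineConfig(scheme="qssa", t_end=8.0, n_replicates=2, seed=21)
        ens = run_replicates(model, cfg, proto)
        phos = ens.column("pT286") + ens.column("pp_bound")
        after = phos[:, ens.times >= 3.0]
        assert np.all(np.diff(after, axis=1) <= 0)

    def test_phosphatase_inhibitor_preserves_binding_but_not_catalysis(self):
        model = small_model(cam4=60, pp=5, n_holo=3)
        proto = StimulusProtocol(
            mode="continuous_bolus", events=((2.0, "phosphatase_inhibitor"),)
        )
        cfg = EngineConfig(scheme="qssa", t_end=8.0, n_replicates=2, seed=22)
        ens = run_replicates(model, cfg, proto)
        phos = ens.column("pT286") + ens.column("pp_bound")
        after = phos[:, ens.times >= 2.0]
        assert np.all(np.diff(after, axis=1) >= 0)

    def test_chelation_warns_in_two_state_model(self):
        model = small_model()
        proto = StimulusProtocol(mode="none", events=((0.5, "chelate_Ca"),))
        cfg = EngineConfig(scheme="qssa", t_end=1.0, n_replicates=1, seed=1)
        with pytest.warns(UserWarning, match="chelate_Ca"):
            run_replicates(model, cfg, proto)


class TestFixedStep:
    def test_refuses_coarse_dt_with_stiff_flicker(self):
        """k = 1e7 s^-1 at dt = 1e-7 s gives p ~ 0.63 > 0.1: refused."""
        model = small_model()
        cfg = EngineConfig(
            scheme="fixed_step", dt=1e-7, t_end=1e-5, record_interval=1e-5,
            n_replicates=1, seed=0,
        )
        with pytest.raises(EngineError, match="> 0.1"):
            run_replicates(model, cfg, StimulusProtocol(mode="none"))

    def test_accepts_fine_dt(self, tame_rates):
        model = small_model(tame_rates, cam4=5, pp=0)
        cfg = EngineConfig(
            scheme="fixed_step", dt=1e-6, t_end=1e-3, record_interval=1e-3,
            n_replicates=1, seed=0,
        )
        ens = run_replicates(model, cfg, StimulusProtocol(mode="continuous_bolus"))
        assert ens.data.shape[1] == 2

    def test_bernoulli_probability_formula(self):
        # p = 1 - exp(-a dt) for the documented example values
        assert 1 - np.exp(-590.0 * 1e-7) == pytest.approx(5.9e-5, rel=1e-3)
        assert 1 - np.exp(-1e7 * 1e-7) == pytest.approx(0.632, rel=1e-3)


class TestEngineCrossEquivalence:
    """fixed_step, ssa and qssa sample the same law (tamed flicker).

    The published flicker (1e7 s^-1) forces the fixed-step scheme below
    dt = 1e-8 s, so the three-way comparison uses a 1000-fold slower flicker
    with the same stationary open probability; the SSA-vs-CME tests cover
    the published rates.
    """

    def test_mean_flag_counts_agree_within_3_se(self, tame_rates):
        n_rep = 60
        t_end = 0.1
        results = {}
        for scheme, dt in (("ssa", None), ("qssa", None), ("fixed_step", 4e-6)):
            finals = []
            for r in range(n_rep):
                sys = SystemState(small_model(tame_rates, cam4=10, pp=1))
                cfg = EngineConfig(
                    scheme=scheme, dt=dt or 1e-6, t_end=t_end,
                    record_interval=t_end, n_replicates=1, seed=1000 + r,
                    validate_frames=False,
                )
                _, frames = simulate_state(
                    sys, cfg, StimulusProtocol(mode="continuous_bolus")
                )
                finals.append(frames[-1])
            results[scheme] = np.asarray(finals)

        cols = {"cam_initial": 1, "cam_full": 2, "docked": 6}
        for name, j in cols.items():
            means = {s: results[s][:, j].mean() for s in results}
            ses = {s: results[s][:, j].std(ddof=1) / np.sqrt(n_rep) for s in results}
            for a in results:
                for b in results:
                    tol = 3 * np.hypot(ses[a], ses[b]) + 1e-9
                    assert abs(means[a] - means[b]) <= tol, (name, a, b, means)


def test_incremental_bookkeeping_matches_rebuild(rng):
    """After thousands of events the incrementally maintained propensity
    matrix equals a fresh vectorised rebuild (both modes)."""
    for marg in (True, False):
        rates = RateTable() if marg else RateTable(
            k_activate=20.0, k_inactivate=1e4
        )
        sys = SystemState(small_model(rates, cam4=30, pp=3, n_holo=2))
        eng = _JumpEngine(sys, marg, np.random.default_rng(77))
        t = 0.0
        for _ in range(5000):
            ev = eng.sample(t, np.inf)
            if ev is None:
                break
            t, ch, idx = ev
            eng.fire(ch, idx)
        R, A = build_propensities(sys, marg)
        assert np.allclose(eng.R, R, rtol=1e-9, atol=1e-12)
        assert np.allclose(eng.A, A, rtol=1e-9, atol=1e-12)


def test_record_grid():
    model = small_model()
    cfg = EngineConfig(scheme="qssa", t_end=1.0, record_interval=0.25,
                       n_replicates=1, seed=0)
    ens = run_replicates(model, cfg, StimulusProtocol(mode="none"))
    assert np.allclose(ens.times, [0, 0.25, 0.5, 0.75, 1.0])
    assert np.all(np.diff(ens.times) > 0)


def test_engine_config_validation():
    with pytest.raises(ConfigurationError):
        EngineConfig(scheme="magic")
    with pytest.raises(ConfigurationError):
        EngineConfig(t_end=0.0)
    with pytest.raises(ConfigurationError):
        EngineConfig(scheme="fixed_step", dt=0.1, record_interval=0.01)
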