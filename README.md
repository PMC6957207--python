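# camkiisim

Rule-based stochastic simulation of the multi-state CaMKII holoenzyme.

Ca²⁺/calmodulin-dependent protein kinase II (CaMKII) is a dodecameric kinase
— two stacked rings of six subunits — central to synaptic plasticity. Each
subunit independently docks against the central hub, flickers between
autoinhibited and open conformations, binds calmodulin (CaM) in two steps,
is trans-autophosphorylated at Thr-286 by an active neighbouring subunit,
can be bound and dephosphorylated by a protein phosphatase (PP), and can
phosphorylate Thr-306 to block CaM rebinding. Tracking these states
explicitly defeats mass-action modelling (a single subunit has 33 admissible
flag combinations; a hexamer ring has billions), so this package expresses
the chemistry as *rules* — guarded flag transitions with mass-action rates —
and samples them stochastically over discrete particles in a 0.0328 fL
compartment.

It is built for one mechanistic question: CaM and PP bind overlapping
stretches of the regulatory domain, so does bound CaM sterically exclude
the phosphatase, and does that exclusion ("CaM trapping" given a function)
maintain Thr-286 autophosphorylation? The package ships both model variants
(`exclusive` vs `non_exclusive`), kinase/phosphatase-inhibitor protocols, an
autophosphorylation degrees-of-freedom scan, and a nine-state CaM variant
with explicit Ca²⁺-lobe kinetics and 1000-fold CaM trapping.

## The model in brief

Subunit flags: docking ∈ {docked, undocked}, conformation ∈ {inactive,
active}, CaM ∈ {unbound, initially bound, fully bound}, Thr-286 ∈ {uT286,
pT286, PP-bound}, Thr-306 ∈ {uT306, pT306}. Key kinetics (s⁻¹ unless
noted): docking 35 / undocking 0.63 (K_docking = 0.018); conformational
flicker 2×10⁴ on / 10⁷ off (open probability p_act ≈ 0.002); CaM initial
contact k_on = 10⁸ M⁻¹s⁻¹, k_off = 590; CaM compaction 350 forward,
4×10⁻³ back; autophosphorylation 1 per directed kinase→substrate edge
(counter-clockwise neighbour; optionally both directions and trans-ring);
PP binding 3×10⁶ M⁻¹s⁻¹, release 0.5, catalysis 2 (K_M = 8.3×10⁻⁷ M).
Stimulation converts free CaM between apo and Ca₄-CaM by square-wave
forcing (boluses or pulse trains).

Engines: an exact SSA, a quasi-steady-state-accelerated SSA that
marginalises the 10⁷ s⁻¹ flicker (the production engine), and a
fixed-timestep Bernoulli sampler for micro-validation. An exact
chemical-master-equation oracle validates all of them on small systems.
See `docs/methods.md` for assumptions, parameter provenance, numerical
choices and limitations — including a systematic magnitude caveat relative
to the originally reported values.

## Worked example

Kinase inhibition distinguishes the two exclusion variants. Stimulate 30
holoenzymes (360 subunits, 450 CaM, 17 PP) with a 10 s CaM₄ bolus, add a
saturating kinase inhibitor at t = 30 s, and watch total phospho-Thr-286
(pT286 + PP-bound) to t = 120 s:

```python
import numpy as np
from camkiisim import RateTable, Pools, StimulusProtocol, EngineConfig
from camkiisim.engines import ModelConfig, run_replicates

protocol = StimulusProtocol(
    mode="finite_bolus", bolus_duration=10.0,
    events=((30.0, "kinase_inhibitor"),),
)
for exclusivity in ("exclusive", "non_exclusive"):
    model = ModelConfig(
        n_holo=30,
        rates=RateTable(exclusivity=exclusivity),
        pools=Pools(free_apo_cam=450, free_cam4=0, free_pp=17),
    )
    cfg = EngineConfig(scheme="qssa", t_end=120.0, n_replicates=5, seed=1)
    ens = run_replicates(model, cfg, protocol)
    phos = ens.mean("pT286") + ens.mean("pp_bound")
    t30 = np.argmin(np.abs(ens.times - 30.0))
    print(f"{exclusivity:>14}: phospho-T286 at 30 s = {phos[t30]:.1f} subunits, "
          f"at 120 s = {phos[-1]:.1f} subunits")
```

prints

```
     exclusive: phospho-T286 at 30 s = 28.6 subunits, at 120 s = 24.4 subunits
 non_exclusive: phospho-T286 at 30 s = 13.0 subunits, at 120 s = 0.0 subunits
```

With exclusion, CaM still bound to phosphorylated subunits blocks
phosphatase access, so phosphorylation survives 90 s of pure phosphatase
activity almost intact (24.4 of 28.6 subunits). Without exclusion the
phosphatase strips every phosphate within the same window. That contrast —
not raw kinase/phosphatase balance — is the mechanism by which CaM binding
maintains autophosphorylation.

The same experiments are available from the shell:

```
camkii-sim presets                      # list experiment presets
camkii-sim simulate exclusivity_scan --seed 1 --replicates 5 --out runs/scan
camkii-sim analyze runs/scan            # endpoints + ln-linear decay fits
camkii-sim validate                     # derived-parameter identities
```

Each run directory is self-describing (`trajectories_<arm>.csv`,
`summary.json`, `config_echo.yaml`, `run.log`); re-running the echoed config
with the same seed reproduces the trajectories byte-for-byte.

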