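# Methods

## The model

`camkiisim` simulates the Ca²⁺/calmodulin-dependent protein kinase II
(CaMKII) holoenzyme as a well-mixed, discrete-particle stochastic reaction
system. A holoenzyme is twelve subunits in two radially symmetric, directly
apposed rings of six. Each subunit carries five flags:

| flag | values | meaning |
|---|---|---|
| docking | docked / undocked | compact against the hub (CaM-inaccessible) vs extended |
| conformation | inactive / active | autoinhibited vs catalytically open |
| cam | unbound / initial / full | CaM binding: none, low-affinity first contact, full wrap |
| t286 | uT286 / pT286 / PP-bound | Thr-286 phosphorylation state or a bound phosphatase |
| t306 | uT306 / pT306 | Thr-306 phosphorylation (blocks CaM binding; irreversible here) |

plus a boolean overlay for the kinase inhibitor K252a. Unconstrained this is
72 flag combinations per subunit; the three structural invariants (docked or
pThr-306 ⇒ CaM-unbound; fully bound ⇒ active) leave 33. State spaces of
whole holoenzymes are astronomically large, which is why transitions are
expressed as *rules* — guard predicates over a subunit's flags (and, for
trans-autophosphorylation, a neighbour's) with mass-action rates — and
sampled stochastically rather than enumerated.

Free ligands are finite counted pools in a 0.0328 fL compartment: by default
30 holoenzymes (1.52 µM; 18.24 µM subunits), 450 CaM (22.8 µM) and 17
phosphatase molecules (0.86 µM). Macroscopic association constants
(M⁻¹ s⁻¹) convert to per-pair propensities as k/(N_A·V).

### Rate constants

All kinetics come from published measurements or derivations from them:
docking/undocking 35 / 0.63 s⁻¹ (equilibrium constant 0.018, the ratio of
CaM on-rates for free peptide, 1×10⁸ M⁻¹s⁻¹, and full-length kinase,
1.8×10⁶ M⁻¹s⁻¹); conformational flicker 2×10⁴ s⁻¹ activation against
1×10⁷ s⁻¹ inactivation (stationary open probability
p_act = 2×10⁴/(2×10⁴+10⁷) ≈ 0.002); initial-CaM dissociation
590 s⁻¹ (= 5.9 µM × 10⁸ M⁻¹s⁻¹); CaM compaction 350 s⁻¹ forward,
4×10⁻³ s⁻¹ back (occupancy ratio ≈ 1.1×10⁻⁵); trans-autophosphorylation
1 s⁻¹ per directed kinase edge; Thr-306 phosphorylation 50-fold slower
(0.02 s⁻¹); phosphatase binding 3×10⁶ M⁻¹s⁻¹, release 0.5 s⁻¹, catalysis
2 s⁻¹ (Michaelis constant 8.3×10⁻⁷ M). The `oracle.derive_parameters`
identities pin the rate table to these derivations in the test suite.

### Variants

* **Exclusivity** — in the exclusive model bound CaM and bound phosphatase
  sterically exclude each other (phosphatase binding requires CaM-unbound,
  CaM binding requires not-PP-bound); the non-exclusive model drops exactly
  those two guard clauses and nothing else.
* **Degrees of freedom (DOF)** — the directed kinase→substrate adjacency:
  DOF 1, the counter-clockwise intra-ring neighbour (positions 0–5
  counter-clockwise, kinase of i is (i+1) mod 6 — the direction is fixed by
  the model, the index origin is our convention and equivalent by symmetry);
  DOF 2 adds the clockwise neighbour; DOF 3 adds the directly apposed
  subunit of the other ring.
* **Nine-state CaM** (see below).

### Ambiguous rule readings (toggles)

Where the verbal rule descriptions admit two readings we implement the
literal flag semantics and expose a toggle:

* `pp_bound_counts_as_phospho` (default false) — the inactivation guard
  reads the t286 flag literally, so a PP-occupied subunit may transiently
  inactivate; the effect is negligible because re-activation is fast.
* `dock_requires_inactive` (default false) — docking requires only
  CaM-unbound ∧ uT306; the alternative adds an inactive-conformation guard.
* `k252a_blocks_kinase_role` (default true) — the saturating kinase
  inhibitor blocks a subunit both as substrate and as kinase; at a
  saturating dose every subunit is bound, so the distinction is
  unobservable in the inhibition protocol either way.
* `count_pp_bound_as_pT286` (census toggle, default false) — the pThr-286
  census reads the flag literally, so PP-occupied subunits are reported as
  PP-bound, not pThr-286.

## Stimulation

Free CaM is driven between apo and fully loaded CaM4 by square-wave forcing
standing in for Ca²⁺ flux. Because the nominal conversion rate (10⁸ s⁻¹)
exceeds every other rate by ≥10⁵, conversion is applied deterministically at
phase edges: during an activating phase all free CaM is CaM4, during an
inactivating phase all free CaM is apo; CaM bound to subunits is untouched,
and a CaM released during an inactivating phase joins the apo pool. Pulse
trains place the first pulse at t = 0 (the indexing origin is a convention;
starting at 0 makes duty cycles exactly frequency × width for every
frequency). Protocols: continuous bolus, finite bolus, pulse trains, plus
timed events — saturating K252a (instantaneous flag set on all subunits,
rather than explicit 18.2 µM binding kinetics whose on-rate is not
specified), phosphatase inhibition (catalytic rate set to zero from the
event time; binding and release continue unchanged), and Ca²⁺ chelation
(nine-state model only; one-time removal of the free Ca²⁺ pool, so total
Ca²⁺ is conserved between chelation events).

## Engines

Three interchangeable schemes advance the same jump process:

* **ssa** — exact stochastic simulation (direct method with incremental
  propensity updates restricted to the entities touched by each event).
  With the 10⁷ s⁻¹ conformational flicker simulated explicitly this is only
  practical for small systems or short windows.
* **qssa** (production default) — the flicker is marginalised: every rule
  gated on the active conformation carries the stationary factor
  p_act ≈ 0.002 per non-stabilised gated participant (the
  autophosphorylation rule can carry it twice — e.g. its effective rate is
  1 s⁻¹ × 0.002² for two unstabilised participants, 0.699 s⁻¹ for
  initial→full CaM on an unstabilised subunit), while subunits pinned
  active by full CaM or pThr-286 carry factor 1. The reported "active"
  count is the conditional expectation
  n_stabilised + p_act·(n − n_stabilised). The reduction is exact in the
  limit k_inactivate ≫ every other rate, which holds by four orders of
  magnitude.
* **fixed_step** — a fixed-timestep Bernoulli sampler (each eligible rule
  instance fires independently with p = 1 − exp(−a·dt); conflicting
  firings on one subunit are resolved by a uniform random winner, a
  tie-break justified by the order-indistinguishability of events within
  one step). It refuses any dt for which some p would exceed 0.1 — with
  the published flicker that means dt ≤ ~10⁻⁸ s, which is why this engine
  is used for micro-validation only.

Stimulus changepoints are hard barriers: the jump clock never crosses one,
and all propensities are rebuilt after the barrier's deterministic update.
Replicate r of an ensemble uses seed base+r; identical configuration and
seed reproduce trajectories bit-for-bit on every engine.

Correctness is cross-checked three ways in the test suite: the vectorised
propensity builder, the incremental per-event bookkeeping, and the
interpreted declarative rule table must agree exactly on random states; SSA
samples must match exact chemical-master-equation (CME) solutions on one-
and two-subunit systems (the CME treats the finite pools as part of the
global state, so it is exact, not mean-field); and the three engines must
agree on mean flag counts within 3 SE. For the three-way engine comparison
the flicker is slowed 1000-fold (preserving p_act) so the fixed-step scheme
can run within its probability cap; the published rates are covered by the
SSA-vs-CME checks.

## Nine-state CaM variant

The nine-state-one-step variant removes the docking and conformation flags
("active" ≡ CaM-bound) and represents each CaM's Ca²⁺ loading explicitly:
0–2 ions on each of the N and C lobes (nine states, (0,0) = apo-CaM). Every
state binds CaMKII in one step with state-specific kinetics; Ca²⁺ binds and
leaves lobes both on free and on kinase-bound CaM (which is what lets
apo-CaM arise *in place* on the kinase after chelation). CaM trapping is a
division of the CaM–CaMKII off-rate by 1000 on pThr-286 subunits — an
affinity change implemented purely through the off-rate, applied uniformly
across the nine states by default (`trap_all_states`; the sub-saturated
case is genuinely undetermined, so the toggle exposes the CaM4-only
alternative). Exclusion modes: all bound CaM states block phosphatase
binding (`exclusive`), none (`non_exclusive`), or only CaM4 (`cam4_only`).
Thr-306 phosphorylation requires an active *and* CaM-unbound subunit, which
is unsatisfiable once activation ≡ CaM-bound; the flag is retained but
never set in this variant.

The shipped rate set (`data/nine_state_rates_synthetic.yaml`) is **synthetic**:
it anchors the printed dissociation constants — CaM2C–CaMKII 7.4 µM,
apoCaM–CaMKII 1.45 mM (1.45 µM on pThr-286 subunits via trapping), PP1
0.166 µM — and fills the remaining per-state and lobe kinetics with a
documented monotone interpolation (affinity and on-rate grow with Ca²⁺
load, the C lobe contributing more; lobe on-rates scaled so Ca²⁺–CaM
equilibration is fast relative to stimulus timescales yet tractable
event-by-event). Conclusions that depend on the *specific* sub-saturated
kinetics should not be drawn from the defaults; conclusions about the
exclusion/trapping mechanism are insensitive to them, and the conservation
and trapping properties are asserted for any complete rate set.

## Observables and fits

Censuses count flags exactly per frame; concentrations are count/(N_A·V)
(one subunit ≈ 0.0506 µM in the default volume). Ensemble statistics are
pointwise means with SEM = SD/√N (absent for N = 1). Decay constants are
least-squares slopes of ln(concentration) vs time on a configurable window,
[5, 120] s by default — the fitting procedure behind the published decay
constants is unstated, so this convention is our choice; where an ensemble
mean touches zero inside the window the acceptance script restricts the fit
to strictly positive frames. Frequency-response fits are ordinary least
squares of endpoint concentration (read at t = 20 s) against frequency with
R²; an all-equal response is reported as slope 0, R² 0 with a degeneracy
flag. Consecutive-pThr-286 run lengths are maximal cyclic runs per ring
(PP-bound counts as phosphorylated — the site is still a phosphothreonine);
a full ring reports 6.

## Problem sizes and numerical choices

Stochastic analyses in the tests and the acceptance script use the full
published composition (30 holoenzymes, 450 CaM, 17 PP) with 5–6 replicates
per condition on the QSSA engine — enough for 3-SE comparisons of ensemble
means at desk scale; the 50-replicate fixed-step runs of the original model at
dt = 0.1 µs are reproducible with this package but are not what the routine
suites execute. CME transients integrate the forward equation with a stiff
BDF method (rtol 10⁻⁸) and renormalise only within 10⁻⁹; stationary
distributions come from the null eigenvector of the transposed generator.
Reachable-state enumeration is capped (10⁶ states) and refuses larger
systems by design. Incremental propensity sums are resynchronised from the
full matrix every 8192 events to bound floating-point drift.

## Known limitations

* Space is deliberately absent: the model's fast-diffusion assumption
  makes mass-action-per-volume propensities the effective model, and this
  package implements exactly that well-mixed limit. Spatial gradients,
  realistic spine geometries and diffusion-limited rebinding are out of
  scope.
* A systematic quantitative caveat: interpreting the published rate
  constants as exact continuous-time kinetics, capture of CaM into the
  fully-bound state is rate-limited to ≈0.05 s⁻¹ per subunit (undocking
  0.63 s⁻¹ × branching (350·p_act)/590 per initial contact), i.e. a ~20 s
  time constant. Phosphorylation magnitudes under strong stimulation are
  correspondingly lower than the originally reported values, which were
  produced by a fixed-step scheme whose per-step inactivation probability
  saturated (1 − e⁻¹ ≈ 0.63 at dt = 0.1 µs). The mechanistic contrasts
  (exclusive vs non-exclusive stability, inhibitor responses, frequency
  dependence) are insensitive to this and reproduce; absolute
  percent-phosphorylated values are not comparable to the originally reported ones.
  The fixed-step engine here enforces its probability cap rather than
  reproducing that discretisation.
* Thr-305 chemistry, inter-holoenzyme subunit exchange and actin binding
  are not modelled.
* The nine-state defaults are anchor-calibrated synthetic values, as above.
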