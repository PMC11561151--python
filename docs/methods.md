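# Model and methods

`magnet` simulates how a single neuromodulator, dopamine (DA), can play two
distinct biophysical roles in goal-directed navigation: **reinforcement**
(gating the consolidation of synaptic eligibility traces into long-term
weights, which builds a place–reward assembly) and **motivation**
(transiently scaling NMDA conductances, which ignites that assembly and
turns it into an attractor of the joint neural/behavioural dynamics).  This
note documents the model equations, the parameters that matter, the design
choices made where the design was genuinely open, and what the synthetic
study conditions do and do not show.

## The embodied architecture

A simulated mouse ("e-mouse") moves in a circular open field (67 cm
diameter) at 50-ms behaviour frames (20-fps video-tracking resolution).
Four stages close the action–perception loop:

1. **Place input.**  Excitatory neurons sit on a 20 × 20 lattice of
   preferred positions covering the arena and receive feed-forward AMPA
   current `gain · exp(-||x - x_i||² / 2σ²)` from the e-mouse position
   (σ = 5 cm, gain = 500 pA).
2. **Recurrent network.**  400 excitatory (E) and 100 inhibitory (I)
   leaky integrate-and-fire neurons (E/I ratio 4), Bernoulli connectivity
   p = 0.2, conductance-based AMPA/NMDA/GABA-A/GABA-B synapses, a uniform
   1.5-ms conduction delay, exponentially filtered Gaussian background
   current, and an adaptive spike threshold on E cells.  Inhibitory weights
   are scaled once at build time so expected inhibitory charge balances
   expected excitatory charge per postsynaptic neuron (the network operates
   in an inhibition-dominated balanced regime).
3. **Goal decode.**  A stochastic soft-max over instantaneous E rates
   selects one neuron per frame; its preferred position is the internal
   goal (a minimal stand-in for basal-ganglia action selection).
4. **Motor layer.**  Linear-speed and angular commands blend a default
   wall-following drive with ballistic convergence toward the internal
   goal; the blend weight collapses when the decoded goal is salient
   (further than a 5-cm dead-zone from the current position).  Goal pursuit
   carries behavioural commitment with hysteresis: the drive engages only
   after the decoded goal has stayed salient for 300 ms, and an engaged
   approach survives brief decode flickers (released after 500 ms without a
   salient goal, with a minimum committed weight of 0.4), so one-frame
   soft-max fluctuations never move the e-mouse while a sustained ignited
   assembly does.  Occasional random heading perturbations launch straight
   interior forays, reproducing the incursion statistics of naive mice.

Entering a rewarded zone triggers a phasic DA train (the optogenetic
stimulus shape: ten 5-ms pulses at 20 Hz over 500 ms) under protocol rules
taken from the behavioural task: a central zone re-arms only after the
e-mouse is detected ≥ 10 cm from its centre; in the three-zone layout a
zone just rewarded stays disarmed until another is visited; experimenter
stimulation in test sessions requires > 10 cm from the reference point and
is a sham with probability 0.5.  After each reward the e-mouse pauses in place for 2.5 s (consummatory
behaviour); this anchors the consolidation window at the rewarded site.

## Dopamine

DA is one global concentration.  Release events inject impulses into a
second-order linear system (release feeding a recapture-cleared
concentration; rise 30 ms, decay 200 ms) on a tonic baseline of 0.1 a.u.,
clipped at zero and saturating at 1.5 a.u. (releasable-pool limit under
overlapping trains).  Spontaneous single-pulse transients occur as a
Poisson process (0.05 events/s).

**DA-excitability** scales every excitatory-to-excitatory NMDA maximal
conductance by `g = clip(1 + slope · (DA - baseline), 0, 2.4)`.  A full
train peaks at g ≈ 2.3 and the gain is back within 5% of 1 about 0.66 s
after train end — the sub-second motivational window.  Commanded
"photo-inhibition" multiplicatively suppresses the tonic baseline (and any
release during the window), pushing the gain below 1.

**DA-plasticity** gates consolidation (below).  Consolidation is driven by
the concentration in excess of 0.45 a.u.: tonic DA does not read out the
eligibility traces (low-affinity D1-receptor activation by phasic
transients), which keeps background activity from slowly erasing or
inflating weights.

## Plasticity

Plastic E→E synapses carry calcium from presynaptic spikes (arriving after
the conduction delay) and postsynaptic spikes, with 20-ms clearance.  The
presynaptic contribution saturates at the single-spike level (0.6) while
the postsynaptic contribution stacks across a burst up to 2.0: synaptic
calcium can therefore cross the kinase half-activation (2.5) only when a
presynaptic spike arrives during vigorous postsynaptic firing.  The kinase
and a phosphatase (half-activation 0.7) compete: eLTP integrates kinase
activation, eLTD integrates phosphatase in excess of kinase; both decay
with 600 ms and saturate (finite tag resources).  Dopamine converts traces
into weight changes, `dW = η · DA⁺ · (eLTP − eLTD) · dt`, clipped to
[0, w_max = 8].

This gives timing-dependence at burst pairings (pre → post-doublet at
+5…+10 ms is net potentiating, the reversed order net depressing), Hebbian
rate dependence (coincident 40-Hz firing potentiates, one-sided firing in
either direction does not), and — critically for stability — no
potentiation of the assembly's outgoing synapses when it broadcasts during
ignition, because its low-rate targets never burst.

## Why the attractor is latent, and how DA reveals it

Initial E→E weights are small (0.3), so the ~80 weak NMDA inputs a neuron
receives sum to little drive and the ×2.4 gain excursion barely moves the
naive network.  Conditioning saturates weights among neurons with fields
within ~10 cm of the rewarded site (a 25–30-cell assembly).  At baseline
DA the assembly is silent: recurrent drive at gain 1 is below ignition
threshold.  A phasic train lifts the gain to ~2.3 and the assembly ignites
(40–70 Hz against a ~35-Hz position bump), the soft-max decode jumps to
the rewarded location, and the motor layer launches a directed, energized
run; adaptation and the decaying gain terminate the episode within
seconds.  Saturating NMDA gating (per-presynaptic-site occupancy, increment
0.63 toward 1) bounds the ignited assembly's output so the rest of the
network stays near baseline, and AMPA-dominated fast-spiking interneurons
(no recurrent NMDA) let the gain act on E cells while inhibition tracks
only as feedback.

## The reduced behavioural-potential-energy model

Radial symmetry of the single-reward arena collapses the architecture to a
particle at distance p from the assembly (p = 0) in

    E(p, DA) = α_w · w(p) · Î_exc(DA) + ½ · α_g · ρ · DA · p²

with w(p) the radial profile of reward-reinforced incoming weights
(uniform before learning, Gaussian afterwards) and Î_exc(DA) =
−(1 + slope·DA) the DA-dependent inward excitatory current per weight unit,
mirroring the NMDA-gain law.  Defaults: α_w = α_g = 1, ρ = 0.08, Gaussian
amplitude 6, width 7 cm, mobility 2.5, Langevin noise 1.2 cm/√s, reflecting
boundaries at 0 and 33.5 cm.  At baseline DA the basin of attraction is a
narrow band (≈ 16 cm, weak local convergence); at phasic DA levels depth
and width grow monotonically and the basin spans the arena (strong global
convergence).  Scenario simulations model optogenetic manipulations as
plateaus of ±DA with exponential edges and reproduce the
distance-to-attractor logic: stimulation raises action probability and cuts
latency only for distal starts; inhibition suppresses action only for
distal starts and spares an agent already near the goal.
`calibrate_mobility` fits the particle's single mobility constant to
observed radial descent speeds when a quantitative match to full-model runs
is wanted.

## Study conditions (synthetic data)

All experiments are generated by the simulator itself; no external data is
consumed.  The scaled-down study conditions used by the test-suite are:

- **Conditioning**: a central 5-cm zone, up to five 240-s sessions under
  DA-plasticity alone, stopping at a criterion of 8 rewards
  (conditioning-to-criterion with a moderate visit rate; with excitability
  live during conditioning, each reward's ignition recruits the shell
  around the assembly and the attractor stops being latent).  Naive visits
  arise from chance incursions.
- **Convergence probes**: 40 random peripheral starts (r = 30 cm), one
  commanded train at t = 1 s, 30-s horizon, plasticity frozen; four
  conditions crossing trained/naive weights with excitability on/off.
- **Stimulation tests**: extinction-style sessions (rewards off, DA only
  from commanded events): peripheral experimenter stimulation (mean
  interval 14 s, 50% shams, > 10 cm rule) in the conditioned circular
  arena (R context) and a naive square arena (no-R context).  Event-aligned
  effects are read on the timescale each unfolds over: speed change over
  0-4 s (relative to the 3 s before the event, truncated at target entry),
  closest approach within 6 s, bout directionality over 10 s.
- **Learning curve**: ten 60-s sessions with both mechanisms on in a 50-cm
  arena, so chance visits, take-off and the goal-directed phase all fit the
  session budget.

What these conditions do *not* emulate: sensory richness and visual cues,
within-subject variability across animals, satiety/effort modulation, and
the D2-receptor and basal-ganglia circuitry deliberately reduced to the
soft-max stage.  Passing tests show the mechanisms interact as described
at desk scale, not that parameter values are quantitative fits to tissue.

## Numerical choices and degenerate inputs

Network integration: exact exponential decay for all gating variables and
traces, forward Euler for membrane potentials, dt = 0.5 ms (≤ the 1.5-ms
delay; three-step ring buffer).  Eligibility updates run on a 4-ms
sub-step (calcium spikes are still applied at 0.5 ms); consolidation
scatters into the dense propagation matrix once per 50-ms frame.  The
soft-max subtracts the maximum logit before exponentiation.  Reflecting
boundaries implement the particle model;
positions are projected back inside the arena after every motor step.
Degenerate cases are defined explicitly: zero-duration sessions return
empty records with initial snapshots; delay metrics flag censored events
instead of dropping them; frames standing exactly on the metric target are
skipped in the directionality statistic; a zone just rewarded cannot
re-trigger until the re-arm rule is satisfied, and `max_rewards` disarms
delivery beyond the criterion.

## Known limitations

- The quantitative biophysical constants are desk-scale calibrations
  chosen to realize the documented operating regime (latent assembly,
  selective ignition, bounded learning), not fits to recordings.
- The latent/expressed boundary is a genuine knife edge of the biology the
  model describes: over-conditioning (no criterion stop) eventually
  produces an assembly wide enough to self-ignite at tonic DA.  The
  conditioning protocol's criterion stop is the model's honest account of
  why moderate visit rates were enforced experimentally.
- Even below that boundary the learned assembly exerts weak local
  convergence at tonic DA (the latent attractor's own captures).  At desk
  scale this baseline attraction saturates the probability of approaching
  the centre from distal positions within short test windows, so the
  distance dependence of the phasic-DA effect is expressed by the reduced
  model but not resolved by the full embodied model's stimulation test;
  for the same reason the event-aligned approach-distance and
  bout-directionality contrasts between stimulation and sham in the reward
  context are thin and can invert between conditioning endpoints, while
  the speed contrast and the no-reward-context nulls are stable.
- STDP timing-dependence is expressed at burst pairings; isolated
  single-spike pairs at low rates leave traces too small to consolidate,
  a known property of calcium-threshold plasticity models.
- One global DA signal; no D1/D2 dissociation, no spatial DA gradients,
  no DA-neuron spiking model (release is event-level).
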