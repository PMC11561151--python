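# magnet

An embodied, dopamine-modulated spiking-network model of goal-directed
navigation, together with its reduced behavioural-energy theory and the
open-field trajectory metrics used to analyse sessions.

## The science

How can one dopamine (DA) signal both *reinforce* (store which places are
worth visiting) and *motivate* (launch a run toward one of them, right
now)?  This package implements a decision architecture in which the two
roles are two biophysical actions of the same phasic transient at recurrent
excitatory synapses:

- **DA-plasticity** — calcium-driven spike-timing eligibility traces
  (eLTP/eLTD) are consolidated into long-term weight changes only when
  phasic DA arrives: `dW = η · DA⁺ · (eLTP − eLTD) · dt`, bounded in
  `[0, w_max]`.  Repeated rewards at a place carve a Hebbian assembly of
  neurons whose place fields cover it.
- **DA-excitability** — DA instantaneously scales NMDA maximal
  conductances, `g = clip(1 + s·(DA − DA₀), 0, g_max)`, for well under a
  second after a release train.

The assembly built by plasticity is a **latent attractor**: at tonic DA it
is silent, and the simulated mouse ("e-mouse") wall-follows.  A phasic
transient raises the NMDA gain, the assembly ignites, a soft-max decode of
the population rates jumps to the rewarded location, and the motor layer
converges on it — DA "reveals" the attractor, energizing and directing
behaviour at once.  The radially symmetric task admits a one-dimensional
reduction, the behavioural potential energy

    E(p, DA) = α_w · w(p) · Î_exc(DA) + ½ · α_g · ρ · DA · p²,

with `p` the distance to the assembly and `w(p)` the learned incoming-weight
profile; basin depth and width grow with DA, which reconciles conflicting
optogenetic findings through the distance between the agent's state and the
attractor.  See `docs/methods.md` for the full model description.

## A worked example

`python examples/bpe_scenarios.py` Monte-Carlos the reduced model (1000
trials per scenario) and prints:

```
distal start, baseline DA              P(action) = 0.07   latency = 8.82 s
distal start, phasic DA stimulation    P(action) = 1.00   latency = 1.87 s
distal start, DA inhibition            P(action) = 0.01   latency = 8.94 s
near the goal, DA inhibition           P(action) = 1.00   latency = 0.88 s
basin depth/width at baseline DA: 9.3 / 16 cm; under phasic DA: 139.8 / 30 cm
```

Reading: an agent 20 cm from the learned goal rarely reaches it within the
10-s horizon at baseline DA; a phasic DA plateau makes convergence certain
and five times faster; suppressing DA abolishes it — but an agent already
near the goal is immune to DA inhibition, because the local basin carved by
learning persists at any DA level.  The last line is the latent-attractor
statement in numbers: learning alone leaves a narrow (16-cm) basin, phasic
DA widens it to the whole arena.

Other examples: `examples/dopamine_transient.py` (the sub-second NMDA-gain
transient), `examples/run_session.py` (a closed-loop conditioning session),
`examples/stim_test.py` (peripheral stimulation vs sham in reward and
no-reward contexts), `examples/trajectory_metrics.py` (the tracking-metrics
battery).  A thin CLI wraps the same functions: `magnet run`,
`magnet sweep`, `magnet stimtest`, `magnet bpe`, `magnet metrics`.

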