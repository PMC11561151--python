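"""The two timescales of dopamine at a synapse.

Delivers one 500-ms optogenetic-style release train (ten 5-ms pulses at
20 Hz) and prints the resulting concentration transient and its effect on
the NMDA-conductance gain — the "DA-excitability" mechanism, which outlasts
the train by well under a second.  Eligibility traces consolidated by the
same transient (the "DA-plasticity" mechanism) are what persists.
"""

import numpy as np

from magnet import damod

params = damod.DAParams()
state = damod.DAState.at_baseline(params)
damod.command_phasic(state, params, "stimulation", 100.0)

dt = 0.5
ts, conc, gain = [], [], []
for _ in range(int(3000 / dt)):
    damod.da_step(state, params, dt)
    ts.append(state.t_ms)
    conc.append(state.concentration)
    gain.append(damod.nmda_gain(state.concentration, params))
ts, conc, gain = map(np.asarray, (ts, conc, gain))

print(f"tonic baseline: {params.baseline} a.u.; peak concentration: "
      f"{conc.max():.2f} a.u. at t = {ts[conc.argmax()] / 1000:.2f} s")
print(f"peak NMDA gain: {gain.max():.2f} (saturates at {params.gain_max})")
train_end = 600.0
after = ts > train_end
outside = np.abs(gain - 1.0) > 0.05
idx = np.nonzero(after & outside)[0]
t_back = (ts[idx[-1]] - train_end) / 1000.0 if idx.size else 0.0
print(f"gain back within 5% of baseline {t_back:.2f} s after train end "
      "(sub-second excitability transient)")
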