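"""Run one closed-loop conditioning session and summarize it.

Builds the default recurrent network, places the e-mouse in a 50-cm
circular open field with a single rewarded central zone, and runs three
chained 100-s sessions of the action-perception loop with both dopamine
mechanisms active (DA-gated plasticity and DA-scaled NMDA excitability).
"""

import numpy as np

import magnet
from magnet import embodiment

arena = magnet.central_zone_layout(radius_cm=25.0)
net = magnet.build_network(magnet.NetworkParams(), seed=6,
                           arena_half_extent_cm=25.0)
pose = None
for sess in range(3):
    result = embodiment.run_closed_loop(
        net,
        magnet.DAParams(),
        magnet.PlasticityParams(),
        arena,
        magnet.Protocol("central_conditioning"),
        duration_s=100.0,
        seed=600 + sess,
        start_pose=pose,
    )
    pose = result.final_pose
    speeds = np.hypot(*np.diff(result.positions_cm, axis=0).T) / 0.05
    radius = np.hypot(*result.positions_cm.T)
    print(f"session {sess}: rewards {result.reward_count:2d}  "
          f"mean speed {speeds.mean():4.1f} cm/s  "
          f"outer-third occupancy {(radius > 17).mean():.2f}")

w = net.ee_weights
d_pref = np.hypot(*net.place_map.positions_cm.T)
mid = 0.5 * (d_pref[net.ee_pre] + d_pref[net.ee_post])
print(f"mean E->E weight near the rewarded centre: {w[mid < 6].mean():.2f} "
      f"vs far from it: {w[mid > 17].mean():.2f}")
print("rising reward counts and centre-weighted synapses show reward-paired "
      "dopamine carving the place-reward assembly")
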