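"""Detect proton-hop events and hydronium lifetimes on a scripted relay.

A donor-water-acceptor chain (heavy atoms 2.8 A apart) is scripted to
mimic a nonconcerted excited-state proton transfer: brief visits of the
acidic proton to the bridging water, a permanent hop at 800 fs, and the
onward jump of a water proton to the acceptor at 1 ps.
"""

import numpy as np

import genmodes as g

heavy = np.array([[0.0, 0.0, 0.0],   # donor oxygen
                  [2.8, 0.0, 0.0],   # bridging water oxygen
                  [5.6, 0.0, 0.0]])  # acceptor oxygen
script = [
    (0, 0, 1, 300.0, 12.0),   # brief visit to the water
    (0, 0, 1, 620.0, 8.0),
    (0, 0, 1, 800.0, None),   # permanent first transfer
    (1, 1, 2, 1000.0, None),  # onward transfer to the acceptor
]
# hydrogens: the acidic proton (home 0), a water proton that later moves
# on to the acceptor (home 1), and the water's second, spectator proton
s = g.make_pt_script(heavy, hydrogen_home=[0, 1, 1], events=script,
                     dt=0.2, nframes=6001)

events = g.detect_pt_events(s.trajectory, s.hydrogens, s.heavy,
                            r_bond=1.3, t_permanent=100.0)
print("proton-hop events:")
for e in events:
    print(f"  H{e.hydrogen}: O{e.from_atom} -> O{e.to_atom}  "
          f"t = {e.t_start:6.0f} .. {e.t_end:6.0f} fs  ({e.kind})")

hyd = g.hydronium_series(s.trajectory, s.heavy, s.hydrogens)
print(f"hydronium lifetimes (fs): {hyd.lifetimes}")
print("# between the first transfer (800 fs) and the onward jump (1 ps) the")
print("# bridging water holds 3 protons: a hydronium living 200 fs.")
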