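"""Time-resolved wavelet map of a transient low-frequency mode.

The demo molecule carries damped modes at 110 and 198 cm^-1 (band power
1/e in about 700 fs) — a miniature of the transient ring wagging and
breathing activity a photoexcited chromophore shows before a proton
transfer. The Morlet spectrogram localizes each mode in time and
frequency; the band-power decay time quantifies how long it survives.
"""

import numpy as np

import genmodes as g

spec = g.demo_chromophore_spec(seed=0)
traj = g.make_harmonic(spec, dt=0.5, nframes=8192)  # ~4.1 ps

clean = g.remove_global_motion(traj)
mw = g.mass_weight(clean)
basis = g.diagonalize(g.compute_K(mw))
series = g.project(basis, mw, dt=clean.dt)

# pick the generalized mode whose spectrum peaks nearest 198 cm^-1
peaks = [g.power_spectrum(series.Qdot[:, k], clean.dt).peak_frequency()
         for k in range(3)]
mode = int(np.argmin(np.abs(np.array(peaks) - 198.0)))

spec_map = g.cwt(series.Qdot[:, mode], clean.dt,
                 g.WaveletParams(fmin=60.0, fmax=400.0))
ridge = spec_map.ridge()
mid = np.isfinite(ridge)
print(f"mode {mode}: ridge frequency ~ {np.nanmedian(ridge[mid]):.0f} cm^-1")

bp = g.band_power(spec_map, (160.0, 240.0))
td = g.decay_time(bp, spec_map.times)
print(f"band power (160-240 cm^-1) decays to 1/e at {td:.0f} fs")
print("# amplitude damping tau = 1400 fs means power decays as exp(-2t/tau),")
print("# i.e. 1/e at 700 fs; the measured time is somewhat longer because the")
print("# Morlet wavelet at 198 cm^-1 has a ~160 fs time-width that smears the")
print("# envelope (time-frequency uncertainty).")

g.write_matrix(spec_map.power, spec_map.frequencies, spec_map.times,
               "wavelet_map.txt", "frequency_cm-1", "time_fs")
print("spectrogram written to wavelet_map.txt")
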