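"""Current-clamp preprocessing: spike removal, cycle averaging, magnitude.

Synthesizes one membrane-potential sweep (2 Hz modulated depolarization
with stereotyped spikes riding on top), then runs the preprocessing chain:
dV/dt spike detection, 6 ms median-filter spike removal, cycle averaging
over the 50-550 ms post-cycle-onset windows, and baseline-subtracted peak
response magnitude.
"""

import numpy as np

from binomatch import (Baseline, StimulusProtocol, compute_baseline,
                       cycle_average, detect_spikes, remove_spikes,
                       response_magnitude)

protocol = StimulusProtocol()
fs = protocol.sampling_rate
onset, depol = 0.2, 9.0  # s, mV
t = np.arange(int(1.8 * fs)) / fs

rng = np.random.default_rng(0)
env = np.clip(np.sin(2 * np.pi * 2 * (t - onset)), 0, None)
env[(t < onset) | (t >= onset + 1.5)] = 0.0
vm = -60.0 + depol * env + 0.3 * rng.normal(size=t.size)
spike = np.concatenate([np.linspace(0, 70, 5), np.linspace(70, 0, 10)])
for i in np.flatnonzero(vm >= -52.5)[::220]:  # fire while depolarized
    vm[i:i + spike.size] += spike[:vm.size - i]

spikes = detect_spikes(vm, fs, dvdt_threshold=10.0)
sub = remove_spikes(vm, fs)
avg = cycle_average(sub, protocol, onset, direction=0.0, units="mV")
blank = -60.0 + 0.3 * rng.normal(size=t.size)
baseline = compute_baseline([remove_spikes(blank, fs)], (onset, onset + 1.5),
                            fs, units="mV")
mag = response_magnitude(avg, baseline, "current_clamp")

print(f"detected {spikes.size} spikes (dV/dt threshold 10 mV/ms)")
print(f"baseline: {baseline.mean:.2f} mV (SD {baseline.sd:.2f} mV)")
print(f"cycles averaged: {avg.n_cycles_used}")
print(f"response magnitude: {mag.magnitude:.2f} mV "
      f"(generator depolarization was {depol} mV)")
print()
print("The median filter removes the ~1.5 ms spikes without biasing the")
print("subthreshold envelope, so the peak of the baseline-subtracted")
print("cycle average recovers the underlying depolarization amplitude.")
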