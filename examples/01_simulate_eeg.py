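"""Simulate a contaminated single-channel EEG record.

Builds an 8-second record at 200 Hz from four Markov-amplitude rhythms
(delta/theta/alpha/beta), adds EOG blink pulses, baseline drift and white
measurement noise, and prints the scale of each constituent.
"""

import numpy as np

import eegssa as e

sim = e.simulate_eeg(e.preset_config("full", seed=7))

print(f"record: {sim.eeg.n} samples at {sim.eeg.fs:g} Hz ({sim.eeg.duration:g} s)")
print(f"spontaneous EEG RMS : {np.std(sim.spontaneous.values):6.2f} uV")
for name, ts in sim.rhythms.items():
    print(f"  {name:5s} rhythm RMS : {np.std(ts.values):6.2f} uV")
print(f"artifact peak       : {sim.artifacts.values.max():6.2f} uV (EOG apex + drift)")
print(f"noise RMS           : {np.std(sim.noise.values):6.2f} uV")

# The artifact peak towers over the ongoing rhythms: this is the low-SNR
# regime in which plain frequency filtering struggles and SSA helps.
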