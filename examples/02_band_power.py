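"""Welch band power of one synthetic recording, pre vs post fatigue.

Computes the whole-brain mean log10 band power in θ/α/β for both
conditions of one subject. With the default signatures every band's
power rises after fatigue and the α increase is the largest.
"""

from fatiguenet import BANDS, SimulationConfig, simulate_recording
from fatiguenet.spectral import band_spectrum

config = SimulationConfig(n_subjects=1, duration=30.0, fs=250.0, seed=7)

means = {}
for condition in ("pre", "post"):
    rec = simulate_recording(config, 0, condition)
    spec = band_spectrum(rec.data, rec.fs, rec.channels)
    means[condition] = spec.whole_brain_mean

print("whole-brain mean log10 band power (one subject):")
print(f"{'band':<8}{'pre':>10}{'post':>10}{'change':>10}")
for band in BANDS:
    pre, post = means["pre"][band.name], means["post"][band.name]
    print(f"{band.name:<8}{pre:>10.3f}{post:>10.3f}{post - pre:>+10.3f}")
print("\nall changes should be positive, alpha largest")
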