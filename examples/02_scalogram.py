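"""Turn an ECG segment into a Mexican-hat CWT scalogram.

Compares a normal and an AF segment: the AF scalogram shows irregular QRS
ridge spacing and extra energy in the 4-10 Hz fibrillatory band.
"""

import numpy as np

import afwave
from afwave.timefreq import ScaleGrid

fs = 300.0
grid = ScaleGrid.log_spaced(fs=fs, n_scales=64, fmin=1.0, fmax=50.0)

for make in (afwave.normal_spec, afwave.af_spec):
    trace = afwave.generate_ecg(make(duration_s=5.0, seed=5))
    clean = afwave.denoise(trace)
    scal = afwave.cwt(clean, grid)
    image = afwave.render_scalogram(scal, (224, 224))

    band = (grid.pseudo_frequencies >= 4) & (grid.pseudo_frequencies <= 10)
    band_energy = scal.coefficients[band].mean()
    total_energy = scal.coefficients.mean()
    print(f"{trace.label:>6}: scalogram {scal.shape} -> image {image.pixels.shape}, "
          f"4-10 Hz band / total energy = {band_energy / total_energy:.2f}")

print("The AF segment concentrates relatively more energy in the")
print("fibrillatory 4-10 Hz rows; this is one cue the classifier learns.")
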