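"""Normalize one enhancement curve and read off its kinetic parameters.

Builds a single tumor-like raw curve from the phantom archetype (no noise),
applies baseline normalization, and prints the five kinetic features.
"""

import numpy as np

from dceseg import TissueClass, archetype_tic, kinetic_features, noiseless_archetypes, normalize_tic

arch = noiseless_archetypes()[TissueClass.TUMOR]
raw = archetype_tic(arch, n_frames=65, rng=np.random.default_rng(0))
tic = normalize_tic(raw, n_pre=8)

print(f"baseline intensity i_pre = {tic.baseline:.1f} (raw units)")
k = kinetic_features(tic, n_pre=8)
print(f"i_max    = {k.i_max:.3f}   (peak relative enhancement over baseline)")
print(f"t_peak   = {k.t_peak}       (frame of first maximum)")
print(f"t_onset  = {k.t_onset}        (frames after injection to 10% of peak)")
print(f"wash_in  = {k.wash_in:.4f}  (mean enhancement slope up to the peak)")
print(f"wash_out = {k.wash_out:.4f}  (mean decline slope after the peak)")
# A tumor-like curve: strong fast wash-in, shallow persistent wash-out.
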