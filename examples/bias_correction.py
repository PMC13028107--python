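"""MICO bias-field estimation on a phantom with a known bias field.

The phantom multiplies the scene by a smooth order-2 polynomial field
with a 30% relative amplitude. MICO alternates closed-form updates of
crisp class memberships, class means, and the polynomial bias
coefficients; the estimated field should correlate strongly with the
truth inside the breast.
"""

import numpy as np

import mammoseg as ms
from mammoseg import imagio, mico

spec = ms.PhantomSpec(seed=3, n_tumors=1, bias_amplitude=0.3)
image, semantic, _, true_bias = ms.generate_phantom(spec)

norm = imagio.normalize_intensity(image, 255.0)
roi = imagio.extract_breast_region(norm, roi_threshold=5.0)
S0, est_bias, corrected, state = mico.run_mico(
    norm, n_classes=3, q=1.0, iters=20, basis_order=3, roi=roi
)

inside = roi > 0
corr = np.corrcoef(est_bias.values[inside], true_bias.values[inside])[0, 1]
print(f"class means (dark -> bright): {np.round(state.means, 1)}")
print(f"bias correlation with truth : {corr:.4f}")
print(f"energy: {state.energy_trace[0]:.3g} -> {state.energy_trace[-1]:.3g} "
      f"({len(state.energy_trace)} iterations, non-increasing)")
print(f"tumor-class Dice vs truth   : {ms.dice(semantic, S0 == 3):.4f}")

# Correlation >= 0.95 means the polynomial field tracks the simulated
# inhomogeneity; the brightest MICO class alone already outlines the
# tumor well before any level-set refinement.
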