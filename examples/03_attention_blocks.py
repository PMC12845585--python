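"""Tour of the four blocks on small tensors, checking their defining algebra.

Each block has a mathematical signature that holds regardless of training:
SimAM's constant-plane energy, Haar's isometry and perfect inversion, FEAM's
identity start (pre-gate output = 2X), and EMA's bounded modulation.
"""

import numpy as np

from aphidseg import EMA, EmaConfig, FEAM, FeamConfig, simam_energy
from aphidseg.hwd import haar_dwt2, haar_idwt2
from aphidseg.nn import Tensor
from aphidseg.simam import simam_apply

rng = np.random.default_rng(0)

# SimAM: a constant plane has energy exactly 2 everywhere
em = simam_energy(np.full((8, 8), 3.3), lam=1e-4)
print(f"SimAM constant-plane energy      : {em.values[0, 0]:.6f}  (closed form: 2)")
x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
out = simam_apply(x).data
print(f"SimAM attention weight range     : "
      f"({np.abs(out / x).min():.3f}, {np.abs(out / x).max():.3f})  (inside (0,1))")

# Haar: energy conservation + exact reconstruction
sub = haar_dwt2(Tensor(x))
err = np.abs(haar_idwt2(sub).data - x).max()
print(f"Haar energy in/out               : {(x ** 2).sum():.3f} / "
      f"{(sub.data ** 2).sum():.3f}")
print(f"Haar round-trip max error        : {err:.2e}")

# FEAM: identity-initialised weights make the pre-gate output exactly 2X
feam = FEAM(4, FeamConfig(scales=(4, 8)), rng=rng)
pre = feam.pre_gate(Tensor(x))
print(f"FEAM identity pre-gate max |y-2x|: {np.abs(pre.data - 2 * x).max():.2e}")

# EMA: the output is the input times a spatial map bounded in (0, 1)
ema = EMA(EmaConfig(channels=4, groups=2), rng=rng)
y = ema(Tensor(x)).data
ratio = np.abs(y[x != 0] / x[x != 0])
print(f"EMA modulation range             : ({ratio.min():.3f}, {ratio.max():.3f})")
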