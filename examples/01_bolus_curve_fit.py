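"""Fit the LDRW bolus model to a single noisy concentration curve.

Builds one synthetic bolus passage on the DSC time grid (TR = 1.92 s,
50 volumes, arrival at the 10th image), adds measurement noise, refits the
model, and prints true vs recovered parameters together with the derived
perfusion values.
"""

import numpy as np

from nawmperf import AcquisitionProtocol, fit_ldrw_voxel, ldrw_forward
from nawmperf.ldrw import ldrw_first_moment

protocol = AcquisitionProtocol()
t = np.arange(protocol.n_volumes) * protocol.tr

true = dict(A=7.6, mu=9.82, lam=5.0, t0=protocol.bolus_start_time)
curve = ldrw_forward(t, **true)
rng = np.random.default_rng(2)
noisy = curve + rng.normal(0, 0.05, curve.shape)

fit = fit_ldrw_voxel(noisy, t)
print(f"{'param':>6} {'true':>8} {'fitted':>8}")
for k in ("A", "mu", "lam", "t0"):
    print(f"{k:>6} {true[k]:8.3f} {getattr(fit, k):8.3f}")

mtt = ldrw_first_moment(fit.mu, fit.lam)
print(f"\nCBV  = A            = {fit.A:6.2f} ml/100g")
print(f"MTT  = mu(1 + 1/lam) = {mtt:6.2f} s")
print(f"CBF  = 60 CBV / MTT  = {60 * fit.A / mtt:6.2f} ml/100g/min")
print(f"r^2 = {fit.r_squared:.4f}")
# CBV is the curve area, MTT the mean transit time of the fitted density,
# and CBF follows from the central volume theorem; values are
# semi-quantitative (no arterial input function).  At TR = 1.92 s only
# ~10 samples carry bolus signal, so (mu, lam, t0) trade off along a flat
# ridge for unlucky noise draws while the area A - the CBV surrogate -
# stays well determined; map-level summaries average this scatter away.
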