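"""Quantify one rendered DSC visit and summarize NAWM perfusion.

Generates a phantom and one high-inflammatory subject, renders the first
visit's 4D DSC series, fits perfusion maps over the white-matter mask,
builds the NAWM mask (WM probability >= 0.70 minus the 2-voxel-dilated T2
lesion mask) and prints the 256-bin histogram summary next to the
subject's generating truth.
"""

import numpy as np

from nawmperf import (
    AcquisitionProtocol,
    CohortConfig,
    build_phantom,
    fit_quality_mask,
    make_nawm_mask,
    perfusion_maps,
    quantify_series,
    sample_cohort,
    simulate_lesion_masks,
    summarize_nawm,
)
from nawmperf.synthetic_data import render_dsc_series

protocol = AcquisitionProtocol()
phantom = build_phantom((64, 64, 27), seed=1)
subject = sample_cohort(CohortConfig(n_subjects=1, n_hi=1, seed=5))[0]
simulate_lesion_masks(subject, phantom, np.random.default_rng(5))

series = render_dsc_series(subject, phantom, protocol, visit=0,
                           rng=np.random.default_rng(50))
print(f"series shape {series.shape} (last axis: {series.shape[-1]} volumes)")

wm = phantom.wm_prob >= 0.70
fits = quantify_series(series, protocol, wm)
maps = perfusion_maps(fits, protocol)
quality = fit_quality_mask(fits, r2_min=0.5)
nawm = make_nawm_mask(phantom.wm_prob, subject.t2_masks[0],
                      wm_threshold=0.70, dilation_voxels=2)

cbv = summarize_nawm(maps.cbv, nawm, quality, n_bins=256)
cbf = summarize_nawm(maps.cbf, nawm, quality, n_bins=256)
print(f"WM voxels fitted: {int(wm.sum())}, kept (r^2 >= 0.5): "
      f"{int(quality.sum())}, NAWM voxels: {cbv.n_voxels}")
print(f"NAWM CBV: histogram mean {cbv.mean:.2f}, direct mean "
      f"{cbv.direct_mean:.2f}, truth {subject.visit_cbv_true[0]:.2f} ml/100g")
print(f"NAWM CBF: histogram mean {cbf.mean:.2f}, direct mean "
      f"{cbf.direct_mean:.2f}, truth {subject.visit_cbf_true[0]:.2f} "
      "ml/100g/min")
# the two means agree within half a histogram bin; recovery error on a
# single visit reflects voxel noise averaged over ~2000 NAWM voxels
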