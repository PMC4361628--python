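"""Normal-appearing white matter (NAWM) masking and summary metrics.

NAWM is white matter outside visible T2 lesions.  The mask is built by
thresholding the white-matter probability map (default 0.70) and removing
the T2 lesion mask after morphological dilation (default 2 voxels,
6-connected, one iteration per voxel), so that partial-volume rims around
lesions do not contaminate the perfusion summary.  Perfusion maps are then
summarized per visit by a 256-bin normalized histogram from which the mean
is extracted; the direct arithmetic mean is carried alongside and the two
must agree within half a bin width.

Lesion metrics: volumes in mL from voxel counts, total and *newly emerged*
gadolinium-enhancing lesion counts via 26-connected component labelling
(a current component is new iff it shares no voxel with the previous
visit's mask; at the first visit every component counts as new).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "NawmSummary",
    "LesionMetrics",
    "make_nawm_mask",
    "histogram_mean",
    "lesion_volume",
    "count_new_gd_lesions",
    "summarize_nawm",
]

#: 6-connected (face) structuring element used for dilation
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
#: 26-connected (face+edge+corner) structure used for component labelling
_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class NawmSummary:
    """Histogram summary of one perfusion map over the NAWM mask."""

    mean: float            # histogram-derived mean
    direct_mean: float     # plain arithmetic mean of the masked values
    n_voxels: int
    hist: np.ndarray       # normalized bin heights (sum to 1)
    bin_edges: np.ndarray


@dataclass
class LesionMetrics:
    """Per-visit lesion burden."""

    t2_lv: float   # mL
    t1_lv: float   # mL
    gd_lv: float   # mL
    n_gd: int      # enhancing components at this visit
    n_new_gd: int  # newly emerged enhancing components


def make_nawm_mask(wm_prob, t2_lesion_mask, wm_threshold: float = 0.70,
                   dilation_voxels: int = 2):
    """NAWM mask: thresholded WM probability minus the dilated T2 lesion mask."""
    wm_prob = np.asarray(wm_prob)
    t2 = np.asarray(t2_lesion_mask, dtype=bool)
    if wm_prob.shape != t2.shape:
        raise ValueError("wm_prob and lesion mask grids differ")
    if not 0.0 < wm_threshold < 1.0:
        raise ValueError("wm_threshold must lie in (0, 1)")
    if dilation_voxels < 0:
        raise ValueError("dilation_voxels must be >= 0")
    excluded = t2
    if dilation_voxels > 0 and t2.any():
        excluded = ndimage.binary_dilation(t2, structure=_STRUCT_6,
                                           iterations=dilation_voxels)
    return (wm_prob >= wm_threshold) & ~excluded


def histogram_mean(values, n_bins: int = 256) -> NawmSummary:
    """Normalized-histogram summary of a sample of map values.

    Bins span [min, max] of the finite sample with equal widths; heights
    are normalized to sum to 1 and the mean is read off the histogram as
    sum(height * bin center).  A degenerate sample (all values equal c)
    occupies a single bin centred at c.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty sample")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vmin, vmax = values.min(), values.max()
    # a range below float resolution at n_bins cannot form distinct edges;
    # treat it like the all-equal case (single occupied bin at the value)
    degenerate = (vmax - vmin) <= 4 * n_bins * np.finfo(float).eps * max(
        abs(vmin), abs(vmax), 1.0)
    if degenerate:
        vmin = vmax = values.mean()
        edges = np.linspace(vmin - 0.5, vmax + 0.5, n_bins + 1)
        heights, _ = np.histogram(values, bins=edges)
    else:
        heights, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    heights = heights / heights.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    hmean = float(np.sum(heights * centers)) if vmin != vmax else float(vmin)
    return NawmSummary(mean=hmean, direct_mean=float(values.mean()),
                       n_voxels=int(values.size), hist=heights, bin_edges=edges)


def lesion_volume(mask, voxel_size) -> float:
    """Lesion volume in mL: voxel count times voxel volume (mm^3) / 1000."""
    mask = np.asarray(mask, dtype=bool)
    vx = np.asarray(voxel_size, dtype=float)
    if vx.shape != (3,) or np.any(vx <= 0):
        raise ValueError("voxel_size must be three positive extents in mm")
    return float(mask.sum()) * float(np.prod(vx)) / 1000.0


def count_new_gd_lesions(gd_mask_current, gd_mask_previous=None) -> int:
    """Number of newly emerged enhancing components at the current visit.

    Components are 26-connected; a component is *new* iff it shares no
    voxel with the previous visit's mask.  With no previous visit (MRI-1)
    every component counts as new.
    """
    cur = np.asarray(gd_mask_current, dtype=bool)
    labels, n = ndimage.label(cur, structure=_STRUCT_26)
    if n == 0:
        return 0
    if gd_mask_previous is None:
        return int(n)
    prev = np.asarray(gd_mask_previous, dtype=bool)
    if prev.shape != cur.shape:
        raise ValueError("current and previous mask grids differ")
    overlapping = np.unique(labels[prev & (labels > 0)])
    return int(n - overlapping.size)


def count_gd_lesions(gd_mask) -> int:
    """Total number of 26-connected enhancing components."""
    _, n = ndimage.label(np.asarray(gd_mask, dtype=bool), structure=_STRUCT_26)
    return int(n)


def summarize_nawm(parameter_map, nawm_mask, valid_mask=None,
                   n_bins: int = 256) -> NawmSummary:
    """Histogram summary of a perfusion map over NAWM (and valid-fit) voxels."""
    nawm = np.asarray(nawm_mask, dtype=bool)
    sel = nawm if valid_mask is None else nawm & np.asarray(valid_mask, dtype=bool)
    return histogram_mean(np.asarray(parameter_map)[sel], n_bins=n_bins)
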