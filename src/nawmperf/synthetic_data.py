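"""Seeded synthetic MS perfusion cohorts.

Generates everything the downstream analysis consumes, with the statistical
structure of a 33-subject, 4-monthly-visit relapsing-remitting MS cohort
with two latent inflammatory groups:

* a tissue phantom (concentric ellipsoids: brain mask, cortical GM shell,
  WM core) standing in for structural segmentations;
* per-subject ground-truth NAWM perfusion trajectories: group-dependent
  marginal means (CBV 9.1 vs 7.6 ml/100g, CBF 43.7 vs 38.7 ml/100g/min for
  the high-/low-inflammatory group), a common monotone visit decline, and a
  Gaussian between-subject random intercept;
* lesion dynamics: chronic T2 lesions (with a T1-hypointense subset), one
  prevalent enhancing lesion per subject whose volume decays by a fixed
  factor per visit, and transient incident enhancing lesions whose per-visit
  counts drive the high-inflammatory stratification rule;
* DSC signal series rendered voxelwise through the LDRW bolus model with
  slice-time offsets, multiplicative voxel-level perfusion scatter and
  additive Gaussian signal noise.

High-inflammatory subjects draw their per-visit incident-lesion count from
a shifted Poisson, 1 + Poisson(rate - 1), so that the defining criterion
(>= 1 new enhancing lesion in >= 3 of 4 scans) holds by construction while
the configured expected count per visit is preserved.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .ldrw import _batch_model_and_jac
from .protocol import AcquisitionProtocol

__all__ = [
    "CohortConfig",
    "TissuePhantom",
    "SubjectGroundTruth",
    "build_phantom",
    "sample_cohort",
    "ldrw_forward",
    "render_dsc_series",
    "simulate_lesion_masks",
    "write_cohort",
    "read_manifest",
]

# the LDRW forward model is shared with the quantifier; re-exported here
# because the generator is its other consumer
from .ldrw import ldrw_forward  # noqa: E402  (re-export)

#: fixed skewness of every synthetic bolus curve
LAMBDA_SYNTH = 5.0
#: baseline signal level of the rendered series (arbitrary units)
S0_SYNTH = 100.0

# Internal spread/range constants of the clinical covariates (group order
# HI, LI); means are configurable, these shape parameters are not.
_AGE = dict(mean=(35.6, 39.0), sd=(9.0, 10.0), lo=18.0, hi=(49.0, 56.0))
_SEX_P_FEMALE = (10 / 13, 16 / 20)
_DD = dict(mean=(5.44, 3.47), sd=(5.00, 4.69))
_EDSS = dict(sd=0.5, lo=1.0, hi=(2.5, 3.0))
_GMV_SD = 48.0
_WMV_SD = 29.0
# lesion-volume spread as coefficients of variation, so that configs with
# scaled-down volume means keep a proportionate between-subject scatter
_T2LV_CV = (3.86 / 5.47, 3.21 / 3.07)
_T1LV_CV = (0.69 / 0.46, 2.00 / 0.92)
_GDLV_CV = 0.5


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the reference study conditions: 33 subjects of whom
    13 are high-inflammatory, four monthly visits, the published group
    marginal means and visit declines for NAWM CBV/CBF, Table-1 lesion and
    volumetric means, and enhancing-lesion dynamics calibrated to the
    13/33 stratification split and the 60.9% visit-1-to-2 Gd-volume drop
    (retained fraction 0.391).
    """

    n_subjects: int = 33
    n_hi: int = 13
    n_visits: int = 4
    visit_interval: float = 1.0  # months
    cbv_marginal_mean_hi: float = 9.1   # ml/100g
    cbv_marginal_mean_lo: float = 7.6
    cbf_marginal_mean_hi: float = 43.7  # ml/100g/min
    cbf_marginal_mean_lo: float = 38.7
    cbv_visit_offsets: tuple = (0.0, -0.2, -0.6, -0.9)
    cbf_visit_offsets: tuple = (0.0, -1.0, -3.5, -5.1)
    between_subject_sd_cbv: float = 0.8
    between_subject_sd_cbf: float = 4.0
    voxel_noise_sd_fraction: float = 0.05
    signal_noise_sd: float = 0.01     # fraction of baseline signal
    gd_rate_hi: float = 1.5           # expected new Gd lesions per visit
    gd_rate_lo: float = 0.15
    gdlv_visit_decay: float = 0.391   # Gd-LV fraction retained per visit
    t2lv_mean_hi: float = 5.47        # mL
    t2lv_mean_lo: float = 3.07
    t1lv_mean_hi: float = 0.46
    t1lv_mean_lo: float = 0.92
    gdlv_mean_hi: float = 0.15
    gdlv_mean_lo: float = 0.02
    gmv_mean: float = 831.0
    wmv_mean: float = 729.0
    edss_mean_hi: float = 1.58
    edss_mean_lo: float = 2.03
    seed: int = 0

    def __post_init__(self):
        if self.n_hi > self.n_subjects:
            raise ValueError("n_hi cannot exceed n_subjects")
        if self.n_visits < 1:
            raise ValueError("need at least one visit")
        for name in ("between_subject_sd_cbv", "between_subject_sd_cbf",
                     "voxel_noise_sd_fraction", "signal_noise_sd",
                     "gd_rate_hi", "gd_rate_lo", "gdlv_visit_decay",
                     "t2lv_mean_hi", "t2lv_mean_lo", "t1lv_mean_hi",
                     "t1lv_mean_lo", "gdlv_mean_hi", "gdlv_mean_lo",
                     "gmv_mean", "wmv_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("cbv_visit_offsets", "cbf_visit_offsets"):
            off = tuple(getattr(self, name))
            object.__setattr__(self, name, off)
            if len(off) != self.n_visits:
                raise ValueError(f"{name} must have one entry per visit")
            if off[0] != 0:
                raise ValueError(f"{name} must start at 0 (reference visit)")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in dataclasses.asdict(self).items()},
                fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cbv_visit_offsets", "cbf_visit_offsets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TissuePhantom:
    """Ellipsoidal head phantom with tissue probability maps."""

    grid_shape: tuple
    voxel_size: tuple
    wm_prob: np.ndarray
    gm_prob: np.ndarray
    brain_mask: np.ndarray

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass
class SubjectGroundTruth:
    """Latent state of one synthetic subject.

    Lesion masks are ``None`` until realized by
    :func:`simulate_lesion_masks` (mask realization needs a phantom grid).
    """

    subject_id: str
    group: str                      # "HI" or "LI"
    age: float
    sex: str                        # "F" or "M"
    edss: float
    disease_duration: float
    gmv: float                      # mL
    wmv: float                      # mL
    visit_cbv_true: np.ndarray      # per-visit NAWM mean, ml/100g
    visit_cbf_true: np.ndarray      # per-visit NAWM mean, ml/100g/min
    n_new_gd: np.ndarray            # per-visit newly emerged component count
    gd_volume_targets: np.ndarray   # per-visit total Gd-LV target, mL
    t2_volume_target: float         # chronic T2 lesion volume target, mL
    t1_volume_target: float         # T1-hypointense subset target, mL
    seed: int
    t2_masks: list | None = field(default=None, repr=False)
    t1_masks: list | None = field(default=None, repr=False)
    gd_masks: list | None = field(default=None, repr=False)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def build_phantom(grid_shape=(64, 64, 27), seed: int = 0,
                  voxel_size=(1.9, 1.9, 4.0)) -> TissuePhantom:
    """Concentric-ellipsoid tissue phantom.

    An outer brain ellipsoid with a cortical gray-matter shell and an
    interior white-matter core whose probability falls off smoothly at the
    edge; at the default 64 x 64 x 27 grid the WM mask at threshold 0.70
    holds roughly 3000 voxels and the core (wm_prob >= 0.9) roughly 2400.
    The seed perturbs the ellipsoid centre/axes slightly so distinct seeds
    give distinct (but statistically equivalent) anatomies.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or any(g < 16 for g in grid_shape):
        raise ValueError("each grid dimension must be >= 16")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    center = np.array(grid_shape, dtype=float) / 2.0 - 0.5 + rng.uniform(-1, 1, 3)
    a_brain = 0.45 * np.array(grid_shape, dtype=float) * rng.uniform(0.98, 1.02, 3)
    a_wm = 0.44 * a_brain * rng.uniform(0.97, 1.03, 3)

    ii = np.indices(grid_shape, dtype=float)
    r_brain = np.sqrt(sum(((ii[d] - center[d]) / a_brain[d]) ** 2 for d in range(3)))
    r_wm = np.sqrt(sum(((ii[d] - center[d]) / a_wm[d]) ** 2 for d in range(3)))

    brain_mask = r_brain <= 1.0
    wm_prob = _sigmoid((1.0 - r_wm) / 0.06) * brain_mask
    gm_prob = (1.0 - wm_prob) * _sigmoid((1.0 - r_brain) / 0.04) * brain_mask
    return TissuePhantom(grid_shape=grid_shape, voxel_size=tuple(voxel_size),
                         wm_prob=wm_prob, gm_prob=gm_prob,
                         brain_mask=brain_mask)


def _truncnorm_at_zero(rng, mean, sd):
    """One draw from a normal truncated to (0, inf)."""
    if sd == 0:
        return float(max(mean, 0.0))
    a = -mean / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                               random_state=rng))


def _new_count(rng, rate):
    """Per-visit incident enhancing-lesion count.

    Rates above 1 use the shifted form 1 + Poisson(rate - 1): the expected
    count equals ``rate`` while at least one new lesion per visit is
    guaranteed, which makes the high-inflammatory criterion hold by
    construction.
    """
    if rate >= 1.0:
        return 1 + int(rng.poisson(rate - 1.0))
    return int(rng.poisson(rate))


def sample_cohort(config: CohortConfig) -> list[SubjectGroundTruth]:
    """Draw the latent ground truth for every subject of a cohort.

    The first ``n_hi`` subjects are high-inflammatory.  Per-visit true NAWM
    means are ``group marginal mean - mean(visit_offsets) + visit_offset +
    subject random intercept``, so the across-visit average equals the
    group marginal mean in expectation (exactly, when the between-subject
    SD is zero).
    """
    cfg = config
    n_visits = cfg.n_visits
    decay_w = cfg.gdlv_visit_decay ** np.arange(n_visits)
    gd_v1_factor = 1.0 / decay_w.mean()  # across-visit mean -> visit-1 mean

    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_subjects, np.uint32)
    subjects = []
    for i in range(cfg.n_subjects):
        hi = i < cfg.n_hi
        g = 0 if hi else 1
        rng = np.random.default_rng(np.random.SeedSequence([int(seeds[i]), 1]))

        cbv_marg = cfg.cbv_marginal_mean_hi if hi else cfg.cbv_marginal_mean_lo
        cbf_marg = cfg.cbf_marginal_mean_hi if hi else cfg.cbf_marginal_mean_lo
        off_cbv = np.asarray(cfg.cbv_visit_offsets, dtype=float)
        off_cbf = np.asarray(cfg.cbf_visit_offsets, dtype=float)
        b_cbv = rng.normal(0.0, cfg.between_subject_sd_cbv)
        b_cbf = rng.normal(0.0, cfg.between_subject_sd_cbf)
        cbv_true = cbv_marg - off_cbv.mean() + off_cbv + b_cbv
        cbf_true = cbf_marg - off_cbf.mean() + off_cbf + b_cbf

        age = float(np.clip(rng.normal(_AGE["mean"][g], _AGE["sd"][g]),
                            _AGE["lo"], _AGE["hi"][g]))
        sex = "F" if rng.random() < _SEX_P_FEMALE[g] else "M"
        edss_mean = cfg.edss_mean_hi if hi else cfg.edss_mean_lo
        edss = float(np.clip(rng.normal(edss_mean, _EDSS["sd"]),
                             _EDSS["lo"], _EDSS["hi"][g]))
        edss = round(edss * 2.0) / 2.0
        dd = max(float(rng.normal(_DD["mean"][g], _DD["sd"][g])), 0.1)
        gmv = float(rng.normal(cfg.gmv_mean, _GMV_SD))
        wmv = float(rng.normal(cfg.wmv_mean, _WMV_SD))

        rate = cfg.gd_rate_hi if hi else cfg.gd_rate_lo
        # visit 1 additionally counts the prevalent enhancing lesion as new
        # (subjects with any enhancing activity carry one at study entry)
        n_new = np.array(
            [_new_count(rng, rate) + (1 if (v == 0 and 0 < rate < 1.0) else 0)
             for v in range(n_visits)], dtype=int)

        gdlv_mean = cfg.gdlv_mean_hi if hi else cfg.gdlv_mean_lo
        if rate > 0 and gdlv_mean > 0:
            v1 = _truncnorm_at_zero(rng, gdlv_mean * gd_v1_factor,
                                    _GDLV_CV * gdlv_mean * gd_v1_factor)
        else:
            v1 = 0.0
        gd_targets = v1 * decay_w

        t2_mean = cfg.t2lv_mean_hi if hi else cfg.t2lv_mean_lo
        t1_mean = cfg.t1lv_mean_hi if hi else cfg.t1lv_mean_lo
        t2_target = _truncnorm_at_zero(rng, t2_mean, _T2LV_CV[g] * t2_mean)
        t1_target = min(_truncnorm_at_zero(rng, t1_mean, _T1LV_CV[g] * t1_mean),
                        0.9 * t2_target)

        subjects.append(SubjectGroundTruth(
            subject_id=f"S{i + 1:02d}",
            group="HI" if hi else "LI",
            age=age, sex=sex, edss=edss, disease_duration=dd,
            gmv=gmv, wmv=wmv,
            visit_cbv_true=cbv_true, visit_cbf_true=cbf_true,
            n_new_gd=n_new, gd_volume_targets=gd_targets,
            t2_volume_target=t2_target, t1_volume_target=t1_target,
            seed=int(seeds[i]),
        ))
    return subjects


def _core_neighbors(idx):
    """26-neighbourhood adjacency (list of arrays) among core voxels."""
    lookup = {tuple(p): j for j, p in enumerate(idx)}
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]
    neigh = []
    for p in idx:
        ns = [lookup[q] for o in offsets
              if (q := (p[0] + o[0], p[1] + o[1], p[2] + o[2])) in lookup]
        neigh.append(np.array(ns, dtype=np.int64))
    return neigh


def _grow_region(coords_mm, neigh, allowed, center_idx, k):
    """Grow a 26-connected region of up to k allowed voxels, nearest-first.

    Best-first expansion from the centre guarantees that every prefix of
    the returned ordering is itself connected, which is what the nested
    shrinkage of the prevalent enhancing lesion relies on.
    """
    import heapq

    if not allowed[center_idx]:
        return np.empty(0, dtype=np.int64)
    c = coords_mm[center_idx]
    heap = [(0.0, int(center_idx))]
    in_heap = {int(center_idx)}
    region = []
    taken = set()
    while heap and len(region) < k:
        _, j = heapq.heappop(heap)
        if j in taken or not allowed[j]:
            continue
        region.append(j)
        taken.add(j)
        for q in neigh[j]:
            qi = int(q)
            if qi not in taken and qi not in in_heap and allowed[qi]:
                heapq.heappush(heap, (float(np.linalg.norm(coords_mm[qi] - c)), qi))
                in_heap.add(qi)
    return np.array(region, dtype=np.int64)


def simulate_lesion_masks(subject: SubjectGroundTruth, phantom: TissuePhantom,
                          rng) -> SubjectGroundTruth:
    """Realize per-visit T2/T1/Gd lesion masks inside the WM core.

    Chronic T2 lesions are quasi-spherical voxel balls placed once; a
    subset of whole lesions forms the T1-hypointense mask.  Enhancing (Gd)
    lesions comprise one prevalent component whose voxel count follows the
    subject's decaying volume target (shrinking concentrically, so each
    visit's extent nests inside the previous one) plus transient incident
    components (1-3 voxels, one visit long) that realize the new-lesion
    counts; incident components are placed with a one-voxel 26-connectivity
    margin from the previous and current Gd mask, so component counting
    reproduces the ground-truth counts exactly.  The per-visit T2 mask is
    the chronic mask united with that visit's Gd mask, which enforces the
    Gd-within-T2 nesting invariant.
    """
    core = phantom.wm_prob >= 0.9
    n_core = int(core.sum())
    if n_core < 50:
        raise ValueError("phantom has insufficient WM core volume for lesions")
    vox_ml = phantom.voxel_volume_ml
    cache = getattr(phantom, "_core_cache", None)
    if cache is None:
        idx = np.array(np.nonzero(core)).T                  # (n_core, 3)
        coords_mm = idx * np.asarray(phantom.voxel_size)
        neigh = _core_neighbors([tuple(p) for p in idx])
        phantom._core_cache = cache = (idx, coords_mm, neigh)
    idx, coords_mm, neigh = cache
    shape = phantom.grid_shape
    n_visits = len(subject.gd_volume_targets)

    free = np.ones(n_core, dtype=bool)

    # --- chronic T2 lesions -------------------------------------------------
    # keep a free-voxel reserve so enhancing lesions can always be placed,
    # even when a heavy-tailed T2 volume draw exceeds a small phantom core
    reserve = 60
    t2_goal = min(int(round(subject.t2_volume_target / vox_ml)),
                  max(n_core - reserve, 0))
    lesions = []
    while t2_goal > 0 and free.sum() > reserve:
        size = int(np.clip(round(rng.lognormal(np.log(25.0), 0.6)), 3, 120))
        size = min(size, t2_goal) if t2_goal >= 3 else t2_goal
        size = min(size, int(free.sum()) - reserve)
        if size < 1:
            break
        center = rng.choice(np.flatnonzero(free))
        chosen = _grow_region(coords_mm, neigh, free, center, max(size, 1))
        if chosen.size == 0:
            break
        free[chosen] = False
        lesions.append(chosen)
        t2_goal -= chosen.size
    t2_base = np.zeros(shape, dtype=bool)
    for les in lesions:
        t2_base[tuple(idx[les].T)] = True

    # T1-hypointense subset: whole lesions until the target is covered
    t1_goal = int(round(subject.t1_volume_target / vox_ml))
    t1_mask = np.zeros(shape, dtype=bool)
    for les in rng.permutation(len(lesions)) if lesions else []:
        if t1_goal <= 0:
            break
        t1_mask[tuple(idx[lesions[les]].T)] = True
        t1_goal -= lesions[les].size

    # --- enhancing lesions --------------------------------------------------
    # prevalent component (present iff the subject has any enhancing
    # activity at study entry): connected nearest-first ordering, so taking
    # any prefix yields a nested, connected shrinking lesion
    has_prevalent = int(subject.n_new_gd[0]) >= 1
    if has_prevalent:
        pers_center = int(rng.choice(np.flatnonzero(free))) if free.any() else 0
        max_pers = int(round(subject.gd_volume_targets[0] / vox_ml)) + 2
        pers_order = _grow_region(coords_mm, neigh, free, pers_center,
                                  max(max_pers, 1))
    else:
        pers_order = np.empty(0, dtype=np.int64)

    from scipy import ndimage  # local import to avoid cycle at module load
    struct26 = ndimage.generate_binary_structure(3, 3)

    gd_masks = []
    prev_mask = None
    prev_pers = None
    for v in range(n_visits):
        target_vox = int(round(subject.gd_volume_targets[v] / vox_ml))
        n_incident = int(subject.n_new_gd[v]) - (1 if (v == 0 and has_prevalent) else 0)
        incident_sizes = [int(rng.integers(1, 4)) for _ in range(n_incident)]
        pers_n = max(1, target_vox - sum(incident_sizes)) if has_prevalent else 0
        if prev_pers is not None:
            pers_n = min(pers_n, prev_pers)      # nested shrinkage
        pers_n = min(pers_n, pers_order.size)
        cur = np.zeros(shape, dtype=bool)
        cur[tuple(idx[pers_order[:pers_n]].T)] = True
        prev_pers = pers_n

        blocked = cur if prev_mask is None else (cur | prev_mask)
        blocked = ndimage.binary_dilation(blocked, structure=struct26)
        for size in incident_sizes:
            allowed = free & ~blocked[tuple(idx.T)] & ~t2_base[tuple(idx.T)]
            cand = np.flatnonzero(allowed)
            if cand.size == 0:
                raise ValueError("insufficient WM volume to place lesions")
            center = int(rng.choice(cand))
            chosen = _grow_region(coords_mm, neigh, allowed, center, size)
            cur[tuple(idx[chosen].T)] = True
            newly = np.zeros(shape, dtype=bool)
            newly[tuple(idx[chosen].T)] = True
            blocked |= ndimage.binary_dilation(newly, structure=struct26)
        gd_masks.append(cur)
        prev_mask = cur

    subject.gd_masks = gd_masks
    subject.t1_masks = [t1_mask.copy() for _ in range(n_visits)]
    subject.t2_masks = [t2_base | gd for gd in gd_masks]
    return subject


def render_dsc_series(subject: SubjectGroundTruth, phantom: TissuePhantom,
                      protocol: AcquisitionProtocol, visit: int, rng,
                      voxel_sd_fraction: float = 0.05,
                      signal_noise_sd: float = 0.01,
                      wm_threshold: float = 0.70,
                      background_noise: bool = True) -> np.ndarray:
    """Render one visit's 4D DSC signal series.

    Every WM voxel (wm_prob >= ``wm_threshold``) draws a voxel-level CBV
    and CBF around the subject's visit-level true means with fractional SD
    ``voxel_sd_fraction``, synthesizes its LDRW bolus curve on its slice's
    acquisition time grid, and converts to signal S = S0 * exp(-te * C)
    plus Gaussian noise of SD ``signal_noise_sd`` times baseline.  Non-WM
    voxels carry the baseline plus noise (no gray-matter perfusion model);
    ``background_noise=False`` leaves them flat, which is a pure speed
    optimization for mask-restricted quantification.
    """
    if not 0 <= visit < len(subject.visit_cbv_true):
        raise ValueError(f"visit index {visit} out of range")
    if protocol.n_volumes < protocol.bolus_start_index + 10:
        raise ValueError("protocol too short: need >= 10 post-bolus volumes")
    vox_frac = voxel_sd_fraction
    sig_sd = signal_noise_sd * S0_SYNTH

    shape = phantom.grid_shape
    series = np.full(shape + (protocol.n_volumes,), S0_SYNTH, dtype=np.float64)
    wm = phantom.wm_prob >= wm_threshold
    ix, iy, iz = np.nonzero(wm)
    n = ix.size

    cbv_v = float(subject.visit_cbv_true[visit])
    cbf_v = float(subject.visit_cbf_true[visit])
    cbv = np.maximum(rng.normal(cbv_v, vox_frac * cbv_v, n), 0.05 * cbv_v)
    cbf = np.maximum(rng.normal(cbf_v, vox_frac * cbf_v, n), 0.05 * cbf_v)
    mtt = 60.0 * cbv / cbf
    mu = mtt / (1.0 + 1.0 / LAMBDA_SYNTH)
    theta = np.stack([cbv, mu, np.full(n, LAMBDA_SYNTH),
                      np.full(n, protocol.bolus_start_time)], axis=1)

    k = np.arange(protocol.n_volumes, dtype=float)
    t_vox = (k[None, :] * protocol.tr
             + (iz * (protocol.tr / protocol.n_slices))[:, None])
    conc, _ = _batch_model_and_jac(theta, t_vox, jac=False)
    series[ix, iy, iz, :] = S0_SYNTH * np.exp(-protocol.te * conc)

    if sig_sd > 0:
        # WM noise is drawn first with a fixed call shape, so the WM signal
        # is identical whether or not background noise is rendered
        series[ix, iy, iz, :] += rng.normal(0.0, sig_sd,
                                            (n, protocol.n_volumes))
        if background_noise:
            bg = rng.normal(0.0, sig_sd, series.shape)
            bg[ix, iy, iz, :] = 0.0
            series += bg
    return series


# ---------------------------------------------------------------------------
# cohort I/O

_CLINICAL_HEADER = ["subject_id", "visit", "group_true", "age", "sex", "edss",
                    "disease_duration", "gmv_ml", "wmv_ml"]


def _nifti(data, voxel_size, dtype):
    affine = np.diag(list(voxel_size) + [1.0])
    return nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)


def write_cohort(cohort, phantom: TissuePhantom, protocol: AcquisitionProtocol,
                 out_dir, config: CohortConfig | None = None,
                 include_series: bool = True) -> pd.DataFrame:
    """Write a cohort to disk in standard formats.

    NIfTI-1 volumes (masks as uint8, series as float32, voxel size in the
    header), a comma-separated clinical table, a ground-truth sidecar and a
    manifest listing every file with its subject, visit and role.  DSC
    series are rendered here with per-subject-visit seeds derived from the
    subject seeds, so re-running with the same cohort reproduces every
    array bit-exactly.  Returns the manifest as a DataFrame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vx = phantom.voxel_size
    rows = []

    def save(name, data, dtype, sid="", visit="", role=""):
        nib.save(_nifti(data, vx, dtype), out / name)
        rows.append((sid, visit, role, name))

    save("wm_prob.nii", phantom.wm_prob, np.float32, role="wm_prob")
    save("gm_prob.nii", phantom.gm_prob, np.float32, role="gm_prob")
    save("brain_mask.nii", phantom.brain_mask, np.uint8, role="brain_mask")

    clin = []
    truth = []
    for subj in cohort:
        if subj.t2_masks is None:
            raise ValueError(f"{subj.subject_id}: lesion masks not realized")
        for v in range(len(subj.t2_masks)):
            tag = f"{subj.subject_id}_v{v + 1}"
            save(f"t2_{tag}.nii", subj.t2_masks[v], np.uint8,
                 subj.subject_id, v + 1, "t2_mask")
            save(f"t1_{tag}.nii", subj.t1_masks[v], np.uint8,
                 subj.subject_id, v + 1, "t1_mask")
            save(f"gd_{tag}.nii", subj.gd_masks[v], np.uint8,
                 subj.subject_id, v + 1, "gd_mask")
            if include_series:
                rng = np.random.default_rng(
                    np.random.SeedSequence([subj.seed, 1000 + v]))
                kw = {}
                if config is not None:
                    kw = dict(voxel_sd_fraction=config.voxel_noise_sd_fraction,
                              signal_noise_sd=config.signal_noise_sd)
                series = render_dsc_series(subj, phantom, protocol, v, rng, **kw)
                save(f"dsc_{tag}.nii", series, np.float32,
                     subj.subject_id, v + 1, "dsc_series")
            clin.append([subj.subject_id, v + 1, subj.group, subj.age,
                         subj.sex, subj.edss, subj.disease_duration,
                         subj.gmv, subj.wmv])
            truth.append([subj.subject_id, v + 1, subj.group,
                          subj.visit_cbv_true[v], subj.visit_cbf_true[v],
                          int(subj.n_new_gd[v])])

    with open(out / "clinical.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CLINICAL_HEADER)
        w.writerows(clin)
    rows.append(("", "", "clinical", "clinical.csv"))
    with open(out / "truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "visit", "group_true", "cbv_true",
                    "cbf_true", "n_new_gd"])
        w.writerows(truth)
    rows.append(("", "", "ground_truth", "truth.csv"))
    if config is not None:
        config.to_yaml(out / "cohort_config.yaml")
        rows.append(("", "", "config", "cohort_config.yaml"))

    manifest = pd.DataFrame(rows, columns=["subject_id", "visit", "role",
                                           "filename"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_manifest(cohort_dir) -> pd.DataFrame:
    path = Path(cohort_dir) / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no manifest at {path}")
    return pd.read_csv(path, keep_default_na=False)
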