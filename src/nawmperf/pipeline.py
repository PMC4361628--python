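"""Cohort pipeline: synthesis -> quantification -> NAWM metrics -> statistics.

Two execution styles share the same stages:

* an in-memory path (:func:`run_cohort`, :func:`replicate_study`) used for
  replicate effect-recovery studies, where no intermediate volume touches
  disk and quantification is restricted to the NAWM mask (voxelwise fits
  are independent, so this is exactly equivalent to fitting the full
  thresholded-WM mask and masking afterwards);
* a file-based path (:func:`run_synthesis`, :func:`run_pipeline`) that
  writes/reads NIfTI volumes and delimited tables through a manifest, so
  stages can be re-run independently on stored cohorts.

All randomness flows from named seeds in the configuration; there is no
global random state, and a fixed configuration reproduces every output
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from . import nawm_metrics as nm
from .dsc_quant import (
    AcquisitionProtocol,
    fit_quality_mask,
    perfusion_maps,
    quantify_series,
)
from .synthetic_data import (
    CohortConfig,
    SubjectGroundTruth,
    TissuePhantom,
    build_phantom,
    read_manifest,
    render_dsc_series,
    sample_cohort,
    simulate_lesion_masks,
    write_cohort,
)

__all__ = [
    "PipelineConfig",
    "CohortResult",
    "ReplicateSummary",
    "run_cohort",
    "replicate_study",
    "run_synthesis",
    "run_pipeline",
]

LONG_TABLE_COLUMNS = [
    "subject_id", "visit", "group", "group_true", "cbv_nawm", "cbf_nawm",
    "n_voxels_nawm", "t2_lv", "t1_lv", "gd_lv", "n_gd", "n_new_gd",
    "gmv", "wmv", "edss", "age", "sex", "disease_duration",
]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults reproduce the study settings
    (WM threshold 0.70, 2-voxel lesion dilation, 256 histogram bins)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    grid_shape: tuple = (64, 64, 27)
    wm_threshold: float = 0.70
    dilation_voxels: int = 2
    n_bins: int = 256
    r2_min: float = 0.5
    output_dir: str | None = None
    replicate_seeds: tuple = tuple(range(1, 21))

    def __post_init__(self):
        if not 0 < self.wm_threshold < 1:
            raise ValueError("wm_threshold must lie in (0, 1)")
        if self.dilation_voxels < 0 or self.n_bins < 2:
            raise ValueError("invalid dilation_voxels or n_bins")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must lie in [0, 1]")


@dataclass
class CohortResult:
    """Everything one cohort analysis produces."""

    long_table: pd.DataFrame
    time_models: dict            # outcome -> MixedModelResult (visit only)
    group_models: dict           # outcome -> MixedModelResult (group + visit)
    adjusted_models: dict        # outcome -> MixedModelResult (Table-2 layout)
    marginal_means: dict         # outcome -> {group: (est, lo, hi)}
    gd_log_model: cs.MixedModelResult
    gd_pct_change_v2: tuple      # (% decrease, ci_low, ci_high)
    baseline_table: pd.DataFrame
    hi_fraction: float
    n_stratification_agree: int


@dataclass
class ReplicateSummary:
    """Replicate means of the headline quantities across seeded cohorts."""

    per_cohort: pd.DataFrame

    def mean(self, column: str) -> float:
        return float(self.per_cohort[column].mean())


def _visit_rows(subject: SubjectGroundTruth, phantom: TissuePhantom,
                cfg: PipelineConfig, fit_wm_mask=None, fast: bool = True):
    """Quantify all visits of one subject; yields long-table row dicts."""
    proto = cfg.protocol
    wm = phantom.wm_prob
    prev_gd = None
    n_visits = len(subject.visit_cbv_true)
    for v in range(n_visits):
        nawm = nm.make_nawm_mask(wm, subject.t2_masks[v], cfg.wm_threshold,
                                 cfg.dilation_voxels)
        rng = np.random.default_rng(
            np.random.SeedSequence([subject.seed, 1000 + v]))
        series = render_dsc_series(
            subject, phantom, proto, v, rng,
            voxel_sd_fraction=cfg.cohort.voxel_noise_sd_fraction,
            signal_noise_sd=cfg.cohort.signal_noise_sd,
            background_noise=not fast)
        fit_mask = nawm if fast else (
            fit_wm_mask if fit_wm_mask is not None else wm >= cfg.wm_threshold)
        fits = quantify_series(series, proto, fit_mask)
        quality = fit_quality_mask(fits, cfg.r2_min)
        maps = perfusion_maps(fits, proto)
        cbv_sum = nm.summarize_nawm(maps.cbv, nawm, quality, cfg.n_bins)
        cbf_sum = nm.summarize_nawm(maps.cbf, nawm, quality, cfg.n_bins)
        vx = phantom.voxel_size
        n_new = nm.count_new_gd_lesions(subject.gd_masks[v], prev_gd)
        yield dict(
            subject_id=subject.subject_id, visit=v + 1,
            group_true=subject.group,
            cbv_nawm=cbv_sum.direct_mean, cbf_nawm=cbf_sum.direct_mean,
            cbv_hist_mean=cbv_sum.mean, cbf_hist_mean=cbf_sum.mean,
            n_voxels_nawm=cbv_sum.n_voxels,
            t2_lv=nm.lesion_volume(subject.t2_masks[v], vx),
            t1_lv=nm.lesion_volume(subject.t1_masks[v], vx),
            gd_lv=nm.lesion_volume(subject.gd_masks[v], vx),
            n_gd=nm.count_gd_lesions(subject.gd_masks[v]),
            n_new_gd=n_new,
            gmv=subject.gmv, wmv=subject.wmv, edss=subject.edss,
            age=subject.age, sex=subject.sex,
            disease_duration=subject.disease_duration,
        )
        prev_gd = subject.gd_masks[v]


def _fit_all_models(table: pd.DataFrame) -> dict:
    out = {}
    out["time_models"] = {
        y: cs.fit_random_intercept_model(table, y, ("visit",))
        for y in ("cbv_nawm", "cbf_nawm")
    }
    out["group_models"] = {
        y: cs.fit_random_intercept_model(table, y, ("group", "visit"))
        for y in ("cbv_nawm", "cbf_nawm")
    }
    out["marginal_means"] = {
        y: cs.marginal_group_means(out["group_models"][y], table)
        for y in ("cbv_nawm", "cbf_nawm")
        if out["group_models"][y].converged
    }
    out["adjusted_models"] = {
        y: cs.adjusted_group_model(table, y) for y in ("cbv_nawm", "cbf_nawm")
    }
    gd_log = cs.fit_random_intercept_model(table, "gd_lv", ("visit",),
                                           scale="log")
    out["gd_log_model"] = gd_log
    try:
        c2 = gd_log.visit_coefficient(2)
        out["gd_pct_change_v2"] = cs.percent_change(c2.beta, c2.ci_low,
                                                    c2.ci_high)
    except KeyError:
        out["gd_pct_change_v2"] = (np.nan, np.nan, np.nan)
    return out


def analyze_long_table(table: pd.DataFrame) -> CohortResult:
    """Stratify and fit every model on an assembled visit-level table."""
    strat = (table.sort_values("visit").groupby("subject_id")["n_new_gd"]
             .apply(lambda c: cs.stratify_subject(c.to_numpy())))
    table = table.copy()
    table["group"] = table["subject_id"].map(strat)
    models = _fit_all_models(table)
    subj = cs.subject_level_table(table)
    baseline = cs.baseline_comparison(subj) if subj["group"].nunique() == 2 \
        else pd.DataFrame()
    agree = int((table.groupby("subject_id")[["group", "group_true"]]
                 .first().eval("group == group_true")).sum())
    return CohortResult(
        long_table=table,
        time_models=models["time_models"],
        group_models=models["group_models"],
        adjusted_models=models["adjusted_models"],
        marginal_means=models["marginal_means"],
        gd_log_model=models["gd_log_model"],
        gd_pct_change_v2=models["gd_pct_change_v2"],
        baseline_table=baseline,
        hi_fraction=float((strat == "HI").mean()),
        n_stratification_agree=agree,
    )


def run_cohort(cfg: PipelineConfig, fast: bool = True) -> CohortResult:
    """Generate and analyze one synthetic cohort fully in memory.

    ``fast=True`` restricts voxelwise fitting to the NAWM mask and skips
    background-noise rendering outside white matter; both are exact
    optimizations for the downstream statistics.
    """
    phantom = build_phantom(cfg.grid_shape, seed=cfg.cohort.seed,
                            voxel_size=cfg.protocol.voxel_size)
    subjects = sample_cohort(cfg.cohort)
    rows = []
    for subj in subjects:
        rng = np.random.default_rng(np.random.SeedSequence([subj.seed, 101]))
        simulate_lesion_masks(subj, phantom, rng)
        rows.extend(_visit_rows(subj, phantom, cfg, fast=fast))
        subj.t2_masks = subj.t1_masks = subj.gd_masks = None  # free memory
    return analyze_long_table(pd.DataFrame(rows))


def replicate_study(cfg: PipelineConfig | None = None, seeds=None,
                    progress=None) -> ReplicateSummary:
    """Run seeded replicate cohorts and collect the headline estimates.

    Returns one row per cohort with the HI/LI marginal mean CBV/CBF, the
    visit-4 time coefficients, the HI fraction, the Gd-LV visit-2 percent
    decrease, and the adjusted group coefficients.
    """
    cfg = cfg or PipelineConfig()
    seeds = list(cfg.replicate_seeds if seeds is None else seeds)
    recs = []
    for s in seeds:
        c = dataclasses.replace(cfg, cohort=dataclasses.replace(cfg.cohort, seed=int(s)))
        t0 = time.time()
        res = run_cohort(c)
        mm_cbv = res.marginal_means.get("cbv_nawm", {})
        mm_cbf = res.marginal_means.get("cbf_nawm", {})
        rec = dict(
            seed=int(s),
            cbv_mm_hi=mm_cbv.get("HI", (np.nan,) * 3)[0],
            cbv_mm_lo=mm_cbv.get("LI", (np.nan,) * 3)[0],
            cbf_mm_hi=mm_cbf.get("HI", (np.nan,) * 3)[0],
            cbf_mm_lo=mm_cbf.get("LI", (np.nan,) * 3)[0],
            cbv_visit4_beta=res.time_models["cbv_nawm"].visit_coefficient(4).beta,
            cbf_visit4_beta=res.time_models["cbf_nawm"].visit_coefficient(4).beta,
            cbv_visit3_beta=res.time_models["cbv_nawm"].visit_coefficient(3).beta,
            cbf_visit3_beta=res.time_models["cbf_nawm"].visit_coefficient(3).beta,
            hi_fraction=res.hi_fraction,
            gd_pct_decrease_v2=res.gd_pct_change_v2[0],
            strat_agree_fraction=res.n_stratification_agree
            / res.long_table["subject_id"].nunique(),
            cbv_group_beta=res.group_models["cbv_nawm"].group_coefficient().beta,
            cbv_group_p=res.group_models["cbv_nawm"].group_coefficient().p,
            cbv_group_ci_low=res.group_models["cbv_nawm"].group_coefficient().ci_low,
            cbv_group_ci_high=res.group_models["cbv_nawm"].group_coefficient().ci_high,
            cbv_adj_group_beta=res.adjusted_models["cbv_nawm"]
            .group_coefficient().beta,
            cbf_adj_group_beta=res.adjusted_models["cbf_nawm"]
            .group_coefficient().beta,
            runtime_s=time.time() - t0,
        )
        recs.append(rec)
        if progress is not None:
            progress(rec)
    return ReplicateSummary(per_cohort=pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# file-based stages


def run_synthesis(cfg: PipelineConfig, out_dir=None, overwrite: bool = False,
                  include_series: bool = True) -> Path:
    """Write a complete synthetic cohort (with ground-truth sidecar) to disk."""
    out = Path(out_dir or cfg.output_dir or "cohort")
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    phantom = build_phantom(cfg.grid_shape, seed=cfg.cohort.seed,
                            voxel_size=cfg.protocol.voxel_size)
    subjects = sample_cohort(cfg.cohort)
    for subj in subjects:
        rng = np.random.default_rng(np.random.SeedSequence([subj.seed, 101]))
        simulate_lesion_masks(subj, phantom, rng)
    write_cohort(subjects, phantom, cfg.protocol, out, config=cfg.cohort,
                 include_series=include_series)
    return out


def _manifest_loader(cohort_dir, manifest):
    import nibabel as nib

    cohort_dir = Path(cohort_dir)

    def load(fname):
        path = cohort_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"manifest names missing file: {path}")
        return np.asarray(nib.load(path).dataobj)

    def pick(role, sid=None, visit=None):
        m = manifest[manifest["role"] == role]
        if sid is not None:
            m = m[(m["subject_id"] == sid)
                  & (m["visit"].astype(str) == str(visit))]
        if len(m) != 1:
            raise FileNotFoundError(f"manifest lacks a unique {role} entry "
                                    f"({role}, {sid}, {visit})")
        return m["filename"].iloc[0]

    return load, pick


def quantify_stage(cfg: PipelineConfig, cohort_dir, out_dir=None) -> Path:
    """Fit perfusion maps for every stored DSC series.

    Writes CBV/CBF/MTT/TTP and the valid-fit mask as NIfTI float volumes
    per subject and visit, plus a maps manifest and a fitting log (voxels
    fitted and rejected, median r-squared).
    """
    import nibabel as nib

    cohort_dir = Path(cohort_dir)
    out = Path(out_dir or (cohort_dir / "maps"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(cohort_dir)
    load, pick = _manifest_loader(cohort_dir, manifest)
    proto = cfg.protocol
    wm_mask = load(pick("wm_prob")) >= cfg.wm_threshold
    affine = np.diag(list(proto.voxel_size) + [1.0])

    rows, log = [], []
    series_entries = manifest[manifest["role"] == "dsc_series"]
    for _, e in series_entries.iterrows():
        sid, v = e["subject_id"], e["visit"]
        series = load(e["filename"]).astype(float)
        fits = quantify_series(series, proto, wm_mask)
        quality = fit_quality_mask(fits, cfg.r2_min)
        maps = perfusion_maps(fits, proto)
        for role, data in (("cbv", maps.cbv), ("cbf", maps.cbf),
                           ("mtt", maps.mtt), ("ttp", maps.ttp),
                           ("valid_mask", quality.astype(np.float32))):
            name = f"{role}_{sid}_v{v}.nii"
            nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine),
                     out / name)
            rows.append((sid, v, role, name))
        n_fit = int(fits.converged.sum())
        log.append(dict(subject_id=sid, visit=v, n_fitted=n_fit,
                        n_rejected=int(wm_mask.sum()) - int(quality.sum()),
                        median_r2=float(np.median(
                            fits.r_squared[fits.converged]))
                        if n_fit else np.nan))
    pd.DataFrame(rows, columns=["subject_id", "visit", "role", "filename"]
                 ).to_csv(out / "maps_manifest.csv", index=False)
    pd.DataFrame(log).to_csv(out / "fit_log.csv", index=False)
    return out


def metrics_stage(cfg: PipelineConfig, cohort_dir, maps_dir=None,
                  out_path=None) -> Path:
    """Build the visit-level long table from stored maps and masks."""
    cohort_dir = Path(cohort_dir)
    maps_dir = Path(maps_dir or (cohort_dir / "maps"))
    manifest = read_manifest(cohort_dir)
    load, pick = _manifest_loader(cohort_dir, manifest)
    maps_manifest = pd.read_csv(maps_dir / "maps_manifest.csv",
                                keep_default_na=False)
    mload, mpick = _manifest_loader(maps_dir, maps_manifest)
    wm = load(pick("wm_prob"))
    clinical = pd.read_csv(cohort_dir / pick("clinical"))
    vx = cfg.protocol.voxel_size

    rows = []
    for sid, sub_clin in clinical.groupby("subject_id", sort=True):
        prev_gd = None
        for _, crow in sub_clin.sort_values("visit").iterrows():
            v = int(crow["visit"])
            t2 = load(pick("t2_mask", sid, v)).astype(bool)
            t1 = load(pick("t1_mask", sid, v)).astype(bool)
            gd = load(pick("gd_mask", sid, v)).astype(bool)
            nawm = nm.make_nawm_mask(wm, t2, cfg.wm_threshold,
                                     cfg.dilation_voxels)
            quality = mload(mpick("valid_mask", sid, v)) > 0.5
            cbv_sum = nm.summarize_nawm(mload(mpick("cbv", sid, v)), nawm,
                                        quality, cfg.n_bins)
            cbf_sum = nm.summarize_nawm(mload(mpick("cbf", sid, v)), nawm,
                                        quality, cfg.n_bins)
            rows.append(dict(
                subject_id=sid, visit=v, group_true=crow["group_true"],
                cbv_nawm=cbv_sum.direct_mean, cbf_nawm=cbf_sum.direct_mean,
                cbv_hist_mean=cbv_sum.mean, cbf_hist_mean=cbf_sum.mean,
                n_voxels_nawm=cbv_sum.n_voxels,
                t2_lv=nm.lesion_volume(t2, vx),
                t1_lv=nm.lesion_volume(t1, vx),
                gd_lv=nm.lesion_volume(gd, vx),
                n_gd=nm.count_gd_lesions(gd),
                n_new_gd=nm.count_new_gd_lesions(gd, prev_gd),
                gmv=crow["gmv_ml"], wmv=crow["wmv_ml"], edss=crow["edss"],
                age=crow["age"], sex=crow["sex"],
                disease_duration=crow["disease_duration"],
            ))
            prev_gd = gd
    out_path = Path(out_path or (maps_dir.parent / "long_table.csv"))
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path


def stats_stage(long_table_path, out_dir) -> Path:
    """Fit stratification and all models on a stored long table."""
    table = pd.read_csv(long_table_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = analyze_long_table(table)
    _write_stats(res, out)
    return out


def run_pipeline(cfg: PipelineConfig, cohort_dir, out_dir=None) -> Path:
    """Quantify a stored cohort end-to-end and write all result tables.

    Chains the quantify, metrics and stats stages; each consumes only
    files named in a manifest, so they can equally be re-run one by one.
    """
    import numpy
    import statsmodels

    from . import __version__

    cohort_dir = Path(cohort_dir)
    out = Path(out_dir or cfg.output_dir or (cohort_dir / "results"))
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    maps_dir = quantify_stage(cfg, cohort_dir, out / "maps")
    t_quant = time.time()
    long_path = metrics_stage(cfg, cohort_dir, maps_dir,
                              out / "long_table.csv")
    t_metrics = time.time()
    res = analyze_long_table(pd.read_csv(long_path))
    _write_stats(res, out)
    all_converged = all(m.converged for m in
                        list(res.time_models.values())
                        + list(res.group_models.values())
                        + list(res.adjusted_models.values())
                        + [res.gd_log_model])
    report = dict(
        settings=dict(wm_threshold=cfg.wm_threshold,
                      dilation_voxels=cfg.dilation_voxels,
                      n_bins=cfg.n_bins, r2_min=cfg.r2_min,
                      seed=cfg.cohort.seed,
                      protocol=dataclasses.asdict(cfg.protocol)),
        n_subjects=int(res.long_table["subject_id"].nunique()),
        n_rows=int(len(res.long_table)),
        hi_fraction=res.hi_fraction,
        gd_pct_decrease_v2=res.gd_pct_change_v2[0],
        all_models_converged=bool(all_converged),
        versions=dict(nawmperf=__version__, numpy=numpy.__version__,
                      statsmodels=statsmodels.__version__),
        stage_timing_s=dict(quantify=round(t_quant - t_start, 3),
                            metrics=round(t_metrics - t_quant, 3),
                            stats=round(time.time() - t_metrics, 3)),
        runtime_s=time.time() - t_start,
    )
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return out


def _write_stats(res: CohortResult, out: Path):
    res.long_table.to_csv(out / "long_table_stratified.csv", index=False)
    (res.long_table.groupby("subject_id")[["group", "group_true"]].first()
     .reset_index().to_csv(out / "stratification.csv", index=False))
    for name, models in (("time", res.time_models),
                         ("group", res.group_models),
                         ("adjusted", res.adjusted_models)):
        for outcome, m in models.items():
            m.to_frame().to_csv(out / f"model_{name}_{outcome}.csv",
                                index=False)
    res.gd_log_model.to_frame().to_csv(out / "model_log_gd_lv.csv", index=False)
    if len(res.baseline_table):
        res.baseline_table.to_csv(out / "baseline_comparison.csv", index=False)
    mm_rows = [(y, g, *vals) for y, d in res.marginal_means.items()
               for g, vals in d.items()]
    pd.DataFrame(mm_rows, columns=["outcome", "group", "estimate", "ci_low",
                                   "ci_high"]).to_csv(
        out / "marginal_means.csv", index=False)
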