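"""Run the full pipeline on one small synthetic cohort, on disk.

Synthesizes an 8-subject cohort (NIfTI volumes + clinical table +
manifest), then chains the quantify, metrics and stats stages and prints
the stratification, the marginal group means and the visit-4 time
effects. The same stages back the `nawmperf synth/quantify/metrics/stats`
command-line interface.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from nawmperf import CohortConfig, PipelineConfig, run_pipeline, run_synthesis

cfg = PipelineConfig(
    cohort=CohortConfig(n_subjects=8, n_hi=3, seed=12,
                        t2lv_mean_hi=1.0, t2lv_mean_lo=0.6,
                        t1lv_mean_hi=0.15, t1lv_mean_lo=0.15,
                        gdlv_mean_hi=0.10, gdlv_mean_lo=0.02),
    grid_shape=(32, 32, 20))

work = Path(tempfile.mkdtemp())
cohort_dir = run_synthesis(cfg, work / "cohort")
print(f"cohort written to {cohort_dir}")
results = run_pipeline(cfg, cohort_dir, work / "results")

strat = pd.read_csv(results / "stratification.csv")
print("\nstratification (assigned vs generating group):")
print(strat.to_string(index=False))

mm = pd.read_csv(results / "marginal_means.csv")
print("\nmarginal group means:")
print(mm.round(2).to_string(index=False))

time_cbv = pd.read_csv(results / "model_time_cbv_nawm.csv")
print("\nCBV time effects (reference MRI-1):")
print(time_cbv.round(3).to_string(index=False))

report = json.loads((results / "run_report.json").read_text())
print(f"\nGd-LV decrease MRI-1 to MRI-2: "
      f"{report['gd_pct_decrease_v2']:.1f}%")
# with only 8 subjects the estimates are noisy; the defaults (33 subjects,
# 13 high-inflammatory) reproduce the calibrated group means
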