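"""Train the full pipeline on one synthetic cohort and apply it to another.

The training flow runs morphometry, connectivity, network inference and
classification; the apply flow bypasses discovery and feeds the stored
network edges of a fresh 57-subject cohort to the trained classifiers —
mirroring a train/test split across independently acquired samples.
"""

import warnings

from psyconn import PipelineConfig, run_apply, run_training
from psyconn.pipeline import simulate_cohort

warnings.filterwarnings("ignore", category=UserWarning)

SETTINGS = dict(
    n_subjects=150, n_rois=30, n_parameters=1, grid=(8, 8, 8), n_parcels=8,
    n_perm_vbm=200, n_perm=1000, edge_target_r=0.5,
    c_grid=(1.0, 16.0), gamma_grid=(2**-6, 2**-3, 2**-1),
)

cfg = PipelineConfig(seed=1, **SETTINGS)
manifest = run_training(cfg)
print("training manifest counts:", manifest.counts)
report = manifest.reports["param-01"]
print(
    f"training LOOCV: accuracy {report.accuracy_pct:.1f}% "
    f"(corrected chance {report.corrected_chance_pct:.1f}%), "
    f"p vs chance {report.p_vs_chance:.1e}"
)

fresh = simulate_cohort(PipelineConfig(seed=2, **{**SETTINGS, "n_subjects": 57}))
apply_manifest = run_apply(cfg, manifest.models, fresh)
ar = apply_manifest.reports["param-01"]
print(
    f"held-out n=57:  accuracy {ar.accuracy_pct:.1f}% "
    f"(corrected chance {ar.corrected_chance_pct:.1f}%), "
    f"sensitivity {ar.sensitivity_pct:.1f}%, specificity {ar.specificity_pct:.1f}%"
)
print(
    "\nBoth accuracies above their corrected chance levels show the trained"
    "\nclassifiers generalize to a cohort they never saw."
)
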