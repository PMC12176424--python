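"""Run the full anemia-screening analysis end to end on a phantom cohort.

Simulates 60 participants, extracts radiomic features for the palpebral
and bulbar conjunctivae, selects 20 stable features per region, trains the
20-50-50 network with SMOTE balancing, and reports test ROC AUCs plus the
paired DeLong comparison between regions. Takes a couple of minutes.
"""

from conjradiomics import PhantomParams, PipelineConfig, run_pipeline
from conjradiomics.classifier import NetworkSpec
from conjradiomics.pipeline import SelectionConfig

config = PipelineConfig(
    phantom=PhantomParams(n_participants=60, photos_per_eye_per_device=1,
                          image_size=(64, 64)),
    selection=SelectionConfig(n_select=20, n_seeds=5, top_k=30,
                              threshold=0.6, n_estimators=50),
    network=NetworkSpec(epochs=100),
    master_seed=1,
)
result = run_pipeline(config, out_dir="out_run")

for region, entry in result.metrics["regions"].items():
    auc = entry["auc"]
    print(f"{region:10s} test AUC {auc['auc']:.3f} "
          f"[{auc['ci95'][0]:.3f}, {auc['ci95'][1]:.3f}] "
          f"({auc['n_pos']} anemic / {auc['n_neg']} nonanemic photos)")
    print(f"{'':10s} top features: {entry['selected'][:3]}")
comp = result.metrics["region_comparison"]
print(f"palpebral vs bulbar DeLong p = {comp['p']:.3f}")
# With the default strong phantom class effect both regions should reach
# AUCs well above 0.85, and the two regions' ROC curves should not differ
# significantly (p > 0.05) since both carry the same simulated signal.
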