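"""Full pipeline: rejection, hybrid feature fusion, 1-NN cross-validation.

Runs the complete chain on an in-memory phantom set and prints the
cross-validated metric suite for the 684-value hybrid feature set and a
sub-hybrid, demonstrating segment selection.
"""

from mgmtpmp.nnet import TrainingConfig
from mgmtpmp.phantoms import PhantomSpec, generate_arrays
from mgmtpmp.pipeline import PipelineConfig, run_pipeline

images, labels = generate_arrays(PhantomSpec(n_per_class=40, seed=0))

for segments in [("FC1", "FC2", "GLCM", "HOG", "LBP"), ("GLCM", "HOG")]:
    cfg = PipelineConfig(
        training=TrainingConfig(epochs=2, seed=0),
        segments=segments,
        folds=5,
        seed=0,
        per_fold_network=False,
    )
    bundle = run_pipeline(cfg, images=images, labels=labels)
    agg = bundle["results"]["aggregate"]
    print(f"segments {'+'.join(segments)} ({bundle['feature_length']} features):")
    print(f"  accuracy {agg['accuracy']['mean']:6.2f} +- {agg['accuracy']['sd']:.2f} %")
    print(f"  MCC      {agg['mcc']['mean']:6.3f}")
    print(f"  AUC      {agg['auc']['mean']:6.3f}")

# Both feature sets classify the well-separated phantom textures
# essentially perfectly; on real MRI data the hybrid set is where the
# fusion of latent and hand-crafted features pays off.
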