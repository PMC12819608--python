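"""Compare the full model against its three ablated variants.

``no_msi`` freezes the fusion weights uniform and replaces the
cross-attention pair head with plain concatenation; ``no_gbap`` replaces
attention propagation with plain mean aggregation; ``no_cmrg`` drops the
contrastive term and the distribution-alignment / ranking / entropy
regularizers.
"""

from ddikit import TrainConfig, generate_cohort, train
from ddikit.training import run_ablation

cohort = generate_cohort(n_drugs=100, n_modalities=4, n_clusters=4,
                         noise_sd=1.0, flip_prob=0.05, seed=0)
config = TrainConfig.small_synthetic(seed=0, max_epochs=30,
                                     early_stop_patience=10)

full = train(cohort, config)
print(f"{'variant':10s} ROC-AUC   F1")
print(f"{'full':10s} {full.metrics.roc_auc:.4f}   {full.metrics.f1:.4f}")
for variant in ("no_msi", "no_gbap", "no_cmrg"):
    res = run_ablation(cohort, config, variant)
    print(f"{variant:10s} {res.metrics.roc_auc:.4f}   {res.metrics.f1:.4f}")
# On cohorts with one informative modality the full model should match or
# exceed every ablated variant; gaps grow with noise and scarcity.
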