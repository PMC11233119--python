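"""Impute completely missing probes from a tissue reference panel.

Probes present only on the target platform cannot be converted — they were
never measured.  Each sample is matched to its nearest reference tissue
(mean absolute deviation over shared probes) and missing probes are filled
with that tissue's median beta.  Probes whose within-tissue SD exceeds a
threshold are too variable to impute confidently and stay missing.
"""

import numpy as np

from methlift import (
    BetaMatrix,
    SimulationConfig,
    impute_missing,
    make_platform_pair,
    simulate_cohort,
    true_tissue_profiles,
)

cfg = SimulationConfig(seed=11, n_prefixes=200, noise_sd=0.02, tissue_separation=0.1)
legacy, _, _ = make_platform_pair(cfg)
betas, labels, ref = simulate_cohort(cfg, legacy, n_samples_per_tissue=2)
profiles = true_tissue_profiles(cfg, legacy)

# delete 50 probes to emulate platform-specific content
deleted = list(betas.values.index[:50])
partial = BetaMatrix(betas.platform, betas.values.drop(index=deleted))
print(f"cohort: {betas.shape[1]} samples, {betas.shape[0]} probes; deleted {len(deleted)}")

result = impute_missing(partial, ref, sd_threshold=0.08, min_overlap=50)

n_correct = sum(result.tissue_used[s] == t for s, t in zip(betas.sample_ids, labels))
print(f"tissue inference: {n_correct}/{len(labels)} samples matched their generating tissue")

errs = [
    np.abs(
        result.betas.values.loc[deleted, s].to_numpy()
        - profiles.loc[t, deleted].to_numpy()
    )
    for s, t in zip(betas.sample_ids, labels)
]
n_imputed = int((result.provenance == "imputed").to_numpy().sum())
print(f"imputed cells: {n_imputed}")
print(f"imputed-cell MAE vs generating medians: {float(np.mean(errs)):.5f}")
print(
    "MAE well below the 0.02 measurement noise: the tissue median is an\n"
    "accurate stand-in for a probe the source platform never measured."
)
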