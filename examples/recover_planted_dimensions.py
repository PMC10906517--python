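"""Recover planted shared dimensions from a synthetic six-country panel.

Generates ratings for 500 stimuli x 48 concepts in 6 countries with 5
shared latent dimensions plus one culture-specific dimension per
country, then runs the full preservation pipeline: leave-one-stimulus-
out G-PPCA, pairwise partial-correlation tests with BH correction, and
the significance-graph criterion.
"""

import numpy as np

from gppca import count_preserved, make_panel

panel, truth = make_panel(
    n_stimuli=500, n_datasets=6, n_concepts=48,
    d_shared=5, d_spec_per_dataset=1, noise_sd=0.3, seed=7,
)
report = count_preserved(panel, max_dims=48, alpha=0.05, mode="both")

print(f"retained dimensions: {report.retained}")
print(f"planted shared dimensions: {truth.d_shared}")
# match each retained dimension's loadings to the planted ones
eff = np.mean(
    [truth.effective_shared_loadings(d) for d in truth.datasets], axis=0
)
for m in report.retained:
    r = max(
        abs(np.corrcoef(eff[j], report.model.loadings[:, m])[0, 1])
        for j in range(truth.d_shared)
    )
    print(f"  dim {m}: preserved covariance {report.model.preserved_cov[m]:.3f}, "
          f"best |r| with a planted loading {r:.3f}")

# The retained list should be exactly the five shared dimensions (the
# culture-specific ones fail the cross-country significance graph), and
# each |r| should be >= 0.9: the pipeline recovers not just the count
# but the planted attribute patterns themselves.
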