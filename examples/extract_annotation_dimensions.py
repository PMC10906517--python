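"""Extract the dimensions an annotation source shares with human judgments.

Builds a paired annotation/judgment dataset (both reading out the same
5 planted latent dimensions, each supported on 6 concepts, through
independent noise), runs PPCA between the two wide matrices with
leave-one-stimulus-out scoring, bootstrap significance, the triple
BH + ForwardStop + SNR filter, varimax rotation, and finally the
top-N loading significance test.
"""

import numpy as np

from gppca import (
    extract_dimensions,
    loading_significance,
    make_annotation_pair,
    make_panel,
)

_, truth = make_panel(
    n_stimuli=500, n_datasets=2, n_concepts=48, d_shared=5,
    d_spec_per_dataset=0, noise_sd=0.3, support=6, seed=19,
)
A, B = make_annotation_pair(truth, annotation_noise_sd=0.3, seed=20)

report = extract_dimensions(A, B, B_boot=200, alpha=0.05,
                            snr_min=3.0, max_dims=48, seed=21)
print(f"retained dimensions: {report.retained} (planted: 5)")
for k in report.retained:
    print(f"  dim {k}: held-out partial Spearman {report.statistic[k]:.3f}, "
          f"bootstrap p {report.p_boot[k]:.3f}, SNR {report.snr[k]:.1f}")

counts, _ = loading_significance(A, B, report, B_boot=200, seed=22)
print("significant-loading counts per dimension "
      f"(planted support is 6 concepts x 2 datasets = 12): {counts}")
# Each retained dimension's held-out correlation is large with p = 0 and
# SNR far above 3; dimensions 5+ fail the filters. The loading counts
# sit at or just above 12 — the bootstrap sign test finds the planted
# support, with occasional +1/+2 overshoot from null attributes whose
# sample signs happen to line up.
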