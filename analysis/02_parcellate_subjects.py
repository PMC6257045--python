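#!/usr/bin/env python
"""Cluster-based thalamic parcellation of every cohort subject.

For each subject: refine the thalamic mask (CSF > 5% and FA > 0.55
exclusion), average the bootstrap ODF stacks into mean SH-coefficient
features, run the combined-metric k-means (k = 7 per hemisphere, weights
0.5/0.5, feature scale 100, averaged 50-restart position-only
initialization) and name the clusters against the planted ground truth.
Writes per-subject parcellations and a per-subject quality table
(adjusted Rand index vs the planted nuclei, QC flags).
"""

from pathlib import Path

import pandas as pd

from thalparc import ClusteringConfig, load_cohort, write_maxlik
from thalparc.io import write_affine
from thalparc.pipeline import ari_vs_truth, parcellate_subject

ROOT = Path(__file__).resolve().parent.parent / "results"
CLUSTER_SEED = 404


def main() -> None:
    cohort = load_cohort(ROOT / "cohort")
    out = ROOT / "parcellations"
    out.mkdir(parents=True, exist_ok=True)
    clustering = ClusteringConfig(n_init_runs=50, seed=CLUSTER_SEED)
    rows = []
    for s, bundle in enumerate(cohort):
        result = parcellate_subject(bundle, clustering)
        write_maxlik(result.labeled, out / f"subject{s:03d}.nii.gz")
        write_affine(bundle.to_template, out / f"subject{s:03d}.txt")
        rows.append(
            {
                "subject": s,
                "ari_vs_truth": ari_vs_truth(result, bundle),
                "n_labeled_voxels": int((result.labeled.labels > 0).sum()),
                "qc_flags": "; ".join(result.qc_flags) or "none",
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "parcellation_quality.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nmean ARI vs planted nuclei: {table['ari_vs_truth'].mean():.3f} "
          f"(min {table['ari_vs_truth'].min():.3f})")
    flagged = (table["qc_flags"] != "none").sum()
    print(f"subjects with QC flags (candidates for exclusion): {flagged}/{len(table)}")


if __name__ == "__main__":
    main()
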