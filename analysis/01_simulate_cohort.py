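#!/usr/bin/env python
"""Generate the synthetic study cohort.

Ten subjects, each with two ellipsoidal thalami of seven planted nuclei,
50-sample bootstrap ODF stacks (order-6 SH, 28 coefficients), planted CSF
and high-FA contamination rims, and a known subject-to-template affine.
Writes one subdirectory per subject under results/cohort/ plus the
bilateral color LUT.
"""

from pathlib import Path

from thalparc import SyntheticConfig, generate_cohort, save_cohort

COHORT_SEED = 20250925
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    config = SyntheticConfig(seed=COHORT_SEED, n_subjects=10)
    bundles = generate_cohort(config)
    save_cohort(bundles, OUT, config.k_per_hemisphere)
    n_vox = [int(b.thalamus_mask.sum()) for b in bundles]
    print(f"wrote {len(bundles)} subjects to {OUT}")
    print(f"thalamic mask sizes (voxels): min={min(n_vox)}, max={max(n_vox)}")
    print(f"bootstrap stack per subject: {bundles[0].odf_samples.shape} "
          "(voxels x samples x SH coefficients)")


if __name__ == "__main__":
    main()
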