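#!/usr/bin/env python
"""Build the probabilistic atlas from the cohort parcellations.

Warps every subject's parcellation to the template grid through its known
affine (nearest-neighbor interpolation), averages subject label indicators
into the 14-frame SPAM, and derives the maximum-likelihood atlas (seeded
random tie-break at multi-mode voxels).  Writes spam.nii.gz, maxlik.nii.gz
and the color LUT alongside.
"""

from pathlib import Path

import numpy as np

from thalparc import AffineTransform, SyntheticConfig, write_maxlik, write_spam
from thalparc.io import ColorLUT, read_affine, read_nifti
from thalparc.pipeline import build_cohort_atlas
from thalparc.types import LabeledVolume

ROOT = Path(__file__).resolve().parent.parent / "results"
ATLAS_SEED = 77
COHORT_SEED = 20250925  # template geometry is part of the cohort definition


def main() -> None:
    lut = ColorLUT.read(ROOT / "cohort" / "lut.txt")
    volumes, transforms = [], []
    for path in sorted((ROOT / "parcellations").glob("subject*.nii.gz")):
        labels, affine = read_nifti(path)
        labels = labels.astype(np.int32)
        table = {c: lut.names[c] for c in set(np.unique(labels)) - {0}}
        volumes.append(LabeledVolume(labels, affine, table))
        transforms.append(AffineTransform(read_affine(path.with_suffix("").with_suffix(".txt"))))
    config = SyntheticConfig(seed=COHORT_SEED, n_subjects=len(volumes))
    spam, maxlik = build_cohort_atlas(volumes, transforms, config, seed=ATLAS_SEED)

    out = ROOT / "atlas"
    out.mkdir(parents=True, exist_ok=True)
    write_spam(spam, out / "spam.nii.gz")
    write_maxlik(maxlik, out / "maxlik.nii.gz")
    lut.write(out / "lut.txt")

    sums = spam.probabilities.sum(axis=3)
    n_multi = int(((spam.probabilities == spam.probabilities.max(axis=3, keepdims=True)).sum(axis=3) > 1)[sums > 0].sum())
    print(f"SPAM: {spam.probabilities.shape[3]} frames over {spam.n_subjects} subjects")
    print(f"atlas support: {int((sums > 0).sum())} template voxels; "
          f"{n_multi} with tied modes (random tie-break)")
    print(f"max-likelihood atlas labels: {sorted(set(np.unique(maxlik.labels)) - {0})}")


if __name__ == "__main__":
    main()
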