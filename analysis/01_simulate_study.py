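"""Generate the default synthetic study and write it under results/study/.

The study is a 10-participant, 24^3-voxel (2 mm) head with ten sector ROIs,
each holding a small and a large correlated hub; antipodal sectors carry
long-range-paired hubs.  Outputs: per-participant BOLD and PET volumes,
tissue probability maps, the parcellation with its label table, planted
ground-truth degree volumes, and a manifest.
"""

import os
import sys

import numpy as np
import pandas as pd

from neurofcd.io_volumes import Volume3D, write_label_table, write_volume
from neurofcd.synthetic import default_study_config, generate_study

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "study")


def main(seed: int = 7) -> None:
    os.makedirs(OUT, exist_ok=True)
    cfg = default_study_config(seed=seed)
    study = generate_study(cfg)
    rows = []
    for p in range(cfg.n_participants):
        write_volume(study.bold[p], os.path.join(OUT, f"sub-{p:02d}_bold.nii.gz"))
        write_volume(study.pet[p], os.path.join(OUT, f"sub-{p:02d}_pet.nii.gz"))
        rows.append({"participant": p,
                     "bold": f"sub-{p:02d}_bold.nii.gz",
                     "pet": f"sub-{p:02d}_pet.nii.gz"})
    for name, vol in (("wm_prob", study.wm_prob), ("gm_prob", study.gm_prob),
                      ("csf_prob", study.csf_prob)):
        write_volume(vol, os.path.join(OUT, f"{name}.nii.gz"))
    write_volume(study.parcellation, os.path.join(OUT, "parcellation.nii.gz"))
    write_label_table(study.parcellation.label_table, os.path.join(OUT, "labels.tsv"))
    truth = study.truth
    write_volume(Volume3D(cfg.grid, truth.planted_local_degree.astype(float)),
                 os.path.join(OUT, "truth_local_degree.nii.gz"))
    write_volume(Volume3D(cfg.grid, truth.planted_long_degree.astype(float)),
                 os.path.join(OUT, "truth_long_degree.nii.gz"))
    pd.DataFrame(rows).to_csv(os.path.join(OUT, "manifest.tsv"), sep="\t", index=False)

    sizes = [len(h.voxels()) for h in cfg.hubs]
    print(f"wrote study (seed {seed}) to {os.path.abspath(OUT)}")
    print(f"  {cfg.n_participants} participants, grid {cfg.grid_shape}, "
          f"{len(cfg.hubs)} hubs (sizes {sorted(set(sizes))}), "
          f"{len(cfg.long_range)} long-range pairs")
    print(f"  planted max total degree: "
          f"{int((truth.planted_local_degree + truth.planted_long_degree).max())}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
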