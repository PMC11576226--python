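"""Validation summary: planted-coupling recovery and null calibration.

A condensed version of the checks the test suite runs at larger replicate
counts: whole-map recovery rate under planted coupling, Bonferroni hub
survival, family-wise error under the null, spin-test calibration against
the naive shuffle, and second-level gradient recovery.  Writes
results/validation.tsv.
"""

import os
import sys

import numpy as np
import pandas as pd

from neurofcd.experiments import (
    gradient_coupling_replicate,
    null_fwer_replicate,
    recovery_replicate,
    shuffle_pvalue,
    spin_calibration_pvalue,
)
from neurofcd.spin_perm import build_icosphere

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main(seed: int = 7, n_rep: int = 20) -> None:
    os.makedirs(OUT, exist_ok=True)
    rows = []

    wins = surv = rois = 0
    for k in range(n_rep):
        res = recovery_replicate(seed * 1000 + k)
        wins += res.whole_map_rho["srfcd"] > 0 and res.whole_map_p["srfcd"] < 0.05
        surv += res.n_bonferroni_survivors["srfcd"]
        rois += res.n_hub_rois
    rows.append({"check": "whole_map_recovery_rate", "value": wins / n_rep, "n": n_rep})
    rows.append({"check": "bonferroni_hub_survival_rate", "value": surv / rois, "n": rois})

    fwer = np.mean([null_fwer_replicate(seed * 1000 + k) for k in range(100)])
    rows.append({"check": "null_family_wise_error", "value": float(fwer), "n": 100})

    mesh = build_icosphere(2)
    spin_rej = np.mean([spin_calibration_pvalue(seed * 1000 + k, mesh=mesh, n_perm=200) < 0.05
                        for k in range(60)])
    shuf_rej = np.mean([shuffle_pvalue(seed * 1000 + k, mesh=mesh, n_perm=100) < 0.05
                        for k in range(60)])
    rows.append({"check": "spin_null_rejection_at_05", "value": float(spin_rej), "n": 60})
    rows.append({"check": "shuffle_null_rejection_at_05", "value": float(shuf_rej), "n": 60})

    grad = np.mean([gradient_coupling_replicate(seed * 1000 + k) > 0 for k in range(8)])
    rows.append({"check": "second_level_gradient_positive_rate", "value": float(grad), "n": 8})

    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "validation.tsv"), sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
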