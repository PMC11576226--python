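# neurofcd

Voxel-wise functional connectivity density (FCD) mapping and its coupling
with PET receptor-density maps, with rank-based group inference corrected by
Bonferroni and spin-based spatial permutation.

## The problem

Resting-state fMRI defines a voxel-level notion of hubness: with C_ij the
Pearson correlation between the BOLD series of voxels i and j, an edge joins
i and j when C_ij > 0.6. **gFCD** counts a voxel's edges to the whole brain
(global degree centrality); **lFCD** counts only the edges inside the
spatially contiguous cluster grown from the voxel (intraregional
centrality); **gFCD − lFCD** counts connections to spatially disjoint
regions (interregional centrality). The scientific question this package
operationalizes is whether a molecular density map — a PET standardized
uptake value ratio (SUVR), the uptake volume divided by its white-matter
reference mean, restricted to gray matter and SUVR > 1 — covaries with
log-transformed, smoothed FCD maps (srFCD = log lFCD, lrFCD =
log (gFCD − lFCD)) across and within brain regions.

Inference is rank-based throughout: Spearman correlations across ROIs for
group-mean maps; per-participant voxel-wise Spearman within each ROI or
network, pooled by Fisher z (atanh) and a one-sample t-test; a strict
Bonferroni step over ROIs + networks (p < 0.05/m); and a spin permutation
step that rotates the SUVR map over per-hemisphere icosphere meshes
(10,242 vertices each at order 5) to build a null that preserves spatial
autocorrelation, with p = #(null ≥ observed)/n_perm.

Because data of this kind is access-restricted, the package ships a seeded
synthetic-study generator that plants hub-structured BOLD correlations and
a coupled SUVR volume with exposed ground truth, so every claim the
pipeline makes is tested as parameter recovery or null calibration. It is
aimed at methods developers and reviewers who want the complete analysis
chain — graph algorithms, masks, normalization, two-step inference —
runnable and checkable end to end on a desk.

## Worked example

Run the full synthetic study end to end (simulate → SUVR → per-participant
FCD → group means → two-step corrected associations → second level):

```bash
python analysis/01_simulate_study.py      # writes results/study/
python analysis/02_participant_fcd.py     # per-participant maps + recovery
python analysis/03_group_associations.py  # the full corrected analysis
python analysis/04_validation_checks.py   # recovery / calibration summary
```

`03_group_associations.py` prints (seed 7, 10 participants, 24³ grid,
n_perm = 200):

```
== whole-map associations (Spearman across ROIs) ==
  SUVR vs srfcd: rho = 0.952, p = 2.28e-05, spin p = 0
  SUVR vs lrfcd: rho = 0.964, p = 7.32e-06, spin p = 0
  SUVR vs gfcd: rho = 0.964, p = 7.32e-06
== per-ROI/network results (sorted by mean z) ==
  network Somatomotor [lrfcd]: mean z = 1.285 (rho = 0.858), p = 3.16e-11 -> survived both steps
  roi 1 [lrfcd]: mean z = 1.165 (rho = 0.823), p = 5.21e-09 -> survived both steps
  ...
```

Reading it: across the ten synthetic ROIs, regions with higher mean SUVR
have higher mean srFCD/lrFCD (rho ≈ 0.95, significant after the whole-map
spin test) — the generator planted exactly this coupling (β = 0.8) between
receptor density and hub degree, so the pipeline recovers it. Each listed
ROI/network row is the Fisher-z-pooled within-region voxel-wise
correlation; "survived both steps" means p < 0.05/17 at the Bonferroni step
and spin p < 0.05.

`04_validation_checks.py` prints the package's self-checks:

```
                              check    value   n
            whole_map_recovery_rate 1.000000  20
       bonferroni_hub_survival_rate 1.000000 200
             null_family_wise_error 0.020000 100
          spin_null_rejection_at_05 0.050000  60
       shuffle_null_rejection_at_05 0.283333  60
second_level_gradient_positive_rate 1.000000   8
```

i.e. planted coupling is always detected, the corrected inference keeps its
family-wise error below the nominal 5% under the null, the spin test is
calibrated (5% rejections at the 5% level) where a naive vertex shuffle on
the same smooth nulls rejects 28%, and a planted gradient of coupling
strength across regions is recovered at the second level.

A `neurofcd` CLI wraps the same library (`neurofcd simulate`, `neurofcd
suvr`, `neurofcd fcd`, `neurofcd run`); see `neurofcd --help`.

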