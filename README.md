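# grassid

Multi-perspective identification of grass (Poaceae) species by score-level
fusion of per-perspective classifiers.

## The problem

Grasses are notoriously hard to identify from photographs: most species lack
conspicuous flowers, and the diagnostic characters (ligule shape, leaf
surfaces, culm nodes) are small and easily confused. A practical way around
this is to photograph each plant from several standardized perspectives —
inflorescence (F), ligule in frontal (LiF) and side (LiS) view, leaf top
(LeT) and back (LeB), and the culm node (N) — embed each image with a
pretrained CNN, train one classifier per perspective on the embedding
vectors, and combine the per-perspective species scores.

`grassid` implements that pipeline for anyone working on fine-grained,
multi-organ plant identification: the data model and long-format feature
tables, species-stratified splitting, per-perspective classifier training
with bootstrap hyperparameter tuning, sum-rule score fusion over every
perspective subset, and the accuracy/ranking statistics used to compare
subsets. A class-conditional Gaussian simulator generates multi-view feature
data with controllable per-perspective discriminability for testing and
power studies.

## The core statistic

Each perspective classifier emits a normalized score vector `s_p` over the
`K` species for a test observation (rows sum to 1). For a perspective subset
`P`, the fused score is the normalized sum rule

    S = (1 / |P|) * Σ_{p ∈ P} s_p

and the predicted species is `argmax_k S_k`. Accuracy is reported per
species (percentage of correctly identified test observations) and as the
unweighted mean across species (macro recall); relative accuracy divides
each species' accuracy by the maximum across species. The combination study
evaluates all `2^|P| − 1` non-empty subsets, partitioned into those with and
without the inflorescence, and reports the best subset per size — the
question being how well non-flowering grasses can be identified.

## Worked example

```python
import grassid as g

cfg = g.SyntheticConfig(n_species=8, n_per_species=40, dim=16, noise_sd=3.0, seed=3)
model = g.PerspectiveFusionModel.from_synthetic(
    cfg, classifier=g.ClassifierSpec("svm_linear", grid=[{"C": 1.0}]),
    train_per_species=30, test_per_species=10, split_seed=3)
res = model.fit()
print(res.summary())
```

prints

```
Multi-perspective fusion results
================================================
species: 8   observations: 320   perspectives: N, F, LeT, LeB, LiS, LiF   dim: 16
split: 30 train / 10 test per species (seed 3)
classifier: svm_linear

Single-perspective macro accuracy (%):
      F   76.2
    LiF   61.2
    LiS   41.2
      N   31.2
    LeT   27.5
    LeB   27.5

Best combination per size (macro accuracy, %):
  vegetative       size 1: LiF                       61.2
  vegetative       size 2: N_LiF                     60.0
  vegetative       size 3: N_LiS_LiF                 65.0
  vegetative       size 4: N_LeB_LiS_LiF             68.8
  vegetative       size 5: N_LeT_LeB_LiS_LiF         66.2
  flowers_present  size 1: F                         76.2
  flowers_present  size 2: F_LiF                     81.2
  flowers_present  size 3: N_F_LiF                   82.5
  flowers_present  size 4: F_LeT_LiS_LiF             85.0
  flowers_present  size 5: N_F_LeB_LiS_LiF           83.8
  flowers_present  size 6: N_F_LeT_LeB_LiS_LiF       80.0
```

The single-view ranking follows the simulator's per-perspective
discriminability (inflorescence strongest, ligule front next); fusing
perspectives raises accuracy over the best single view in both partitions;
and accuracy need not grow monotonically with subset size — a well-chosen
four-perspective set beats the five-perspective one here.

The same pipeline runs from the shell: `grassid simulate | split | train |
fuse | evaluate | report`, or end-to-end from a YAML config with
`grassid run --config experiment.yaml` (writes report CSVs, per-subset
confusion matrices and a JSON manifest of seeds, chosen hyperparameters and
versions). Real embedding tables enter through the same long-format CSV
(`obs_id, species, perspective, f0..f{d-1}`).

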