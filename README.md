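# gaitscore

Video-derived gait assessment for parkinsonism severity rating.

Parkinsonism — slow, shuffling, asymmetric, unstable gait — is common in
older adults with dementia, where it may signal disease progression or a
reversible side effect of antipsychotic medication. Clinically it is rated
on ordinal 0–4 scales: the gait item of the Unified Parkinson's Disease
Rating Scale (**UPDRS-gait**) and of the Simpson–Angus Scale (**SAS-gait**).
`gaitscore` implements the analysis pipeline that connects markerless
vision data to those ratings:

1. **Feature extraction** from per-frame joint keypoints of short walking
   bouts: eight features from 2D pixel keypoints (MPII/OpenPose-style
   skeleton) and sixteen from 3D metric joints (Kinect-style 25-joint
   skeleton) — spatiotemporal (cadence, step length/time/width, walking
   speed), variability (coefficients of variation), symmetry (symmetry
   index, symmetry angles), trunk sway (sacrum medio-lateral dynamics) and
   lateral stability (margin of stability from the extrapolated centre of
   mass).
2. **Ordinal regression**: univariate proportional-odds screening of every
   feature (p < α, no multiplicity correction), Pearson collinearity
   pruning (|r| > 0.5 keeps the feature more correlated with the outcome),
   and a multivariate proportional-odds model with age and sex.
3. **A synthetic cohort generator** with known ground truth — kinematic
   walking bouts projected through a perspective camera, and a latent
   severity process that drives both the gait parameters and the ordinal
   ratings — so that every stage is testable without clinical video.

## The core model

Foot strikes are detected from the vertical ankle trajectory: the
downward velocity is computed per gait cycle, and the strike is marked
where this signal falls back through 35% of the cycle's peak. Steps are
the intervals between strikes of alternating feet.

Severity scores are modelled with the proportional-odds (ordinal
logistic) model

```
logit P(y ≤ j | x) = θ_j − xᵀβ ,   j = 0|1, 1|2, 2|3, 3|4
```

with ordered cut-points θ_j and common slopes β, fitted by maximum
likelihood; a positive β means larger feature values shift probability
toward more severe scores. Wald standard errors come from the observed
information; predictions take the most probable category.

The lateral margin of stability (MOS) uses the extrapolated centre of
mass, XCoM = CoM + v_CoM/ω₀ with ω₀ = √(g/ℓ): the signed medio-lateral
distance from the XCoM to the stance-ankle boundary, positive when the
XCoM stays inside the base of support.

## Worked example

```python
from gaitscore import (RunConfig, run_pipeline, simulate_cohort)

bouts, metadata, truths = simulate_cohort(
    n_participants=14, bouts_per_participant=28, seed=11, dim="3d")
cfg = RunConfig(dimensionality="3d", outcome="updrs_gait", seed=11)
report = run_pipeline(cfg, bouts=bouts, metadata=metadata, write_outputs=False)

print(report.qc_counts)
print(report.selection.univariate.loc[["walking_speed", "step_length"]].round(3))
print(f"accuracy {report.evaluation.accuracy:.1f}%  "
      f"adjacent {report.evaluation.adjacent_agreement:.1f}%")
```

prints

```
{'total': 392, 'included': 392, 'too_short': 0, 'untracked': 0}
               coefficient  std_error  p_value  n_obs
walking_speed       -4.837      0.392      0.0    392
step_length        -10.190      0.865      0.0    392
accuracy 38.3%  adjacent 83.4%
```

The 392 simulated bouts all pass quality control; univariate
proportional-odds regression finds slower walking and shorter steps
strongly associated with higher UPDRS-gait scores (negative coefficients,
p < 0.001), and the final multivariate model reproduces 38.3% of the
annotated 0–4 scores exactly and 83.4% to within one category —
misclassifications concentrate in adjacent severity levels, as expected
when a continuous severity spectrum is discretized.

The same pipeline is available from the shell:

```bash
gaitscore simulate --dim 3d --n-participants 14 --seed 7 --out data/
gaitscore features --input-dir data/ --dim 3d --out features.csv
gaitscore stats --features features.csv --meta data/metadata.csv \
    --outcome updrs_gait --report out/
```

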