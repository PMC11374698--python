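# avoidspace

Population-level analysis of prefrontal calcium-imaging activity during
two-dimensional active avoidance: cross-subject joint-subspace alignment,
time-resolved linear decoding, and an iterative nullspace decomposition
that separates population activity into orthogonal **motion**,
**avoidance** and **tone** coding dimensions. A synthetic multi-subject
cohort generator with planted latent structure makes every stage of the
pipeline verifiable by parameter recovery.

The package is aimed at systems neuroscientists analysing multi-subject
population recordings (one-photon miniscope ΔF/F traces, behaviour
tracking and trial metadata at 5 Hz) in paradigms where sensory, motor
and cognitive variables overlap in time.

## The analysis in brief

**Subject alignment.** For each subject, event-aligned condition averages
(avoid, error and ITI-shuttle trials in two tasks; cells × 40 samples
each) are row-centred, normalised to unit Frobenius norm and concatenated
over conditions and subjects into an *n* × 240 matrix. PCA gives an
*n* × *k* coefficient matrix (default *k* = 10); its per-subject row
blocks, orthonormalised by QR, are the projection matrices P_s with
P_sᵀP_s = I that map each subject's cells into one shared coding space.

**Decoding.** All decoders are linear max-margin classifiers (hinge loss,
box constraint C = 1) with five-fold cross-validation on class-balanced
trial subsamples; every analysis is repeated over independently drawn
trial samples and summarised by the sorted-rank 95% bootstrap CI (the
3rd and 78th of 80 sorted values). Error trials are aligned to
*pseudoshuttle* times resampled from the avoid-trial latency
distribution so trial length carries no class information.

**Decomposition.** Motion dimensions are the leading PCs of the
ITI-shuttle condition average (shuttle motion without task context).
Avoid dimensions are found iteratively: a time-independent avoid/error
decoder is trained on one randomly sampled timepoint per trial in the
nullspace of everything found so far, its unit-normalised weight vector
is mapped back into the joint subspace, and the nullspace shrinks. The
tone dimension repeats the construction for tone-vs-baseline samples.
The result is an orthonormal basis [motion-1, motion-2, avoid-1,
avoid-2, tone] plus a residual complement, so that, e.g., avoidance-
specific activity is read out free of motion and tone components.

## Worked example

```python
import numpy as np
import avoidspace as av
from avoidspace import pipeline, evaluation

cohort, truth = av.generate_cohort(seed=1)      # 3 subjects x 60 cells
rng = np.random.default_rng(42)
ac = pipeline.align_cohort(cohort, rng)          # joint subspace, k = 10
basis, motion, avoid = pipeline.decompose_cohort(ac, rng)

print(pipeline.recovery_angles(truth, ac.subspace, basis))
ve = evaluation.variance_study(ac, basis)
drop = evaluation.tone_drop_study(cohort, ac, basis, rng)
```

prints (abridged):

```
recovery angles (deg): {'motion-1': 5.0, 'motion-2': 5.2, 'avoid-1': 12.4,
                        'avoid-2': 19.8, 'tone': 11.3}
VE by 5 coding dims (avoid/error averages): 98.8%
VE by motion dims (ITI shuttles): 98.5%, by avoid dims: 0.3%
tone/projection correlation: 0.90
tone drop: 34.8% at 1.2 s after action onset
```

The recovery angles say that each planted latent direction is found
within a few degrees (the task-2-specific avoid direction is the
statistically hardest at this cohort size). The variance split shows the
signature of the decomposition: almost all trial-average variance lives
in the five coding dimensions, ITI shuttling is carried by the motion
dimensions and hardly at all by the avoid dimensions. The tone dimension
tracks the tone stimulus closely but drops by about a third shortly
after the animal initiates its (here incorrect, tone-preserving)
shuttle — the behaviour-gated tone suppression the generator plants.

## Layout

| module | contents |
| --- | --- |
| `avoidspace.synthetic` | cohort/movie generator with planted latents |
| `avoidspace.preprocess` | ΔF/F, bleach model, lowpass normalisation, duplicate cells |
| `avoidspace.events` | speed, shuttle detection, windows, condition averages |
| `avoidspace.alignment` | joint subspace (PCA + per-subject QR) |
| `avoidspace.decoding` | per-timestep SVMs, balancing, rank CIs |
| `avoidspace.decomposition` | motion/avoid/tone dimensions, nullspace removal |
| `avoidspace.metrics` | responsiveness, overlap, VE, weight entropy, tone drop |
| `avoidspace.pipeline` | end-to-end orchestration |
| `avoidspace.evaluation` | recovery / dissociation / calibration studies |
| `avoidspace.io` | HDF5 + CSV serialisation |
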