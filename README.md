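# dyadsync

Analysis pipeline for dyadic motor-synchrony experiments that pair a
mirror-game movement activity with a Go/NoGo response-inhibition task
recorded under fNIRS.  The package covers the full chain a study of this
design needs:

1. **Pose similarity (manipulation check).**  From per-frame 2-D upper-body
   keypoints (OpenPose JSON dialect: neck, left/right shoulder, elbow,
   wrist), each person's pose in a frame is summarized as the 7×7 matrix
   *D* of Euclidean inter-joint distances.  After median imputation of
   missing joints and Savitzky–Golay smoothing (window 13 frames, order 2),
   two poses are compared through degree-normalized graph Laplacians of the
   affinity *W* = max(*D̂*) − *D̂* (with *D̂* = *D*/‖*D*‖_F):

   score = 1 / (1 + β‖L̂ₐ − L̂_b‖_F),  L̂ = I − Deg^(−1/2) W Deg^(−1/2)

   The score lies in (0, 1], equals 1 exactly for identical poses, and is
   invariant to translation, rotation and isotropic scaling.  A dyad's
   movement-similarity score is the mean over frames.

2. **Go/NoGo behavioural models.**  Go-trial reaction times follow a
   hierarchical lognormal model, `RT ~ 1 + Group*BlockType +
   (1 + BlockType | ID)` with treatment coding (Control = 0, Synchronized
   = 1; AllGo = 0, Mixed = 1), reported in ms as differences of posterior
   marginal means.  Commission errors (button presses on NoGo trials) are
   Poisson counts per participant, `CE ~ 1 + Group + (1 | ID)` with a
   log-exposure offset, reported per 80 NoGo trials and as an error-rate
   percentage.  All intervals are 95% highest-posterior-density (HPD)
   intervals; PSIS-LOO model comparison is available.

3. **fNIRS first level.**  Raw two-wavelength (760/850 nm) intensity is
   downsampled 4.5 → 0.6 Hz, converted to optical density and then to
   HbO/HbR concentration changes via the modified Beer–Lambert law
   (partial pathlength factor 0.1), and fitted per channel with a GLM:
   16-s boxcar regressors convolved with a canonical double-gamma HRF,
   cosine drift terms up to 0.01 Hz, all principal components of the 8-mm
   short channels as systemic nuisance regressors, and an AR(1) noise
   model.  Channel amplitudes (20–40 mm separations only) are pooled per
   ROI (LIFG, LPFC, MPFC, RPFC, RIFG) by inverse-variance weighting.

4. **Second level.**  A bivariate hierarchical Gaussian model of
   (HbO, HbR) amplitudes with correlated participant random effects,
   marginal contrasts (AllGo−Mixed per ROI; Control−Synchronized per
   ROI × block type), the HbO−HbR difference statistic *d* = β_HbO −
   β_HbR with its negative-correlation (cortical-vs-systemic) filter, and
   a brain–behaviour model linking *d* to reaction times and commission
   errors.

Because raw recordings of such experiments are rarely shareable, the
package ships first-class synthetic generators (`dyadsync.synthetic`) for
all three data streams, with known ground truth and packaged defaults
calibrated so the full analysis chain reproduces the reference estimates
it documents (similarity 0.80 synchronized / 0.43 control; block-type RT
effect 146.8 ms; group RT effect 18.1 ms; commission-error group
difference 2.93).  Every analysis stage is verified by parameter recovery
against its generator.

## Worked example

```python
from dyadsync import (MotionParams, generate_dyad_motion, dyad_similarity,
                      BehaviourParams, generate_behaviour,
                      generate_task_schedule, fit_rt_model, fit_ce_model)

sync = dyad_similarity(*generate_dyad_motion(MotionParams(seed=0)))
ctrl = dyad_similarity(*generate_dyad_motion(
    MotionParams(regime="control", seed=0)))
print(f"synchronized dyad: mean similarity {sync.mean:.3f}")
print(f"control dyad:      mean similarity {ctrl.mean:.3f}")

schedule = generate_task_schedule(seed=1, n_blocks=20)
trials = generate_behaviour(BehaviourParams(n_per_group=20, seed=2), schedule)
rt = fit_rt_model(trials, seed=3)
for name in ("block_effect_ms", "group_effect_ms"):
    s = rt.summaries[name]
    print(f"{name}: {s.mean:.1f} ms, 95% HPD [{s.hpd_lo:.1f}, {s.hpd_hi:.1f}]")
ce = fit_ce_model(trials, seed=4)
s = ce.summaries["group_effect_count"]
print(f"commission-error group effect: {s.mean:.2f} errors per 80 NoGo "
      f"trials, 95% HPD [{s.hpd_lo:.2f}, {s.hpd_hi:.2f}]")
```

prints

```
synchronized dyad: mean similarity 0.799
control dyad:      mean similarity 0.428
block_effect_ms: 144.8 ms, 95% HPD [140.1, 149.8]
group_effect_ms: 16.9 ms, 95% HPD [5.9, 26.2]
commission-error group effect: 2.67 errors per 80 NoGo trials, 95% HPD [-0.89, 6.60]
```

The two regimes separate cleanly on the similarity score; responses are
~145 ms slower in blocks that require response inhibition (Mixed); the
observed (Synchronized) group responds ~17 ms slower but makes ~2.7 fewer
commission errors — a speed–accuracy trade-off.

A full simulate → score → fit → report run, with cached stages and a
manifest of seeds and file hashes:

```bash
dyadsync run --seed 7 --out runs/demo
dyadsync report runs/demo
```

## Layout

| module | contents |
|---|---|
| `dyadsync.pose` | keypoint I/O, imputation, smoothing, Laplacian similarity |
| `dyadsync.behaviour` | trial parsing, questionnaire scoring, descriptives, RT/CE models |
| `dyadsync.fnirs` | montage, Beer–Lambert, design matrix, AR(1) GLM, ROI pooling |
| `dyadsync.inference` | bivariate model, contrasts, HbO−HbR difference, brain–behaviour |
| `dyadsync.synthetic` | task schedule, dyad motion, behaviour and fNIRS generators |
| `dyadsync.pipeline` | end-to-end runs, manifest/caching, markdown report |
| `dyadsync._bayes` | posterior engine (marginal Laplace + exact conditionals), HPD, LOO |

See `docs/methods.md` for the statistical models, the inference scheme,
generator calibration and known limitations.
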