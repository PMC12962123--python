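# facedecode

Time-resolved EEG decoding and representational similarity analysis
(RSA) of facial signals — emotional valence and perceived sex — with a
ground-truth synthetic-data generator, for researchers who study rapid
visual processing with multivariate EEG methods.

When people view a face, different social signals become available to
the brain at different times.  This package implements the full
analysis chain used to ask *when*: behavioral 9-point ratings of
hundreds of naturalistic face images are aggregated into attribute
scores; epoched EEG is decoded timepoint by timepoint with linear
discriminant analysis (LDA); representational geometry is compared
between brain and behavior; and Bayes-factor time series with interval
nulls decide when information is reliably present, yielding onset and
peak latencies with bootstrap confidence intervals.

## The method in brief

**Decoding.**  At each timepoint t, a two-class LDA with analytically
shrunk pooled covariance (shrinkage toward scaled identity) classifies
the 64-channel pattern x(t).  Pairwise image decoding runs every
unordered stimulus pair through leave-one-block-out cross-validation
(12 blocks; each block contains every stimulus once) and averages the
n(n−1)/2 pair accuracies; class decoding contrasts the k lowest- vs k
highest-rated stimuli, holding out one exemplar of each class *and*
one block per fold (k × 12 folds), so above-chance accuracy implies
generalization to unseen faces.

**RSA.**  The neural representational dissimilarity matrix (RDM) at
time t is the matrix of cross-validated pairwise decoding accuracies
(or, optionally, 1 − r between condition mean patterns); the behavioral
RDM is |mean rating i − mean rating j|.  Their correspondence is
Spearman's ρ per subject and timepoint, averaged across subjects, and
interpreted against a leave-one-participant-out lower-bound noise
ceiling.

**Inference.**  At each timepoint a one-sample Jeffreys–Zellner–Siow
Bayes factor (Cauchy prior, scale 0.707) weighs the evidence that the
standardized effect δ lies outside a null interval ([0, 0.5] one-sided
for accuracies, [−0.5, 0.5] two-sided for correlations) against inside
it.  BF₁₀ > 10 sustained over ≥ 2 consecutive samples counts as a
decision; the first post-stimulus decided sample is the onset latency,
CIs come from a subject-level percentile bootstrap.

Because real recordings are not bundled, a synthetic-data module
generates rating tables, stimulus images, and epoched EEG with known
injected effects (onsets, peaks, amplitudes, spatial patterns), so
every stage is testable end to end and parameter recovery can be
verified.  See `docs/methods.md` for the full model and all numerical
choices.

## Worked example

Simulate a small high-SNR study (40 stimuli, 8 subjects, 24 channels,
12 blocks) in which the valence signal turns on at 80 ms and the
perceived-sex signal at 110 ms, then recover both latencies:

```python
import facedecode as fd
from facedecode import behavior, decoding, inference

cfg = fd.SimConfig.desk_scale(
    seed=3, n_stimuli=40, n_human=36, trials_per_sequence=20,
    n_subjects=8, n_channels=24, epoch_window=(-100.0, 300.0),
    class_effect={"valence": fd.ClassEffect(80.0, 120.0, amplitude=3.0, spatial_pattern_seed=11),
                  "sex": fd.ClassEffect(110.0, 150.0, amplitude=3.0, spatial_pattern_seed=12)},
    image_effect_amplitude=0.3,
)
catalog = fd.make_catalog(cfg)
schedule = fd.build_schedule(cfg)

for attr in ("valence", "sex"):
    scores = behavior.aggregate(fd.simulate_ratings(catalog, cfg, attr),
                                expected_ids=catalog["stimulus_id"])
    split = behavior.select_extremes(scores, k=10)
    tcs = [decoding.class_decoding(fd.simulate_epochs(catalog, schedule, cfg, subject_seed=100 + s)[0],
                                   split, pairing_seed=0)
           for s in range(cfg.n_subjects)]
    group = decoding.group_average(tcs)
    est = inference.latency(group.subject_stack, group.times, 0.5,
                            inference.BFConfig.for_accuracy(), n_boot=100, seed=1)
    print(f"{attr}: onset {est.onset_ms:.2f} ms (95% CI [{est.ci95_onset[0]:.2f}, {est.ci95_onset[1]:.2f}]), "
          f"peak {est.peak_ms:.2f} ms, peak accuracy {est.peak_value:.3f}")
```

Output (≈2 minutes on one CPU):

```
valence: onset 82.03 ms (95% CI [82.03, 82.03]), peak 148.44 ms, peak accuracy 0.996
sex: onset 113.28 ms (95% CI [15.62, 113.28]), peak 128.91 ms, peak accuracy 1.000
```

Both onsets land on the first sample of the 256 Hz grid after the
injected onset (82.03 ms for 80 ms, 113.28 ms for 110 ms) and in the
correct order — the valence signal is detected before the sex signal.
At ceiling-level SNR the peak time is only loosely identified (the
accuracy curve saturates), and with 8 subjects an occasional bootstrap
resample can produce a spuriously early onset, visible as the wide
lower CI bound for the sex attribute.

The same pipeline runs from the shell:

```bash
facedecode run --out results/demo --seed 1        # simulate → … → infer
facedecode simulate --out sim --seed 1            # individual stages
facedecode decode pairwise --epochs sim/sub-00 --out tc.csv
facedecode infer latency --tc tc.csv --out latency.json --null-interval 0,0.5
```

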