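# pcgclassify

Classification of heart sounds from phonocardiogram (PCG) recordings.

Auscultation distinguishes a surprising number of acoustic events: the
normal "lub-dub" tones S1/S2, the low-frequency gallop sounds S3/S4, and
variant or pathological morphologies — ejection clicks, split S1/S2, opening
snaps, systolic murmurs, diastolic rumbles. Automatic identification of
these twelve classes is hard because PCG signals are non-stationary (each
tone is a short burst of variable length) and the classes differ by subtle
spectral detail. This package implements a hybrid pipeline for that
problem, aimed at researchers prototyping auto-auscultation methods:

1. **Variable-window segmentation** — a normalized Shannon-energy envelope
   isolates each heart tone in a window sized to that tone.
2. **LPC features** — every segment is fitted with a 24th-order all-pole
   model `H(z) = G / (1 + Σ_{k=1}^{24} a_k z^{-k})` via Levinson–Durbin;
   the denominator coefficients `a_1..a_24` summarize the spectral envelope
   and are the (amplitude-invariant) feature vector.
3. **SVM-MCS classifier** — m one-against-others soft-margin SVMs (one per
   class), predicting by argmax of decision values. A Modified Cuckoo
   Search selects, jointly: which of the 24 coefficients are used (a shared
   binary mask) and, per classifier, the kernel (linear / quadratic /
   polynomial / RBF), its parameter (u or σ) and the penalty C — a
   mixed space of dimension 24 + 3m. Fitness is the leave-one-out average
   **balanced accuracy** (sensitivity + specificity)/2, or alternatively the
   support-vector count.

Because no free heart-sound corpus exists, a first-class synthetic generator
(`pcgclassify.synth`) renders seeded, labeled recordings of all twelve
classes (damped sinusoids for tones, enveloped bandpass noise for murmurs,
with per-realization jitter) at the study scale of 6 recordings per class.
See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
import numpy as np
from pcgclassify import generate_dataset, MCSConfig, RunConfig, run_experiment

data_dir = "pcg_data"
generate_dataset(per_class_count=6, sample_rate=4000.0, seed=42).write(data_dir)

config = RunConfig(mcs=MCSConfig(n_nests=15, max_generations=20, seed=1))
table, models = run_experiment(config, data_dir, out_dir="run")
print(table.frame.loc[["Average", "Average var."]].round(2))
```

which prints (a few minutes; the search retrains 12 classifiers in a
72-fold leave-one-out loop per fitness evaluation):

```
              SVM-MCS  svm-poly  svm-rbf  svm-quad
Average         92.42     90.91    87.88     89.39
Average var.   154.12    204.73   315.97    337.05
```

Reading: each column is one trained system; rows (not shown) give the
per-class balanced accuracy of its leave-one-out predictions, `Average` the
unweighted mean over the 12 classes, `Average var.` the variance of the
per-class values. The MCS-tuned ensemble (92.4 %) outperforms every
fixed-kernel baseline trained on all 24 coefficients, which is the point of
the joint feature/kernel/penalty search.

The same flow is available from the shell:

```sh
pcgclassify synth --per-class 6 --seed 42 --out pcg_data
pcgclassify compare pcg_data --nests 15 --generations 20 --seed 1 --out run
pcgclassify classify pcg_data/S3-00.wav --model run/model_SVM-MCS.json
```

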