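# pollenspect

Computer-aided diagnosis of thyroid disorders from planar SPECT scintigrams,
built as a reusable training framework around two ideas:

* a **weighted DenseNet** — a dense-block CNN in which every skip connection
  carries a trainable scalar weight k_{l,i}, so layer *l* computes
  y_l = F_l(k_{l,0}·x_0, …, k_{l,l−1}·x_{l−1}; W_l) and learns how much each
  earlier feature map matters, with dilated-convolution downsampling in place
  of pooling; and
* **per-minibatch learning-rate search** — before each SGD commit
  w ← w − l·∇w, the scalar rate l is optimized by the flower pollination
  algorithm on the fitness f(l) = C(w − l·∇w) of the *current* minibatch,
  seeded with the previously committed rate so that no step is ever worse
  than fixed-rate SGD on that minibatch.

The four diagnostic classes are Graves' disease, Hashimoto disease, subacute
thyroiditis and normal. Because clinical SPECT archives are not publicly
shareable, the package ships a seeded synthetic generator producing
class-separable butterfly-shaped uptake patterns (enlarged/bright for
Graves', patchy for Hashimoto, suppressed for subacute) at the emulated
cohort sizes 780/438/810/860, plus mixup balancing of every class to 2000
samples (α ~ U[0.5, 1], soft labels) and a 1400/600 per-class train/test
split. Evaluation reports a column-=-actual confusion matrix and per-class
one-vs-rest recall, precision, accuracy, specificity and F1.

The network and training loop run on a compact float64 autodiff engine
included in the package; see `docs/methods.md` for the model, the design
decisions and what the synthetic experiments do and do not demonstrate.

## Worked example

```python
from pollenspect import (MixupConfig, NetworkConfig, SpectClassifier,
                         TrainConfig, augment_and_split, generate_dataset)
from pollenspect.fpa import FPAConfig

images = generate_dataset({"graves": 60, "hashimoto": 40,
                           "subacute": 60, "normal": 60},
                          image_size=32, seed=7)
mix = MixupConfig(target_per_class=100, train_per_class=80, test_per_class=20)
train_set, test_set = augment_and_split(images, mix, seed=8)

clf = SpectClassifier(
    train_set,
    NetworkConfig.preset("tiny"),
    TrainConfig(batch_size=5, max_epochs=3, lr_init=0.05,
                fpa=FPAConfig(n_iterations=3, n_pollen=5), seed=9))
results = clf.fit()
print(results.summary(test_set))
```

prints

```
Weighted-DenseNet thyroid SPECT classifier
============================================
blocks: (3, 3), growth rate 8, input 32x32, downsample dilated_conv
trainable parameters: 5978 (of which 6 skip-connection weights)
epochs run: 3; best validation loss 0.8227; final validation macro precision 0.3300
committed learning rates: median 0.5, range [0.2892, 0.5]
skip weights: mean 1.0006, min 0.9250, max 1.0760

test metrics (percent):
        Metric        graves     hashimoto      subacute        normal
        Recall         95.00          0.00         90.00        100.00
     Precision        100.00                       90.00         48.78
      Accuracy         98.75         75.00         95.00         73.75
   Specificity        100.00        100.00         96.67         65.00
      F1 score         97.44          0.00         90.00         65.57
  micro accuracy: 71.25
```

Reading the output: after three epochs at this very small scale the model
already separates Graves' (bright, enlarged gland) and subacute (suppressed
uptake) almost perfectly, while Hashimoto — whose patchy pattern is the
subtlest — is still absorbed into the normal column (its precision is blank
because nothing was predicted Hashimoto yet: undefined metrics are reported
as empty, never as 0 or 100). The skip weights have moved off their neutral
initialization of 1.0, and the committed learning rates show the
per-minibatch search favouring much larger steps than the 0.05 incumbent.
Longer desk-scale runs (see below) reach macro precision well above chance.

The same pipeline is available from the shell:

```sh
pollen-train generate --counts graves=60,hashimoto=40,subacute=60,normal=60 \
    --size 32 --seed 7 --out data/
pollen-train augment --in data/ --out aug/ --target 100 --train 80 --test 20
pollen-train train --data aug/ --out run/
pollen-train evaluate --model run/checkpoint.npz --data aug/ --out report/
pollen-train diagnose --model run/checkpoint.npz data/graves_00000.png
pollen-train run --config cfg.yaml --out run/      # everything end to end
```

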