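# apiscan

Acoustic classification of honey-bee swarming activity from in-hive audio.

Swarming — the old queen leaving with part of the colony — is the event a
beekeeper most wants to know about immediately, and it announces itself
acoustically: queen *piping* (a 340–450 Hz challenge tone), defensive
*hissing* (a noise band near 3 kHz) and intensified *flying* hum (~250 Hz)
stand out against the everyday soundscape of flying and ventilation
*fanning* (225–285 Hz). `apiscan` classifies 3-second, 16 kHz mono clips
as **normal** or **swarm** activity using the classical speech-recognition
toolchain:

- **Front-ends** — 12 Mel-frequency cepstral coefficients plus log energy,
  extended with Δ and ΔΔ regression coefficients to 39 dimensions per
  25 ms frame (10 ms shift, Hamming window), with optional cepstral mean
  normalization; or order-12 LPC via the Levinson–Durbin recursion in the
  same 39-dimensional layout.
- **Acoustic models** — left–right continuous-density HMMs (15-state or
  1-state, plus a silence model) with diagonal-covariance Gaussian-mixture
  emissions, trained by embedded Baum–Welch in two stages: flat start and
  mixture doubling to 16 components, forced-alignment outlier filtering,
  then per-class re-initialization and doubling to 32 components.
  Alternatively, per-class GMMs with frame-level scoring and a
  majority-vote clip decision.
- **Noise tooling** — SNR-controlled mixing of synthetic urban street
  noise and Boll-style spectral-subtraction denoising.
- **Synthetic corpus** — a deterministic soundscape generator producing
  labeled hive clips with the spectral signatures above, so the entire
  pipeline trains and evaluates without any field recordings.

Evaluation reports accuracy `Acc = H/N · 100` (H correct clips of N),
precision/recall/F1 with swarm as the positive class, the confusion
table, and the real-time factor.

## Worked example

```python
import apiscan as ap
from apiscan import pipeline as pl

ds = ap.synth_dataset(n_train_per_class=30, n_test_per_class=10,
                      master_seed=1)
train = pl.dataset_features(ds, "train", "mfcc")
test = pl.dataset_features(ds, "test", "mfcc")

cfg = pl.TrainingConfig(architecture="hmm_15", stage2_target_m=8,
                        snapshot_at=(2, 8))
system = pl.train_pipeline(train, cfg)
print("outlier fraction:", system.log["outlier_fraction"])

hyp = pl.classify_batch(system.final_models, test, "hmm_15")
report = pl.evaluate([label for _, label in test], hyp)
print(f"Acc = {report.acc:.2f}%  P = {report.precision:.2f} "
      f"R = {report.recall:.2f}  F1 = {report.f1:.2f}")
```

Output:

```
outlier fraction: 0.0
Acc = 100.00%  P = 1.00 R = 1.00  F1 = 1.00
```

The 20-clip test split of this miniature corpus is fully separable; the
`Acc` line means all 20 held-out clips (10 normal, 10 swarm) were
classified correctly, and the forced-alignment filter found no outlier
clips in the clean synthetic training set. At benchmark scale
(300 training clips per class) the complexity gradient becomes visible:
2-component models sit measurably below the 8- and 32-component ones.

The same flow is available from the shell:

```sh
apiscan synth --out data/ --n-train 300 --n-test 100 --seed 1
apiscan train --data data/ --model-out models.txt --arch hmm15 --features mfcc
apiscan evaluate --model models.txt --data data/ --arch hmm15
apiscan classify --model models.txt --arch hmm15 data/test/swarm_0001.wav
```

## Layout

```
src/apiscan/
  audio_io.py        WAV I/O, canonicalization, segmentation, manifests
  preprocess.py      preemphasis/framing, SNR mixing, spectral subtraction
  features.py        MFCC (+CMN), deltas, LPC (Levinson–Durbin)
  hmm_core.py        left-right HMMs, Baum–Welch, Viterbi, alignment
  gmm_classifier.py  per-class GMMs, frame votes, majority decision
  pipeline.py        training recipes, evaluation metrics, RTF, footprint
  synthetic_data.py  deterministic hive soundscape generator
  cli.py             `apiscan` command-line interface
docs/methods.md      model and design notes
```
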