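# vmdecg

Simulation-grounded arrhythmia signal classification: Hodgkin-Huxley
action-potential simulation, variational mode decomposition (VMD) tuned by a
multi-objective crayfish optimizer, and a multi-head-attention classifier,
with TPE hyperparameter search.

## Who this is for

Researchers in biomedical signal processing who want a self-contained,
reproducible testbed in which the *mechanism* of an arrhythmia is known by
construction: instead of starting from recorded ECGs, the three signal
classes are generated from the Hodgkin-Huxley membrane model

    Cm dV/dt = I - gNa m^3 h (V - ENa) - gK n^4 (V - EK) - gL (V - EL),

either unmodified (model 0) or perturbed by the exponentially attenuated
sinusoid Psi(t) = e^(-4t) sin(2 pi t) applied to the stimulus current
(model 1) or to the sodium-inactivation kinetics dh/dt (model 2).  Every
stage downstream of the generator — decomposition, tuning, classification,
hyperparameter search — is ordinary signal-processing/ML machinery that
transfers to real recordings (an MIT-BIH/WFDB loading path is included).

## The method

1. **Simulate**: noisy, periodized membrane-potential records at 300 Hz
   (3000 records, 1000 per class, Gaussian noise sigma = 5 mV, 90/10
   stratified split).
2. **Tune the decomposition**: VMD splits each record into K band-limited
   modes under bandwidth penalty alpha.  The pair (K, alpha), K in [3, 8],
   alpha in [500, 5000], is chosen by a multi-objective crayfish optimizer
   (MOCOA: temperature-gated summer-resort / competition / foraging moves +
   fast non-dominated sorting + special crowding distance) minimizing two
   mode-quality indicators at once: aggregate spectral kurtosis
   SK(f) = <|X(f)|^4>/<|X(f)|^2>^2 - 2 and the KL divergence between mode
   and signal amplitude distributions.  One point is picked from the Pareto
   front by distance to the ideal point.
3. **Classify**: the decomposed modes are framed into tokens and fed to a
   Transformer-encoder classifier (scaled dot-product attention,
   softmax(QK^T/sqrt(d_k))V, 4 heads, 2 layers), trained with momentum SGD;
   batch size, learning rate, epochs and momentum can be tuned by a
   tree-structured Parzen estimator.

## Worked example

```python
from vmdecg import (make_dataset, tune_vmd, VMDConfig,
                    AttentionClassifier, TrainHyperparams)
from vmdecg.pipeline import decompose_dataset

ds = make_dataset(seed=1)                      # 3000 labeled noisy records
sig = next(s for s in ds.signals if s.label == "model0")
front, (K, alpha), obj = tune_vmd(sig.samples, N=40, T=60, seed=1)
print(K, round(alpha, 1), round(obj.sk, 3), round(obj.dkl, 1))
# 5 4299.0 1.319 105.1

modes = decompose_dataset(ds, VMDConfig(K=K, alpha=alpha, max_iter=200))
model = AttentionClassifier(modes, ds.y)
res = model.fit(ds.train_idx, ds.test_idx,
                TrainHyperparams(epochs=5, batch_size=32,
                                 learning_rate=0.01, momentum=0.9, seed=1))
print(res.summary())
# Attention classifier results
# ----------------------------
# test accuracy: 100.00%
# per-class accuracy: 100.00%, 100.00%, 100.00%
# confusion matrix (rows = true):
#     100      0      0
#       0    100      0
#       0      0    100
# hyperparameters: batch=32, lr=0.01, epochs=5, momentum=0.9, seed=1
```

The tuned (K, alpha) sits on a Pareto front trading spectral kurtosis
against KL divergence (more modes lower the per-mode kurtosis but drive the
mode histograms further from the source signal's).  On this synthetic
dataset the three classes differ by construction in their nonlinear
dynamics, so the classifier separates them essentially perfectly; see
`docs/methods.md` for what that does and does not demonstrate.

There is also a CLI covering each stage (`vmdecg simulate | decompose |
tune-vmd | train | tune-hyper | ablate | run-all | benchmark |
mitbih-prepare`); `vmdecg run-all --config cfg.yaml` executes the whole
chain and writes every intermediate artifact with a content-hash manifest.

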